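"""Delaunay neighbor graph over cell records.

Cells are treated as points in the 40x pixel plane; the Delaunay
triangulation of those points defines which cells are neighbors (every
triangle edge is a neighbor relation).  Edges longer than a threshold —
spurious neighbor relations across tissue gaps or along the convex hull —
are pruned before any downstream use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import Delaunay, QhullError

from .cell_model import CellClass, CellRecord, is_epithelial
from .errors import GraphError, ParameterError

__all__ = [
    "CellGraph",
    "build_delaunay_graph",
    "prune_long_edges",
    "connected_components",
    "write_graphml",
    "DEFAULT_MAX_EDGE_LEN",
]

#: Neighbor relations longer than this many 40x pixels are deleted.
DEFAULT_MAX_EDGE_LEN = 500.0

#: Jitter amplitude applied to exactly co-located points so the
#: triangulation is defined; original coordinates are retained on nodes.
_DEGENERACY_EPS = 1e-6


@dataclass
class CellGraph:
    """Undirected neighbor graph with per-node cell metadata.

    ``graph`` is a networkx graph whose nodes are cell ids (with
    ``cell_class``/``x``/``y`` attributes) and whose edges carry the
    Euclidean ``length`` in 40x pixels, computed from the original (unjittered)
    coordinates.
    """

    graph: nx.Graph
    cells: dict[int, CellRecord] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors(self, node: int) -> list[int]:
        return list(self.graph.neighbors(node))

    def cell_class(self, node: int) -> CellClass:
        return self.cells[node].cell_class

    def epithelial_nodes(self) -> list[int]:
        return [n for n, c in self.cells.items() if is_epithelial(c.cell_class)]


def build_delaunay_graph(cells: Sequence[CellRecord], seed: int = 0) -> CellGraph:
    """Triangulate cell positions and return the unique-edge neighbor graph.

    Exactly co-located points (possible in real tables when two detections
    share a centroid) are perturbed by a deterministic jitter of amplitude
    1e-6 px before triangulation; node coordinates and edge lengths keep the
    original values.

    Raises :class:`GraphError` for fewer than 3 points or an all-collinear
    input, where the triangulation is undefined.
    """
    if len(cells) < 3:
        raise GraphError("triangulation undefined: fewer than 3 points")
    ids = [c.id for c in cells]
    if len(set(ids)) != len(ids):
        raise GraphError("duplicate cell ids in input")
    pts = np.array([[c.x, c.y] for c in cells], dtype=float)

    tri_pts = pts
    # jitter only the duplicated coordinates, deterministically
    _, first_idx, inverse = np.unique(pts, axis=0, return_index=True, return_inverse=True)
    if len(first_idx) < len(pts):
        rng = np.random.default_rng(seed)
        tri_pts = pts.copy()
        dup_mask = np.ones(len(pts), dtype=bool)
        dup_mask[first_idx] = False
        tri_pts[dup_mask] += rng.uniform(-_DEGENERACY_EPS, _DEGENERACY_EPS, (dup_mask.sum(), 2))
    if len(np.unique(tri_pts, axis=0)) < 3:
        raise GraphError("triangulation undefined: fewer than 3 distinct points")

    try:
        tri = Delaunay(tri_pts)
    except QhullError as exc:
        raise GraphError(f"triangulation undefined: {exc}") from exc
    if tri.simplices.size == 0:
        raise GraphError("triangulation undefined: degenerate (collinear) input")

    g = nx.Graph()
    for c in cells:
        g.add_node(c.id, x=c.x, y=c.y, cell_class=c.cell_class.value, is_pseudo=c.is_pseudo)
    simplices = tri.simplices
    for a, b in ((0, 1), (1, 2), (0, 2)):
        for i, j in zip(simplices[:, a], simplices[:, b]):
            u, v = ids[i], ids[j]
            if not g.has_edge(u, v):
                length = float(np.hypot(*(pts[i] - pts[j])))
                g.add_edge(u, v, length=length)
    return CellGraph(graph=g, cells={c.id: c for c in cells})


def prune_long_edges(graph: CellGraph, max_edge_len: float = DEFAULT_MAX_EDGE_LEN) -> CellGraph:
    """Remove edges strictly longer than ``max_edge_len`` pixels.

    The threshold is inclusive: an edge of exactly ``max_edge_len`` is a
    neighbor relation, one any longer is not.  Nodes are untouched and the
    operation is idempotent.
    """
    if not max_edge_len > 0:
        raise ParameterError(f"max_edge_len must be > 0, got {max_edge_len}")
    g = graph.graph.copy()
    too_long = [(u, v) for u, v, d in g.edges(data="length") if d > max_edge_len]
    g.remove_edges_from(too_long)
    return CellGraph(graph=g, cells=dict(graph.cells))


def connected_components(
    graph: CellGraph, node_filter: Callable[[CellRecord], bool] | None = None
) -> list[set[int]]:
    """Connected components of the subgraph induced by ``node_filter``.

    Returns maximal connected node-id sets, ordered by smallest member for
    determinism.  With no filter, components of the whole graph.
    """
    if node_filter is None:
        sub = graph.graph
    else:
        keep = [n for n, c in graph.cells.items() if node_filter(c)]
        sub = graph.graph.subgraph(keep)
    comps = [set(c) for c in nx.connected_components(sub)]
    comps.sort(key=min)
    return comps


def write_graphml(graph: CellGraph, path: str | Path) -> None:
    """Export the pruned graph for external inspection (classes as strings)."""
    nx.write_graphml(graph.graph, str(path))
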