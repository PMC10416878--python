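"""Layer counting by wave-front peeling over the cell neighbor graph.

The epithelium is a stratified sheet: basal cells sit on the stroma (the
*inner* edge) and the outermost nucleated cells face the stratum corneum or
the slide background (the *outer* edge).  Given the pruned Delaunay neighbor
graph, the procedure is:

1. classify every epithelial node by its neighbors — a background/corneum
   neighbor makes it an outer-edge point, a stroma neighbor an inner-edge
   point (both conditions at once: a one-cell-thick sheet);
2. drop small disconnected epithelial components (slivers and crack
   fragments) by re-labeling their nodes NON_EDGE;
3. expand a synchronous wave from the outer-edge seeds through epithelial
   nodes only, one layer per step; the wave index at which each inner-edge
   node is first reached is its layer count.

The layer count therefore satisfies ``count(v) = 1 + min-hop(seed set, v)``
within the epithelial subgraph, and the per-slide thickness is the median of
the inner-edge counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .cell_graph import (
    CellGraph,
    DEFAULT_MAX_EDGE_LEN,
    build_delaunay_graph,
    connected_components,
    prune_long_edges,
)
from .cell_model import CellClass, CellRecord, LayerCountResult, is_epithelial
from .errors import ParameterError, PeelingError

__all__ = [
    "NodeRole",
    "EdgeLabeling",
    "classify_edge_points",
    "filter_small_components",
    "peel_layers",
    "summarize_slide",
    "count_layers",
    "DEFAULT_MIN_COMPONENT_SIZE",
]

#: Epithelial components smaller than this are re-categorized NON_EDGE.
DEFAULT_MIN_COMPONENT_SIZE = 20


class NodeRole(str, Enum):
    """Role of a node in the peeling traversal."""

    OUTER_EDGE = "outer_edge"  # epithelial, has a background/corneum neighbor
    INNER_EDGE = "inner_edge"  # epithelial, has a stroma neighbor
    BOTH = "both"              # both of the above (one-cell-thick sheet)
    INTERIOR = "interior"      # epithelial, neither
    NON_EDGE = "non_edge"      # epithelial but in a filtered small component
    NON_EPITHELIAL = "non_epithelial"


_EPITHELIAL_ROLES = frozenset(
    {NodeRole.OUTER_EDGE, NodeRole.INNER_EDGE, NodeRole.BOTH, NodeRole.INTERIOR, NodeRole.NON_EDGE}
)


@dataclass
class EdgeLabeling:
    """Per-node role assignment produced by edge-point classification."""

    roles: dict[int, NodeRole]

    def __post_init__(self) -> None:
        for node, role in self.roles.items():
            if not isinstance(role, NodeRole):
                raise ParameterError(f"node {node}: invalid role {role!r}")

    def outer_seeds(self) -> set[int]:
        return {n for n, r in self.roles.items() if r in (NodeRole.OUTER_EDGE, NodeRole.BOTH)}

    def inner_targets(self) -> set[int]:
        return {n for n, r in self.roles.items() if r in (NodeRole.INNER_EDGE, NodeRole.BOTH)}

    def epithelial(self) -> set[int]:
        return {n for n, r in self.roles.items() if r in _EPITHELIAL_ROLES}


def classify_edge_points(graph: CellGraph) -> EdgeLabeling:
    """Label every node by the classes among its graph neighbors.

    For an epithelial node (BASAL / EPITHELIAL_OTHER / LYMPHOCYTE): any
    BACKGROUND or CORNEUM neighbor makes it OUTER_EDGE; any STROMA neighbor
    makes it INNER_EDGE; both conditions make it BOTH; neither, INTERIOR.
    STROMA/CORNEUM/BACKGROUND nodes are NON_EPITHELIAL — they provide
    classification context and are never traversed.
    """
    roles: dict[int, NodeRole] = {}
    for node, cell in graph.cells.items():
        if not is_epithelial(cell.cell_class):
            roles[node] = NodeRole.NON_EPITHELIAL
            continue
        outer = inner = False
        for nb in graph.graph.neighbors(node):
            nb_class = graph.cells[nb].cell_class
            if nb_class in (CellClass.BACKGROUND, CellClass.CORNEUM):
                outer = True
            elif nb_class is CellClass.STROMA:
                inner = True
        if outer and inner:
            roles[node] = NodeRole.BOTH
        elif outer:
            roles[node] = NodeRole.OUTER_EDGE
        elif inner:
            roles[node] = NodeRole.INNER_EDGE
        else:
            roles[node] = NodeRole.INTERIOR
    return EdgeLabeling(roles=roles)


def filter_small_components(
    graph: CellGraph,
    labeling: EdgeLabeling,
    min_component_size: int = DEFAULT_MIN_COMPONENT_SIZE,
) -> EdgeLabeling:
    """Re-label small epithelial components as NON_EDGE.

    Connected components are taken over the subgraph induced by epithelial
    nodes (the full graph is usually globally connected through stroma and
    pseudo-points, which would make the filter vacuous).  Components with
    strictly fewer than ``min_component_size`` cells — detached crack
    fragments, small connective slivers — have all their nodes set to
    NON_EDGE; larger components are untouched.  Monotone: raising the
    threshold never restores an edge role.
    """
    if min_component_size < 1:
        raise ParameterError(f"min_component_size must be >= 1, got {min_component_size}")
    roles = dict(labeling.roles)
    for comp in connected_components(graph, node_filter=lambda c: is_epithelial(c.cell_class)):
        if len(comp) < min_component_size:
            for node in comp:
                roles[node] = NodeRole.NON_EDGE
    return EdgeLabeling(roles=roles)


def peel_layers(graph: CellGraph, labeling: EdgeLabeling, slide_id: str = "") -> LayerCountResult:
    """Run the peeling wave-front and collect inner-edge layer counts.

    All OUTER_EDGE and BOTH nodes seed the wave at layer 1.  Each expansion
    step visits the unvisited epithelial neighbors of the whole current
    frontier at once (breadth-synchronous, so the result is independent of
    node iteration order) and increments the layer index.  When an
    INNER_EDGE node is first visited, the current layer index becomes its
    layer count; BOTH nodes count 1.  The wave never enters stroma, corneum
    or background nodes — letting it cross the stroma would short-circuit
    folds of the epithelium.  Inner-edge nodes in components with no outer
    seed are reported as unreachable, excluded from the summary.
    """
    seeds = labeling.outer_seeds()
    targets = labeling.inner_targets()
    if not seeds:
        raise PeelingError("no outer boundary found")
    if not targets:
        raise PeelingError("no inner boundary found")

    traversable = labeling.epithelial()
    counts: dict[int, int] = {}
    visited: set[int] = set(seeds)
    wave = set(seeds)
    layer = 1
    for node in wave & targets:  # BOTH nodes: one-cell-thick, layer 1
        counts[node] = layer
    adj = graph.graph
    while wave:
        nxt: set[int] = set()
        for node in wave:
            for nb in adj.neighbors(node):
                if nb in traversable and nb not in visited:
                    nxt.add(nb)
        if not nxt:
            break
        layer += 1
        visited |= nxt
        for node in nxt & targets:
            counts[node] = layer
        wave = nxt

    unreachable = targets - counts.keys()
    return LayerCountResult.from_counts(counts, unreachable_ids=unreachable, slide_id=slide_id)


def summarize_slide(result: LayerCountResult, quantile: float = 0.5) -> dict:
    """Slide-level summary: a quantile (default the median) and population SD.

    The 0.5 quantile of all inner-edge layer counts is the slide's epithelial
    thickness; the SD measures thickness variability.  Quantiles use the
    linear-interpolation convention; SD uses ddof=0.  With no reached
    inner-edge nodes the summary fields are None and a warning is issued.
    """
    if not 0 < quantile < 1:
        raise ParameterError(f"quantile must be in (0, 1), got {quantile}")
    if not result.counts:
        warnings.warn("no reached inner-edge nodes: summary undefined", stacklevel=2)
        return {"median_layers": None, "sd_layers": None, "n_inner": 0}
    values = np.fromiter(result.counts.values(), dtype=float)
    return {
        "median_layers": float(np.quantile(values, quantile)),
        "sd_layers": float(np.std(values, ddof=0)),
        "n_inner": int(values.size),
    }


def count_layers(
    cells: Sequence[CellRecord],
    max_edge_len: float = DEFAULT_MAX_EDGE_LEN,
    min_component_size: int = DEFAULT_MIN_COMPONENT_SIZE,
    slide_id: str = "",
    seed: int = 0,
) -> LayerCountResult:
    """Full chain: triangulate, prune, classify, filter, peel.

    Convenience entry point used by the CLI and the pipeline; equivalent to
    calling the five stages explicitly.
    """
    graph = prune_long_edges(build_delaunay_graph(cells, seed=seed), max_edge_len)
    labeling = filter_small_components(
        graph, classify_edge_points(graph), min_component_size
    )
    return peel_layers(graph, labeling, slide_id=slide_id)
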