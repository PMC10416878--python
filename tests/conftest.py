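"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the implementation's code paths:
brute-force empty-circumcircle triangulation, union-find components,
exhaustive simple-path enumeration and scipy.sparse.csgraph shortest paths.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.sparse import lil_matrix
from scipy.sparse.csgraph import shortest_path

from epilayer.cell_graph import CellGraph, build_delaunay_graph, prune_long_edges
from epilayer.cell_model import CellClass, CellRecord, is_epithelial
from epilayer.onion_peeling import classify_edge_points


# ---------------------------------------------------------------------------
# graph construction helpers
# ---------------------------------------------------------------------------


def make_cells(points, classes, slide_id="t"):
    return [
        CellRecord(
            id=i,
            x=float(p[0]),
            y=float(p[1]),
            cell_class=c,
            is_pseudo=c in (CellClass.BACKGROUND, CellClass.CORNEUM),
            slide_id=slide_id,
        )
        for i, (p, c) in enumerate(zip(points, classes))
    ]


def build_graph(cells, edges):
    """CellGraph from explicit node/edge lists (no triangulation)."""
    g = nx.Graph()
    lookup = {c.id: c for c in cells}
    for c in cells:
        g.add_node(c.id, x=c.x, y=c.y, cell_class=c.cell_class.value, is_pseudo=c.is_pseudo)
    for u, v in edges:
        length = float(np.hypot(lookup[u].x - lookup[v].x, lookup[u].y - lookup[v].y))
        g.add_edge(u, v, length=length)
    return CellGraph(graph=g, cells=lookup)


def grid_strip_graph(n_layers, length, corneum_rows=1, stroma_rows=1, spacing=10.0):
    """Hand-built square-lattice strip with 4-neighbor adjacency.

    Rows top to bottom: corneum, n_layers epithelial (bottom row basal),
    stroma.  Independent of any triangulation, so every inner-edge node is
    exactly n_layers hops + 1 from the outer edge.
    """
    n_rows = corneum_rows + n_layers + stroma_rows
    points, classes = [], []
    for r in range(n_rows):
        if r < corneum_rows:
            cls = CellClass.CORNEUM
        elif r < corneum_rows + n_layers - 1:
            cls = CellClass.EPITHELIAL_OTHER
        elif r < corneum_rows + n_layers:
            cls = CellClass.BASAL
        else:
            cls = CellClass.STROMA
        for c in range(length):
            points.append((c * spacing, r * spacing))
            classes.append(cls)
    cells = make_cells(points, classes)
    edges = []
    idx = lambda r, c: r * length + c
    for r in range(n_rows):
        for c in range(length):
            if c + 1 < length:
                edges.append((idx(r, c), idx(r, c + 1)))
            if r + 1 < n_rows:
                edges.append((idx(r, c), idx(r + 1, c)))
    return build_graph(cells, edges)


def random_epithelial_graph(rng, n_max=200):
    """Random pruned Delaunay graph over a mixed-class point cloud.

    Draws until the labeling has at least one outer seed and one inner
    target.  Returns (graph, labeling).
    """
    class_pool = [
        CellClass.BASAL,
        CellClass.EPITHELIAL_OTHER,
        CellClass.LYMPHOCYTE,
        CellClass.STROMA,
        CellClass.CORNEUM,
        CellClass.BACKGROUND,
    ]
    probs = [0.2, 0.35, 0.05, 0.2, 0.1, 0.1]
    while True:
        n = int(rng.integers(12, n_max + 1))
        pts = rng.uniform(0, 400, (n, 2))
        classes = rng.choice(len(class_pool), size=n, p=probs)
        cells = make_cells(pts, [class_pool[i] for i in classes])
        graph = prune_long_edges(build_delaunay_graph(cells), 500.0)
        labeling = classify_edge_points(graph)
        if labeling.outer_seeds() and labeling.inner_targets():
            return graph, labeling


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def brute_force_delaunay_edges(points):
    """Edge set as the union of all empty-circumcircle triangles.

    O(n^4); valid for point sets in general position (no 4 cocircular).
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    edges = set()
    for i, j, k in itertools.combinations(range(n), 3):
        ax, ay = pts[i]
        bx, by = pts[j]
        cx, cy = pts[k]
        d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
        if abs(d) < 1e-12:
            continue  # collinear triple
        ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay) + (cx**2 + cy**2) * (ay - by)) / d
        uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx) + (cx**2 + cy**2) * (bx - ax)) / d
        r2 = (ax - ux) ** 2 + (ay - uy) ** 2
        empty = True
        for m in range(n):
            if m in (i, j, k):
                continue
            if (pts[m, 0] - ux) ** 2 + (pts[m, 1] - uy) ** 2 < r2 - 1e-9:
                empty = False
                break
        if empty:
            edges.update({frozenset((i, j)), frozenset((j, k)), frozenset((i, k))})
    return edges


class UnionFind:
    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, a):
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def union_find_components(nodes, edges):
    uf = UnionFind(nodes)
    for u, v in edges:
        if u in uf.parent and v in uf.parent:
            uf.union(u, v)
    groups = {}
    for node in nodes:
        groups.setdefault(uf.find(node), set()).add(node)
    return sorted(groups.values(), key=min)


def exhaustive_min_hops(graph: CellGraph, seeds, target, traversable):
    """Minimum hop count seed->target by exhaustive simple-path enumeration.

    Exponential; for graphs with at most a few dozen traversable nodes.
    Returns None when no path exists.
    """
    best = [None]

    def dfs(node, visited, depth):
        if best[0] is not None and depth >= best[0]:
            return
        if node == target:
            best[0] = depth
            return
        for nb in graph.graph.neighbors(node):
            if nb in traversable and nb not in visited:
                dfs(nb, visited | {nb}, depth + 1)

    for s in seeds:
        if s == target:
            return 0
        dfs(s, {s}, 0)
    return best[0]


def csgraph_min_hops(graph: CellGraph, seeds, traversable):
    """Min hop distance from the seed set to every traversable node (scipy)."""
    nodes = sorted(traversable)
    pos = {n: i for i, n in enumerate(nodes)}
    adj = lil_matrix((len(nodes), len(nodes)))
    for u, v in graph.graph.edges():
        if u in pos and v in pos:
            adj[pos[u], pos[v]] = 1
            adj[pos[v], pos[u]] = 1
    seed_idx = [pos[s] for s in seeds if s in pos]
    dist = shortest_path(adj.tocsr(), method="D", unweighted=True, indices=seed_idx)
    best = dist.min(axis=0)
    return {n: (None if np.isinf(best[i]) else int(best[i])) for n, i in pos.items()}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
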