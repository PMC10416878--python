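"""Edge-point classification, component filtering and the peeling wave-front."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import (
    build_graph,
    csgraph_min_hops,
    exhaustive_min_hops,
    grid_strip_graph,
    make_cells,
    random_epithelial_graph,
)
from epilayer.cell_graph import prune_long_edges
from epilayer.cell_model import CellClass, LayerCountResult
from epilayer.errors import ParameterError, PeelingError
from epilayer.onion_peeling import (
    EdgeLabeling,
    NodeRole,
    classify_edge_points,
    count_layers,
    filter_small_components,
    peel_layers,
    summarize_slide,
)
from epilayer.synthetic_data import EpitheliumSpec, generate_epithelium


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "neighbor_classes, expected",
    [
        ([CellClass.BACKGROUND], NodeRole.OUTER_EDGE),
        ([CellClass.CORNEUM], NodeRole.OUTER_EDGE),
        ([CellClass.STROMA], NodeRole.INNER_EDGE),
        ([CellClass.STROMA, CellClass.CORNEUM], NodeRole.BOTH),
        ([CellClass.EPITHELIAL_OTHER, CellClass.BASAL], NodeRole.INTERIOR),
    ],
)
def test_edge_classification_by_neighbor_type(neighbor_classes, expected):
    classes = [CellClass.EPITHELIAL_OTHER] + neighbor_classes
    pts = [(0, 0)] + [(10 * (i + 1), 0) for i in range(len(neighbor_classes))]
    g = build_graph(make_cells(pts, classes), [(0, i + 1) for i in range(len(neighbor_classes))])
    roles = classify_edge_points(g).roles
    assert roles[0] is expected


def test_non_epithelial_nodes_always_non_epithelial():
    classes = [CellClass.STROMA, CellClass.CORNEUM, CellClass.BACKGROUND, CellClass.BASAL]
    g = build_graph(make_cells([(0, 0), (10, 0), (20, 0), (30, 0)], classes), [(0, 3), (1, 2)])
    roles = classify_edge_points(g).roles
    assert roles[0] is NodeRole.NON_EPITHELIAL
    assert roles[1] is NodeRole.NON_EPITHELIAL
    assert roles[2] is NodeRole.NON_EPITHELIAL
    assert roles[3] is NodeRole.INNER_EDGE


def test_lymphocytes_acquire_roles_by_neighbor_rules():
    classes = [CellClass.LYMPHOCYTE, CellClass.STROMA]
    g = build_graph(make_cells([(0, 0), (10, 0)], classes), [(0, 1)])
    assert classify_edge_points(g).roles[0] is NodeRole.INNER_EDGE


# ---------------------------------------------------------------------------
# small-component filter
# ---------------------------------------------------------------------------


def _strip_plus_fragment(fragment_size):
    """A large connected strip plus a detached epithelial fragment."""
    g = grid_strip_graph(n_layers=3, length=10)  # 30 epithelial cells
    base = max(g.cells) + 1
    frag_cells = make_cells(
        [(1000 + 10 * i, 0) for i in range(fragment_size)],
        [CellClass.EPITHELIAL_OTHER] * fragment_size,
    )
    frag_cells = [
        type(c)(id=base + i, x=c.x, y=c.y, cell_class=c.cell_class) for i, c in enumerate(frag_cells)
    ]
    all_cells = list(g.cells.values()) + frag_cells
    edges = list(g.graph.edges()) + [(base + i, base + i + 1) for i in range(fragment_size - 1)]
    return build_graph(all_cells, edges), {base + i for i in range(fragment_size)}


@pytest.mark.parametrize("size, filtered", [(19, True), (20, False)])
def test_small_component_threshold_is_strict(size, filtered):
    g, frag_ids = _strip_plus_fragment(size)
    labeling = filter_small_components(g, classify_edge_points(g), 20)
    frag_roles = {labeling.roles[i] for i in frag_ids}
    if filtered:
        assert frag_roles == {NodeRole.NON_EDGE}
    else:
        assert NodeRole.NON_EDGE not in frag_roles


def test_filter_leaves_single_giant_component_unchanged():
    g = grid_strip_graph(n_layers=4, length=10)  # 40 epithelial cells
    labeling = classify_edge_points(g)
    assert filter_small_components(g, labeling, 20).roles == labeling.roles


def test_filter_is_monotone_in_threshold():
    g, frag_ids = _strip_plus_fragment(15)
    labeling = classify_edge_points(g)
    prev_non_edge = set()
    for threshold in (1, 5, 16, 31, 100):
        out = filter_small_components(g, labeling, threshold)
        non_edge = {n for n, r in out.roles.items() if r is NodeRole.NON_EDGE}
        assert prev_non_edge <= non_edge
        prev_non_edge = non_edge


def test_filter_rejects_bad_threshold():
    g = grid_strip_graph(2, 5)
    with pytest.raises(ParameterError):
        filter_small_components(g, classify_edge_points(g), 0)


# ---------------------------------------------------------------------------
# peeling wave-front
# ---------------------------------------------------------------------------


def _peel(graph, min_component=1):
    labeling = filter_small_components(graph, classify_edge_points(graph), min_component)
    return peel_layers(graph, labeling)


@pytest.mark.parametrize("n_layers", [1, 2, 3, 5, 9, 15])
def test_strip_lattice_counts_equal_row_count(n_layers):
    g = grid_strip_graph(n_layers=n_layers, length=12)
    result = _peel(g)
    assert set(result.counts.values()) == {n_layers}
    assert result.median_layers == n_layers
    assert not result.unreachable_ids


def test_single_row_is_both_edge_layer_one():
    g = grid_strip_graph(n_layers=1, length=8)
    labeling = classify_edge_points(g)
    epi_roles = {labeling.roles[n] for n in g.epithelial_nodes()}
    assert epi_roles == {NodeRole.BOTH}
    result = _peel(g)
    assert set(result.counts.values()) == {1}
    assert result.median_layers == 1


def test_three_row_strip_matches_exhaustive_path_oracle():
    g = grid_strip_graph(n_layers=3, length=4)
    labeling = filter_small_components(g, classify_edge_points(g), 1)
    result = peel_layers(g, labeling)
    traversable = labeling.epithelial()
    seeds = labeling.outer_seeds()
    for node, count in result.counts.items():
        hops = exhaustive_min_hops(g, seeds, node, traversable)
        assert count == 1 + hops


def test_monotonicity_appending_a_row_increments_every_count():
    for k in (2, 4, 7):
        r1 = _peel(grid_strip_graph(n_layers=k, length=10))
        r2 = _peel(grid_strip_graph(n_layers=k + 1, length=10))
        # inner-edge rows are the bottom rows; compare count multisets
        assert sorted(v + 1 for v in r1.counts.values()) == sorted(r2.counts.values())
        assert all(v2 == v1 + 1 for v1, v2 in zip(sorted(r1.counts.values()), sorted(r2.counts.values())))


def test_unreachable_inner_nodes_reported_not_imputed():
    # a >=20-cell epithelial blob touching only stroma: inner edges, no outer seed
    g = grid_strip_graph(n_layers=3, length=10)
    base = max(g.cells) + 1
    blob_pts = [(2000 + 10 * i, 10 * j) for j in range(3) for i in range(7)]
    blob_classes = [CellClass.EPITHELIAL_OTHER] * 14 + [CellClass.BASAL] * 7
    stroma_pts = [(2000 + 10 * i, 30) for i in range(7)]
    cells = (
        list(g.cells.values())
        + make_cells(blob_pts, blob_classes)
        + make_cells(stroma_pts, [CellClass.STROMA] * 7)
    )
    # reassign unique ids for the appended nodes
    cells = list(g.cells.values()) + [
        type(c)(id=base + i, x=c.x, y=c.y, cell_class=c.cell_class)
        for i, c in enumerate(make_cells(blob_pts + stroma_pts, blob_classes + [CellClass.STROMA] * 7))
    ]
    edges = list(g.graph.edges())
    idx = lambda j, i: base + j * 7 + i
    for j in range(3):
        for i in range(7):
            if i + 1 < 7:
                edges.append((idx(j, i), idx(j, i + 1)))
            if j + 1 < 3:
                edges.append((idx(j, i), idx(j + 1, i)))
    for i in range(7):  # basal row to stroma row
        edges.append((idx(2, i), base + 21 + i))
    big = build_graph(cells, edges)
    result = _peel(big)
    blob_basal = {idx(2, i) for i in range(7)}
    assert blob_basal <= result.unreachable_ids
    assert result.median_layers == 3  # main strip unaffected
    assert not (blob_basal & set(result.counts))


def test_peel_requires_both_boundaries():
    # epithelium adjacent to stroma only
    classes = [CellClass.BASAL, CellClass.EPITHELIAL_OTHER, CellClass.STROMA]
    g = build_graph(make_cells([(0, 0), (10, 0), (0, 10)], classes), [(0, 1), (0, 2)])
    with pytest.raises(PeelingError, match="no outer boundary"):
        _peel(g)
    classes = [CellClass.BASAL, CellClass.EPITHELIAL_OTHER, CellClass.CORNEUM]
    g = build_graph(make_cells([(0, 0), (10, 0), (0, 10)], classes), [(0, 1), (0, 2)])
    with pytest.raises(PeelingError, match="no inner boundary"):
        _peel(g)


@pytest.mark.parametrize("seed", range(8))
def test_counts_equal_one_plus_min_hops_on_random_graphs(seed):
    rng = np.random.default_rng(seed)
    graph, labeling = random_epithelial_graph(rng, n_max=120)
    labeling = filter_small_components(graph, labeling, 1)
    result = peel_layers(graph, labeling)
    oracle = csgraph_min_hops(graph, labeling.outer_seeds(), labeling.epithelial())
    for node in labeling.inner_targets():
        hops = oracle[node]
        if hops is None:
            assert node in result.unreachable_ids
        else:
            assert result.counts[node] == 1 + hops


def test_global_pre_pruning_equals_pruning_during_traversal():
    """Deleting long edges once up front equals skipping them while peeling."""
    rng = np.random.default_rng(3)
    pts = rng.uniform(0, 600, (80, 2))
    pool = [CellClass.EPITHELIAL_OTHER, CellClass.BASAL, CellClass.STROMA, CellClass.BACKGROUND]
    classes = [pool[i] for i in rng.choice(4, size=80, p=[0.45, 0.15, 0.2, 0.2])]
    from epilayer.cell_graph import build_delaunay_graph

    raw = build_delaunay_graph(make_cells(pts, classes))
    cutoff = 120.0
    pruned = prune_long_edges(raw, cutoff)
    labeling = filter_small_components(pruned, classify_edge_points(pruned), 1)
    if not (labeling.outer_seeds() and labeling.inner_targets()):
        pytest.skip("random draw lacks one boundary")
    ours = peel_layers(pruned, labeling)

    # independent traversal on the *unpruned* graph, skipping long edges inline
    traversable = labeling.epithelial()
    seeds = labeling.outer_seeds()
    dist = {s: 0 for s in seeds}
    frontier = set(seeds)
    while frontier:
        nxt = set()
        for u in frontier:
            for v in raw.graph.neighbors(u):
                if v in traversable and v not in dist and raw.graph[u][v]["length"] <= cutoff:
                    dist[v] = dist[u] + 1
                    nxt.add(v)
        frontier = nxt
    expected = {n: 1 + dist[n] for n in labeling.inner_targets() if n in dist}
    assert ours.counts == expected


def test_rigid_motion_invariance():
    spec = EpitheliumSpec(n_layers=4, length=30, seed=5)
    cells, _ = generate_epithelium(spec)
    base = count_layers(cells)
    theta = 0.7
    c, s = np.cos(theta), np.sin(theta)
    moved = [
        type(rec)(
            id=rec.id,
            x=c * rec.x - s * rec.y + 3000,
            y=s * rec.x + c * rec.y + 1000,
            cell_class=rec.cell_class,
            is_pseudo=rec.is_pseudo,
        )
        for rec in cells
    ]
    rotated = count_layers(moved)
    assert rotated.counts == base.counts
    assert rotated.median_layers == base.median_layers


# ---------------------------------------------------------------------------
# slide summary
# ---------------------------------------------------------------------------


def test_summarize_hand_values():
    res = LayerCountResult.from_counts({0: 2, 1: 3, 2: 3, 3: 4})
    out = summarize_slide(res)
    assert out["median_layers"] == 3.0
    assert out["sd_layers"] == pytest.approx(np.sqrt(0.5), abs=1e-12)
    assert out["n_inner"] == 4
    single = summarize_slide(LayerCountResult.from_counts({0: 5}))
    assert single["median_layers"] == 5.0 and single["sd_layers"] == 0.0


def test_summarize_quantile_linear_interpolation():
    res = LayerCountResult.from_counts({i: v for i, v in enumerate([1, 2, 3, 4])})
    assert summarize_slide(res, quantile=0.25)["median_layers"] == 1.75


def test_summarize_empty_and_bad_quantile():
    empty = LayerCountResult.from_counts({})
    with pytest.warns(UserWarning):
        out = summarize_slide(empty)
    assert out == {"median_layers": None, "sd_layers": None, "n_inner": 0}
    with pytest.raises(ParameterError):
        summarize_slide(LayerCountResult.from_counts({0: 1}), quantile=1.0)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.integers(min_value=1, max_value=40), min_size=1, max_size=60))
def test_summary_matches_numpy_reference(values):
    res = LayerCountResult.from_counts({i: v for i, v in enumerate(values)})
    out = summarize_slide(res)
    assert out["median_layers"] == pytest.approx(float(np.quantile(values, 0.5)))
    assert out["sd_layers"] == pytest.approx(float(np.std(values)))
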