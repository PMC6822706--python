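"""Tests for skeleton-to-graph conversion and mycelial metrics."""

import math

import numpy as np
import pytest
from shapely.geometry import MultiPoint
from skimage.draw import circle_perimeter

from mycovision import presets, synthetic
from mycovision.core import thin_skeleton
from mycovision.mycelium import (
    GraphNode,
    MycelialGraph,
    analyze_mycelium_image,
    analyze_time_series,
    graph_metrics,
    mycelium_binary,
    skeleton_to_graph,
)

SQRT2 = math.sqrt(2.0)


def _line_skeleton(n=10):
    sk = np.zeros((5, n + 2), bool)
    sk[2, 1 : 1 + n] = True
    return sk


def _y_skeleton(arm=11):
    sk = np.zeros((2 * arm + 6, 2 * arm + 6), bool)
    c = arm + 3
    sk[c, c] = True
    for i in range(1, arm + 1):
        sk[c, c - i] = True  # west
        sk[c - i, c + i] = True  # north-east diagonal
        sk[c + i, c + i] = True  # south-east diagonal
    return sk


# ---------------------------------------------------------------------------
# skeleton_to_graph


def test_horizontal_line_graph():
    g = skeleton_to_graph(_line_skeleton(10))
    assert len(g.nodes) == 2 and len(g.edges) == 1
    assert g.edges[0].length_px == pytest.approx(9.0)
    assert g.n_tips == 2


def test_y_shape_graph():
    g = skeleton_to_graph(_y_skeleton(11))
    assert len(g.nodes) == 4  # 3 tips + 1 junction
    assert len(g.edges) == 3
    assert g.n_tips == 3
    degs = sorted(g.degrees().values())
    assert degs == [1, 1, 1, 3]
    lengths = sorted(e.length_px for e in g.edges)
    assert lengths[0] == pytest.approx(11.0)  # straight west arm
    assert lengths[1] == pytest.approx(11 * SQRT2)  # diagonal arms
    assert lengths[2] == pytest.approx(11 * SQRT2)


def test_empty_isolated_and_loop_graphs():
    assert skeleton_to_graph(np.zeros((5, 5), bool)).nodes == ()
    sk = np.zeros((5, 5), bool)
    sk[2, 2] = True
    g = skeleton_to_graph(sk)
    assert len(g.nodes) == 1 and len(g.edges) == 0 and g.n_tips == 0  # dot is not a tip
    sk = np.zeros((30, 30), bool)
    rr, cc = circle_perimeter(15, 15, 8)
    sk[rr, cc] = True
    g = skeleton_to_graph(thin_skeleton(sk))
    assert len(g.nodes) == 1 and len(g.edges) == 1
    assert g.edges[0].u == g.edges[0].v  # self-loop
    assert g.degrees()[g.nodes[0].id] == 2  # self-loop counts twice
    assert g.n_tips == 0


def test_skeleton_pixel_conservation_on_line_and_y():
    """Edge paths cover every skeleton pixel, junction pixels once."""
    for sk in (_line_skeleton(10), _y_skeleton(11)):
        g = skeleton_to_graph(sk)
        covered = set()
        for e in g.edges:
            covered.update(map(tuple, np.rint(e.path).astype(int)))
        assert covered == set(map(tuple, np.argwhere(sk)))


def test_disjoint_segment_adds_length_and_tips():
    sk = _y_skeleton(11)
    g0 = skeleton_to_graph(sk)
    m0 = graph_metrics(g0)
    n = 7
    sk2 = sk.copy()
    sk2[1, 1 : 1 + n] = True  # disjoint straight n-pixel segment
    m1 = graph_metrics(skeleton_to_graph(sk2))
    assert m1.total_length == pytest.approx(m0.total_length + (n - 1))
    assert m1.n_tips == m0.n_tips + 2


def test_planted_tree_satisfies_euler_relation():
    scene = synthetic.generate_mycelium_scene(n_branches=7, seed=5, shape=(512, 512))
    nx_graph = scene.planted_graph.to_networkx()
    import networkx as nx

    n_components = nx.number_connected_components(nx_graph)
    assert nx_graph.number_of_edges() == nx_graph.number_of_nodes() - n_components


# ---------------------------------------------------------------------------
# graph metrics


def test_metrics_on_line_and_triangle_and_empty():
    m = graph_metrics(skeleton_to_graph(_line_skeleton(10)))
    assert (m.total_length, m.n_tips, m.hull_area) == (pytest.approx(9.0), 2, 0.0)
    tri = MycelialGraph(
        nodes=(GraphNode(0, 0, 0), GraphNode(1, 4, 0), GraphNode(2, 0, 3)), edges=()
    )
    assert graph_metrics(tri).hull_area == pytest.approx(6.0)
    empty = graph_metrics(MycelialGraph(nodes=(), edges=()))
    assert (empty.total_length, empty.n_tips, empty.n_edges, empty.hull_area) == (0, 0, 0, 0)


def test_hull_matches_shapely_oracle_and_is_permutation_invariant(rng):
    for _ in range(20):
        pts = rng.uniform(0, 100, size=(int(rng.integers(3, 11)), 2))
        nodes = tuple(GraphNode(i, r, c) for i, (r, c) in enumerate(pts))
        area = graph_metrics(MycelialGraph(nodes=nodes, edges=())).hull_area
        expected = MultiPoint([(r, c) for r, c in pts]).convex_hull.area
        assert area == pytest.approx(expected, abs=1e-8)
        perm = rng.permutation(len(nodes))
        shuffled = tuple(GraphNode(i, *pts[j]) for i, j in enumerate(perm))
        assert graph_metrics(MycelialGraph(nodes=shuffled, edges=())).hull_area == pytest.approx(area)


def test_metrics_scale_units():
    g = skeleton_to_graph(_line_skeleton(10))
    m = graph_metrics(g, scale=0.5)
    assert m.total_length == pytest.approx(4.5)


# ---------------------------------------------------------------------------
# full image pipeline


def test_blank_image_gives_empty_graph(mycelium_params):
    g, m = analyze_mycelium_image(np.zeros((128, 128)), mycelium_params)
    assert len(g.nodes) == 0 and m.total_length == 0 and m.hull_area == 0


def test_pipeline_recovers_planted_tips_and_length(mycelium_scene, mycelium_params):
    planted = mycelium_scene.planted_graph
    g, m = analyze_mycelium_image(mycelium_scene.image, mycelium_params)
    assert m.n_tips == planted.n_tips
    assert m.total_length == pytest.approx(planted.total_length_px(), rel=0.10)


def test_pipeline_is_robust_to_illumination_gradient(mycelium_params):
    kw = dict(n_branches=8, seed=21, shape=(512, 512), noise_sigma=0.0,
              branch_length_range=(50.0, 120.0))
    flat = synthetic.generate_mycelium_scene(gradient_amplitude=0.0, **kw)
    graded = synthetic.generate_mycelium_scene(gradient_amplitude=0.1, **kw)
    _, m_flat = analyze_mycelium_image(flat.image, mycelium_params)
    _, m_grad = analyze_mycelium_image(graded.image, mycelium_params)
    assert m_flat.n_tips == m_grad.n_tips == flat.planted_graph.n_tips


def test_pipeline_deterministic(mycelium_scene, mycelium_params):
    m1 = analyze_mycelium_image(mycelium_scene.image, mycelium_params)[1]
    m2 = analyze_mycelium_image(mycelium_scene.image, mycelium_params)[1]
    assert m1 == m2


def test_mask_subtraction_removes_border_structure(mycelium_scene, mycelium_params):
    mask = np.zeros_like(mycelium_scene.truth_mask)
    mask[:, :] = True  # mask everything -> nothing survives
    g, m = analyze_mycelium_image(mycelium_scene.image, mycelium_params, mask=mask)
    assert m.total_length == 0
    with pytest.raises(ValueError):
        analyze_mycelium_image(mycelium_scene.image, mycelium_params, mask=np.zeros((3, 3), bool))


def test_mycelium_binary_matches_truth_closely(mycelium_scene, mycelium_params):
    from mycovision.validation import accuracy_metrics, confusion_counts

    pred = mycelium_binary(mycelium_scene.image, mycelium_params)
    p, r, f, mcc = accuracy_metrics(confusion_counts(pred, mycelium_scene.truth_mask))
    assert p > 0.9 and r > 0.9 and f > 0.9 and mcc > 0.9


# ---------------------------------------------------------------------------
# time series


def test_time_series_identical_frames_and_empty(mycelium_scene, mycelium_params):
    frames = [mycelium_scene.image] * 3
    out = analyze_time_series(frames, mycelium_params)
    assert [t for t, _ in out] == [0, 1, 2]
    assert out[0][1] == out[1][1] == out[2][1]
    assert analyze_time_series([], mycelium_params) == []
    with pytest.raises(ValueError):
        analyze_time_series([np.zeros((8, 8)), np.zeros((9, 9))], mycelium_params)


def test_growth_series_total_length_non_decreasing(mycelium_params):
    scenes = synthetic.generate_growth_series(
        n_frames=3, growth_per_frame=3, seed=9, shape=(512, 512),
        branch_length_range=(50.0, 110.0),
    )
    out = analyze_time_series([s.image for s in scenes], mycelium_params)
    lengths = [m.total_length for _, m in out]
    assert all(b >= a for a, b in zip(lengths, lengths[1:]))
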