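"""Graph construction, node classification and morphometry."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import PITCH, add_ball, add_polyline_tube, add_tube, binary, empty_mask
from lcnpipe.connectome import (
    LcnGraph,
    build_graph,
    classify_nodes,
    matrix_distances,
    morphometry,
    network_summary,
)
from lcnpipe.io_core import DataError
from lcnpipe.segment import canalicular_mask, identify_lacunae, skeletonize_canaliculi


def analyze_mask(mask, **lac_kwargs):
    b = binary(mask)
    lac = identify_lacunae(b, **lac_kwargs)
    canal = canalicular_mask(b, lac)
    skel = skeletonize_canaliculi(canal, prune_um=1.0, lacunae=lac)
    return b, lac, skel, build_graph(skel, lac)


def lcn_graph(g: nx.Graph) -> LcnGraph:
    return LcnGraph.from_multigraph(g)


# -- build_graph -----------------------------------------------------------

def test_two_lacunae_one_straight_canaliculus():
    """Two 3 µm balls joined by a 10 µm tube -> one lacuna-lacuna edge."""
    m = empty_mask((40, 40, 80))
    add_ball(m, (8.0, 8.0, 8.0), 3.0)
    add_ball(m, (8.0, 8.0, 24.0), 3.0)
    add_tube(m, (8.0, 8.0, 11.0), (8.0, 8.0, 21.0), 0.8)
    _, lac, _, g = analyze_mask(m)
    assert lac.n == 2
    assert sorted(k for _, k in g.graph.nodes(data="kind")) == ["lacuna", "lacuna"]
    assert g.n_edges == 1
    (length,) = [l for _, _, l in g.graph.edges(data="geodesic_length_um")]
    assert length == pytest.approx(10.0, abs=0.6)


def test_isolated_lacuna_has_degree_zero():
    m = empty_mask((40, 40, 40))
    add_ball(m, (8.0, 8.0, 8.0), 3.0)
    _, lac, _, g = analyze_mask(m)
    assert g.n_nodes == 1 and g.n_edges == 0
    node, attrs = next(iter(g.graph.nodes(data=True)))
    assert attrs["kind"] == "lacuna" and attrs["degree"] == 0


def test_y_junction_three_lacunae():
    m = empty_mask((40, 60, 60))
    hub = np.array([8.0, 12.0, 12.0])
    tips = [np.array([8.0, 12.0, 22.0]), np.array([8.0, 20.0, 6.0]), np.array([8.0, 4.0, 6.0])]
    for t in tips:
        add_ball(m, t, 2.8)
    for t in tips:
        d = (t - hub) / np.linalg.norm(t - hub)
        add_tube(m, hub, t - d * 2.0, 0.8)
    _, lac, _, g = analyze_mask(m)
    assert lac.n == 3
    kinds = sorted(k for _, k in g.graph.nodes(data="kind"))
    assert kinds == ["branch", "lacuna", "lacuna", "lacuna"]
    assert g.n_edges == 3
    (branch,) = [n for n, k in g.graph.nodes(data="kind") if k == "branch"]
    assert g.graph.degree(branch) == 3


def test_edge_length_at_least_euclidean_between_path_ends():
    m = empty_mask((40, 40, 80))
    add_ball(m, (8.0, 8.0, 8.0), 3.0)
    add_ball(m, (8.0, 8.0, 24.0), 3.0)
    add_tube(m, (8.0, 8.0, 11.0), (8.0, 8.0, 21.0), 0.8)
    _, _, _, g = analyze_mask(m)
    for _, _, data in g.graph.edges(data=True):
        path = np.asarray(data["voxel_path"], float) * PITCH
        euclid = np.linalg.norm(path[0] - path[-1])
        assert data["geodesic_length_um"] >= euclid - 1e-9


def test_build_graph_grid_mismatch_rejected():
    m1 = empty_mask((8, 8, 8))
    m2 = empty_mask((8, 8, 9))
    b2 = binary(m2)
    lac2 = identify_lacunae(b2)
    skel1 = skeletonize_canaliculi(binary(m1), 1.0)
    with pytest.raises(DataError):
        build_graph(skel1, lac2)


# -- classification --------------------------------------------------------

def test_classify_path_graph():
    g = nx.path_graph(["A", "B", "C"])
    cls = classify_nodes(lcn_graph(g))
    assert (cls.n_end, cls.n_tree, cls.n_cluster, cls.n_intermediate) == (2, 1, 0, 0)
    props = cls.proportions
    assert props["end"] == pytest.approx(2 / 3)
    assert sum(props.values()) == pytest.approx(1.0, abs=1e-9)


def test_classify_triangle_all_cluster():
    cls = classify_nodes(lcn_graph(nx.cycle_graph(3)))
    assert cls.n_cluster == 3 and cls.n_end == cls.n_tree == cls.n_intermediate == 0


def test_classify_square_all_tree():
    """4-cycle: every node has degree 2 and cc 0 (no closed neighbor pairs)."""
    cls = classify_nodes(lcn_graph(nx.cycle_graph(4)))
    assert cls.n_tree == 4 and cls.n_cluster == 0


def test_classification_partitions_random_graphs(rng):
    for seed in range(5):
        g = nx.gnp_random_graph(12, 0.3, seed=seed)
        wrapped = lcn_graph(g)
        cls = classify_nodes(wrapped)
        assert cls.n_total == wrapped.n_nodes
        assert sum(cls.proportions.values()) == pytest.approx(1.0, abs=1e-9)


def test_network_summary_path_and_empty():
    n, mean_deg, _ = network_summary(lcn_graph(nx.path_graph(3)))
    assert n == 3 and mean_deg == pytest.approx(4 / 3)
    n, mean_deg, cls = network_summary(LcnGraph.from_multigraph(nx.MultiGraph()))
    assert n == 0 and mean_deg is None and cls.n_total == 0


@settings(deadline=None, max_examples=20)
@given(st.integers(0, 2**31 - 1))
def test_handshake_identity_on_random_graphs(seed):
    g = nx.gnp_random_graph(10, 0.35, seed=seed)
    wrapped = lcn_graph(g)
    n, mean_deg, _ = network_summary(wrapped)
    if n:
        assert mean_deg == pytest.approx(2 * g.number_of_edges() / n)


def test_self_loop_counts_twice_in_degree():
    g = nx.MultiGraph()
    g.add_edge("a", "a", geodesic_length_um=3.0)
    wrapped = LcnGraph.from_multigraph(g)
    assert wrapped.graph.nodes["a"]["degree"] == 2


# -- morphometry -----------------------------------------------------------

def test_lacuna_density_unit_conversion():
    """5 lacunae in a (100 µm)^3 region are 5000 per mm^3."""
    shape = (50, 50, 50)  # (100 µm)^3 at 2 µm pitch
    mask = np.zeros(shape, bool)
    labels = np.zeros(shape, np.int32)
    import pandas as pd

    rows = []
    for i, z in enumerate(range(5, 50, 9)):
        if i >= 5:
            break
        mask[z, 25, 25] = True
        labels[z, 25, 25] = i + 1
        rows.append(
            dict(label=i + 1, cz_um=z * 2.0, cy_um=50.0, cx_um=50.0,
                 volume_vox=1, volume_um3=8.0, edge_touching=False)
        )
    from lcnpipe.segment import BinaryStack, LacunaLabels, Skeleton

    b = BinaryStack(mask, 2.0)
    lac = LacunaLabels(labels, 2.0, pd.DataFrame(rows))
    skel = Skeleton(np.zeros(shape, bool), 2.0, np.zeros(shape, np.int32), 0)
    g = build_graph(skel, lac)
    rep = morphometry(b, lac, skel, g, "include_all")
    assert rep.roi_volume_um3 == pytest.approx(1e6)
    assert rep.lacuna_density_mm3 == pytest.approx(5000.0)
    assert rep.canalicular_total_length_um == 0.0
    assert rep.canalicular_density_um2 == 0.0


def test_edge_policy_drops_edge_touching_lacunae():
    m = empty_mask((40, 40, 60))
    add_ball(m, (8.0, 8.0, 8.0), 3.0)  # interior
    add_ball(m, (0.8, 8.0, 18.0), 3.0)  # clipped by the z=0 face
    b, lac, skel, g = analyze_mask(m)
    inc = morphometry(b, lac, skel, g, "include_all")
    exc = morphometry(b, lac, skel, g, "exclude_touching")
    assert inc.n_lacunae == 2 and exc.n_lacunae == 1
    assert inc.n_lacunae - exc.n_lacunae == inc.n_lacunae_edge_touching == 1


def test_no_canaliculi_zero_lengths():
    m = empty_mask((40, 40, 40))
    add_ball(m, (8.0, 8.0, 8.0), 3.0)
    b, lac, skel, g = analyze_mask(m)
    rep = morphometry(b, lac, skel, g)
    assert rep.canalicular_total_length_um == 0.0
    assert rep.canalicular_mean_length_um == 0.0


# -- distances -------------------------------------------------------------

def test_matrix_distances_curved_canaliculus():
    """Two small lacunae 10 µm apart joined by a bulging arc: the network
    distance exceeds the straight-line distance."""
    m = empty_mask((40, 60, 60))
    c1 = np.array([8.0, 10.0, 7.0])
    c2 = np.array([8.0, 10.0, 17.0])
    add_ball(m, c1, 1.4)
    add_ball(m, c2, 1.4)
    p0 = c1 + np.array([0.0, 0.0, 1.4])
    p1 = c2 - np.array([0.0, 0.0, 1.4])
    ts = np.linspace(0, 1, 40)
    pts = np.stack([p0 + t * (p1 - p0) + np.array([0.0, 3.0 * np.sin(np.pi * t), 0.0]) for t in ts])
    arc = add_polyline_tube(m, pts, 0.8)
    b = binary(m)
    lac = identify_lacunae(b, dist_thresh_vox=2.0, min_size_vox=10)
    assert lac.n == 2
    canal = canalicular_mask(b, lac)
    skel = skeletonize_canaliculi(canal, 1.0, lac)
    g = build_graph(skel, lac)
    d_l, d_lc, d_net = matrix_distances(b, lac, skel, g)
    assert d_l == pytest.approx([10.0, 10.0], abs=0.5)
    expected_net = arc + 2 * 1.4  # arc plus the centroid-to-surface spans
    assert d_net == pytest.approx([expected_net, expected_net], rel=0.10)
    assert np.all(d_net >= d_l)
    assert d_lc > 0


def test_d_lc_zero_when_lcn_fills_stack():
    m = np.ones((10, 10, 10), bool)
    b = binary(m)
    lac = identify_lacunae(b, dist_thresh_vox=2.0, min_size_vox=5)
    skel = skeletonize_canaliculi(canalicular_mask(b, lac), 1.0, lac)
    g = build_graph(skel, lac)
    _, d_lc, _ = matrix_distances(b, lac, skel, g)
    assert d_lc == 0.0


def test_single_lacuna_distances_missing():
    m = empty_mask((40, 40, 40))
    add_ball(m, (8.0, 8.0, 8.0), 3.0)
    b, lac, skel, g = analyze_mask(m)
    d_l, d_lc, d_net = matrix_distances(b, lac, skel, g)
    assert np.isnan(d_l).all() and np.isnan(d_net).all()
    assert d_lc > 0


def test_disconnected_lacunae_have_missing_d_net():
    m = empty_mask((40, 40, 80))
    add_ball(m, (8.0, 8.0, 8.0), 3.0)
    add_ball(m, (8.0, 8.0, 24.0), 3.0)  # no connecting canaliculus
    b, lac, skel, g = analyze_mask(m)
    d_l, _, d_net = matrix_distances(b, lac, skel, g)
    assert np.isfinite(d_l).all()
    assert np.isnan(d_net).all()


def test_matrix_distances_requires_nonempty_mask():
    b = binary(empty_mask((8, 8, 8)))
    lac = identify_lacunae(b)
    skel = skeletonize_canaliculi(b, 1.0)
    g = build_graph(skel, lac)
    with pytest.raises(DataError):
        matrix_distances(b, lac, skel, g)
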