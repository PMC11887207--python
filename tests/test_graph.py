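import numpy as np
import pytest

from conftest import make_patch
from coroseg.clustering import ClusterLabeling, cluster_stats, ward_cluster
from coroseg.graph import (ClusterGraph, VesselPath, boruvka_mst, build_graph,
                           find_vessel_path, remove_background)
from coroseg.errors import StateError
from oracles import kruskal_mst_weight, random_connected_graph


def _two_cluster_labeling():
    labels = np.zeros((32, 32), dtype=int)
    labels[:, 16:] = 1
    lab = ClusterLabeling(labels, 2)
    lab.mean_hu = np.array([500.0, 400.0])
    lab.centroid_px = np.array([[16.0, 16.0], [16.0, 24.0]])
    lab.size_px = np.array([512, 512])
    return lab


def test_build_graph_edge_weight_arithmetic():
    graph = build_graph(_two_cluster_labeling())
    assert graph.x[0] == 0.0 and graph.x[1] == 8.0
    assert len(graph.edges) == 1
    a, b, w = graph.edges[0]
    assert (a, b) == (0, 1)
    assert w == pytest.approx(np.sqrt(64 + 10000))


def test_build_graph_requires_stats():
    with pytest.raises(StateError):
        build_graph(ClusterLabeling(np.zeros((32, 32), int), 1))


def test_three_in_a_row_has_two_edges():
    labels = np.zeros((32, 32), dtype=int)
    labels[:, 11:22] = 1
    labels[:, 22:] = 2
    lab = cluster_stats(np.arange(1024, dtype=float).reshape(32, 32),
                        ClusterLabeling(labels, 3))
    graph = build_graph(lab)
    assert sorted((a, b) for a, b, _ in graph.edges) == [(0, 1), (1, 2)]


def test_boruvka_triangle():
    g = ClusterGraph(np.arange(3), np.zeros(3), np.zeros(3),
                     [(0, 1, 1.0), (1, 2, 2.0), (0, 2, 3.0)], 0)
    mst = boruvka_mst(g)
    assert sorted(w for _, _, w in mst.mst_edges) == [1.0, 2.0]
    assert not mst.is_forest


def test_boruvka_tree_input_is_identity():
    edges = [(0, 1, 5.0), (1, 2, 3.0), (1, 3, 4.0)]
    g = ClusterGraph(np.arange(4), np.zeros(4), np.zeros(4), edges, 0)
    mst = boruvka_mst(g)
    assert sorted(mst.mst_edges) == sorted(edges)


def test_boruvka_disconnected_returns_flagged_forest():
    g = ClusterGraph(np.arange(4), np.zeros(4), np.zeros(4),
                     [(0, 1, 1.0), (2, 3, 1.0)], 0)
    mst = boruvka_mst(g)
    assert mst.is_forest
    assert len(mst.mst_edges) == 2


def test_boruvka_matches_kruskal_on_random_graphs(rng):
    for _ in range(100):
        n, edges = random_connected_graph(rng)
        g = ClusterGraph(np.arange(n), np.zeros(n), np.zeros(n), edges, 0)
        mst = boruvka_mst(g)
        assert len(mst.mst_edges) == n - 1
        # distinct random weights make the MST unique: the edge-weight
        # multiset must match Kruskal's exactly (no tolerance)
        got = sorted(w for _, _, w in mst.mst_edges)
        assert got == kruskal_mst_weight(n, edges)


def _chain_graph(means, center_node=0):
    n = len(means)
    edges = [(i, i + 1, 1.0) for i in range(n - 1)]
    g = ClusterGraph(np.arange(n), np.arange(n, dtype=float),
                     np.asarray(means, float), edges, center_node)
    return boruvka_mst(g)


def test_vessel_path_chain_stops_below_threshold():
    path = find_vessel_path(_chain_graph([500.0, 300.0, 120.0, 40.0]))
    assert path.mean_hus == [500.0, 300.0, 120.0]


def test_vessel_path_star_collects_descending_leaves():
    edges = [(0, 1, 1.0), (0, 2, 1.0), (0, 3, 1.0)]
    g = boruvka_mst(ClusterGraph(np.arange(4), np.arange(4, dtype=float),
                                 np.array([450.0, 400.0, 350.0, 90.0]),
                                 edges, 0))
    path = find_vessel_path(g)
    assert path.mean_hus == [450.0, 400.0, 350.0]


def test_vessel_path_empty_when_all_dim():
    path = find_vessel_path(_chain_graph([80.0, 60.0]))
    assert path.empty


def test_vessel_path_monotone_blocks_bright_reentry():
    # bright structure beyond a dim gap must not re-enter the path
    path = find_vessel_path(_chain_graph([450.0, 180.0, 420.0]))
    assert path.mean_hus == [450.0, 180.0]


def test_vessel_path_start_falls_back_to_nearest_bright():
    # centre pixel sits in a dim cluster; start from the eligible node
    # nearest the centre instead
    path = find_vessel_path(_chain_graph([80.0, 400.0, 300.0], center_node=0))
    assert path.mean_hus == [400.0, 300.0]


def _clustered(values):
    patch = make_patch(values)
    lab = cluster_stats(patch, ward_cluster(values, min(4, values.size)))
    graph = boruvka_mst(build_graph(lab))
    return patch, lab, graph


def test_remove_background_identity_when_all_on_path():
    values = np.full((32, 32), 300.0)
    patch = make_patch(values)
    lab = cluster_stats(patch, ward_cluster(values, 1))
    path = find_vessel_path(boruvka_mst(build_graph(lab)))
    out, applied = remove_background(patch, lab, path)
    assert applied
    np.testing.assert_array_equal(out.values, values)


def test_remove_background_flattens_off_path_and_is_idempotent():
    values = np.full((32, 32), 100.0)
    ii, jj = np.indices((32, 32))
    disc_a = (ii - 16) ** 2 + (jj - 16) ** 2 <= 16
    disc_b = (ii - 16) ** 2 + (jj - 27) ** 2 <= 9
    values[disc_a] = 400.0
    values[disc_b] = 400.0  # bright structure separated from the vessel
    patch, lab, graph = _clustered(values)
    path = find_vessel_path(graph)
    out, applied = remove_background(patch, lab, path)
    assert applied
    fill = lab.mean_hu.min()
    # off-path pixels all share the single fill value
    off = ~np.isin(lab.labels, path.cluster_ids)
    assert set(np.unique(out.values[off])) == {fill}
    assert np.all(out.values[disc_b] == fill)      # the kissing disc is gone
    assert np.all(out.values[disc_a] == 400.0)     # the vessel is untouched
    # idempotence under the recomputed identical labeling
    out2, _ = remove_background(out, lab, path)
    np.testing.assert_array_equal(out2.values, out.values)


def test_remove_background_empty_path_returns_unmodified():
    values = np.full((32, 32), 50.0)
    patch = make_patch(values)
    lab = cluster_stats(patch, ward_cluster(values, 1))
    path = VesselPath([], [])
    out, applied = remove_background(patch, lab, path)
    assert not applied
    np.testing.assert_array_equal(out.values, values)


def test_removal_mechanism_with_intermediate_band():
    # two equal-brightness discs whose contact runs through an
    # intermediate-intensity band: the path admits the band, then the
    # monotone rule blocks the second disc, and removal flattens it
    values = np.full((32, 32), 100.0)
    ii, jj = np.indices((32, 32))
    disc_a = (ii - 16) ** 2 + (jj - 13) ** 2 <= 25
    disc_b = (ii - 16) ** 2 + (jj - 26) ** 2 <= 16
    band = (np.abs(jj - 20) <= 1) & (np.abs(ii - 16) <= 4)
    values[disc_a] = 400.0
    values[disc_b] = 400.0
    values[band] = 200.0
    patch = make_patch(values)
    lab = cluster_stats(patch, ward_cluster(values, 4))
    path = find_vessel_path(boruvka_mst(build_graph(lab)))
    out, applied = remove_background(patch, lab, path)
    assert applied
    centre_label = lab.labels[16, 13]
    assert centre_label in path.cluster_ids
    assert np.all(out.values[disc_b & ~band] == lab.mean_hu.min())
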