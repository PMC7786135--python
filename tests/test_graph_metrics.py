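"""Density thresholding and graph statistics against brute-force oracles."""

import numpy as np
import pytest

import metacov as mc
from metacov.graph_metrics import (
    DEFAULT_DENSITY_GRID,
    BinaryGraph,
    MetricCurve,
    global_metrics,
    metric_curve,
    nodal_metrics,
    threshold_by_density,
)
from metacov.network import CovNetwork

from _oracles import (
    betweenness_by_path_enumeration,
    char_path_length_by_bfs,
    clustering_by_triangles,
    efficiency_from_bfs,
    local_efficiency_by_subgraph,
    random_adjacency,
)


def _network_from_weights(w):
    w = np.asarray(w, dtype=float)
    np.fill_diagonal(w, 1.0)
    return CovNetwork((w + w.T) / 2, [f"r{i}" for i in range(w.shape[0])])


def _complete(n):
    return BinaryGraph(~np.eye(n, dtype=bool))


def _ring_lattice(n, k):
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for off in range(1, k // 2 + 1):
            j = (i + off) % n
            adj[i, j] = adj[j, i] = True
    return BinaryGraph(adj)


def _star(leaves):
    adj = np.zeros((leaves + 1, leaves + 1), dtype=bool)
    adj[0, 1:] = adj[1:, 0] = True
    return BinaryGraph(adj)


def _path(n):
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n - 1):
        adj[i, i + 1] = adj[i + 1, i] = True
    return BinaryGraph(adj)


class TestThreshold:
    def test_full_density_gives_complete_graph(self, rng):
        w = rng.uniform(0.1, 1.0, (6, 6))
        net = _network_from_weights(w)
        g = threshold_by_density(net, 1.0)
        assert g.n_edges == 15
        assert np.array_equal(g.adjacency, ~np.eye(6, dtype=bool))

    def test_keeps_top_k_edges(self):
        w = np.zeros((4, 4))
        ranked = [(0, 1, 0.9), (0, 2, 0.8), (1, 2, 0.7), (0, 3, 0.6), (1, 3, 0.5), (2, 3, 0.4)]
        for i, j, v in ranked:
            w[i, j] = w[j, i] = v
        g = threshold_by_density(_network_from_weights(w), 0.5)
        assert g.n_edges == 3
        assert {(0, 1), (0, 2), (1, 2)} == set(g.edge_list())

    def test_negative_weights_never_kept(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.3
        w[2, 3] = w[3, 2] = -0.9
        with pytest.warns(UserWarning, match="sparser"):
            g = threshold_by_density(_network_from_weights(w), 0.5)
        assert set(g.edge_list()) == {(0, 1)}

    def test_tie_break_is_deterministic_and_exact(self):
        w = np.full((5, 5), 0.5)  # every off-diagonal weight tied
        net = _network_from_weights(w)
        g1 = threshold_by_density(net, 0.3)
        g2 = threshold_by_density(net, 0.3)
        k = round(0.3 * 10)
        assert g1.n_edges == k
        assert np.array_equal(g1.adjacency, g2.adjacency)
        # lexicographically smallest pairs win the tie
        assert set(g1.edge_list()) == {(0, 1), (0, 2), (0, 3)}

    def test_nested_edge_sets_across_grid(self, rng):
        w = rng.uniform(0.0, 1.0, (10, 10))
        net = _network_from_weights(w)
        prev = None
        for dens in DEFAULT_DENSITY_GRID:
            g = threshold_by_density(net, float(dens))
            edges = set(g.edge_list())
            if prev is not None:
                assert prev <= edges
            prev = edges

    def test_density_bounds(self, rng):
        net = _network_from_weights(rng.random((4, 4)))
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                threshold_by_density(net, bad)


class TestNodalMetrics:
    def test_complete_graph_identities(self):
        nm = nodal_metrics(_complete(4))
        assert np.allclose(nm.clustering, 1.0)
        assert np.allclose(nm.degree, 3)
        assert np.allclose(nm.betweenness, 0.0)
        assert np.allclose(nm.local_efficiency, 1.0)

    def test_star_center_betweenness_closed_form(self):
        leaves = 5
        nm = nodal_metrics(_star(leaves))
        assert nm.betweenness.iloc[0] == pytest.approx(leaves * (leaves - 1) / 2)
        assert np.allclose(nm.betweenness.iloc[1:], 0.0)
        assert np.allclose(nm.clustering, 0.0)

    def test_matches_bruteforce_on_random_graphs(self, rng):
        """Exhaustive triangle/path oracles on all four nodal metrics."""
        for _ in range(60):
            n = int(rng.integers(3, 7))
            adj = random_adjacency(n, float(rng.uniform(0.2, 0.9)), rng)
            nm = nodal_metrics(BinaryGraph(adj))
            assert np.allclose(nm.clustering, clustering_by_triangles(adj), atol=1e-10)
            assert np.allclose(nm.degree, adj.sum(axis=1), atol=0)
            assert np.allclose(
                nm.local_efficiency, local_efficiency_by_subgraph(adj), atol=1e-10
            )
            assert np.allclose(
                nm.betweenness, betweenness_by_path_enumeration(adj), atol=1e-10
            )


class TestGlobalMetrics:
    def test_complete_graph_values(self):
        gm = global_metrics(_complete(7))
        assert gm["Lp"] == pytest.approx(1.0)
        assert gm["Eglob"] == pytest.approx(1.0)
        assert gm["synchronization"] == pytest.approx(1.0)
        assert gm["Cp"] == pytest.approx(1.0)

    def test_ring_lattice_clustering_closed_form(self):
        # k-nearest-neighbor ring: Cp = 3(k-2) / (4(k-1)), k = 4 -> 0.5
        gm = global_metrics(_ring_lattice(20, 4))
        assert gm["Cp"] == pytest.approx(0.5)

    def test_path_graph_against_bfs_oracle(self):
        g = _path(5)
        gm = global_metrics(g)
        assert gm["Lp"] == pytest.approx(char_path_length_by_bfs(g.adjacency), abs=1e-12)
        assert gm["Eglob"] == pytest.approx(efficiency_from_bfs(g.adjacency), abs=1e-12)

    def test_path3_synchronization_spectrum(self):
        # P3 Laplacian eigenvalues are 0, 1, 3
        gm = global_metrics(_path(3))
        assert gm["synchronization"] == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_disconnected_graph_synchronization_zero(self):
        adj = np.zeros((6, 6), dtype=bool)
        adj[0, 1] = adj[1, 0] = True
        adj[2, 3] = adj[3, 2] = True
        gm = global_metrics(BinaryGraph(adj))
        assert gm["synchronization"] == 0.0

    def test_lp_averages_connected_pairs_only(self):
        # two components: an edge pair and a path of 3
        adj = np.zeros((5, 5), dtype=bool)
        adj[0, 1] = adj[1, 0] = True
        adj[2, 3] = adj[3, 2] = True
        adj[3, 4] = adj[4, 3] = True
        gm = global_metrics(BinaryGraph(adj))
        # connected distances: (0,1)=1, (2,3)=1, (3,4)=1, (2,4)=2
        assert gm["Lp"] == pytest.approx(5 / 4)

    def test_hierarchy_least_squares_by_hand(self):
        # "paw" graph: triangle 0-1-2 plus pendant 3 on node 0
        adj = np.zeros((4, 4), dtype=bool)
        for i, j in [(0, 1), (0, 2), (1, 2), (0, 3)]:
            adj[i, j] = adj[j, i] = True
        gm = global_metrics(BinaryGraph(adj))
        # eligible nodes: (k=3, C=1/3), (k=2, C=1), (k=2, C=1)
        x = np.log(np.array([3.0, 2.0, 2.0]))
        y = np.log(np.array([1 / 3, 1.0, 1.0]))
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        assert gm["hierarchy"] == pytest.approx(-slope, abs=1e-10)

    def test_hierarchy_undefined_on_regular_graph(self):
        # all degrees equal: no spread in log k, fit undefined
        assert np.isnan(global_metrics(_complete(5))["hierarchy"])

    def test_adding_edges_never_decreases_efficiency_or_degree(self, rng):
        adj = random_adjacency(8, 0.3, rng)
        g = BinaryGraph(adj)
        before = global_metrics(g)["Eglob"]
        deg_before = g.degrees.copy()
        missing = [
            (i, j)
            for i in range(8)
            for j in range(i + 1, 8)
            if not adj[i, j]
        ]
        i, j = missing[0]
        adj2 = adj.copy()
        adj2[i, j] = adj2[j, i] = True
        g2 = BinaryGraph(adj2)
        assert global_metrics(g2)["Eglob"] >= before - 1e-12
        assert np.all(g2.degrees >= deg_before)

    def test_isomorphism_invariance(self, rng):
        adj = random_adjacency(9, 0.4, rng)
        perm = rng.permutation(9)
        padj = adj[np.ix_(perm, perm)]
        gm1 = global_metrics(BinaryGraph(adj))
        gm2 = global_metrics(BinaryGraph(padj))
        for key in ("Cp", "Lp", "Eglob", "synchronization"):
            assert gm1[key] == pytest.approx(gm2[key], abs=1e-10)
        nm1 = nodal_metrics(BinaryGraph(adj))
        nm2 = nodal_metrics(BinaryGraph(padj))
        for col in ("clustering", "degree", "betweenness", "local_efficiency"):
            assert np.allclose(
                nm1[col].to_numpy()[perm], nm2[col].to_numpy(), atol=1e-10
            )


class TestMetricCurve:
    def test_default_grid_has_ten_points(self):
        assert len(DEFAULT_DENSITY_GRID) == 10
        assert DEFAULT_DENSITY_GRID[0] == pytest.approx(0.05)
        assert DEFAULT_DENSITY_GRID[-1] == pytest.approx(0.50)

    def test_constant_metric_auc(self):
        curve = MetricCurve("m", DEFAULT_DENSITY_GRID, np.full(10, 2.5))
        assert curve.auc == pytest.approx(0.45 * 2.5, abs=1e-12)

    def test_identity_metric_auc(self):
        grid = np.asarray(DEFAULT_DENSITY_GRID)
        curve = MetricCurve("m", grid, grid)
        assert curve.auc == pytest.approx((0.50**2 - 0.05**2) / 2, abs=1e-12)

    def test_single_point_grid_rejected(self, rng):
        net = _network_from_weights(rng.random((5, 5)))
        with pytest.raises(ValueError, match="single-point"):
            metric_curve(net, "Cp", [0.2])

    def test_degree_curve_values(self, rng):
        """Mean degree at density d is ~ d (n-1) by construction."""
        net = _network_from_weights(rng.uniform(0.01, 1.0, (20, 20)))
        curve = metric_curve(net, "degree", [0.1, 0.2, 0.5])
        npairs = 20 * 19 / 2
        for dens, val in zip(curve.grid, curve.values):
            assert val == pytest.approx(2 * round(dens * npairs) / 20, abs=1e-12)
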