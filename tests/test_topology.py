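"""Sparsity thresholding, graph metrics, small-world sigma, AUC aggregation."""

from __future__ import annotations

import numpy as np
import networkx as nx
import pytest

from distractnet.connectivity import ConnectivityMatrix
from distractnet.topology import (
    BinaryAdjacency,
    SparsitySweep,
    auc_average,
    char_path_length,
    clustering_coefficient,
    global_efficiency,
    local_efficiency,
    small_world_sigma,
    sweep_and_validate,
    threshold_at_sparsity,
    topology_profile,
)


def _adj(edges, n):
    a = np.zeros((n, n), dtype=np.uint8)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return BinaryAdjacency(a, 0.5)


def _complete(n):
    a = np.ones((n, n), dtype=np.uint8)
    np.fill_diagonal(a, 0)
    return BinaryAdjacency(a, 1.0)


class TestThreshold:
    def test_four_node_enumerated(self):
        """6 hand-set weights; s = 0.5 keeps exactly the 3 largest."""
        w = np.zeros((4, 4))
        w[0, 1], w[0, 2], w[0, 3] = 0.9, 0.1, 0.5
        w[1, 2], w[1, 3], w[2, 3] = 0.7, 0.2, 0.3
        w = w + w.T
        adj = threshold_at_sparsity(w, 0.5)
        assert adj.n_edges == 3
        assert adj.values[0, 1] == 1 and adj.values[1, 2] == 1 and adj.values[0, 3] == 1
        assert adj.values[0, 2] == 0

    def test_s_one_gives_complete_graph(self):
        w = np.random.default_rng(0).random((5, 5))
        w = np.triu(w, 1) + np.triu(w, 1).T
        adj = threshold_at_sparsity(w, 1.0)
        assert adj.n_edges == 10

    def test_symmetric_zero_diagonal(self):
        w = np.random.default_rng(1).random((6, 6))
        w = np.triu(w, 1) + np.triu(w, 1).T
        adj = threshold_at_sparsity(w, 0.3)
        assert np.array_equal(adj.values, adj.values.T)
        assert np.all(np.diag(adj.values) == 0)

    def test_invalid_sparsity_rejected(self):
        with pytest.raises(ValueError, match="sparsity"):
            threshold_at_sparsity(np.zeros((3, 3)), 0.0)

    def test_deterministic_tie_breaking(self):
        w = np.full((4, 4), 0.5)
        np.fill_diagonal(w, 0)
        a = threshold_at_sparsity(w, 0.5)
        b = threshold_at_sparsity(w, 0.5)
        assert np.array_equal(a.values, b.values)
        # lexicographic order: (0,1),(0,2),(0,3) first
        assert a.values[0, 1] == a.values[0, 2] == a.values[0, 3] == 1


class TestMetricsTrivial:
    def test_complete_k5(self):
        adj = _complete(5)
        assert char_path_length(adj) == 1.0
        assert global_efficiency(adj) == 1.0

    def test_path_graph(self):
        adj = _adj([(0, 1), (1, 2)], 3)
        assert char_path_length(adj) == pytest.approx(4.0 / 3.0)
        assert global_efficiency(adj) == pytest.approx(5.0 / 6.0)

    def test_triangle(self):
        adj = _adj([(0, 1), (1, 2), (0, 2)], 3)
        assert clustering_coefficient(adj) == 1.0
        assert local_efficiency(adj) == 1.0

    def test_star(self):
        adj = _adj([(0, 1), (0, 2), (0, 3)], 4)
        assert clustering_coefficient(adj) == 0.0
        assert local_efficiency(adj) == 0.0

    def test_edgeless(self):
        adj = BinaryAdjacency(np.zeros((4, 4), dtype=np.uint8), 0.5)
        assert global_efficiency(adj) == 0.0


class TestMetricsOracle:
    def test_networkx_equivalence_on_random_graphs(self):
        """All four metrics match networkx on 50 random graphs to 1e-10."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(5, 31))
            p = rng.uniform(0.1, 0.9)
            a = np.triu((rng.random((n, n)) < p).astype(np.uint8), 1)
            a = a + a.T
            adj = BinaryAdjacency(a, 0.5)
            g = nx.from_numpy_array(a)
            total = count = 0
            for s, dists in nx.all_pairs_shortest_path_length(g):
                for t, d in dists.items():
                    if t != s:
                        total += d
                        count += 1
            if count:
                assert abs(char_path_length(adj) - total / count) < 1e-10
            assert abs(clustering_coefficient(adj) - nx.average_clustering(g)) < 1e-10
            assert abs(global_efficiency(adj) - nx.global_efficiency(g)) < 1e-10
            assert abs(local_efficiency(adj) - nx.local_efficiency(g)) < 1e-10


class TestSmallWorld:
    def test_complete_graph_sigma_one(self):
        assert small_world_sigma(_complete(12), n_null=5, seed=0) == 1.0

    def test_watts_strogatz_small_world(self):
        a = nx.to_numpy_array(nx.watts_strogatz_graph(63, 8, 0.1, seed=5)).astype(np.uint8)
        sigma = small_world_sigma(BinaryAdjacency(a, 0.13), n_null=20, seed=3)
        assert sigma > 1.1

    def test_dense_random_graph_sigma_near_one(self):
        a = nx.to_numpy_array(nx.erdos_renyi_graph(63, 0.3, seed=7)).astype(np.uint8)
        sigma = small_world_sigma(BinaryAdjacency(a, 0.3), n_null=20, seed=3)
        assert abs(sigma - 1.0) <= 0.15

    def test_deterministic_given_seed(self):
        a = nx.to_numpy_array(nx.erdos_renyi_graph(30, 0.2, seed=1)).astype(np.uint8)
        adj = BinaryAdjacency(a, 0.2)
        assert small_world_sigma(adj, n_null=5, seed=9) == small_world_sigma(
            adj, n_null=5, seed=9
        )

    def test_edgeless_rejected(self):
        with pytest.raises(ValueError, match="edge"):
            small_world_sigma(BinaryAdjacency(np.zeros((4, 4), dtype=np.uint8), 0.1))


class TestSweep:
    def test_default_grid_35_points(self):
        assert len(SparsitySweep().grid) == 35

    def test_degree_rule_arithmetic_at_47_percent(self):
        """At s = 0.47, n = 63: mean degree 2*round(0.47*1953)/63 passes the
        degree rule under any log base in use."""
        w = np.random.default_rng(0).random((63, 63))
        w = np.triu(w, 1) + np.triu(w, 1).T
        adj = threshold_at_sparsity(w, 0.47)
        mean_deg = adj.degrees.mean()
        assert mean_deg == pytest.approx(2 * round(0.47 * 1953) / 63)
        assert mean_deg > 2 * np.log(63)  # natural log, the strictest base

    def test_nested_thresholding_and_eg_monotone(self):
        w = np.random.default_rng(3).random((20, 20))
        w = np.triu(w, 1) + np.triu(w, 1).T
        sweep = SparsitySweep()
        prev = None
        prev_eg = -1.0
        for s in sweep.grid:
            adj = threshold_at_sparsity(w, float(s))
            if prev is not None:
                assert np.all(adj.values >= prev)  # subgraph nesting
                assert adj.values.sum() >= prev.sum()
            eg = global_efficiency(adj)
            assert eg >= prev_eg - 1e-12
            prev, prev_eg = adj.values, eg

    def test_flags_recorded_not_dropped(self):
        w = np.random.default_rng(4).random((20, 20))
        w = np.triu(w, 1) + np.triu(w, 1).T
        pts = sweep_and_validate(w, SparsitySweep(), seed=0, compute_sigma=False)
        assert len(pts) == 35
        assert all(p.sigma is None for p in pts)
        assert all(isinstance(p.degree_ok, (bool, np.bool_)) for p in pts)


class TestAUC:
    def test_constant_curve(self):
        grid = SparsitySweep().grid
        assert auc_average(grid, np.full_like(grid, 2.0)) == pytest.approx(2.0)

    def test_linear_ramp(self):
        grid = SparsitySweep().grid
        ramp = np.linspace(0, 1, len(grid))
        assert auc_average(grid, ramp) == pytest.approx(0.5)

    def test_mean_value_property(self):
        rng = np.random.default_rng(5)
        grid = SparsitySweep().grid
        vals = rng.random(len(grid))
        a = auc_average(grid, vals)
        assert vals.min() <= a <= vals.max()

    def test_single_point_returns_value_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            assert auc_average(np.array([0.2]), np.array([3.0])) == 3.0
        assert "single point" in caplog.text


class TestProfile:
    def test_profile_features_complete(self):
        w = np.random.default_rng(6).random((12, 12))
        w = np.clip(np.triu(w, 1) + np.triu(w, 1).T, 0, 1)
        mat = ConnectivityMatrix(w, "PLV", "theta")
        prof = topology_profile(mat)
        feats = prof.as_features()
        assert set(feats) == {
            "PLV_theta_V", "PLV_theta_Lg", "PLV_theta_Cg", "PLV_theta_Eg", "PLV_theta_El"
        }
        for f in ("Cg", "Eg", "El"):
            assert 0.0 <= prof.auc[f] <= 1.0
        assert prof.auc["Lg"] >= 1.0
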