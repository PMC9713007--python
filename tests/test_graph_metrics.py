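"""Weighted topology metrics, reference nulls, and AUC integration."""

import networkx as nx
import numpy as np
import pytest

from conftest import complete_graph, nx_to_graph, unit_graph
from ridgeconn.connectome import WeightedGraph
from ridgeconn.graph_metrics import (
    GLOBAL_ATTRIBUTES,
    MetricCurve,
    ReferenceConfig,
    assemble_auc_features,
    auc_over_thresholds,
    global_metrics,
    lattice_reference,
    nodal_metrics,
    random_reference,
)

FAST_REF = ReferenceConfig(n_refs=2, n_swaps_per_edge=2, lattice_passes=1, louvain_restarts=3)


class TestClosedFormGlobalMetrics:
    def test_complete_k4_identities(self):
        m = global_metrics(complete_graph(4), FAST_REF, seed=0)
        assert m.Cp == pytest.approx(1.0, abs=1e-12)
        assert m.Lp == pytest.approx(1.0, abs=1e-12)
        assert m.E_glob == pytest.approx(1.0, abs=1e-12)
        assert m.Sp == pytest.approx(3.0, abs=1e-12)

    def test_path_graph_global_efficiency(self):
        p3 = unit_graph(3, [(0, 1), (1, 2)])
        m = global_metrics(p3, FAST_REF, seed=0)
        # pair inverse distances 1, 1, 1/2 averaged over 3 pairs
        assert m.E_glob == pytest.approx(5 / 6, abs=1e-12)

    def test_two_disjoint_cliques_modularity_half(self):
        edges = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        g = unit_graph(8, edges + [(i + 4, j + 4) for i, j in edges])
        m = global_metrics(g, FAST_REF, seed=0)
        assert m.Q == pytest.approx(0.5, abs=1e-12)

    def test_edgeless_rejected(self):
        with pytest.raises(ValueError):
            global_metrics(
                WeightedGraph(3, np.array([], dtype=int), np.array([], dtype=int),
                              np.array([]), 0.1),
                FAST_REF,
            )


class TestNodalMetrics:
    def test_path_graph_nodal_efficiency(self):
        nm = nodal_metrics(unit_graph(3, [(0, 1), (1, 2)]))
        assert nm.E_nodal[1] == pytest.approx(1.0, abs=1e-12)
        assert nm.E_nodal[0] == pytest.approx(0.75, abs=1e-12)
        assert nm.E_nodal[2] == pytest.approx(0.75, abs=1e-12)

    def test_star_betweenness(self):
        nm = nodal_metrics(unit_graph(4, [(0, 1), (0, 2), (0, 3)]))
        assert nm.btwn_cent[0] == pytest.approx(3.0, abs=1e-12)
        assert np.all(nm.btwn_cent[1:] == 0)

    def test_complete_graph_betweenness_zero(self):
        nm = nodal_metrics(complete_graph(5))
        assert np.all(nm.btwn_cent == 0)


def brute_force_binary_metrics(g: WeightedGraph):
    """Floyd-Warshall oracle for binary Cp / Lp / E_glob on tiny graphs."""
    n = g.n_nodes
    A = g.to_dense() > 0
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0)
    D[A] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                D[i, j] = min(D[i, j], D[i, k] + D[k, j])
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    lp = D[finite].mean()
    eg = (1 / D[finite]).sum() / (n * (n - 1))
    cps = []
    for i in range(n):
        nb = np.flatnonzero(A[i])
        k = len(nb)
        if k < 2:
            cps.append(0.0)
            continue
        links = sum(A[u, v] for ui, u in enumerate(nb) for v in nb[ui + 1:])
        cps.append(2 * links / (k * (k - 1)))
    return np.mean(cps), lp, eg


class TestUnweightedReduction:
    def test_matches_brute_force_oracle_on_small_graphs(self, rng):
        for trial in range(5):
            G = nx.gnp_random_graph(10, 0.35, seed=int(rng.integers(1e6)))
            if G.number_of_edges() < 2:
                continue
            g = nx_to_graph(G, 10)
            cp_o, lp_o, eg_o = brute_force_binary_metrics(g)
            m = global_metrics(g, FAST_REF, seed=trial)
            assert m.Cp == pytest.approx(cp_o, abs=1e-12)
            assert m.Lp == pytest.approx(lp_o, abs=1e-12)
            assert m.E_glob == pytest.approx(eg_o, abs=1e-12)


class TestReferenceNulls:
    def _degrees(self, g):
        deg = np.zeros(g.n_nodes, dtype=int)
        for i, j in zip(g.edge_i, g.edge_j):
            deg[i] += 1
            deg[j] += 1
        return deg

    def test_random_reference_preserves_degrees_and_weights(self, rng):
        G = nx.gnp_random_graph(30, 0.2, seed=5)
        g = nx_to_graph(G, 30)
        ref = random_reference(g, n_swaps_per_edge=10, seed=3)
        assert np.array_equal(self._degrees(g), self._degrees(ref))
        assert np.allclose(np.sort(g.weights), np.sort(ref.weights))
        assert ref.n_edges == g.n_edges

    def test_lattice_reference_preserves_degrees_and_weights(self):
        G = nx.gnp_random_graph(30, 0.2, seed=6)
        g = nx_to_graph(G, 30)
        ref = lattice_reference(g, n_passes=2, seed=4)
        assert np.array_equal(self._degrees(g), self._degrees(ref))
        assert np.allclose(np.sort(g.weights), np.sort(ref.weights))

    def test_randomizing_ring_lattice_lowers_clustering_and_path_length(self):
        from ridgeconn.graph_metrics import _cp_lp

        wins = 0
        for seed in range(10):
            g = nx_to_graph(nx.watts_strogatz_graph(100, 10, 0.0, seed=seed), 100)
            cp0, lp0 = _cp_lp(g)
            ref = random_reference(g, n_swaps_per_edge=10, seed=seed)
            cp1, lp1 = _cp_lp(ref)
            wins += (cp1 < cp0) and (lp1 < lp0)
        assert wins == 10

    def test_latticizing_random_graph_raises_clustering(self):
        from ridgeconn.graph_metrics import _cp_lp

        wins = 0
        for seed in range(10):
            g = nx_to_graph(nx.gnp_random_graph(80, 0.12, seed=seed), 80)
            cp0, _ = _cp_lp(g)
            ref = lattice_reference(g, n_passes=5, seed=seed)
            cp1, _ = _cp_lp(ref)
            wins += cp1 > cp0
        assert wins == 10

    def test_perfect_ring_lattice_objective_does_not_increase(self):
        from ridgeconn.graph_metrics import _ring_dist

        g = nx_to_graph(nx.watts_strogatz_graph(40, 6, 0.0, seed=0), 40)
        before = sum(_ring_dist(int(i), int(j), 40) for i, j in zip(g.edge_i, g.edge_j))
        ref = lattice_reference(g, n_passes=3, seed=1)
        after = sum(_ring_dist(int(i), int(j), 40) for i, j in zip(ref.edge_i, ref.edge_j))
        assert after <= before


class TestScaleRobustness:
    def test_weight_rescaling_leaves_normalized_metrics_unchanged(self, rng):
        G = nx.gnp_random_graph(25, 0.3, seed=9)
        edges = sorted((min(u, v), max(u, v)) for u, v in G.edges())
        ei = np.array([e[0] for e in edges])
        ej = np.array([e[1] for e in edges])
        w = rng.uniform(0.2, 1.0, len(edges))
        g1 = WeightedGraph(25, ei, ej, w, 0.1)
        g2 = WeightedGraph(25, ei, ej, 7.3 * w, 0.1)
        m1 = global_metrics(g1, FAST_REF, seed=2)
        m2 = global_metrics(g2, FAST_REF, seed=2)
        for attr in ("Cp", "E_glob", "Q", "sigma", "omega"):
            assert getattr(m1, attr) == pytest.approx(getattr(m2, attr), rel=1e-9)


class TestAUC:
    def test_constant_curve_over_standard_grid(self):
        grid = np.round(np.arange(0.05, 0.401, 0.01), 2)
        c = MetricCurve(grid, np.ones(36), "Cp")
        assert auc_over_thresholds(c) == pytest.approx(0.35, abs=1e-12)

    def test_identity_curve_over_standard_grid(self):
        grid = np.round(np.arange(0.05, 0.401, 0.01), 2)
        c = MetricCurve(grid, grid.copy(), "x")
        assert auc_over_thresholds(c) == pytest.approx(0.07875, abs=1e-12)

    def test_single_interval_trapezoid(self):
        c = MetricCurve(np.array([0.1, 0.2]), np.array([2.0, 4.0]), "x")
        assert auc_over_thresholds(c) == pytest.approx(0.3, abs=1e-12)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            auc_over_thresholds(MetricCurve(np.array([0.1]), np.array([1.0]), "x"))


def _dummy_curves(n_nodes, subject_ids):
    grid = np.array([0.1, 0.2, 0.3])
    out = {}
    for sid in subject_ids:
        curves = {
            a: MetricCurve(grid, np.ones(3), a, sid) for a in GLOBAL_ATTRIBUTES
        }
        for attr in ("E_nodal", "btwn_cent"):
            for k in range(n_nodes):
                name = f"{attr}:roi{k}"
                curves[name] = MetricCurve(grid, np.full(3, 0.5), name, sid)
        out[sid] = curves
    return out


class TestAssembleAUCFeatures:
    def test_column_arithmetic_60_nodes(self):
        table = assemble_auc_features(_dummy_curves(60, ["a", "b"]), include_e_loc=False)
        assert table.shape == (2, 7 + 2 * 60)

    def test_column_arithmetic_246_nodes_matches_atlas_feature_space(self):
        table = assemble_auc_features(_dummy_curves(246, ["a"]), include_e_loc=False)
        assert table.shape[1] == 499
        table = assemble_auc_features(_dummy_curves(246, ["a"]), include_e_loc=True)
        assert table.shape[1] == 500

    def test_missing_curve_fails_naming_subject(self):
        curves = _dummy_curves(4, ["a", "b"])
        del curves["b"]["E_nodal:roi2"]
        with pytest.raises(ValueError, match="b"):
            assemble_auc_features(curves)
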