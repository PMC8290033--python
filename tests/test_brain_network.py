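import numpy as np
import pytest

from multibiodx.brain_network import (
    DEFAULT_COSTS,
    GLOBAL_ATTRS,
    NODAL_ATTRS,
    CostGraph,
    auc_over_costs,
    binarize_at_cost,
    eeg_feature_vector,
    global_metrics,
    nodal_metrics,
    pair_order,
    rewired_null,
    small_world_indices,
)

import oracles


def graph_from_adj(adj, cost=0.5):
    return CostGraph(np.asarray(adj, dtype=np.uint8), cost=cost)


class TestBinarize:
    def test_full_cost_gives_complete_graph(self, random_plv):
        g = binarize_at_cost(random_plv(1), 1.0)
        assert g.n_edges == 120

    def test_cost_grid_start_edge_count(self, random_plv):
        assert binarize_at_cost(random_plv(1), 0.34).n_edges == 41  # round(40.8)

    def test_edges_are_topk_weights(self, random_plv):
        m = random_plv(7)
        g = binarize_at_cost(m, 0.5)
        iu, ju = np.triu_indices(16, k=1)
        w = m.values[iu, ju]
        kth = np.sort(w)[::-1][g.n_edges - 1]  # brute-force sort oracle
        picked = w[g.adjacency[iu, ju] == 1]
        assert picked.min() >= kth - 1e-15
        assert len(picked) == g.n_edges

    def test_nested_across_cost_grid(self, random_plv):
        m = random_plv(3)
        prev = None
        for cost in DEFAULT_COSTS:
            adj = binarize_at_cost(m, cost).adjacency
            if prev is not None:
                assert np.all(adj >= prev)  # edge sets nested
            prev = adj

    def test_invalid_cost_rejected(self, random_plv):
        with pytest.raises(ValueError):
            binarize_at_cost(random_plv(1), 0.0)


class TestMetricsExamples:
    def test_complete_graph(self):
        k16 = 1 - np.eye(16, dtype=int)
        gm = global_metrics(graph_from_adj(k16))
        assert gm.aCp == gm.aLp == gm.aEg == gm.aEloc == 1.0
        nm = nodal_metrics(graph_from_adj(k16))
        assert np.all(nm.aNCp == 1.0)
        assert np.all(nm.aDc == 15)
        assert np.all(nm.aNe == 1.0)

    def test_path_graph_three_nodes(self):
        p3 = [[0, 1, 0], [1, 0, 1], [0, 1, 0]]
        gm = global_metrics(graph_from_adj(p3))
        assert gm.aEg == pytest.approx(5 / 6)
        assert gm.aLp == pytest.approx(4 / 3)

    def test_star_graph_center(self):
        star = np.zeros((5, 5), dtype=int)
        star[0, 1:] = star[1:, 0] = 1
        nm = nodal_metrics(graph_from_adj(star))
        assert nm.aNCp[0] == 0.0
        assert nm.aDc[0] == 4
        assert nm.aNe[0] == 1.0

    def test_empty_graph_degenerates(self):
        gm = global_metrics(graph_from_adj(np.zeros((4, 4), dtype=int)))
        assert gm.aEg == 0.0 and gm.aCp == 0.0
        assert np.isnan(gm.aLp)


class TestOracleEquivalence:
    def test_fifty_random_graphs_match_bruteforce(self):
        r = np.random.default_rng(42)
        for trial in range(50):
            adj = oracles.random_adjacency(r, n=16, p=r.uniform(0.15, 0.85))
            g = graph_from_adj(adj)
            gm = global_metrics(g)
            o_cp, o_lp, o_eg, o_eloc = oracles.oracle_global(adj)
            assert gm.aCp == pytest.approx(o_cp, abs=1e-9)
            assert gm.aEg == pytest.approx(o_eg, abs=1e-9)
            assert gm.aEloc == pytest.approx(o_eloc, abs=1e-9)
            if np.isnan(o_lp):
                assert np.isnan(gm.aLp)
            else:
                assert gm.aLp == pytest.approx(o_lp, abs=1e-9)
            nm = nodal_metrics(g)
            onod = oracles.oracle_nodal(adj)
            for attr in NODAL_ATTRS:
                mine = getattr(nm, attr)
                theirs = onod[attr]
                assert np.allclose(mine, theirs, atol=1e-9, equal_nan=True)

    def test_matches_networkx_library(self):
        nx = pytest.importorskip("networkx")
        r = np.random.default_rng(7)
        for _ in range(10):
            adj = np.asarray(oracles.random_adjacency(r, n=12, p=0.4))
            g = graph_from_adj(adj)
            G = nx.from_numpy_array(adj)
            gm = global_metrics(g)
            assert gm.aCp == pytest.approx(nx.average_clustering(G), abs=1e-9)
            assert gm.aEg == pytest.approx(nx.global_efficiency(G), abs=1e-9)
            assert gm.aEloc == pytest.approx(nx.local_efficiency(G), abs=1e-9)


class TestRewiredNull:
    def test_degree_sequence_and_edge_count_preserved(self, random_plv):
        g = binarize_at_cost(random_plv(5), 0.4)
        nulls = rewired_null(g, n_rand=20, seed=1)
        assert len(nulls) == 20
        for h in nulls:
            assert np.array_equal(h.degrees, g.degrees)
            assert h.n_edges == g.n_edges

    def test_rewiring_destroys_lattice_clustering(self):
        n = 16
        ring = np.zeros((n, n), dtype=int)
        for i in range(n):
            for step in (1, 2):
                ring[i, (i + step) % n] = ring[(i + step) % n, i] = 1
        g = graph_from_adj(ring)
        lattice_cp = global_metrics(g).aCp
        nulls = rewired_null(g, n_rand=30, seed=3)
        null_cp = np.mean([global_metrics(h).aCp for h in nulls])
        assert null_cp < lattice_cp

    def test_complete_graph_has_no_swaps(self):
        g = graph_from_adj(1 - np.eye(6, dtype=int))
        with pytest.warns(UserWarning):
            nulls = rewired_null(g, n_rand=2, seed=0)
        assert all(h.degenerate for h in nulls)
        assert np.array_equal(nulls[0].adjacency, g.adjacency)


class TestSmallWorldIndices:
    def test_self_ensemble_gives_exact_ones(self, random_plv):
        g = binarize_at_cost(random_plv(2), 0.4)
        gamma, lam, sigma = small_world_indices(g, [g])
        assert (gamma, lam, sigma) == (1.0, 1.0, 1.0)

    def test_random_graph_near_unity(self):
        r = np.random.default_rng(11)
        # a uniformly random graph is statistically its own null
        adj = np.asarray(oracles.random_adjacency(r, n=16, p=41 / 120))
        g = graph_from_adj(adj)
        nulls = rewired_null(g, n_rand=100, seed=5)
        gamma, lam, _ = small_world_indices(g, nulls)
        assert gamma == pytest.approx(1.0, abs=0.25)
        assert lam == pytest.approx(1.0, abs=0.08)

    def test_small_world_lattice_has_sigma_above_one(self):
        n = 16
        ring = np.zeros((n, n), dtype=int)
        for i in range(n):
            for step in (1, 2, 3):
                ring[i, (i + step) % n] = ring[(i + step) % n, i] = 1
        rng = np.random.default_rng(0)
        # light Watts-Strogatz-style rewiring of a few edges
        g = graph_from_adj(ring)
        nulls = rewired_null(g, n_rand=50, seed=9)
        _, _, sigma = small_world_indices(g, nulls)
        assert sigma > 1.0


class TestAUC:
    def test_constant_curve_gives_range_width(self):
        assert auc_over_costs(DEFAULT_COSTS, np.ones(40)) == pytest.approx(0.39)

    def test_linear_ramp_gives_triangle_area(self):
        ramp = np.linspace(0, 1, 40)
        assert auc_over_costs(DEFAULT_COSTS, ramp) == pytest.approx(0.195)

    def test_matches_independent_trapezoid_loop(self, rng):
        vals = rng.random(40)
        acc = 0.0
        for i in range(39):  # independent numerical integration
            acc += 0.5 * (vals[i] + vals[i + 1]) * (DEFAULT_COSTS[i + 1] - DEFAULT_COSTS[i])
        assert auc_over_costs(DEFAULT_COSTS, vals) == pytest.approx(acc, abs=1e-12)

    def test_all_undefined_curve_propagates_nan(self):
        assert np.isnan(auc_over_costs(DEFAULT_COSTS, np.full(40, np.nan)))


class TestFeatureVector:
    def test_census_and_naming(self, random_plv):
        bands = {}
        from multibiodx.eeg_preprocess import DEFAULT_BANDS
        for i, b in enumerate(DEFAULT_BANDS):
            bands[b] = random_plv(i, band=b)
        fv = eeg_feature_vector(bands, costs=DEFAULT_COSTS[::8], n_null=2, seed=0)
        assert len(fv) == 696
        n_global = sum(1 for n in fv.index if len(n.split("_")) == 2)
        assert n_global == 56
        assert len(fv) - n_global == 640
        assert "theta_aNLe_T6" in fv.index

    def test_missing_band_rejected(self, random_plv):
        with pytest.raises(ValueError):
            eeg_feature_vector({"theta": random_plv(0)})


def test_efficiency_nondecreasing_along_nested_costs(random_plv):
    m = random_plv(9)
    prev = -1.0
    for cost in DEFAULT_COSTS[::4]:
        eg = global_metrics(binarize_at_cost(m, cost)).aEg
        assert eg >= prev - 1e-12
        prev = eg


def test_pair_order_is_total_and_weight_sorted(random_plv):
    m = random_plv(4)
    rows, cols = pair_order(m.values)
    w = m.values[rows, cols]
    assert len(w) == 120
    assert np.all(np.diff(w) <= 1e-15)
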