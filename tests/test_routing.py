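import numpy as np
import pytest

from thalroute import (
    LambdaGrid,
    NetworkDefinition,
    WeightedConnectome,
    all_pairs,
    cost_spectrum,
    expected_visits,
    geodesic_matrix,
    informational_cost,
    reading_pivot_pairs,
    simulate_walks,
    thalamic_cost,
    threshold_edges,
    toy_fixture,
    transition_model,
    transmission_cost,
    weight_to_length,
)

from conftest import random_connected_connectome


def prep(c):
    d = weight_to_length(c)
    return d, geodesic_matrix(d)


class TestLambdaGrid:
    def test_default_spans_both_averaging_windows(self):
        g = LambdaGrid.default()
        assert g.n_steps == 30
        assert g.ln_lambda_values[0] == pytest.approx(-5.1)
        assert g.ln_lambda_values[-1] == pytest.approx(2.76)

    def test_rejects_unsorted_or_uneven(self):
        with pytest.raises(ValueError):
            LambdaGrid(np.array([0.0, -1.0]))
        with pytest.raises(ValueError):
            LambdaGrid(np.array([0.0, 1.0, 3.0]))


class TestTransitionModel:
    def test_single_neighbour_forces_probability_one(self):
        c = toy_fixture("path3").connectome()
        d, g = prep(c)
        for lnl in (-5.0, 0.0, 5.0):
            tm = transition_model(d, g, lnl, "C")
            assert tm.probabilities[0, 1] == pytest.approx(1.0)  # A -> B

    def test_symmetric_neighbours_split_evenly(self):
        # A connects to B and C with equal weight; B,C -> T equal weight
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 5
        w[0, 2] = w[2, 0] = 5
        w[1, 3] = w[3, 1] = 7
        w[2, 3] = w[3, 2] = 7
        c = WeightedConnectome(("A", "B", "C", "T"), w)
        d, g = prep(c)
        for lnl in (-3.0, 0.7, 4.0):
            tm = transition_model(d, g, lnl, "T")
            assert tm.probabilities[0, 1] == pytest.approx(0.5)
            assert tm.probabilities[0, 2] == pytest.approx(0.5)

    def test_rows_stochastic_with_neighbour_support(self):
        c = threshold_edges(random_connected_connectome(10, 0.4, seed=5))
        d, g = prep(c)
        tm = transition_model(d, g, 0.3, 9)
        P = tm.probabilities
        np.testing.assert_allclose(P[tm.transient].sum(axis=1), 1.0)
        adj = d.adjacency()
        assert np.all(P[tm.transient][~adj[tm.transient]] == 0)
        assert P[9, 9] == 1.0

    def test_large_lambda_argmax_is_dijkstra_successor(self):
        for seed in range(50):
            c = threshold_edges(random_connected_connectome(10, 0.4,
                                                            seed=seed))
            d, g = prep(c)
            tm = transition_model(d, g, 8.0, 0)
            for i in tm.transient:
                nbrs = np.flatnonzero(d.adjacency()[i])
                scores = d.lengths[i, nbrs] + g.g[nbrs, 0]
                # the modal successor must be a minimizer of d_ij + g_jt
                # (ties between equally short routes are both acceptable)
                best = int(np.argmax(tm.probabilities[i]))
                k = int(np.flatnonzero(nbrs == best)[0])
                assert scores[k] == pytest.approx(scores.min(), abs=1e-9)

    def test_permutation_equivariance(self):
        c = threshold_edges(random_connected_connectome(8, 0.5, seed=11))
        d, g = prep(c)
        tm = transition_model(d, g, 0.4, 0)
        rng = np.random.default_rng(3)
        perm = rng.permutation(8)
        labels = tuple(c.node_labels[p] for p in perm)
        cp = WeightedConnectome(labels, c.weights[np.ix_(perm, perm)])
        dp, gp = prep(cp)
        tmp = transition_model(dp, gp, 0.4,
                               int(np.flatnonzero(perm == 0)[0]))
        np.testing.assert_allclose(
            tmp.probabilities,
            tm.probabilities[np.ix_(perm, perm)], atol=1e-12)

    def test_unreachable_nodes_flagged(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 3  # component {A,B}; {C,D} separate
        w[2, 3] = w[3, 2] = 3
        c = WeightedConnectome(("A", "B", "C", "D"), w)
        d, g = prep(c)
        tm = transition_model(d, g, 0.0, "A")
        assert set(tm.excluded) == {2, 3}
        assert list(tm.transient) == [1]


class TestTransmissionCost:
    def test_single_edge_cost_equals_length_for_all_lambda(self):
        fx = toy_fixture("single_edge")
        c = fx.connectome()
        d, g = prep(c)
        for lnl in np.linspace(-5, 3, 7):
            tm = transition_model(d, g, lnl, "B")
            assert transmission_cost(tm, d, "A") == pytest.approx(
                fx.expected["c_trans_flat"])

    def test_path3_closed_form(self):
        # walk B->C on A-B-C: from B step to C w.p. p, else detour via A
        # and return; E[cost] = d_BC + 2 (q/p) d_AB
        c = toy_fixture("path3").connectome()
        d, g = prep(c)
        for lnl in (-2.0, 0.0, 2.0):
            tm = transition_model(d, g, lnl, "C")
            p = tm.probabilities[1, 2]
            q = tm.probabilities[1, 0]
            expected = d.lengths[1, 2] + 2 * (q / p) * d.lengths[0, 1]
            assert transmission_cost(tm, d, "B") == pytest.approx(expected)

    def test_cost_bounded_below_by_geodesic(self):
        for seed in range(10):
            c = threshold_edges(random_connected_connectome(9, 0.4,
                                                            seed=seed))
            d, g = prep(c)
            for lnl in (-4.0, 0.0, 2.0):
                tm = transition_model(d, g, lnl, 8)
                for s in range(8):
                    assert transmission_cost(tm, d, s) >= g.g[s, 8] - 1e-9

    def test_directional_asymmetry_exists(self):
        # costs use target-specific models; generically cost(s,t)!=cost(t,s)
        c = threshold_edges(random_connected_connectome(9, 0.4, seed=21))
        d, g = prep(c)
        tm_t = transition_model(d, g, -0.5, 8)
        tm_s = transition_model(d, g, -0.5, 0)
        fwd = transmission_cost(tm_t, d, 0)
        rev = transmission_cost(tm_s, d, 8)
        assert fwd != pytest.approx(rev, rel=1e-6)


class TestInformationalCost:
    def test_zero_against_itself(self):
        c = threshold_edges(random_connected_connectome(8, 0.5, seed=4))
        d, g = prep(c)
        null = transition_model(d, g, 0.0, 7, null=True)
        assert informational_cost(null, null, 0) == pytest.approx(0.0)

    def test_zero_on_deterministic_chain(self):
        c = toy_fixture("single_edge").connectome()
        d, g = prep(c)
        null = transition_model(d, g, 0.0, "B", null=True)
        for lnl in (-3.0, 0.0, 3.0):
            tm = transition_model(d, g, lnl, "B")
            assert informational_cost(tm, null, "A") == pytest.approx(0.0)

    def test_nonnegative_and_increasing_in_lambda(self):
        c = threshold_edges(random_connected_connectome(9, 0.45, seed=13))
        d, g = prep(c)
        null = transition_model(d, g, 0.0, 8, null=True)
        prev = -1e-12
        for lnl in np.linspace(-5.1, 2.76, 10):
            tm = transition_model(d, g, lnl, 8)
            val = informational_cost(tm, null, 0)
            assert val >= -1e-12
            assert val >= prev - 1e-9
            prev = val


class TestExpectedVisits:
    def test_source_visits_at_least_once(self):
        c = threshold_edges(random_connected_connectome(9, 0.4, seed=17))
        d, g = prep(c)
        tm = transition_model(d, g, 0.0, 8)
        nu = expected_visits(tm, 0)
        assert nu[0] >= 1.0

    def test_bridge_node_visited_from_across_module(self):
        fx = toy_fixture("two_module_bridge")
        c = fx.connectome()
        d, g = prep(c)
        tm = transition_model(d, g, 0.0, "F")  # target in module 2
        nu = expected_visits(tm, "A")          # source in module 1
        for lab in fx.expected["bridge_nodes"]:
            assert nu[c.index_of(lab)] >= 1.0

    def test_visits_agree_with_simulation(self):
        c = threshold_edges(random_connected_connectome(8, 0.5, seed=19))
        d, g = prep(c)
        tm = transition_model(d, g, 0.2, 7)
        nu = expected_visits(tm, 0)
        # simulate and count visits
        rng = np.random.default_rng(0)
        counts = np.zeros(8)
        n_walks = 20000
        for _ in range(n_walks):
            cur = 0
            for _ in range(1000):
                counts[cur] += 1
                cur = rng.choice(8, p=tm.probabilities[cur])
                if cur == 7:
                    break
        emp = counts / n_walks
        for i in tm.transient:
            se = max(np.sqrt(nu[i] / n_walks), 1e-3)
            assert abs(emp[i] - nu[i]) < 5 * se


class TestSpectraAndPivot:
    def test_single_edge_flat_spectra(self):
        fx = toy_fixture("single_edge")
        spec = cost_spectrum(fx.connectome(), [("A", "B")])
        np.testing.assert_allclose(spec.c_trans[0],
                                   fx.expected["c_trans_flat"])
        np.testing.assert_allclose(spec.c_info[0], 0.0, atol=1e-12)

    def test_unreachable_pair_recorded_infinite(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 3
        w[2, 3] = w[3, 2] = 3
        c = WeightedConnectome(("A", "B", "C", "D"), w)
        spec = cost_spectrum(c, [("A", "C"), ("A", "B")])
        assert np.isinf(spec.c_trans[0]).all()
        assert spec.n_unreachable == 1
        mt, _ = spec.mean_curves()
        assert np.isfinite(mt).all()  # averages skip the unreachable pair

    def test_thalamic_cost_single_region(self):
        c = threshold_edges(random_connected_connectome(6, 0.5, seed=23))
        nd = NetworkDefinition(frozenset(), frozenset({"N0", "N5"}),
                               pivot_node="N5")
        pairs = reading_pivot_pairs(nd)
        assert set(pairs) == {("N0", "N5"), ("N5", "N0")}
        spec = cost_spectrum(c, pairs)
        tc = thalamic_cost(spec, nd)
        np.testing.assert_allclose(
            tc.total("trans"),
            spec.c_trans[spec.pair_index("N0", "N5")]
            + spec.c_trans[spec.pair_index("N5", "N0")])

    def test_thalamic_cost_matches_enumeration(self):
        c = threshold_edges(random_connected_connectome(10, 0.4, seed=29))
        regions = {"N1", "N2", "N3"}
        nd = NetworkDefinition(frozenset(), frozenset(regions | {"N0"}),
                               pivot_node="N0")
        spec = cost_spectrum(c, reading_pivot_pairs(nd))
        tc = thalamic_cost(spec, nd)
        for kind, arr in (("trans", spec.c_trans), ("info", spec.c_info)):
            manual = sum(arr[spec.pair_index(r, "N0")] for r in sorted(regions))
            manual = manual + sum(arr[spec.pair_index("N0", r)]
                                  for r in sorted(regions))
            np.testing.assert_allclose(tc.total(kind), manual)

    def test_missing_pair_raises(self):
        c = threshold_edges(random_connected_connectome(6, 0.5, seed=23))
        nd = NetworkDefinition(frozenset(), frozenset({"N0", "N1", "N5"}),
                               pivot_node="N5")
        spec = cost_spectrum(c, [("N0", "N5"), ("N5", "N0")])
        with pytest.raises(ValueError, match="missing"):
            thalamic_cost(spec, nd)

    def test_mean_aggregate_is_sum_over_pair_count(self):
        c = threshold_edges(random_connected_connectome(8, 0.5, seed=31))
        nd = NetworkDefinition(frozenset(), frozenset({"N0", "N1", "N2"}),
                               pivot_node="N0")
        spec = cost_spectrum(c, reading_pivot_pairs(nd))
        tc = thalamic_cost(spec, nd)
        np.testing.assert_allclose(tc.total("trans", "mean"),
                                   tc.total("trans") / 4)


class TestSimulateWalks:
    def test_deterministic_chain_zero_variance(self):
        fx = toy_fixture("single_edge")
        c = fx.connectome()
        d, g = prep(c)
        tm = transition_model(d, g, 0.0, "B")
        est = simulate_walks(tm, d, "A", 500, seed=1)
        assert est.mean_distance == pytest.approx(fx.expected["c_trans_flat"])
        assert est.n_truncated == 0

    def test_same_seed_reproducible(self):
        c = threshold_edges(random_connected_connectome(9, 0.4, seed=37))
        d, g = prep(c)
        tm = transition_model(d, g, 0.0, 8)
        a = simulate_walks(tm, d, 0, 2000, seed=9)
        b = simulate_walks(tm, d, 0, 2000, seed=9)
        assert a == b

    def test_error_shrinks_with_walk_count(self):
        c = threshold_edges(random_connected_connectome(9, 0.4, seed=41))
        d, g = prep(c)
        tm = transition_model(d, g, 0.0, 8)
        exact = transmission_cost(tm, d, 0)
        errs = []
        for n in (500, 50_000):
            reps = [abs(simulate_walks(tm, d, 0, n, seed=s).mean_distance
                        - exact) for s in range(5)]
            errs.append(np.mean(reps))
        assert errs[1] < errs[0]
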