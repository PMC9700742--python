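import numpy as np
import pytest

from hypergraphmt import (
    Hypergraph,
    HypergraphMT,
    LatentState,
    SymPolyCache,
    e_step,
    expected_rate,
    log_likelihood,
    update_u,
    update_w,
)

from _oracles import (
    PairwiseReference,
    log_likelihood_brute,
    u_denominator_brute,
    w_denominator_brute,
)
from conftest import random_instance


def _state(u, w):
    return LatentState(np.asarray(u, float), np.asarray(w, float))


class TestExpectedRate:
    def test_unit_memberships(self):
        st = _state([[1.0], [1.0]], [[0.7]])
        assert expected_rate(st, (0, 1)) == pytest.approx(0.7)

    def test_single_zero_membership_nulls_the_rate(self):
        st = _state([[1.0, 1.0], [0.0, 0.0], [0.5, 0.5]], [[2.0, 4.0], [2.0, 4.0]])
        assert expected_rate(st, (0, 1, 2)) == 0.0

    def test_hand_evaluated_mixture(self):
        u = [[1.0, 0.0], [1.0, 0.0], [0.5, 0.5]]
        st = _state(u, [[1.0, 1.0], [2.0, 4.0]])
        assert expected_rate(st, (0, 1, 2)) == pytest.approx(1.0)

    def test_size_out_of_range_rejected(self):
        st = _state([[1.0], [1.0], [1.0]], [[0.5]])  # D = 2
        with pytest.raises(ValueError, match="outside"):
            expected_rate(st, (0, 1, 2))


class TestLogLikelihood:
    def test_enumerated_triangle_instance(self):
        # N=3, K=1, u=1: Omega holds 3 pairs + 1 triple, each with rate 1
        h = Hypergraph(["a", "b", "c"], [((0, 1), 1)])
        st = _state([[1.0]] * 3, [[1.0], [1.0]])
        assert log_likelihood(st, h) == pytest.approx(-4.0)

    def test_zero_rate_observed_edge_gives_minus_inf(self):
        h = Hypergraph(["a", "b"], [((0, 1), 1)])
        st = _state([[0.0], [1.0]], [[1.0]])
        assert log_likelihood(st, h) == float("-inf")

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(10):
            u, w, h = random_instance(rng)
            st = _state(u, w)
            expected = log_likelihood_brute(u, w, h.hyperedges)
            got = log_likelihood(st, h)
            if np.isinf(expected):
                assert np.isinf(got)
            else:
                assert got == pytest.approx(expected, rel=1e-8)

    def test_dimension_mismatch_rejected(self, tiny_hypergraph):
        st = _state([[1.0]] * 2, [[1.0]])
        with pytest.raises(ValueError):
            log_likelihood(st, tiny_hypergraph)


class TestEStep:
    def test_single_community_is_certain(self, tiny_hypergraph):
        st = _state(np.ones((3, 1)), np.ones((2, 1)))
        rho, degen = e_step(st, tiny_hypergraph)
        assert np.allclose(rho, 1.0)
        assert not degen.any()

    def test_symmetric_state_is_uniform(self, tiny_hypergraph):
        st = _state(np.full((3, 3), 0.4), np.full((2, 3), 0.8))
        rho, _ = e_step(st, tiny_hypergraph)
        assert np.allclose(rho, 1.0 / 3.0)

    def test_hand_computed_responsibility(self):
        h = Hypergraph(["a", "b"], [((0, 1), 1)])
        st = _state([[1.0, 1.0], [1.0, 0.0]], [[3.0, 5.0]])
        rho, _ = e_step(st, h)
        assert np.allclose(rho, [[1.0, 0.0]])

    def test_rows_normalize_and_degenerate_rows_flagged(self, rng):
        for _ in range(5):
            u, w, h = random_instance(rng)
            rho, degen = e_step(_state(u, w), h)
            assert np.allclose(rho.sum(axis=1), 1.0, atol=1e-12)
            for t, (e, _) in enumerate(h.hyperedges):
                lam = expected_rate(_state(u, w), e)
                assert degen[t] == (lam == 0.0)
                if degen[t]:
                    assert np.allclose(rho[t], 1.0 / u.shape[1])


class TestUpdateU:
    def test_hand_computed_update(self):
        # single observed pair {0,1} with weight 2, all memberships 1:
        # numerator 2, denominator w2*C^(-0)(1) + w3*C^(-0)(2) = 2 + 1 = 3
        h = Hypergraph(["a", "b", "c"], [((0, 1), 2)])
        st = _state(np.ones((3, 1)), np.ones((2, 1)))
        rho, _ = e_step(st, h)
        new, _, _ = update_u(st, h, rho)
        assert new.u[0, 0] == pytest.approx(2.0 / 3.0)

    def test_isolated_node_row_becomes_zero(self):
        h = Hypergraph(["a", "b", "c"], [((0, 1), 1)])
        st = _state(np.full((3, 2), 0.5), np.full((2, 2), 0.5))
        rho, _ = e_step(st, h)
        new, _, _ = update_u(st, h, rho)
        assert np.all(new.u[2] == 0.0)

    def test_zero_membership_entry_absorbs(self, rng):
        # a single zero entry keeps the rates positive through the other
        # communities, and its numerator vanishes at the next sweep
        u = rng.uniform(0.1, 1.0, size=(8, 2))
        u[1, 0] = 0.0
        w = rng.uniform(0.1, 1.0, size=(2, 2))
        edges = [((0, 1), 1), ((1, 2, 3), 2), ((1, 4), 1), ((5, 6, 7), 1)]
        h = Hypergraph([f"n{i}" for i in range(8)], edges)
        st = _state(u, w)
        rho, degen = e_step(st, h)
        assert not degen.any()
        new, _, _ = update_u(st, h, rho)
        assert new.u[1, 0] == 0.0 and new.u[1, 1] > 0.0

    def test_denominator_matches_enumeration(self, rng):
        """Deflation-based Omega denominators equal brute-force sums."""
        for _ in range(8):
            u, w, h = random_instance(rng, n_max=10)
            cache = SymPolyCache(u.copy(), w.shape[0] + 1)
            for i in range(min(4, h.N)):
                Cm = cache.deflate(i)
                den = np.einsum("dk,kd->k", w, Cm[:, 1 : w.shape[0] + 1])
                brute = u_denominator_brute(u, w, i)
                assert np.allclose(den, brute, rtol=1e-8, atol=1e-12)

    def test_sparsity_prior_adds_gamma_to_denominator(self):
        h = Hypergraph(["a", "b", "c"], [((0, 1), 2)])
        st = _state(np.ones((3, 1)), np.ones((2, 1)))
        rho, _ = e_step(st, h)
        new, _, _ = update_u(st, h, rho, gamma=1.0)
        assert new.u[0, 0] == pytest.approx(2.0 / 4.0)

    def test_normalized_mode_rows_sum_to_one(self, rng):
        u, w, h = random_instance(rng)
        st = _state(u, w)
        rho, _ = e_step(st, h)
        new, _, _ = update_u(st, h, rho, normalize=True)
        assert np.allclose(new.u.sum(axis=1), 1.0)


class TestUpdateW:
    def test_hand_computed_update(self):
        h = Hypergraph(["a", "b", "c"], [((0, 1), 2)])
        st = _state(np.ones((3, 1)), np.ones((2, 1)))
        rho, _ = e_step(st, h)
        w = update_w(st, h, rho, SymPolyCache(st.u.copy(), 3))
        assert w[0, 0] == pytest.approx(2.0 / 3.0)  # C(2) = 3 pairs
        assert w[1, 0] == 0.0  # no observed triple

    def test_denominator_matches_enumeration(self, rng):
        for _ in range(8):
            u, w0, h = random_instance(rng)
            D = w0.shape[0] + 1
            cache = SymPolyCache(u.copy(), D)
            for d in range(2, D + 1):
                assert np.allclose(
                    cache.C[:, d], w_denominator_brute(u, d), rtol=1e-8, atol=1e-12
                )


class TestFit:
    def test_same_seed_reproduces_trace(self, planted_small):
        _, _, h = planted_small
        r1 = HypergraphMT(h, 2).fit(n_restarts=2, seed=11, max_iter=60)
        r2 = HypergraphMT(h, 2).fit(n_restarts=2, seed=11, max_iter=60)
        assert r1.loglik == r2.loglik
        for t1, t2 in zip(r1.traces, r2.traces):
            assert t1["loglik_trace"] == t2["loglik_trace"]
            assert np.array_equal(r1.u, r2.u)

    def test_single_community_balance_and_oracle_loglik(self):
        h = Hypergraph(["a", "b", "c", "d"], [((0, 1), 2), ((1, 2, 3), 1), ((0, 2), 1)])
        res = HypergraphMT(h, 1).fit(n_restarts=2, seed=5, max_iter=200)
        # with K=1, responsibilities are all 1, so sum_e A_e rho = M
        assert np.allclose(res.rho, 1.0)
        expected = log_likelihood_brute(res.u, res.w, h.hyperedges)
        assert res.loglik == pytest.approx(expected, rel=1e-8)

    def test_bound_never_decreases(self, planted_small):
        _, _, h = planted_small
        res = HypergraphMT(h, 2).fit(n_restarts=1, seed=3, max_iter=80)
        trace = np.array(res.traces[0]["bound_trace"])
        assert np.all(np.diff(trace) >= -1e-9)

    def test_invalid_configurations_rejected(self, tiny_hypergraph):
        with pytest.raises(ValueError):
            HypergraphMT(tiny_hypergraph, 0)
        with pytest.raises(ValueError):
            HypergraphMT(tiny_hypergraph, 2).fit(max_iter=0)
        with pytest.raises(ValueError):
            HypergraphMT(Hypergraph(["a", "b"], []), 2)

    def test_pairs_only_input_matches_pairwise_reference(self, rng):
        """On a graph the model reduces to the assortative pairwise model."""
        u, w, h0 = random_instance(rng, n_max=10, d_max=2)
        from hypergraphmt import pairs_only

        h = pairs_only(h0)
        if h.E == 0:
            pytest.skip("no pairs drawn")
        st = _state(u, w[:1])
        ref = PairwiseReference(h.N, h.hyperedges)
        for _ in range(4):
            rho, _ = e_step(st, h)
            rho_ref = ref.e_step(st.u, st.w)
            assert np.allclose(rho, rho_ref, rtol=1e-12, atol=1e-12)
            u_ref = ref.update_u(st.u, st.w, rho_ref)
            new, cache, _ = update_u(st, h, rho)
            assert np.allclose(new.u, u_ref, rtol=1e-10, atol=1e-12)
            w_ref = ref.update_w(new.u, rho_ref)
            w_new = update_w(new, h, rho, cache)
            assert np.allclose(w_new, w_ref, rtol=1e-10, atol=1e-12)
            st = LatentState(new.u, w_new)
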