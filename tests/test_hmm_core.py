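import math

import numpy as np
import pytest

from snvhmm.hmm_core import (
    GenotypeState,
    HMMParameters,
    PriorHyperparameters,
    TrainConfig,
    TrellisCache,
    baum_welch_train,
    emission_table,
    forward_backward,
    forward_backward_logb,
    init_from_priors,
    load_params,
    save_params,
    site_emission,
    update_initial,
    update_transitions,
    update_u_newton,
    viterbi_decode,
    viterbi_decode_logb,
)

from conftest import make_obs
from oracles import (
    brute_force_loglik,
    brute_force_posteriors,
    brute_force_viterbi,
    grid_argmax_u,
    random_hmm_params,
    random_obs_seq,
)


class TestSiteEmission:
    def test_empty_observation_is_one(self):
        obs = make_obs([])
        assert site_emission(obs, 0.5) == 0.0

    def test_hand_case_half(self):
        obs = make_obs([True], r=[1.0], q=[1.0])
        assert math.exp(site_emission(obs, 1.0)) == pytest.approx(0.5, rel=1e-12)

    def test_hand_case_three_eighths(self):
        obs = make_obs([True, False], r=[1.0, 1.0], q=[1.0, 1.0])
        assert math.exp(site_emission(obs, 0.5)) == pytest.approx(
            0.375, rel=1e-12
        )

    def test_u_out_of_range(self):
        obs = make_obs([True])
        with pytest.raises(ValueError):
            site_emission(obs, 1.5)
        with pytest.raises(ValueError):
            site_emission(obs, -0.1)

    def test_read_order_invariance(self, rng):
        obs = make_obs(
            [True, False, True, False],
            r=[0.9, 0.8, 0.99, 0.7],
            q=[0.95, 0.9, 0.8, 0.99],
        )
        perm = [2, 0, 3, 1]
        obs2 = make_obs(
            np.array(obs.match)[perm], r=obs.r[perm], q=obs.q[perm]
        )
        assert site_emission(obs, 0.3) == pytest.approx(
            site_emission(obs2, 0.3), rel=1e-14
        )


class TestEmissionTable:
    def test_shape_and_finiteness(self):
        obs = make_obs([True, False])
        tab = emission_table([obs], np.array([0.999, 0.5, 0.001]))
        assert tab.shape == (1, 3)
        assert np.isfinite(tab).all()

    def test_matches_site_emission(self, rng):
        seq = random_obs_seq(rng, 5)
        u = np.array([0.9, 0.5, 0.1])
        tab = emission_table(seq, u)
        for t, obs in enumerate(seq):
            for i in range(3):
                assert tab[t, i] == pytest.approx(
                    site_emission(obs, u[i]), rel=1e-12
                )

    def test_monotone_in_u_for_all_matching(self):
        obs = make_obs([True] * 4, r=[0.9999] * 4, q=[0.9999] * 4)
        tab = emission_table([obs], np.array([0.999, 0.5, 0.001]))
        assert tab[0, 0] > tab[0, 1] > tab[0, 2]

    def test_identical_sites_identical_rows(self):
        obs = make_obs([True, False])
        tab = emission_table([obs, obs], np.array([0.9, 0.5, 0.1]))
        np.testing.assert_array_equal(tab[0], tab[1])

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            emission_table([], np.array([0.9, 0.5, 0.1]))


class TestInitFromPriors:
    def test_prior_mean_pi(self):
        p = init_from_priors(mode="prior_mean")
        np.testing.assert_allclose(
            p.pi, np.array([1000, 100, 100]) / 1200, atol=1e-12
        )

    def test_prior_mean_u(self):
        p = init_from_priors(mode="prior_mean")
        np.testing.assert_allclose(
            p.u, [1000 / 1001, 0.5, 1 / 1001], atol=1e-9
        )

    def test_prior_mean_transition_rows(self):
        p = init_from_priors(mode="prior_mean")
        np.testing.assert_allclose(p.A[0], np.array([1000, 100, 100]) / 1200)
        np.testing.assert_allclose(p.A.sum(axis=1), np.ones(3), atol=1e-12)

    def test_prior_sample_reproducible(self):
        a = init_from_priors(mode="prior_sample", seed=11)
        b = init_from_priors(mode="prior_sample", seed=11)
        np.testing.assert_array_equal(a.pi, b.pi)
        np.testing.assert_array_equal(a.A, b.A)
        np.testing.assert_array_equal(a.u, b.u)
        np.testing.assert_allclose(a.A.sum(axis=1), np.ones(3), atol=1e-9)

    def test_prior_sample_needs_seed(self):
        with pytest.raises(ValueError):
            init_from_priors(mode="prior_sample", seed=None)

    def test_bad_hyperparameters(self):
        with pytest.raises(ValueError):
            PriorHyperparameters(alpha=np.array([1.0, -1.0, 1.0]))


class TestForwardBackward:
    def test_length_one_closed_form(self, rng):
        params = random_hmm_params(rng)
        seq = random_obs_seq(rng, 1)
        cache = forward_backward(seq, params)
        b = np.exp(emission_table(seq, params.u)[0])
        assert cache.log_likelihood == pytest.approx(
            math.log(float(params.pi @ b)), rel=1e-12
        )

    def test_constant_emissions(self, rng):
        params = random_hmm_params(rng)
        T, c = 17, 0.123
        log_b = np.full((T, 3), math.log(c))
        cache = forward_backward_logb(log_b, params.pi, params.A)
        assert cache.log_likelihood == pytest.approx(T * math.log(c), rel=1e-12)

    def test_matches_brute_force(self, rng):
        for T in (2, 3, 5):
            params = random_hmm_params(rng)
            seq = random_obs_seq(rng, T)
            log_b = emission_table(seq, params.u)
            cache = forward_backward(seq, params)
            assert cache.log_likelihood == pytest.approx(
                brute_force_loglik(log_b, params.pi, params.A), abs=1e-10
            )
            gamma, xi = brute_force_posteriors(log_b, params.pi, params.A)
            np.testing.assert_allclose(cache.state_posterior, gamma, atol=1e-10)
            np.testing.assert_allclose(cache.pair_posterior, xi, atol=1e-10)

    def test_posterior_invariants(self, rng):
        params = random_hmm_params(rng)
        seq = random_obs_seq(rng, 40)
        cache = forward_backward(seq, params)
        np.testing.assert_allclose(
            cache.state_posterior.sum(axis=1), np.ones(40), atol=1e-9
        )
        np.testing.assert_allclose(
            cache.pair_posterior.sum(axis=(1, 2)), np.ones(39), atol=1e-9
        )
        np.testing.assert_allclose(
            cache.pair_posterior.sum(axis=2),
            cache.state_posterior[:-1],
            atol=1e-9,
        )

    def test_all_zero_emission_row_errors(self, rng):
        params = random_hmm_params(rng)
        log_b = np.zeros((4, 3))
        log_b[2] = -np.inf
        with pytest.raises(FloatingPointError, match="2"):
            forward_backward_logb(log_b, params.pi, params.A)

    def test_empty_sequence_rejected(self, rng):
        params = random_hmm_params(rng)
        with pytest.raises(ValueError):
            forward_backward([], params)


class TestUpdates:
    def _degenerate_cache(self, states):
        """Cache with one-hot posteriors along a deterministic path."""
        T = len(states)
        gamma = np.zeros((T, 3))
        gamma[np.arange(T), states] = 1.0
        xi = np.zeros((T - 1, 3, 3))
        for t in range(T - 1):
            xi[t, states[t], states[t + 1]] = 1.0
        return TrellisCache(
            scaled_forward=gamma.copy(),
            scaled_backward=np.ones((T, 3)),
            scale_factors=np.zeros(T),
            state_posterior=gamma,
            pair_posterior=xi,
            log_likelihood=0.0,
        )

    def test_update_initial_is_first_posterior(self):
        cache = self._degenerate_cache([1, 0, 0])
        np.testing.assert_array_equal(update_initial(cache), [0, 1, 0])

    def test_update_initial_sums_to_one(self, rng):
        params = random_hmm_params(rng)
        cache = forward_backward(random_obs_seq(rng, 10), params)
        pi = update_initial(cache)
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(pi, cache.state_posterior[0], atol=1e-12)

    def test_transition_counting_deterministic_path(self):
        # path aa, aa, ab, aa: row aa has one aa->aa and one aa->ab
        cache = self._degenerate_cache([0, 0, 1, 0])
        A = update_transitions(cache)
        np.testing.assert_allclose(A[0], [0.5, 0.5, 0.0], atol=1e-12)
        np.testing.assert_allclose(A[1], [1.0, 0.0, 0.0], atol=1e-12)

    def test_zero_occupancy_row_kept(self):
        cache = self._degenerate_cache([0, 0, 1, 0])  # state bb never visited
        prev = np.array([[0.1, 0.2, 0.7]] * 3)
        A = update_transitions(cache, prev_A=prev)
        np.testing.assert_allclose(A[2], prev[2], atol=1e-12)

    def test_rows_sum_to_one(self, rng):
        params = random_hmm_params(rng)
        cache = forward_backward(random_obs_seq(rng, 25), params)
        A = update_transitions(cache)
        np.testing.assert_allclose(A.sum(axis=1), np.ones(3), atol=1e-12)

    def test_transitions_match_brute_force(self, rng):
        params = random_hmm_params(rng)
        seq = random_obs_seq(rng, 4)
        log_b = emission_table(seq, params.u)
        cache = forward_backward(seq, params)
        gamma, xi = brute_force_posteriors(log_b, params.pi, params.A)
        expected = xi.sum(axis=0) / gamma[:-1].sum(axis=0)[:, None]
        expected /= expected.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(
            update_transitions(cache), expected, atol=1e-10
        )

    def test_t1_rejected(self):
        cache = self._degenerate_cache([0])
        with pytest.raises(ValueError):
            update_transitions(cache)


class TestNewtonUpdate:
    def test_stationary_point_fixed(self):
        # At u = 0.5 every read has match probability 0.25, so the score
        # derivative is sum_match b/0.25 - sum_mismatch b/0.75.  With r=1,
        # b = q - 0.5: a matching read at q=0.6 (b=0.1) balances a
        # mismatching read at q=0.8 (b=0.3) exactly, making 0.5 a
        # stationary (and by concavity, maximal) point.
        obs = make_obs([True, False], r=[1.0, 1.0], q=[0.6, 0.8])
        cache_gamma = np.ones((1, 3))
        cache = TrellisCache(
            scaled_forward=np.ones((1, 3)),
            scaled_backward=np.ones((1, 3)),
            scale_factors=np.zeros(1),
            state_posterior=cache_gamma,
            pair_posterior=np.zeros((0, 3, 3)),
            log_likelihood=0.0,
        )
        u = update_u_newton([obs], cache, np.array([0.5, 0.5, 0.5]))
        np.testing.assert_allclose(u, 0.5, atol=1e-9)

    def test_all_match_clamps_high(self):
        obs_seq = [
            make_obs([True] * 3, r=[0.999999] * 3, q=[0.9999] * 3)
            for _ in range(4)
        ]
        gamma = np.zeros((4, 3))
        gamma[:, 0] = 1.0
        cache = TrellisCache(
            scaled_forward=gamma,
            scaled_backward=gamma,
            scale_factors=np.zeros(4),
            state_posterior=gamma,
            pair_posterior=np.zeros((3, 3, 3)),
            log_likelihood=0.0,
        )
        u = update_u_newton(
            obs_seq, cache, np.array([0.6, 0.5, 0.4]), TrainConfig(newton_steps=50)
        )
        assert u[0] > 0.999

    def test_matches_grid_search(self, rng):
        for trial in range(10):
            seq = random_obs_seq(rng, 4, max_depth=4)
            w = rng.uniform(0.05, 1.0, size=4)
            gamma = np.zeros((4, 3))
            gamma[:, 0] = w
            cache = TrellisCache(
                scaled_forward=gamma,
                scaled_backward=gamma,
                scale_factors=np.zeros(4),
                state_posterior=gamma,
                pair_posterior=np.zeros((3, 3, 3)),
                log_likelihood=0.0,
            )
            u = update_u_newton(
                seq, cache, np.array([0.5, 0.5, 0.5]),
                TrainConfig(newton_steps=60),
            )
            u_star = grid_argmax_u(seq, w)
            assert abs(u[0] - u_star) < 1e-4

    def test_misaligned_cache_rejected(self, rng):
        seq = random_obs_seq(rng, 3)
        gamma = np.ones((2, 3))
        cache = TrellisCache(
            scaled_forward=gamma,
            scaled_backward=gamma,
            scale_factors=np.zeros(2),
            state_posterior=gamma,
            pair_posterior=np.zeros((1, 3, 3)),
            log_likelihood=0.0,
        )
        with pytest.raises(ValueError):
            update_u_newton(seq, cache, np.array([0.5, 0.5, 0.5]))


class TestBaumWelch:
    def test_loglik_trace_non_decreasing(self, rng):
        from snvhmm.synthetic_data import SimulationConfig, simulate_truth_path
        from snvhmm.synthetic_data import simulate_pileup
        from snvhmm.pileup_io import FilterConfig, stream_observations

        cfg = SimulationConfig(n_sites=2000, mean_depth=8, seed=5)
        states = simulate_truth_path(cfg.true_params, cfg.n_sites, cfg.seed)
        import tempfile

        with tempfile.TemporaryDirectory() as tmp:
            simulate_pileup(states, cfg, f"{tmp}/s.pileup", f"{tmp}/s.tsv")
            obs = list(stream_observations(f"{tmp}/s.pileup", FilterConfig()))
        _, trace, _ = baum_welch_train(
            obs, config=TrainConfig(max_iter=25, tol=1e-6)
        )
        diffs = np.diff(trace)
        assert (diffs >= -1e-6).all()

    def test_max_iter_one(self, rng):
        seq = random_obs_seq(rng, 30)
        params, trace, converged = baum_welch_train(
            seq, config=TrainConfig(max_iter=1, tol=1e-12)
        )
        assert len(trace) == 1 and not converged

    def test_tol_infinite_stops_immediately(self, rng):
        seq = random_obs_seq(rng, 30)
        _, trace, converged = baum_welch_train(
            seq, config=TrainConfig(max_iter=50, tol=np.inf)
        )
        assert converged and len(trace) == 2

    def test_multi_chain_training(self, rng):
        chains = [random_obs_seq(rng, 20), random_obs_seq(rng, 15)]
        params, trace, _ = baum_welch_train(
            chains, config=TrainConfig(max_iter=5, tol=1e-8)
        )
        params.validate()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            baum_welch_train([])


class TestViterbi:
    def test_length_one_argmax(self, rng):
        params = random_hmm_params(rng)
        seq = random_obs_seq(rng, 1)
        path, score = viterbi_decode(seq, params)
        b = emission_table(seq, params.u)[0]
        expected = int(np.argmax(np.log(params.pi) + b))
        assert path[0] == expected

    def test_matches_enumeration(self, rng):
        for T in (2, 4, 6, 8):
            params = random_hmm_params(rng)
            seq = random_obs_seq(rng, T)
            log_b = emission_table(seq, params.u)
            path, score = viterbi_decode(seq, params)
            bpath, bscore = brute_force_viterbi(log_b, params.pi, params.A)
            assert score == pytest.approx(bscore, abs=1e-10)
            np.testing.assert_array_equal(path, bpath)

    def test_tie_break_to_lower_state(self):
        pi = np.full(3, 1 / 3)
        A = np.full((3, 3), 1 / 3)
        log_b = np.zeros((5, 3))
        path, _ = viterbi_decode_logb(log_b, pi, A)
        np.testing.assert_array_equal(path, np.zeros(5, dtype=int))

    def test_scaling_invariance(self, rng):
        params = random_hmm_params(rng)
        seq = random_obs_seq(rng, 20)
        log_b = emission_table(seq, params.u)
        p1, s1 = viterbi_decode_logb(log_b, params.pi, params.A)
        p2, s2 = viterbi_decode_logb(log_b + 7.5, params.pi, params.A)
        np.testing.assert_array_equal(p1, p2)
        c1 = forward_backward_logb(log_b, params.pi, params.A)
        c2 = forward_backward_logb(log_b + 7.5, params.pi, params.A)
        np.testing.assert_allclose(
            c1.state_posterior, c2.state_posterior, atol=1e-12
        )


class TestSerialization:
    def test_round_trip(self, tmp_path, rng):
        params = random_hmm_params(rng)
        f = tmp_path / "params.txt"
        save_params(f, params, n_iter=12, log_likelihood=-123.456)
        loaded, meta = load_params(f)
        np.testing.assert_array_equal(loaded.pi, params.pi)
        np.testing.assert_array_equal(loaded.A, params.A)
        np.testing.assert_array_equal(loaded.u, params.u)
        assert meta["n_iter"] == 12
        assert meta["log_likelihood"] == -123.456
        np.testing.assert_array_equal(
            meta["hyper"].delta, [1000.0, 100.0, 100.0]
        )

    def test_malformed_rejected(self, tmp_path):
        f = tmp_path / "bad.txt"
        f.write_text("pi = 0.5 0.5\n")
        with pytest.raises(ValueError):
            load_params(f)


class TestGenotypeState:
    def test_labels(self):
        assert GenotypeState.AA.label == "aa"
        assert GenotypeState.from_label("bb") is GenotypeState.BB
        assert GenotypeState.from_index(1) is GenotypeState.AB

    def test_snv_flags(self):
        assert not GenotypeState.AA.is_snv
        assert GenotypeState.AB.is_snv and GenotypeState.BB.is_snv
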