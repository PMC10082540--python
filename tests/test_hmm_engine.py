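"""Tests for the trellis recursions, EM updates, initials and the fit driver."""

from itertools import product

import numpy as np
import pytest
from scipy.special import logsumexp

from blockhmm.core_model import InfluenceStrengths, build_contingency_tables
from blockhmm.errors import FittingError, InputValidationError
from blockhmm.hmm_engine import (
    HmmParameters,
    MarkovParameters,
    ThresholdConfig,
    default_initials,
    e_step,
    enforce_thresholds,
    fit,
    forward_backward,
    m_step,
    random_initials,
    random_transition_matrix,
    random_triple,
    viterbi,
)
from blockhmm.simulators import HmmSimConfig, simulate_hmm_dataset

from conftest import random_markov


def brute_force_posteriors(log_em, markov):
    """Enumerate all state sequences; return (log_lik, gamma, xi, best_path)."""
    p = log_em.shape[0]
    log_pi = np.log(markov.pi)
    logA = np.log(markov.A)
    seq_logps = {}
    for seq in product(range(3), repeat=p):
        lp = log_pi[seq[0]] + log_em[0, seq[0]]
        for j in range(1, p):
            lp += logA[seq[j - 1], seq[j]] + log_em[j, seq[j]]
        seq_logps[seq] = lp
    ll = logsumexp(list(seq_logps.values()))
    gamma = np.zeros((p, 3))
    xi = np.zeros((p - 1, 3, 3))
    for seq, lp in seq_logps.items():
        w = np.exp(lp - ll)
        for j in range(p):
            gamma[j, seq[j]] += w
            if j < p - 1:
                xi[j, seq[j], seq[j + 1]] += w
    best = max(seq_logps, key=seq_logps.get)
    return ll, gamma, xi, best, seq_logps


class TestForwardBackward:
    def test_single_site_chain(self, rng):
        log_em = rng.normal(-2, 1, (1, 3))
        mk = random_markov(rng)
        tr = forward_backward(log_em, mk)
        expected_ll = logsumexp(np.log(mk.pi) + log_em[0])
        assert np.isclose(tr.log_likelihood, expected_ll, atol=1e-12)
        expected_gamma = np.exp(np.log(mk.pi) + log_em[0] - expected_ll)
        assert np.allclose(tr.gamma[0], expected_gamma, atol=1e-12)

    @pytest.mark.parametrize("p", [2, 3, 5])
    def test_matches_exhaustive_enumeration(self, p):
        rng = np.random.default_rng(p)
        log_em = rng.normal(-3, 1.5, (p, 3))
        mk = random_markov(rng)
        ll, gamma, _, _, _ = brute_force_posteriors(log_em, mk)
        tr = forward_backward(log_em, mk)
        assert np.isclose(tr.log_likelihood, ll, atol=1e-8)
        assert np.allclose(tr.gamma, gamma, atol=1e-8)

    def test_uninformative_data_gives_prior_marginals(self, rng):
        p = 4
        log_em = np.tile(rng.normal(-2, 1, (p, 1)), (1, 3))  # same across states
        mk = random_markov(rng)
        tr = forward_backward(log_em, mk)
        marginal = mk.pi.copy()
        for j in range(p):
            assert np.allclose(tr.gamma[j], marginal, atol=1e-10)
            marginal = marginal @ mk.A

    def test_alpha_beta_consistency_across_sites(self, rng):
        log_em = rng.normal(-3, 1, (30, 3))
        mk = random_markov(rng)
        tr = forward_backward(log_em, mk)
        for j in range(30):
            assert np.isclose(
                logsumexp(tr.log_alpha[j] + tr.log_beta[j]),
                tr.log_likelihood,
                atol=1e-8,
            )
        assert np.allclose(tr.gamma.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_likelihood_site_raises(self, rng):
        log_em = rng.normal(-2, 1, (4, 3))
        log_em[2] = -np.inf
        with pytest.raises(FittingError, match="site 2"):
            forward_backward(log_em, random_markov(rng))


class TestViterbi:
    def test_single_site_argmax(self, rng):
        log_em = rng.normal(-2, 1, (1, 3))
        mk = random_markov(rng)
        expected = int(np.argmax(np.log(mk.pi) + log_em[0])) - 1
        assert viterbi(log_em, mk)[0] == expected

    @pytest.mark.parametrize("seed", range(6))
    def test_path_probability_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(2, 7))
        log_em = rng.normal(-3, 1.5, (p, 3))
        mk = random_markov(rng)
        _, _, _, best, seq_logps = brute_force_posteriors(log_em, mk)
        path = tuple(viterbi(log_em, mk) + 1)
        assert np.isclose(seq_logps[path], seq_logps[best], atol=1e-8)

    def test_dominant_evidence_wins_everywhere(self, rng):
        p = 12
        log_em = np.full((p, 3), -50.0)
        log_em[:, 2] = -1.0  # overwhelming support for state +1
        A = np.full((3, 3), 0.05)
        np.fill_diagonal(A, 0.9)
        mk = MarkovParameters(np.array([1 / 3, 1 / 3, 1 / 3]), A)
        assert np.all(viterbi(log_em, mk) == 1)

    def test_tie_break_prefers_no_influence(self):
        # fully symmetric instance: every path has identical probability
        log_em = np.zeros((4, 3))
        mk = MarkovParameters(np.full(3, 1 / 3), np.full((3, 3), 1 / 3))
        assert np.all(viterbi(log_em, mk) == 0)

    def test_viterbi_at_least_as_probable_as_gamma_argmax(self):
        def path_logp(path_idx, log_em, mk):
            lp = np.log(mk.pi[path_idx[0]]) + log_em[0, path_idx[0]]
            for j in range(1, len(path_idx)):
                lp += np.log(mk.A[path_idx[j - 1], path_idx[j]])
                lp += log_em[j, path_idx[j]]
            return lp

        for seed in range(10):
            rng = np.random.default_rng(seed + 100)
            log_em = rng.normal(-3, 2, (15, 3))
            mk = random_markov(rng)
            tr = forward_backward(log_em, mk)
            vit = viterbi(log_em, mk) + 1
            greedy = np.argmax(tr.gamma, axis=1)
            assert path_logp(vit, log_em, mk) >= path_logp(greedy, log_em, mk) - 1e-10


class TestEStep:
    def _setup(self, rng, p=6):
        tables = np.stack(
            [rng.multinomial(25, rng.dirichlet(np.ones(3)), 2) for _ in range(p)]
        )
        params = random_initials(rng, p)
        return tables, params

    def test_xi_normalization_and_marginals(self, rng):
        tables, params = self._setup(rng)
        trellis, xi = e_step(tables, params)
        assert np.allclose(xi.sum(axis=(1, 2)), 1.0, atol=1e-9)
        assert np.allclose(xi.sum(axis=2), trellis.gamma[:-1], atol=1e-9)
        assert np.allclose(xi.sum(axis=1), trellis.gamma[1:], atol=1e-9)

    def test_xi_matches_enumeration(self, rng):
        from blockhmm.core_model import emission_log_prob_matrix

        tables, params = self._setup(rng, p=3)
        trellis, xi = e_step(tables, params)
        log_em = emission_log_prob_matrix(tables, params.nulls, params.theta)
        _, gamma_b, xi_b, _, _ = brute_force_posteriors(log_em, params.markov)
        assert np.allclose(xi, xi_b, atol=1e-8)
        assert np.allclose(trellis.gamma, gamma_b, atol=1e-8)


class TestMStep:
    def test_degenerate_posterior_recovers_path_frequencies(self, rng):
        p = 9
        path = np.array([1, 1, 0, 0, 0, 2, 2, 0, 1])
        gamma = np.zeros((p, 3))
        gamma[np.arange(p), path] = 1.0
        xi = np.zeros((p - 1, 3, 3))
        for j in range(p - 1):
            xi[j, path[j], path[j + 1]] = 1.0
        tables = np.stack(
            [rng.multinomial(20, rng.dirichlet(np.ones(3)), 2) for _ in range(p)]
        )
        params = random_initials(rng, p)
        cfg = ThresholdConfig(theta_min=0.1, a_min=0.01)
        new = m_step(tables, gamma, xi, params, cfg)
        assert np.allclose(new.markov.pi, gamma[0], atol=1e-12)
        # empirical transition frequencies of the path
        for k in range(3):
            visits = np.sum(path[:-1] == k)
            for l in range(3):
                trans = np.sum((path[:-1] == k) & (path[1:] == l))
                assert np.isclose(new.markov.A[k, l], trans / visits, atol=1e-12)

    def test_single_site_theta_matches_grid_search(self, rng):
        # one site fully assigned to Negative Influence: the updated strength
        # pair must match a dense grid search of the weighted objective
        tables = np.array([[[30, 15, 5], [42, 6, 2]]])
        nulls = np.array([[0.6, 0.3, 0.1]])
        gamma = np.array([[1.0, 0.0, 0.0]])
        xi = np.zeros((0, 3, 3))
        cfg = ThresholdConfig(theta_min=0.1)
        params = HmmParameters(
            nulls, InfluenceStrengths(0.5, 0.5, 0.5, 0.5),
            MarkovParameters(np.full(3, 1 / 3), np.full((3, 3), 1 / 3)),
        )
        new = m_step(tables, gamma, xi, params, cfg)

        from blockhmm.core_model import case_distribution, emission_log_prob

        def objective(t0, t1):
            q = case_distribution(-1, new.nulls[0], InfluenceStrengths(t0, t1, 0, 0))
            return emission_log_prob(tables[0], new.nulls[0], q)

        grid = np.linspace(0.1, 6.0, 400)
        best = max(((objective(a, b), a, b) for a in grid for b in grid))
        assert abs(new.theta.theta0_minus - best[1]) < 2e-2
        assert abs(new.theta.theta1_minus - best[2]) < 2e-2
        assert objective(new.theta.theta0_minus, new.theta.theta1_minus) >= best[0] - 1e-3


class TestEnforceThresholds:
    def _params(self, A, theta):
        return HmmParameters(
            np.array([[0.5, 0.3, 0.2]]), theta,
            MarkovParameters(np.full(3, 1 / 3), A),
        )

    def test_no_op_when_above_thresholds(self):
        A = np.full((3, 3), 0.2)
        np.fill_diagonal(A, 0.6)
        params = self._params(A, InfluenceStrengths(0.3, 0.3, 0.3, 0.3))
        out = enforce_thresholds(params, ThresholdConfig(theta_min=0.15))
        assert np.allclose(out.markov.A, A, atol=1e-15)
        assert out.theta == params.theta

    def test_proportional_rescale_of_off_diagonals(self):
        A = np.array(
            [[0.3, 0.42, 0.28], [0.1, 0.8, 0.1], [0.2, 0.2, 0.6]]
        )
        params = self._params(A, InfluenceStrengths(0.3, 0.3, 0.3, 0.3))
        out = enforce_thresholds(params, ThresholdConfig())
        assert np.allclose(out.markov.A[0], [0.5, 0.3, 0.2], atol=1e-12)
        assert np.allclose(out.markov.A[1], A[1], atol=1e-12)
        assert np.allclose(out.markov.A.sum(axis=1), 1.0, atol=1e-12)

    def test_theta_floor_applied(self):
        params = self._params(np.eye(3), InfluenceStrengths(0.02, 0.5, 0.2, 0.01))
        out = enforce_thresholds(params, ThresholdConfig(theta_min=0.15))
        assert out.theta.theta0_minus == 0.15
        assert out.theta.theta1_plus == 0.15
        assert out.theta.theta1_minus == 0.5

    def test_idempotent(self, rng):
        A = rng.dirichlet(np.ones(3), 3)
        params = self._params(A, InfluenceStrengths(0.01, 0.02, 0.03, 0.04))
        cfg = ThresholdConfig()
        once = enforce_thresholds(params, cfg)
        twice = enforce_thresholds(once, cfg)
        assert np.allclose(once.markov.A, twice.markov.A, atol=1e-15)
        assert once.theta == twice.theta


class TestDefaultInitials:
    def test_control_frequency_estimate(self):
        tables = np.array([[[10, 6, 4], [5, 5, 10]]])
        params = default_initials(tables, ThresholdConfig())
        assert np.allclose(params.nulls[0], [0.5, 0.3, 0.2], atol=1e-12)

    def test_pseudocount_then_renormalize(self):
        tables = np.array([[[20, 0, 0], [10, 5, 5]]])
        params = default_initials(tables, ThresholdConfig())
        assert np.allclose(
            params.nulls[0], [20 / 21, 0.5 / 21, 0.5 / 21], atol=1e-12
        )

    def test_markov_estimates_are_valid(self, rng):
        tables = np.stack(
            [rng.multinomial(40, rng.dirichlet(np.ones(3)), 2) for _ in range(20)]
        )
        params = default_initials(tables, ThresholdConfig())
        assert np.isclose(params.markov.pi.sum(), 1.0, atol=1e-9)
        assert np.allclose(params.markov.A.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(params.theta.as_array() >= 0.15 - 1e-12)


class TestRandomInitials:
    def test_triples_descending_and_normalized(self, rng):
        t = random_triple(rng, 200)
        assert np.allclose(t.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(np.diff(t, axis=1) <= 0)

    def test_pi_mode_is_no_influence(self, rng):
        for _ in range(50):
            params = random_initials(rng, 3)
            pi = params.markov.pi
            assert pi[1] >= pi[0] and pi[1] >= pi[2]

    def test_diagonal_mean_matches_uniform_law(self, rng):
        # diagonals ~ U(0.5, 1): mean 0.75
        diags = np.array(
            [np.diag(random_transition_matrix(rng)) for _ in range(10_000)]
        )
        assert abs(diags.mean() - 0.75) < 0.01
        assert diags.min() >= 0.5


class TestFit:
    def _separated_dataset(self, seed, p=200):
        rng = np.random.default_rng(seed)
        theta = InfluenceStrengths(1, 1, 1, 1)
        A = np.full((3, 3), 0.01)
        np.fill_diagonal(A, 0.98)
        params = HmmParameters(
            random_triple(rng, p), theta,
            MarkovParameters(np.array([0.1, 0.8, 0.1]), A),
        )
        cfg = HmmSimConfig(n_sites=p, n_controls=500, n_cases=500)
        return simulate_hmm_dataset(cfg, rng, params=params)

    def test_recovers_strongly_separated_states(self):
        ds = self._separated_dataset(5)
        result = fit(ds.data, ThresholdConfig(theta_min=0.15, seed=1), 3)
        accuracy = np.mean((result.states != 0) == (ds.truth != 0))
        assert accuracy >= 0.9

    def test_deterministic_without_random_starts(self):
        ds = self._separated_dataset(6, p=60)
        cfg = ThresholdConfig(theta_min=0.15, seed=0)
        r1 = fit(ds.data, cfg, n_random_starts=0)
        r2 = fit(ds.data, cfg, n_random_starts=0)
        assert np.array_equal(r1.states, r2.states)
        assert np.array_equal(r1.objective_trace, r2.objective_trace)
        assert r1.selected_run == "default"

    def test_reported_objective_is_best_across_runs(self):
        ds = self._separated_dataset(7, p=60)
        result = fit(ds.data, ThresholdConfig(theta_min=0.15, seed=3), 2)
        assert np.isclose(
            result.objective, max(result.run_objectives.values()), atol=1e-9
        )
        assert result.objective == result.objective_trace.max()

    def test_empty_input_rejected(self):
        with pytest.raises(InputValidationError):
            fit(np.zeros((0, 2, 3), dtype=int), ThresholdConfig(), 0)

    def test_transition_diagonal_recovery(self):
        """On well-separated data (diag(A) in [0.9, 1), strengths in
        [0.5, 1], p=1024, n=2000) the fitted self-transition probabilities
        land within 0.1 of truth for at least 80% of diagonal entries."""
        hits = total = 0
        for seed in range(5):
            rng = np.random.default_rng(2000 + seed)
            p = 1024
            diag = rng.uniform(0.9, 1.0, 3)
            A = np.zeros((3, 3))
            for k in range(3):
                others = [l for l in range(3) if l != k]
                t = rng.random()
                A[k, k] = diag[k]
                A[k, others[0]] = t * (1 - diag[k])
                A[k, others[1]] = (1 - t) * (1 - diag[k])
            params = HmmParameters(
                random_triple(rng, p),
                InfluenceStrengths(*rng.uniform(0.5, 1.0, 4)),
                MarkovParameters(np.array([0.2, 0.6, 0.2]), A),
            )
            ds = simulate_hmm_dataset(
                HmmSimConfig(n_sites=p, n_controls=1000, n_cases=1000),
                rng,
                params=params,
            )
            result = fit(ds.data, ThresholdConfig(theta_min=0.15, seed=seed), 1)
            est = np.diag(result.params.markov.A)
            hits += int(np.sum(np.abs(est - diag) <= 0.1))
            total += 3
        assert hits / total >= 0.8

    def test_frozen_nulls_configuration(self):
        ds = self._separated_dataset(8, p=60)
        tables = build_contingency_tables(ds.data)
        cfg = ThresholdConfig(theta_min=0.15, seed=0, update_nulls=False)
        result = fit(tables, cfg, n_random_starts=0)
        init = default_initials(tables, cfg)
        assert np.allclose(result.params.nulls, init.nulls, atol=1e-12)
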