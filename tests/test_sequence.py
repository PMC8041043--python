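"""Sequence likelihood, greedy/MCMC inference and positional densities."""

import itertools

import numpy as np
import pytest

from ebmflow import (
    SequencePosterior,
    cumulative_density,
    ebm_log_likelihood,
    exact_posterior_density,
    exhaustive_argmax,
    greedy_ascent,
    mcmc_sample,
    positional_density,
)
from ebmflow.errors import ValidationError
from ebmflow.sequence import PositionalDensity


def _brute_force_likelihood(p_pre, p_post, order):
    """Independent oracle: enumerate stages and multiply densities."""
    J, N = p_pre.shape
    total_ll = 0.0
    for j in range(J):
        like = 0.0
        for k in range(N + 1):
            term = 1.0
            for i, e in enumerate(order):
                term *= p_post[j, e] if i < k else p_pre[j, e]
            like += term
        total_ll += np.log(like / (N + 1))
    return total_ll


def _random_problem(rng, n_subjects, n_events):
    p_pre = rng.uniform(0.05, 1.0, size=(n_subjects, n_events))
    p_post = rng.uniform(0.05, 1.0, size=(n_subjects, n_events))
    return p_pre, p_post


def _strong_signal_problem(rng, n_subjects, n_events, scale=50.0):
    """Staged subjects with near-deterministic pre/post densities."""
    order = rng.permutation(n_events)
    p_pre = np.full((n_subjects, n_events), 1.0)
    p_post = np.full((n_subjects, n_events), 1.0 / scale)
    for j in range(n_subjects):
        k = rng.integers(0, n_events + 1)
        for pos, e in enumerate(order):
            if pos < k:
                p_pre[j, e], p_post[j, e] = 1.0 / scale, 1.0
    return p_pre, p_post, order


class TestLikelihood:
    def test_two_event_worked_example(self):
        """Hand-enumerated N=2 example: L(A,B) = 0.32667, L(B,A) = 0.09333."""
        p_post = np.array([[0.9, 0.2]])
        p_pre = np.array([[0.1, 0.8]])
        ll_ab = ebm_log_likelihood(p_pre, p_post, [0, 1])
        ll_ba = ebm_log_likelihood(p_pre, p_post, [1, 0])
        assert np.exp(ll_ab) == pytest.approx((0.08 + 0.72 + 0.18) / 3, abs=1e-12)
        assert np.exp(ll_ba) == pytest.approx((0.08 + 0.02 + 0.18) / 3, abs=1e-12)
        assert np.exp(ll_ab) == pytest.approx(0.32667, abs=5e-6)
        assert np.exp(ll_ba) == pytest.approx(0.09333, abs=5e-6)

    def test_single_event_uninformative_subject(self):
        ll = ebm_log_likelihood(np.array([[1.0]]), np.array([[1.0]]), [0])
        assert ll == pytest.approx(0.0, abs=1e-12)

    def test_flat_densities_make_all_permutations_equal(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.1, 1.0, size=(4, 4))
        lls = {
            ebm_log_likelihood(p, p, perm)
            for perm in itertools.permutations(range(4))
        }
        assert np.ptp(list(lls)) < 1e-9

    def test_matches_brute_force_on_random_inputs(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            p_pre, p_post = _random_problem(rng, 5, 4)
            order = rng.permutation(4)
            fast = ebm_log_likelihood(p_pre, p_post, order)
            slow = _brute_force_likelihood(p_pre, p_post, order)
            assert fast == pytest.approx(slow, rel=1e-10)

    def test_invariant_to_subject_order_and_event_relabeling(self):
        rng = np.random.default_rng(2)
        p_pre, p_post = _random_problem(rng, 6, 5)
        order = rng.permutation(5)
        base = ebm_log_likelihood(p_pre, p_post, order)
        shuffle = rng.permutation(6)
        assert ebm_log_likelihood(p_pre[shuffle], p_post[shuffle], order) == \
            pytest.approx(base, rel=1e-12)
        relabel = rng.permutation(5)
        inv = np.argsort(relabel)
        assert ebm_log_likelihood(
            p_pre[:, relabel], p_post[:, relabel], inv[order]
        ) == pytest.approx(base, rel=1e-12)

    def test_non_permutation_sequence_rejected(self):
        p = np.full((2, 3), 0.5)
        with pytest.raises(ValidationError):
            ebm_log_likelihood(p, p, [0, 0, 1])


class TestGreedyAscent:
    def test_finds_exhaustive_argmax_on_strong_signal(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            p_pre, p_post, _ = _strong_signal_problem(rng, 40, 5)
            best, _ = exhaustive_argmax(p_pre, p_post)
            found = greedy_ascent(p_pre, p_post, n_restarts=5, seed=0)
            assert ebm_log_likelihood(p_pre, p_post, found) == pytest.approx(
                ebm_log_likelihood(p_pre, p_post, best), rel=1e-12
            )

    def test_flat_likelihood_returns_valid_permutation(self):
        p = np.full((3, 4), 0.5)
        found = greedy_ascent(p, p, n_restarts=2, seed=1)
        assert sorted(found.tolist()) == [0, 1, 2, 3]
        assert ebm_log_likelihood(p, p, found) == pytest.approx(
            ebm_log_likelihood(p, p, np.arange(4))
        )

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        p_pre, p_post = _random_problem(rng, 20, 6)
        a = greedy_ascent(p_pre, p_post, n_restarts=4, seed=9)
        b = greedy_ascent(p_pre, p_post, n_restarts=4, seed=9)
        np.testing.assert_array_equal(a, b)


class TestMCMC:
    def test_flat_likelihood_gives_uniform_positional_frequencies(self):
        p = np.full((5, 3), 0.5)
        post = mcmc_sample(p, p, np.arange(3), n_iter=30_000, seed=0)
        dens = positional_density(post, ["A", "B", "C"])
        np.testing.assert_allclose(dens.matrix, 1.0 / 3, atol=0.03)

    def test_modal_sample_matches_exhaustive_argmax(self):
        rng = np.random.default_rng(5)
        p_pre, p_post, _ = _strong_signal_problem(rng, 40, 5)
        best, _ = exhaustive_argmax(p_pre, p_post)
        post = mcmc_sample(p_pre, p_post, np.arange(5), n_iter=20_000, seed=1)
        np.testing.assert_array_equal(post.maximum_likelihood_sequence(), best)
        # modal retained sample equals the argmax too
        uniq, counts = np.unique(post.samples, axis=0, return_counts=True)
        np.testing.assert_array_equal(uniq[counts.argmax()], best)

    def test_acceptance_rate_positive_and_bounded(self):
        rng = np.random.default_rng(6)
        p_pre, p_post = _random_problem(rng, 10, 4)
        post = mcmc_sample(p_pre, p_post, np.arange(4), n_iter=2_000, seed=2)
        assert 0.0 < post.acceptance_rate <= 1.0

    def test_positional_density_close_to_enumerated_posterior(self):
        """Total variation between MCMC and exact posterior under 0.05 (N=5)."""
        rng = np.random.default_rng(7)
        p_pre, p_post = _random_problem(rng, 15, 5)
        exact = exact_posterior_density(p_pre, p_post)
        post = mcmc_sample(p_pre, p_post, np.arange(5), n_iter=60_000, seed=3)
        approx = positional_density(post, exact.events)
        tv_rows = 0.5 * np.abs(exact.matrix - approx.matrix).sum(axis=1)
        assert tv_rows.max() < 0.05


class TestPositionalDensity:
    def test_counts_from_explicit_samples(self):
        samples = np.array([[0, 1], [0, 1], [0, 1], [1, 0]])
        post = SequencePosterior(samples, np.zeros(4), 4, 0, 1.0)
        dens = positional_density(post, ["A", "B"])
        np.testing.assert_allclose(dens.matrix, [[0.75, 0.25], [0.25, 0.75]])

    def test_identical_samples_give_permutation_matrix(self):
        samples = np.tile([2, 0, 1], (10, 1))
        post = SequencePosterior(samples, np.zeros(10), 10, 0, 1.0)
        dens = positional_density(post, ["A", "B", "C"])
        expected = np.zeros((3, 3))
        expected[2, 0] = expected[0, 1] = expected[1, 2] = 1.0
        np.testing.assert_array_equal(dens.matrix, expected)

    def test_always_doubly_stochastic(self):
        rng = np.random.default_rng(8)
        samples = np.array([rng.permutation(6) for _ in range(97)])
        post = SequencePosterior(samples, np.zeros(97), 97, 0, 1.0)
        dens = positional_density(post, [f"E{i}" for i in range(6)])
        np.testing.assert_allclose(dens.matrix.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(dens.matrix.sum(axis=0), 1.0, atol=1e-9)


class TestCumulativeDensity:
    def test_running_sum_row(self):
        dens = PositionalDensity(np.array([[0.75, 0.25], [0.25, 0.75]]), ["A", "B"])
        np.testing.assert_allclose(
            cumulative_density(dens), [[0.75, 1.0], [0.25, 1.0]]
        )

    def test_permutation_matrix_gives_step_functions(self):
        m = np.eye(3)[[1, 2, 0]]
        dens = PositionalDensity(m, ["A", "B", "C"])
        cum = cumulative_density(dens)
        assert set(np.unique(cum)) <= {0.0, 1.0}
        np.testing.assert_allclose(cum[:, -1], 1.0)

    def test_final_column_is_one(self):
        rng = np.random.default_rng(9)
        samples = np.array([rng.permutation(5) for _ in range(31)])
        post = SequencePosterior(samples, np.zeros(31), 31, 0, 1.0)
        dens = positional_density(post, [f"E{i}" for i in range(5)])
        np.testing.assert_allclose(cumulative_density(dens)[:, -1], 1.0, atol=1e-9)
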