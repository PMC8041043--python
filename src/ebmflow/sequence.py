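"""Event-sequence inference: the event-based model likelihood, greedy
initialisation, Metropolis MCMC over permutations, and positional densities.

The model assumes every subject follows one monotone cascade of N biomarker
events at an unknown stage k in {0..N}.  With per-subject, per-event
densities p_post (event occurred) and p_pre (not yet), the likelihood of a
sequence s marginalises the stage with a uniform prior:

    L = prod_j (1/(N+1)) * sum_{k=0}^{N} prod_{i<=k} p_post[j, s_i]
                                        * prod_{i>k} p_pre[j, s_i]

computed in log space with a prefix/suffix cumulative-sum scheme, O(J*N)
per sequence.  The posterior over sequences is summarised as the N x N
positional density: the proportion of posterior samples placing each event
at each position (rows and columns each average to a distribution, since
the matrix is a mean of permutation matrices).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .errors import ValidationError

__all__ = [
    "SequencePosterior",
    "PositionalDensity",
    "ebm_log_likelihood",
    "stage_log_likelihoods",
    "greedy_ascent",
    "mcmc_sample",
    "positional_density",
    "cumulative_density",
    "exhaustive_argmax",
    "exact_posterior_density",
]


def _validate_matrices(p_pre: np.ndarray, p_post: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p_pre = np.asarray(p_pre, dtype=float)
    p_post = np.asarray(p_post, dtype=float)
    if p_pre.shape != p_post.shape or p_pre.ndim != 2:
        raise ValidationError("p_pre and p_post must be equal-shape 2-D matrices")
    if not (np.all(np.isfinite(p_pre)) and np.all(np.isfinite(p_post))):
        raise ValidationError("density matrices must be finite")
    if np.any(p_pre <= 0) or np.any(p_post <= 0):
        raise ValidationError("density matrices must be positive (apply the floor)")
    return p_pre, p_post


def stage_log_likelihoods(
    log_pre: np.ndarray, log_post: np.ndarray, order: np.ndarray
) -> np.ndarray:
    """Per-subject log-likelihood at every stage k = 0..N (unnormalised).

    ``order`` is the event sequence as column indices into the matrices.
    Element [j, k] = sum_{i<=k} log_post[j, s_i] + sum_{i>k} log_pre[j, s_i].
    """
    lp = log_post[:, order]
    lq = log_pre[:, order]
    J, N = lp.shape
    L = np.zeros((J, N + 1))
    np.cumsum(lp, axis=1, out=L[:, 1:])
    c_pre = np.zeros((J, N + 1))
    np.cumsum(lq, axis=1, out=c_pre[:, 1:])
    L += c_pre[:, -1:] - c_pre
    return L


def _loglik_from_logs(log_pre: np.ndarray, log_post: np.ndarray, order: np.ndarray) -> float:
    L = stage_log_likelihoods(log_pre, log_post, order)
    # inline log-sum-exp over stages (hot path: called per MCMC proposal)
    m = L.max(axis=1)
    s = np.exp(L - m[:, None]).sum(axis=1)
    return float(np.sum(m + np.log(s)) - L.shape[0] * np.log(L.shape[1]))


def ebm_log_likelihood(p_pre: np.ndarray, p_post: np.ndarray, sequence) -> float:
    """Log-likelihood of an event sequence under the uniform-stage model."""
    p_pre, p_post = _validate_matrices(p_pre, p_post)
    order = np.asarray(sequence, dtype=int)
    N = p_pre.shape[1]
    if sorted(order.tolist()) != list(range(N)):
        raise ValidationError("sequence must be a permutation of all events")
    return _loglik_from_logs(np.log(p_pre), np.log(p_post), order)


def greedy_ascent(
    p_pre: np.ndarray,
    p_post: np.ndarray,
    n_restarts: int = 10,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Best local optimum over pairwise swaps from random restarts.

    From each random starting permutation, repeatedly apply the best
    improving pairwise swap (ties broken by first occurrence in row-major
    (i, j) scan order) until no swap improves the log-likelihood.
    """
    p_pre, p_post = _validate_matrices(p_pre, p_post)
    log_pre, log_post = np.log(p_pre), np.log(p_post)
    N = p_pre.shape[1]
    rng = np.random.default_rng(seed)
    best_order, best_ll = None, -np.inf
    pairs = list(itertools.combinations(range(N), 2))
    for _ in range(max(1, n_restarts)):
        order = rng.permutation(N)
        cur = _loglik_from_logs(log_pre, log_post, order)
        improved = True
        while improved:
            improved = False
            best_delta, best_pair = 0.0, None
            for i, j in pairs:
                order[i], order[j] = order[j], order[i]
                ll = _loglik_from_logs(log_pre, log_post, order)
                order[i], order[j] = order[j], order[i]
                if ll - cur > best_delta:
                    best_delta, best_pair = ll - cur, (i, j)
            if best_pair is not None:
                i, j = best_pair
                order[i], order[j] = order[j], order[i]
                cur += best_delta
                improved = True
        if cur > best_ll:
            best_ll, best_order = cur, order.copy()
    return best_order


@dataclass
class SequencePosterior:
    """Post-burn-in MCMC samples over event sequences.

    ``samples[t]`` is a permutation (event indices in sequence order);
    ``log_likelihoods[t]`` the corresponding model log-likelihood.
    """

    samples: np.ndarray          # (T, N) int
    log_likelihoods: np.ndarray  # (T,)
    n_iterations: int
    burn_in: int
    acceptance_rate: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.samples) == 0:
            raise ValidationError("posterior must contain at least one sample")
        if not np.all(np.isfinite(self.log_likelihoods)):
            raise ValidationError("posterior log-likelihoods must be finite")
        if not 0.0 <= self.acceptance_rate <= 1.0:
            raise ValidationError("acceptance rate must lie in [0, 1]")

    @property
    def n_events(self) -> int:
        return self.samples.shape[1]

    def maximum_likelihood_sequence(self) -> np.ndarray:
        return self.samples[int(np.argmax(self.log_likelihoods))].copy()


def mcmc_sample(
    p_pre: np.ndarray,
    p_post: np.ndarray,
    init,
    n_iter: int = 50_000,
    seed: int | np.random.Generator = 0,
    burn_in_fraction: float = 0.10,
) -> SequencePosterior:
    """Metropolis sampling over sequences with pairwise-swap proposals.

    A proposal swaps two distinct uniformly chosen positions and is accepted
    with probability min(1, exp(delta log L)).  The first
    ``burn_in_fraction`` of iterations is discarded; the current state is
    recorded at every retained iteration (no thinning).
    """
    p_pre, p_post = _validate_matrices(p_pre, p_post)
    log_pre, log_post = np.log(p_pre), np.log(p_post)
    N = p_pre.shape[1]
    order = np.asarray(init, dtype=int).copy()
    if sorted(order.tolist()) != list(range(N)):
        raise ValidationError("init must be a permutation of all events")
    rng = np.random.default_rng(seed)
    n_iter = int(n_iter)
    burn = int(n_iter * burn_in_fraction)
    cur_ll = _loglik_from_logs(log_pre, log_post, order)
    kept = n_iter - burn
    samples = np.empty((kept, N), dtype=np.int64)
    lls = np.empty(kept)
    n_accept = 0
    # pre-draw proposals and acceptance uniforms for speed
    ii = rng.integers(0, N, size=n_iter)
    jj = rng.integers(0, N - 1, size=n_iter)
    jj = np.where(jj >= ii, jj + 1, jj)  # distinct positions, uniform over pairs
    log_u = np.log(rng.random(size=n_iter))
    for t in range(n_iter):
        i, j = ii[t], jj[t]
        order[i], order[j] = order[j], order[i]
        ll = _loglik_from_logs(log_pre, log_post, order)
        if log_u[t] < ll - cur_ll:
            cur_ll = ll
            n_accept += 1
        else:
            order[i], order[j] = order[j], order[i]
        if t >= burn:
            samples[t - burn] = order
            lls[t - burn] = cur_ll
    return SequencePosterior(
        samples=samples,
        log_likelihoods=lls,
        n_iterations=n_iter,
        burn_in=burn,
        acceptance_rate=n_accept / n_iter,
        seed=None if isinstance(seed, np.random.Generator) else int(seed),
    )


@dataclass
class PositionalDensity:
    """N x N row-stochastic matrix of posterior event positions.

    ``matrix[e, p]`` is the proportion of posterior samples placing event
    ``events[e]`` at position p (0-based internally; reported 1-based in
    outputs).  Being an average of permutation matrices it is doubly
    stochastic.  ``display_order`` sorts events by posterior mean position
    (earliest first) for plotting.
    """

    matrix: np.ndarray
    events: list[str]
    modality_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.events):
            raise ValidationError("positional density must be N x N with N event labels")
        if np.any(m < -1e-12) or np.any(m > 1 + 1e-12):
            raise ValidationError("positional density entries must lie in [0, 1]")
        self.matrix = m

    @property
    def n_events(self) -> int:
        return len(self.events)

    def mean_positions(self) -> np.ndarray:
        return self.matrix @ np.arange(self.n_events)

    @property
    def display_order(self) -> np.ndarray:
        return np.argsort(self.mean_positions(), kind="stable")

    def consensus_sequence(self) -> np.ndarray:
        """Event order by posterior mean position (ties by event index)."""
        return self.display_order


def positional_density(
    posterior: SequencePosterior, events: list[str], modality_of: dict[str, str] | None = None
) -> PositionalDensity:
    """Tally posterior samples into the positional density matrix."""
    samples = posterior.samples
    T, N = samples.shape
    if len(events) != N:
        raise ValidationError("event labels must match the sampled permutation length")
    counts = np.zeros((N, N))
    positions = np.arange(N)
    for t in range(T):
        counts[samples[t], positions] += 1.0
    return PositionalDensity(counts / T, list(events), modality_of)


def cumulative_density(density: PositionalDensity) -> np.ndarray:
    """Row-wise running sum of the positional density (cumulative abnormality)."""
    return np.cumsum(density.matrix, axis=1)


def exhaustive_argmax(p_pre: np.ndarray, p_post: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact maximum-likelihood sequence by enumerating all N! permutations.

    Independent oracle for small N (<= ~8); ties broken by lexicographic
    order of the permutation.
    """
    p_pre, p_post = _validate_matrices(p_pre, p_post)
    log_pre, log_post = np.log(p_pre), np.log(p_post)
    N = p_pre.shape[1]
    best, best_ll = None, -np.inf
    for perm in itertools.permutations(range(N)):
        ll = _loglik_from_logs(log_pre, log_post, np.array(perm))
        if ll > best_ll:
            best, best_ll = perm, ll
    return np.array(best), best_ll


def exact_posterior_density(
    p_pre: np.ndarray, p_post: np.ndarray, events: list[str] | None = None
) -> PositionalDensity:
    """Exact posterior positional density under a uniform sequence prior.

    Enumerates all permutations; practical only for small N.
    """
    p_pre, p_post = _validate_matrices(p_pre, p_post)
    log_pre, log_post = np.log(p_pre), np.log(p_post)
    N = p_pre.shape[1]
    perms = np.array(list(itertools.permutations(range(N))))
    lls = np.array([_loglik_from_logs(log_pre, log_post, p) for p in perms])
    w = np.exp(lls - logsumexp(lls))
    D = np.zeros((N, N))
    positions = np.arange(N)
    for perm, wt in zip(perms, w):
        D[perm, positions] += wt
    labels = events if events is not None else [f"E{i}" for i in range(N)]
    return PositionalDensity(D, list(labels))
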