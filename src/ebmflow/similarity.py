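"""Model similarity via the Bhattacharyya coefficient.

Two event-based models are compared through their positional density maps:
for each event row the Hellinger distance between the two discrete position
distributions is computed, and the similarity is

    BC = 1 - Hbar**2,    Hbar = mean row-wise Hellinger distance,

so BC = 1 when the posteriors coincide and BC = 0 when every row pair has
disjoint support.  The discrete Hellinger distance used here is
sqrt(1 - sum_i sqrt(p_i q_i)) WITHOUT the 1/sqrt(2) normalisation, which is
what pins those endpoints to exactly 1 and 0.

A randomized reference BC0 (similarity of models built from uniformly random
sequences) provides the chance-level floor against which cross-validation
similarity is judged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ValidationError
from .sequence import PositionalDensity, SequencePosterior, positional_density


def hellinger(p: np.ndarray, q: np.ndarray) -> float:
    """Hellinger distance between two discrete distributions in [0, 1].

    Inputs are renormalised internally; negative entries are an error.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise ValidationError("distributions must be equal-length vectors")
    if np.any(p < 0) or np.any(q < 0):
        raise ValidationError("distributions must be non-negative")
    sp, sq = p.sum(), q.sum()
    if sp <= 0 or sq <= 0:
        raise ValidationError("distributions must have positive mass")
    if np.array_equal(p, q):
        return 0.0  # identical distributions: exactly zero, no rounding
    affinity = float(np.sum(np.sqrt((p / sp) * (q / sq))))
    return float(np.sqrt(max(0.0, 1.0 - min(affinity, 1.0))))


@dataclass
class SimilarityResult:
    """BC similarity between two models with its row-wise breakdown."""

    bc: float
    mean_hellinger: float
    row_hellinger: np.ndarray = field(repr=False)

    @property
    def n_rows(self) -> int:
        return len(self.row_hellinger)

    @property
    def sd_hellinger(self) -> float:
        return float(np.std(self.row_hellinger, ddof=1)) if self.n_rows > 1 else 0.0


def bhattacharyya_similarity(
    a: PositionalDensity, b: PositionalDensity
) -> SimilarityResult:
    """BC = 1 - (mean row-wise Hellinger distance)^2 between two models.

    Rows are aligned by event label, not display position; the event sets
    must match exactly.
    """
    if set(a.events) != set(b.events):
        diff = sorted(set(a.events) ^ set(b.events))
        raise ValidationError(f"event sets differ: {diff}")
    index_b = {e: i for i, e in enumerate(b.events)}
    rows = np.array([
        hellinger(a.matrix[i], b.matrix[index_b[e]]) for i, e in enumerate(a.events)
    ])
    h_bar = float(rows.mean())
    return SimilarityResult(bc=1.0 - h_bar**2, mean_hellinger=h_bar, row_hellinger=rows)


def randomized_reference(
    n_events: int,
    n_models: int = 50,
    samples_per_model: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Chance-level BC between models built from uniformly random sequences.

    Each of ``n_models`` positional densities is tallied from
    ``samples_per_model`` independent uniform permutations; the mean and SD
    of BC over all unordered model pairs is returned.
    """
    if n_events < 2 or n_models < 2:
        raise ValidationError("need n_events >= 2 and n_models >= 2")
    rng = np.random.default_rng(seed)
    events = [f"E{i}" for i in range(n_events)]
    models = []
    for _ in range(n_models):
        perms = np.array([rng.permutation(n_events) for _ in range(samples_per_model)])
        post = SequencePosterior(
            samples=perms,
            log_likelihoods=np.zeros(len(perms)),
            n_iterations=samples_per_model,
            burn_in=0,
            acceptance_rate=1.0,
        )
        models.append(positional_density(post, events))
    bcs = [
        bhattacharyya_similarity(models[i], models[j]).bc
        for i in range(n_models)
        for j in range(i + 1, n_models)
    ]
    bcs = np.asarray(bcs)
    return float(bcs.mean()), float(bcs.std(ddof=1))


def kendall_tau(order_a, order_b) -> tuple[float, float]:
    """Kendall rank correlation between two rankings of the same items.

    tau-a (equal to tau-b in the absence of ties) with the exact two-sided
    p-value for n <= 10 items, normal approximation above.
    """
    a = np.asarray(order_a, dtype=float)
    b = np.asarray(order_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("rankings must have equal length")
    method = "exact" if len(a) <= 10 else "asymptotic"
    res = stats.kendalltau(a, b, method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ComparisonResult:
    """Cross-model comparison at modality level."""

    bc: float
    tau: float
    tau_pvalue: float
    modalities: list[str]
    mean_positions_a: np.ndarray
    mean_positions_b: np.ndarray


def _modality_density(model: PositionalDensity, modality_of: dict[str, str],
                      modalities: list[str]) -> np.ndarray:
    N = model.n_events
    out = np.zeros((len(modalities), N))
    for k, mod in enumerate(modalities):
        rows = [i for i, e in enumerate(model.events) if modality_of[e] == mod]
        avg = model.matrix[rows].mean(axis=0)
        out[k] = avg / avg.sum()
    return out


def modality_compare(
    a: PositionalDensity, b: PositionalDensity, modality_of: dict[str, str]
) -> ComparisonResult:
    """Compare two models after averaging posterior rows within modality.

    Each model's rows are averaged per modality and renormalised to give a
    modality-level positional map; BC is computed between the maps, and the
    Kendall rank correlation between the two modality orderings by mean
    position (exact two-sided p-value for few modalities).
    """
    for model, name in ((a, "A"), (b, "B")):
        uncovered = [e for e in model.events if e not in modality_of]
        if uncovered:
            raise ValidationError(f"model {name} events lack modality tags: {uncovered}")
    mods_a = {modality_of[e] for e in a.events}
    mods_b = {modality_of[e] for e in b.events}
    if mods_a != mods_b:
        raise ValidationError(f"modalities not shared by both models: {sorted(mods_a ^ mods_b)}")
    modalities = sorted(mods_a)
    if len(modalities) < 2:
        raise ValidationError("need at least 2 shared modalities")
    if a.n_events != b.n_events:
        raise ValidationError("models must have the same number of positions")
    da = _modality_density(a, modality_of, modalities)
    db = _modality_density(b, modality_of, modalities)
    rows = np.array([hellinger(da[i], db[i]) for i in range(len(modalities))])
    h_bar = float(rows.mean())
    positions = np.arange(a.n_events)
    mean_a = da @ positions
    mean_b = db @ positions
    # deterministic tie-break: rank by (mean position, modality name)
    rank_a = np.argsort(np.argsort(mean_a, kind="stable"))
    rank_b = np.argsort(np.argsort(mean_b, kind="stable"))
    tau, p = kendall_tau(rank_a, rank_b)
    return ComparisonResult(
        bc=1.0 - h_bar**2, tau=tau, tau_pvalue=p, modalities=modalities,
        mean_positions_a=mean_a, mean_positions_b=mean_b,
    )
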