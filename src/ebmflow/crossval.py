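"""Repeated stratified cross-validation of the event-based model.

The robustness protocol refits both the mixture models and the sequence on
80% of the cohort for each of ``repeats`` random stratified 5-fold
partitions (50 fold models by default), averages the fold posteriors into
the final model, quantifies fold agreement with the Bhattacharyya
coefficient, and measures staging accuracy with a two-run protocol: gold
stages come from the full cross-validated (averaged) model of run 1, and
run 2 (fresh partitions) stages each fold's held-out subjects under that
fold's model.

Stratification labels are {control, PDD-LR, PDD-HR}, preserving the
case/control and risk mix in every fold.  The event set is fixed before CV
(markers without disease signal on the full data are dropped); markers that
fail the signal check only within some fold are retained there but flagged,
so fold densities stay comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import RepeatedStratifiedKFold

from .cohort import CohortTable
from .config import PipelineConfig
from .distributions import EventDistribution, event_probability, has_disease_signal
from .errors import ValidationError
from .pipeline import (
    PreparedCohort,
    density_matrices,
    fit_event_distributions,
    fit_pipeline,
    greedy_ascent,
    prepare_cohort,
)
from .preprocess import adjust_covariates, assign_risk_groups
from .sequence import (
    PositionalDensity,
    SequencePosterior,
    mcmc_sample,
    positional_density,
)
from .similarity import bhattacharyya_similarity
from .staging import stage_cohort, staging_error

logger = logging.getLogger(__name__)


@dataclass
class CVPlan:
    """k x repeats stratified train/test splits, reproducible from seed."""

    k: int
    repeats: int
    labels: np.ndarray
    splits: list[tuple[np.ndarray, np.ndarray]]  # (train_idx, test_idx)
    fold_of: list[tuple[int, int]]               # (repeat, fold) per split
    seed: int

    @property
    def n_folds(self) -> int:
        return len(self.splits)


def make_splits(labels, k: int = 5, repeats: int = 10, seed: int = 0) -> CVPlan:
    """Build repeated stratified k-fold splits over the given strata labels."""
    labels = np.asarray(labels)
    strata, counts = np.unique(labels, return_counts=True)
    small = strata[counts < k]
    if len(small):
        raise ValidationError(
            f"strata smaller than k={k}: {dict(zip(small.tolist(), counts[counts < k].tolist()))}"
        )
    rskf = RepeatedStratifiedKFold(n_splits=k, n_repeats=repeats,
                                   random_state=int(seed) & 0x7FFFFFFF)
    splits = [(tr, te) for tr, te in rskf.split(np.zeros(len(labels)), labels)]
    fold_of = [(r, f) for r in range(repeats) for f in range(k)]
    return CVPlan(k=k, repeats=repeats, labels=labels, splits=splits,
                  fold_of=fold_of, seed=int(seed))


@dataclass
class FoldModel:
    """Mixtures + sequence posterior refit on one training fold."""

    repeat: int
    fold: int
    events: list[str]
    distributions: dict[str, EventDistribution]
    posterior: SequencePosterior
    density: PositionalDensity
    ml_sequence: np.ndarray
    prepared: PreparedCohort = field(repr=False)
    train_index: np.ndarray = field(repr=False)
    signal_flags: dict[str, bool] = field(default_factory=dict)


def fit_fold(
    table: CohortTable,
    train_index: np.ndarray,
    events: list[str],
    config: PipelineConfig,
    seed: int = 0,
    repeat: int = 0,
    fold: int = 0,
) -> FoldModel:
    """Refit covariates, mixtures and sequence on the training subjects only.

    The covariate model is refit on the fold's training controls and the
    mixtures on the fold's training sample, so no held-out subject touches
    any fit.  The event set is the global one: fold-level screening is not
    re-run (screening and disease-signal exclusion are decided on the full
    data), and markers failing the signal check within this fold are
    retained but recorded in ``signal_flags``.
    """
    train_table = CohortTable(
        table.data.iloc[train_index].reset_index(drop=True), dict(table.modality_of)
    )
    if not (train_table.is_control().any() and (~train_table.is_control()).any()):
        raise ValidationError("training fold must contain controls and patients")
    cfg = config
    prepared = prepare_cohort(train_table, cfg)
    dists = fit_event_distributions(prepared, cfg, markers=events)
    flags = {m: has_disease_signal(dists[m]) for m in events}
    seq_mask = prepared.table.data["risk_group"].isin(set(cfg.sequence_groups)).to_numpy()
    p_pre, p_post = density_matrices(prepared, dists, events, seq_mask)
    rng_seed = np.random.SeedSequence([seed & 0x7FFFFFFF, repeat, fold])
    child_greedy, child_mcmc = rng_seed.spawn(2)
    init = greedy_ascent(p_pre, p_post, cfg.greedy_restarts,
                         np.random.default_rng(child_greedy))
    posterior = mcmc_sample(p_pre, p_post, init, cfg.mcmc_iterations,
                            np.random.default_rng(child_mcmc), cfg.burn_in_fraction)
    density = positional_density(posterior, events,
                                 {m: table.modality_of[m] for m in events})
    return FoldModel(
        repeat=repeat, fold=fold, events=list(events), distributions=dists,
        posterior=posterior, density=density,
        ml_sequence=posterior.maximum_likelihood_sequence(),
        prepared=prepared, train_index=np.asarray(train_index),
        signal_flags=flags,
    )


def run_cv(
    table: CohortTable, config: PipelineConfig, events: list[str],
    seed: int = 0,
) -> tuple[CVPlan, list[FoldModel]]:
    """Fit one repeated stratified CV round: one FoldModel per split."""
    risk = assigned_risk_labels(table, config)
    plan = make_splits(risk, config.cv_folds, config.cv_repeats, seed)
    folds = [
        fit_fold(table, tr, events, config, seed, r, f)
        for (tr, _), (r, f) in zip(plan.splits, plan.fold_of)
    ]
    return plan, folds


def assigned_risk_labels(table: CohortTable, config: PipelineConfig) -> np.ndarray:
    """Stratification labels {control, PDD-LR, PDD-HR} for splitting."""
    t = assign_risk_groups(table, config.onset_threshold)
    return t.data["risk_group"].to_numpy()


def average_model(folds: list[FoldModel]) -> PositionalDensity:
    """Pool post-burn-in samples across folds into the final model.

    Equivalent to the sample-count-weighted mean of the fold densities, so
    the result is still an average of permutation matrices (doubly
    stochastic).
    """
    if not folds:
        raise ValidationError("need at least one fold")
    events = folds[0].events
    for f in folds:
        if f.events != events:
            raise ValidationError("folds have mismatched event sets")
    weights = np.array([len(f.posterior.samples) for f in folds], dtype=float)
    stacked = np.sum(
        [w * f.density.matrix for w, f in zip(weights, folds)], axis=0
    ) / weights.sum()
    return PositionalDensity(stacked, list(events), folds[0].density.modality_of)


def cv_similarity(folds: list[FoldModel]) -> tuple[float, float]:
    """Mean and SD of BC over all unordered fold pairs."""
    if len(folds) < 2:
        raise ValidationError("need at least two folds")
    bcs = [
        bhattacharyya_similarity(folds[i].density, folds[j].density).bc
        for i in range(len(folds))
        for j in range(i + 1, len(folds))
    ]
    bcs = np.asarray(bcs)
    sd = float(bcs.std(ddof=1)) if len(bcs) > 1 else 0.0
    return float(bcs.mean()), sd


@dataclass
class CVStagingResult:
    """Two-run CV staging accuracy."""

    mae: float
    sd: float
    raw_errors: np.ndarray
    gold_stages: np.ndarray
    n_test_occurrences: int


def cv_staging_accuracy(
    table: CohortTable, config: PipelineConfig, seed: int = 0
) -> CVStagingResult:
    """Two-run protocol: gold stages from run 1's averaged model, errors from run 2.

    Run 1 fits the full CV and averages all fold posteriors; every subject
    is staged with full-data mixtures under the averaged model's consensus
    sequence — the gold standard.  Run 2 (seed + 1) refits fresh folds and
    stages each fold's held-out test subjects under that fold's model; the
    error is fold stage minus gold stage, aggregated over every (subject,
    fold) test occurrence.
    """
    full = fit_pipeline(table, config, seed)
    events = full.events

    _, folds1 = run_cv(table, config, events, seed)
    avg = average_model(folds1)
    consensus = avg.consensus_sequence()
    p_pre_all, p_post_all = density_matrices(full.prepared, full.distributions, events)
    ids = full.prepared.table.data["subject_id"].tolist()
    gold_assign = stage_cohort(p_pre_all, p_post_all, consensus, ids)
    gold = {s.subject_id: s.stage for s in gold_assign}

    plan2, folds2 = run_cv(table, config, events, seed + 1)
    errors = []
    for (train, test), fm in zip(plan2.splits, folds2):
        test_table = CohortTable(
            table.data.iloc[test].reset_index(drop=True), dict(table.modality_of)
        )
        t = assign_risk_groups(test_table, config.onset_threshold)
        t = adjust_covariates(t, fm.prepared.covariate_model)
        oriented = fm.prepared.orientation.oriented(t, events)
        J = len(t.data)
        p_pre = np.ones((J, len(events)))
        p_post = np.ones((J, len(events)))
        for e, m in enumerate(events):
            p_pre[:, e], p_post[:, e] = event_probability(
                fm.distributions[m], oriented[:, e]
            )
        assigns = stage_cohort(p_pre, p_post, fm.ml_sequence,
                               t.data["subject_id"].tolist())
        for s in assigns:
            if s.subject_id in gold:  # excluded RBD controls carry no gold stage
                errors.append(s.stage - gold[s.subject_id])
    raw = np.asarray(errors, dtype=float)
    abs_err = np.abs(raw)
    sd = float(np.std(abs_err, ddof=1)) if len(raw) > 1 else 0.0
    gold_arr = np.asarray([gold[i] for i in ids], dtype=float)
    return CVStagingResult(
        mae=float(abs_err.mean()), sd=sd, raw_errors=raw,
        gold_stages=gold_arr, n_test_occurrences=len(raw),
    )
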