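"""End-to-end pipeline: preparation, mixture fitting, sequence inference, staging.

The full analysis on a cohort table is:

1. split patients into risk groups by age at onset, drop probable-RBD
   controls;
2. fit the control-trained covariate model and residualise every marker;
3. orient markers so larger adjusted values mean more abnormal;
4. Mann-Whitney-screen the declared screened modalities (high-risk patients
   vs controls, uncorrected);
5. fit the constrained KDE mixture per marker on controls plus high-risk
   patients, dropping markers without discernible disease signal;
6. infer the event sequence posterior (greedy initialisation + Metropolis
   MCMC) from the patients' per-event densities;
7. stage every subject at their maximum-likelihood model stage.

Sub-seeds for the greedy search and the sampler are derived from the single
run seed, so a run is reproducible end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .config import CONTROL, PipelineConfig
from .distributions import (
    EventDistribution,
    event_probability,
    fit_constrained_kde_mixture,
    has_disease_signal,
    pooled_percentile_labels,
)
from .errors import ValidationError
from .preprocess import (
    CovariateModel,
    MarkerOrientation,
    adjust_covariates,
    assign_risk_groups,
    exclude_rbd_controls,
    fit_covariate_model,
    orient_markers,
    screen_markers_mannwhitney,
)
from .sequence import (
    PositionalDensity,
    SequencePosterior,
    ebm_log_likelihood,
    greedy_ascent,
    mcmc_sample,
    positional_density,
)
from .staging import StageAssignment, stage_cohort

logger = logging.getLogger(__name__)


def _subseed(seed: int, *path: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *path])


@dataclass
class PreparedCohort:
    """Cohort after risk grouping, exclusions, adjustment and orientation."""

    table: CohortTable
    covariate_model: CovariateModel
    orientation: MarkerOrientation
    markers: list[str]

    def oriented_values(self, markers: list[str] | None = None) -> np.ndarray:
        return self.orientation.oriented(self.table, markers or self.markers)


def prepare_cohort(table: CohortTable, config: PipelineConfig) -> PreparedCohort:
    """Steps 1-4: risk groups, RBD exclusion, adjustment, orientation, screening."""
    t = assign_risk_groups(table, config.onset_threshold)
    t = exclude_rbd_controls(t, config.rbd_cutoff)
    declared = [m for m in t.markers if m not in set(config.excluded_markers)]
    t.modality_of = {m: t.modality_of[m] for m in declared}
    covar = fit_covariate_model(t)
    t = adjust_covariates(t, covar)
    orientation = orient_markers(t, declared)

    screened_mods = set(config.screened_modalities)
    to_screen = [m for m in declared if t.modality_of[m] in screened_mods]
    if to_screen:
        # screening operates on oriented values; two-sided tests are
        # sign-invariant, so orientation does not change the outcome
        retained_screened = set(
            screen_markers_mannwhitney(t, to_screen, config.screening_alpha)
        )
        dropped = [m for m in to_screen if m not in retained_screened]
        if dropped:
            logger.info("screening dropped %d markers: %s", len(dropped), dropped)
    else:
        retained_screened = set()
    markers = [
        m for m in declared
        if t.modality_of[m] not in screened_mods or m in retained_screened
    ]
    if not markers:
        raise ValidationError("no markers survived screening")
    return PreparedCohort(table=t, covariate_model=covar,
                          orientation=orientation, markers=markers)


def fit_event_distributions(
    prepared: PreparedCohort, config: PipelineConfig,
    markers: list[str] | None = None,
) -> dict[str, EventDistribution]:
    """Step 5 for each marker: pooled-percentile labels + constrained mixture.

    Mixtures are fitted on controls plus the risk groups named in
    ``config.mixture_groups``; the pooled percentile threshold is computed
    on the same sample.
    """
    markers = markers or prepared.markers
    df = prepared.table.data
    in_fit = df["risk_group"].isin(set(config.mixture_groups)).to_numpy()
    control = (df["group"] == CONTROL).to_numpy()
    oriented = prepared.oriented_values(markers)
    dists: dict[str, EventDistribution] = {}
    for e, marker in enumerate(markers):
        vals = np.where(in_fit, oriented[:, e], np.nan)
        constraint = pooled_percentile_labels(
            vals, control, config.percentile_constraint
        )
        dists[marker] = fit_constrained_kde_mixture(
            vals, control, constraint,
            marker=marker,
            max_iterations=config.max_em_iterations,
            tolerance=config.em_tolerance,
            bandwidth_rule=config.kde_bandwidth_rule,
        )
    return dists


def density_matrices(
    prepared: PreparedCohort,
    dists: dict[str, EventDistribution],
    markers: list[str],
    subject_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject (p_pre, p_post) matrices; missing markers contribute (1, 1)."""
    oriented = prepared.oriented_values(markers)
    if subject_mask is not None:
        oriented = oriented[subject_mask]
    J, N = oriented.shape
    p_pre = np.ones((J, N))
    p_post = np.ones((J, N))
    for e, marker in enumerate(markers):
        p_pre[:, e], p_post[:, e] = event_probability(dists[marker], oriented[:, e])
    return p_pre, p_post


@dataclass
class FittedEBM:
    """A fully fitted event-based model on one cohort."""

    events: list[str]
    distributions: dict[str, EventDistribution]
    posterior: SequencePosterior
    density: PositionalDensity
    ml_sequence: np.ndarray                   # event indices into `events`
    stages: list[StageAssignment]
    prepared: PreparedCohort
    config: PipelineConfig
    seed: int
    dropped_markers: list[str] = field(default_factory=list)

    @property
    def ml_sequence_names(self) -> list[str]:
        return [self.events[i] for i in self.ml_sequence]

    def staging_frame(self) -> pd.DataFrame:
        df = self.prepared.table.data
        return pd.DataFrame({
            "subject_id": [s.subject_id for s in self.stages],
            "risk_group": df["risk_group"].to_numpy(),
            "stage": [s.stage for s in self.stages],
            "log_likelihood": [s.log_likelihood for s in self.stages],
            "flat_likelihood": [s.flat for s in self.stages],
        })


def fit_pipeline(
    table: CohortTable, config: PipelineConfig, seed: int | None = None
) -> FittedEBM:
    """Run the full analysis on a cohort table."""
    seed = config.random_seed if seed is None else int(seed)
    prepared = prepare_cohort(table, config)
    dists = fit_event_distributions(prepared, config)
    events = [m for m in prepared.markers if has_disease_signal(dists[m])]
    dropped = [m for m in prepared.markers if m not in set(events)]
    if dropped:
        logger.info("no disease signal; dropped markers: %s", dropped)
    if len(events) < 2:
        raise ValidationError("fewer than 2 markers carry disease signal")

    df = prepared.table.data
    seq_mask = df["risk_group"].isin(set(config.sequence_groups)).to_numpy()
    p_pre_seq, p_post_seq = density_matrices(prepared, dists, events, seq_mask)
    init = greedy_ascent(
        p_pre_seq, p_post_seq, config.greedy_restarts,
        np.random.default_rng(_subseed(seed, 1)),
    )
    posterior = mcmc_sample(
        p_pre_seq, p_post_seq, init, config.mcmc_iterations,
        np.random.default_rng(_subseed(seed, 2)), config.burn_in_fraction,
    )
    modality = {m: prepared.table.modality_of[m] for m in events}
    density = positional_density(posterior, events, modality)
    # the greedy optimum initialises the sampler; keep the better of the two
    ml_seq = posterior.maximum_likelihood_sequence()
    if ebm_log_likelihood(p_pre_seq, p_post_seq, init) > float(
        np.max(posterior.log_likelihoods)
    ):
        ml_seq = np.asarray(init)

    p_pre_all, p_post_all = density_matrices(prepared, dists, events)
    stages = stage_cohort(
        p_pre_all, p_post_all, ml_seq, df["subject_id"].tolist()
    )
    return FittedEBM(
        events=events, distributions=dists, posterior=posterior,
        density=density, ml_sequence=ml_seq, stages=stages,
        prepared=prepared, config=config, seed=seed, dropped_markers=dropped,
    )
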