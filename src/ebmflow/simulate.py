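"""Synthetic cohort generator with a known monotone event cascade.

Generates cross-sectional cohorts with exactly the statistical structure the
event-based model assumes: every subject sits at a latent stage k of a
single true sequence S*; events at positions <= k draw from the post-event
(abnormal) distribution, later events from the pre-event (normal) one.  On
top of the latent cascade the generator layers the nuisance structure of
real cohort tables — covariate confounds (age/education slopes, gender
offsets), floor/ceiling censoring per modality, MCAR missingness, and
randomised marker orientation — so that every preprocessing step is
exercised, and ground truth (S*, true stages) is returned for recovery
experiments.

Default group sizes (33 controls / 64 low-risk / 36 high-risk patients) and
the 42-marker, 6-modality layout mirror the discovery-cohort structure this
package was built around.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .config import CONTROL, PATIENT, PDD_HR, PDD_LR
from .errors import ValidationError
from .sequence import PositionalDensity
from .similarity import bhattacharyya_similarity, kendall_tau
from .staging import StageAssignment, staging_error

#: Marker counts per modality in the default discovery-style layout (42 total).
DEFAULT_EVENTS_PER_MODALITY = {
    "clinical_cognitive": 8,
    "vision": 6,
    "retinal": 4,
    "cortical_thickness": 8,
    "substantia_nigra": 4,
    "qsm": 12,
}

#: (mean age, SD) per group, matching the discovery-cohort demographics.
_AGE_PARAMS = {CONTROL: (64.7, 9.0), PDD_LR: (59.7, 5.1), PDD_HR: (73.0, 4.0)}
_ONSET_PARAMS = {PDD_LR: (55.5, 4.3), PDD_HR: (70.1, 3.8)}
_RBDSQ_PARAMS = {CONTROL: (1.7, 1.3), PDD_LR: (4.2, 2.5), PDD_HR: (4.2, 2.4)}


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults are the package's study conditions.

    ``effect_size`` is the standardised pre/post separation d: pre-event
    values ~ N(0, 1), post-event ~ N(d, 1) before censoring.  Controls sit
    at stage 0 with probability ``control_stage0_prob`` (else stage 1 —
    slight contamination that exercises the constrained labelling); patients
    are uniform over stages 0..N with high-risk patients shifted later by
    ``hr_stage_offset`` (capped at N).
    """

    events_per_modality: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_EVENTS_PER_MODALITY)
    )
    n_controls: int = 33
    n_pdd_lr: int = 64
    n_pdd_hr: int = 36
    true_sequence: np.ndarray | None = None  # event indices; seed-derived if None
    control_stage0_prob: float = 0.90
    hr_stage_offset: int = 2
    effect_size: float = 2.0
    covariate_effects: dict[str, tuple[float, float, float]] | None = None
    floor_ceiling: dict[str, tuple[float, float]] | None = None
    missingness: float = 0.05
    flip_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_controls, self.n_pdd_lr, self.n_pdd_hr) < 0:
            raise ValidationError("group sizes must be non-negative")
        if self.effect_size <= 0:
            raise ValidationError("effect_size must be positive")
        if not 0.0 <= self.missingness < 1.0:
            raise ValidationError("missingness must lie in [0, 1)")

    @property
    def marker_names(self) -> list[str]:
        return [
            f"{mod}_{i + 1:02d}"
            for mod, n in self.events_per_modality.items()
            for i in range(n)
        ]

    @property
    def modality_of(self) -> dict[str, str]:
        return {
            f"{mod}_{i + 1:02d}": mod
            for mod, n in self.events_per_modality.items()
            for i in range(n)
        }

    @property
    def n_events(self) -> int:
        return sum(self.events_per_modality.values())


@dataclass
class SyntheticGroundTruth:
    """True sequence, true stages and a parameter echo for recovery tests."""

    true_sequence: np.ndarray       # event indices in true order
    event_names: list[str]
    true_stages: np.ndarray         # per subject, aligned with the cohort rows
    flipped: np.ndarray             # bool per event: stored sign-flipped on disk
    config: SyntheticConfig

    @property
    def sequence_names(self) -> list[str]:
        return [self.event_names[i] for i in self.true_sequence]

    def position_of(self) -> dict[str, int]:
        """1-based true cascade position per event name."""
        return {self.event_names[e]: p + 1 for p, e in enumerate(self.true_sequence)}


def default_discovery_config(seed: int = 0) -> SyntheticConfig:
    """Discovery-style defaults: 42 events over 6 modalities, groups 33/64/36.

    The true sequence and per-marker covariate effect sizes are drawn
    deterministically from ``seed``.
    """
    cfg = SyntheticConfig(seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xEB]))
    cfg.true_sequence = rng.permutation(cfg.n_events)
    cfg.covariate_effects = {
        name: (
            float(rng.uniform(-0.05, 0.05)),  # age slope (per year)
            float(rng.uniform(-0.10, 0.10)),  # education slope (per year)
            float(rng.uniform(-0.50, 0.50)),  # male offset
        )
        for name in cfg.marker_names
    }
    d = cfg.effect_size
    cfg.floor_ceiling = {
        mod: (-2.5, d + 2.0) for mod in cfg.events_per_modality
    }
    return cfg


def default_recovery_config(seed: int = 0) -> SyntheticConfig:
    """Recovery-study defaults: 20 events over 6 modalities, groups 33/64/36.

    A scaled-down cascade (N = 20) with the same group structure, effect
    size and nuisance features as :func:`default_discovery_config`, sized
    for repeated fit/recover experiments on one CPU.
    """
    cfg = SyntheticConfig(
        events_per_modality={
            "clinical_cognitive": 4,
            "vision": 3,
            "retinal": 2,
            "cortical_thickness": 4,
            "substantia_nigra": 2,
            "qsm": 5,
        },
        seed=seed,
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xEB]))
    cfg.true_sequence = rng.permutation(cfg.n_events)
    cfg.covariate_effects = {
        name: (
            float(rng.uniform(-0.05, 0.05)),
            float(rng.uniform(-0.10, 0.10)),
            float(rng.uniform(-0.50, 0.50)),
        )
        for name in cfg.marker_names
    }
    cfg.floor_ceiling = {mod: (-2.5, cfg.effect_size + 2.0)
                         for mod in cfg.events_per_modality}
    return cfg


def _draw_stages(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    N = cfg.n_events
    stages = np.empty(cfg.n_controls + cfg.n_pdd_lr + cfg.n_pdd_hr, dtype=int)
    n_c = cfg.n_controls
    stages[:n_c] = np.where(
        rng.random(n_c) < cfg.control_stage0_prob, 0, 1
    )
    lr = rng.integers(0, N + 1, size=cfg.n_pdd_lr)
    hr = np.minimum(rng.integers(0, N + 1, size=cfg.n_pdd_hr) + cfg.hr_stage_offset, N)
    stages[n_c:n_c + cfg.n_pdd_lr] = lr
    stages[n_c + cfg.n_pdd_lr:] = hr
    return stages


def _truncated_normal(rng, mean, sd, lo, hi, size):
    x = rng.normal(mean, sd, size=size)
    return np.clip(x, lo, hi)


def generate_cohort(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[CohortTable, SyntheticGroundTruth]:
    """Draw a full synthetic cohort plus its ground truth.

    Reproducible: the same (config, seed) always yields the same cohort.
    ``seed`` overrides ``config.seed`` when given.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0]))
    names = config.marker_names
    N = config.n_events
    seq = (
        np.asarray(config.true_sequence, dtype=int)
        if config.true_sequence is not None
        else np.random.default_rng(np.random.SeedSequence([seed, 0xEB])).permutation(N)
    )
    if sorted(seq.tolist()) != list(range(N)):
        raise ValidationError("true_sequence must be a permutation of all events")
    position = np.empty(N, dtype=int)
    position[seq] = np.arange(1, N + 1)  # 1-based cascade position per event

    groups = ([CONTROL] * config.n_controls + [PDD_LR] * config.n_pdd_lr
              + [PDD_HR] * config.n_pdd_hr)
    J = len(groups)
    stages = _draw_stages(config, rng)

    age = np.empty(J)
    rbdsq = np.empty(J)
    onset = np.full(J, np.nan)
    for j, g in enumerate(groups):
        m, s = _AGE_PARAMS[g]
        age[j] = _truncated_normal(rng, m, s, 45.0, 85.0, None)
        rm, rs = _RBDSQ_PARAMS[g]
        hi = 4 if g == CONTROL else 13  # keep generated controls below the RBD cutoff
        rbdsq[j] = np.round(_truncated_normal(rng, rm, rs, 0, hi, None))
        if g != CONTROL:
            om, os_ = _ONSET_PARAMS[g]
            lo, hi_o = (40.0, 64.9) if g == PDD_LR else (65.0, 85.0)
            onset[j] = _truncated_normal(rng, om, os_, lo, hi_o, None)
    education = np.round(_truncated_normal(rng, 14.0, 3.0, 6.0, 22.0, J))
    gender = np.where(rng.random(J) < 0.5, "female", "male")

    effects = config.covariate_effects or {}
    bounds = config.floor_ceiling or {}
    modality = config.modality_of
    d = config.effect_size

    values = rng.normal(0.0, 1.0, size=(J, N))
    post_mask = position[None, :] <= stages[:, None]
    values += d * post_mask
    for e, name in enumerate(names):
        a_sl, e_sl, g_off = effects.get(name, (0.0, 0.0, 0.0))
        values[:, e] += (
            a_sl * (age - 60.0)
            + e_sl * (education - 14.0)
            + g_off * (gender == "male")
        )
        lo, hi = bounds.get(modality[name], (-np.inf, np.inf))
        values[:, e] = np.clip(values[:, e], lo, hi)

    flip_rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF1]))
    flipped = flip_rng.random(N) < config.flip_fraction
    values[:, flipped] *= -1.0

    if config.missingness > 0:
        values[rng.random(size=values.shape) < config.missingness] = np.nan

    df = pd.DataFrame({
        "subject_id": [f"S{j + 1:04d}" for j in range(J)],
        "group": [CONTROL if g == CONTROL else PATIENT for g in groups],
        "risk_group": groups,
        "age": np.round(age, 1),
        "gender": gender,
        "education": education,
        "age_at_onset": np.round(onset, 1),
        "rbdsq": rbdsq.astype(int),
    })
    for e, name in enumerate(names):
        df[name] = values[:, e]

    table = CohortTable(df, dict(modality))
    truth = SyntheticGroundTruth(
        true_sequence=seq, event_names=names, true_stages=stages,
        flipped=flipped, config=config,
    )
    return table, truth


def recovery_metrics(
    density: PositionalDensity,
    ml_sequence_names: list[str],
    stages: list[StageAssignment],
    truth: SyntheticGroundTruth,
) -> dict[str, float]:
    """Quantify how well a fitted model recovered the generator's truth.

    Returns Kendall tau between the fitted maximum-likelihood sequence and
    S*, staging MAE against the true stages, and BC between the fitted
    positional density and the delta density of S* (the permutation matrix
    placing each event at its true position).

    The fitted model may legitimately contain fewer events than the
    generator (screening or the disease-signal rule can drop markers);
    tau and BC are then computed over the modelled events, with the number
    of dropped events reported.  Events unknown to the generator are an
    error.
    """
    fitted_set = set(ml_sequence_names)
    if fitted_set != set(density.events):
        raise ValidationError("sequence and density cover different events")
    unknown = fitted_set - set(truth.event_names)
    if unknown:
        raise ValidationError(f"fitted events unknown to the generator: {sorted(unknown)}")
    pos_true = truth.position_of()
    fitted_pos = {name: p + 1 for p, name in enumerate(ml_sequence_names)}
    names = [n for n in truth.event_names if n in fitted_set]
    tau, tau_p = kendall_tau(
        [pos_true[n] for n in names], [fitted_pos[n] for n in names]
    )
    mae, sd, _ = staging_error(stages, truth.true_stages)
    # delta density of S*, restricted to the modelled events and positions
    # ranked within them
    true_rank = {n: r for r, n in enumerate(
        sorted(names, key=lambda n: pos_true[n])
    )}
    N = len(names)
    delta = np.zeros((N, N))
    row_of = {e: i for i, e in enumerate(density.events)}
    for name in names:
        delta[row_of[name], true_rank[name]] = 1.0
    delta_model = PositionalDensity(delta, list(density.events))
    bc = bhattacharyya_similarity(density, delta_model).bc
    return {
        "kendall_tau": tau,
        "kendall_tau_pvalue": tau_p,
        "staging_mae": mae,
        "staging_sd": sd,
        "bc_vs_truth": bc,
        "n_dropped_events": float(len(truth.event_names) - len(names)),
    }
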