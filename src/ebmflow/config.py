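"""Run configuration for the event-based modelling pipeline.

A single :class:`PipelineConfig` object carries every tunable threshold used
across the pipeline, so that a run is fully determined by (cohort CSV, config,
seed).  Defaults follow the study protocol this package implements: dementia
high-risk split at age-at-onset 65, RBDSQ control exclusion at 5, the pooled
90th-percentile control-labelling constraint, Mann-Whitney screening at
alpha = 0.05 (uncorrected), and 10 repeats of stratified 5-fold CV.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

from .errors import SchemaError, ValidationError

#: Diagnostic group labels.
CONTROL = "control"
PATIENT = "patient"

#: Risk-group labels (patients split by age at symptom onset).
PDD_LR = "PDD-LR"
PDD_HR = "PDD-HR"
UNASSIGNED = "unassigned"


@dataclass
class PipelineConfig:
    """All pipeline thresholds, sampler settings and marker declarations.

    Parameters
    ----------
    onset_threshold
        Age at symptom onset (years) at or above which a patient is labelled
        high dementia risk (PDD-HR).
    rbd_cutoff
        Controls with RBDSQ score >= this value are excluded as probable
        REM-sleep-behaviour-disorder cases.
    percentile_constraint
        Pooled quantile q above which a control observation may be labelled
        abnormal during mixture fitting (the control-labelling constraint).
    screening_alpha
        Two-sided Mann-Whitney significance level for marker screening
        (PDD-HR vs controls, uncorrected).
    modality_of
        Map marker name -> modality tag; defines the modelled marker set.
    screened_modalities
        Modalities whose markers must pass Mann-Whitney screening; all other
        markers enter the model by design.
    excluded_markers
        Markers never modelled (e.g. motor scores abnormal in all patients
        by definition).
    mixture_groups / sequence_groups
        Risk groups used to fit the per-marker mixtures and the event
        sequence respectively.  Controls are always part of the mixture fit.
    """

    onset_threshold: float = 65.0
    rbd_cutoff: int = 5
    percentile_constraint: float = 0.90
    screening_alpha: float = 0.05
    cv_folds: int = 5
    cv_repeats: int = 10
    mcmc_iterations: int = 50_000
    burn_in_fraction: float = 0.10
    greedy_restarts: int = 10
    max_em_iterations: int = 100
    em_tolerance: float = 1e-4
    density_floor: float = 1e-12
    kde_bandwidth_rule: str = "silverman"
    random_seed: int = 0
    modality_of: dict[str, str] = field(default_factory=dict)
    screened_modalities: list[str] = field(default_factory=lambda: ["qsm"])
    excluded_markers: list[str] = field(default_factory=lambda: ["updrs_total"])
    mixture_groups: list[str] = field(default_factory=lambda: [CONTROL, PDD_HR])
    sequence_groups: list[str] = field(default_factory=lambda: [PDD_LR, PDD_HR])

    def __post_init__(self) -> None:
        if not 0.0 < self.percentile_constraint < 1.0:
            raise ValidationError("percentile_constraint must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")
        if self.cv_repeats < 1:
            raise ValidationError("cv_repeats must be >= 1")
        if not 0.0 < self.screening_alpha < 1.0:
            raise ValidationError("screening_alpha must lie in (0, 1)")
        if not 0.0 <= self.burn_in_fraction < 1.0:
            raise ValidationError("burn_in_fraction must lie in [0, 1)")

    @property
    def markers(self) -> list[str]:
        """Declared modelled markers, in declaration order."""
        return [m for m in self.modality_of if m not in set(self.excluded_markers)]

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if not isinstance(payload, dict):
            raise SchemaError("config YAML must be a mapping")
        return cls.from_dict(payload)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
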