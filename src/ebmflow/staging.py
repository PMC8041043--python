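"""Maximum-likelihood patient staging within a fitted event sequence.

A subject's model stage is the number of events k in {0..N} that have most
likely occurred, given the per-event pre/post densities at the subject's
measurements.  Stage 0 means "no events yet" — the expected state of a
healthy control.  Ties break toward the lower (healthier) stage; a subject
with all markers missing has a flat likelihood and is flagged at stage 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .sequence import stage_log_likelihoods

_FLAT_TOL = 1e-12


@dataclass
class StageAssignment:
    """Per-subject maximum-likelihood stage with its log-likelihood profile."""

    subject_id: str
    stage: int
    log_likelihoods: np.ndarray  # over k = 0..N
    flat: bool = False           # True when the likelihood carried no information

    @property
    def log_likelihood(self) -> float:
        return float(self.log_likelihoods[self.stage])


def stage_posterior(p_pre_j: np.ndarray, p_post_j: np.ndarray, sequence) -> np.ndarray:
    """Unnormalised log-likelihood of each stage k = 0..N for one subject.

    Element k = sum_{i<=k} log p_post[s_i] + sum_{i>k} log p_pre[s_i].
    Missing markers must already be encoded as density 1 in both inputs.
    """
    p_pre_j = np.asarray(p_pre_j, dtype=float)
    p_post_j = np.asarray(p_post_j, dtype=float)
    if p_pre_j.shape != p_post_j.shape or p_pre_j.ndim != 1:
        raise ValidationError("per-subject densities must be equal-length vectors")
    order = np.asarray(sequence, dtype=int)
    L = stage_log_likelihoods(
        np.log(p_pre_j)[None, :], np.log(p_post_j)[None, :], order
    )
    return L[0]


def assign_stage(
    p_pre_j: np.ndarray, p_post_j: np.ndarray, sequence, subject_id: str = ""
) -> StageAssignment:
    """Assign the stage maximising the subject likelihood (ties -> lower stage)."""
    ll = stage_posterior(p_pre_j, p_post_j, sequence)
    flat = bool(np.ptp(ll) < _FLAT_TOL)
    stage = 0 if flat else int(np.argmax(ll))
    return StageAssignment(subject_id=subject_id, stage=stage,
                           log_likelihoods=ll, flat=flat)


def stage_cohort(
    p_pre: np.ndarray, p_post: np.ndarray, sequence, subject_ids=None
) -> list[StageAssignment]:
    """Stage every row of the subjects x events density matrices."""
    J = p_pre.shape[0]
    ids = subject_ids if subject_ids is not None else [str(j) for j in range(J)]
    return [
        assign_stage(p_pre[j], p_post[j], sequence, subject_id=str(ids[j]))
        for j in range(J)
    ]


def staging_error(
    stages: list[StageAssignment] | np.ndarray, gold: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """Mean absolute stage error vs a gold standard.

    Returns (MAE, SD of the absolute errors, raw signed errors).  The SD is
    the sample standard deviation (ddof = 1; 0 for a single subject).
    """
    stages = list(stages)
    if stages and isinstance(stages[0], StageAssignment):
        stages = [s.stage for s in stages]
    assigned = np.asarray(stages, dtype=float)
    gold = np.asarray(gold, dtype=float)
    if assigned.shape != gold.shape:
        raise ValidationError("stage lists must have equal length")
    raw = assigned - gold
    abs_err = np.abs(raw)
    sd = float(np.std(abs_err, ddof=1)) if len(abs_err) > 1 else 0.0
    return float(abs_err.mean()), sd, raw
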