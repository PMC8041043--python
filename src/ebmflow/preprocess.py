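"""Cohort preparation: risk groups, exclusions, covariate adjustment,
marker orientation and Mann-Whitney marker screening.

All biomarker measurements are residualised against a linear covariate model
``y ~ gender * (age + education)`` trained on controls only, so that
"abnormality" downstream means deviation from the control norm at the
subject's own age, gender and education.  Orientation then flips each marker
so that larger oriented values always mean more abnormal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import CohortTable
from .config import CONTROL, PATIENT, PDD_HR, PDD_LR
from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Columns of the confound design y ~ gender * (age + education).
DESIGN_COLUMNS = (
    "intercept", "male", "age", "education", "male:age", "male:education"
)
_N_DESIGN_COLUMNS = len(DESIGN_COLUMNS)


def _design_matrix(df: pd.DataFrame) -> np.ndarray:
    """Explicit design for y ~ gender * (age + education)."""
    male = (df["gender"] == "male").to_numpy(dtype=float)
    age = df["age"].to_numpy(dtype=float)
    edu = df["education"].to_numpy(dtype=float)
    return np.column_stack(
        [np.ones(len(df)), male, age, edu, male * age, male * edu]
    )


def assign_risk_groups(table: CohortTable, threshold: float = 65.0) -> CohortTable:
    """Split patients into dementia risk groups by age at symptom onset.

    Patients with onset at or above ``threshold`` years become PDD-HR
    (high dementia risk); younger-onset patients become PDD-LR.  Controls
    keep their ``control`` risk group.  Idempotent.
    """
    out = table.copy()
    df = out.data
    is_patient = (df["group"] == PATIENT).to_numpy()
    if "age_at_onset" not in df.columns:
        raise ValidationError("cohort lacks an age_at_onset column")
    onset = df["age_at_onset"].to_numpy(dtype=float)
    missing = is_patient & ~np.isfinite(onset)
    if missing.any():
        subjects = df.loc[missing, "subject_id"].tolist()
        raise ValidationError(f"patients lacking age_at_onset: {subjects}")
    df.loc[is_patient, "risk_group"] = np.where(
        onset[is_patient] >= threshold, PDD_HR, PDD_LR
    )
    df.loc[~is_patient, "risk_group"] = CONTROL
    return out


def exclude_rbd_controls(table: CohortTable, cutoff: int = 5) -> CohortTable:
    """Drop controls with RBDSQ >= cutoff (probable RBD, not true controls).

    Patients are never removed.  Controls with a missing RBDSQ score are
    retained with a warning.  Idempotent.
    """
    out = table.copy()
    df = out.data
    is_control = (df["group"] == CONTROL).to_numpy()
    if "rbdsq" not in df.columns:
        logger.warning("no rbdsq column; RBD control exclusion skipped")
        return out
    rbdsq = df["rbdsq"].to_numpy(dtype=float)
    missing = is_control & ~np.isfinite(rbdsq)
    if missing.any():
        logger.warning(
            "controls with missing RBDSQ retained: %s",
            df.loc[missing, "subject_id"].tolist(),
        )
    drop = is_control & np.isfinite(rbdsq) & (rbdsq >= cutoff)
    if drop.any():
        logger.info("excluding %d controls with RBDSQ >= %d", int(drop.sum()), cutoff)
    out.data = df.loc[~drop].reset_index(drop=True)
    return out


@dataclass
class CovariateModel:
    """Per-marker OLS confound model ``y ~ gender * (age + education)``.

    Fitted on control rows only; stores the coefficient vector (ordered as
    :data:`DESIGN_COLUMNS`) and the control residual scale per marker.
    """

    coefficients: dict[str, np.ndarray] = field(default_factory=dict)
    residual_scale: dict[str, float] = field(default_factory=dict)
    fitted_on_controls: bool = True

    @property
    def markers(self) -> list[str]:
        return list(self.coefficients)

    def predict(self, marker: str, covariates: pd.DataFrame) -> np.ndarray:
        return _design_matrix(covariates) @ self.coefficients[marker]


def _complete_covariates(df: pd.DataFrame) -> np.ndarray:
    return (
        df["age"].notna() & df["education"].notna() & df["gender"].notna()
    ).to_numpy()


def fit_covariate_model(table: CohortTable) -> CovariateModel:
    """Fit the control-trained confound model for every marker."""
    df = table.data
    controls = df[(df["group"] == CONTROL)]
    model = CovariateModel()
    for marker in table.markers:
        sub = controls[_complete_covariates(controls) & controls[marker].notna()]
        if len(sub) < _N_DESIGN_COLUMNS + 2:
            raise ValidationError(
                f"marker {marker!r}: only {len(sub)} complete controls; "
                f"need at least {_N_DESIGN_COLUMNS + 2}"
            )
        X = _design_matrix(sub)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValidationError(f"marker {marker!r}: rank-deficient covariate design")
        y = sub[marker].to_numpy(dtype=float)
        res = sm.OLS(y, X).fit()
        model.coefficients[marker] = np.asarray(res.params, dtype=float)
        model.residual_scale[marker] = float(np.std(res.resid, ddof=1))
    return model


def adjust_covariates(table: CohortTable, model: CovariateModel) -> CohortTable:
    """Replace every marker value by its residual from the control norm.

    Applied to controls and patients alike.  Missing marker cells stay
    missing; subjects with missing covariates get all markers set missing
    for modelling (with a warning), since no prediction is possible.
    """
    out = table.copy()
    df = out.data
    ok = _complete_covariates(df)
    if (~ok).any():
        logger.warning(
            "subjects with missing covariates; their markers set missing: %s",
            df.loc[~ok, "subject_id"].tolist(),
        )
    covs = df.loc[ok, ["age", "gender", "education"]]
    for marker in model.markers:
        if marker not in df.columns:
            continue
        pred = model.predict(marker, covs)
        vals = df[marker].to_numpy(dtype=float)
        adjusted = np.full(len(df), np.nan)
        adjusted[ok] = vals[ok] - pred
        df[marker] = adjusted
    return out


@dataclass
class MarkerOrientation:
    """Map marker -> sign in {+1, -1}; sign * value increases with disease."""

    sign: dict[str, int] = field(default_factory=dict)

    def oriented(self, table: CohortTable, markers: list[str]) -> np.ndarray:
        """Oriented marker matrix (subjects x markers), NaN preserved."""
        mat = table.marker_matrix(markers)
        signs = np.array([self.sign[m] for m in markers], dtype=float)
        return mat * signs


def orient_markers(table: CohortTable, markers: list[str] | None = None) -> MarkerOrientation:
    """Determine, per marker, the direction of abnormality.

    sign = +1 when the patient mean exceeds the control mean (marker rises
    with disease), else -1; ties break to +1.  Requires >= 3 non-missing
    values in each group.
    """
    markers = markers if markers is not None else table.markers
    df = table.data
    is_control = (df["group"] == CONTROL).to_numpy()
    orientation = MarkerOrientation()
    for marker in markers:
        vals = df[marker].to_numpy(dtype=float)
        c = vals[is_control & np.isfinite(vals)]
        p = vals[~is_control & np.isfinite(vals)]
        if len(c) < 3 or len(p) < 3:
            raise ValidationError(
                f"marker {marker!r}: need >=3 non-missing controls and patients"
            )
        orientation.sign[marker] = 1 if p.mean() >= c.mean() else -1
    return orientation


def screen_markers_mannwhitney(
    table: CohortTable,
    marker_subset: list[str],
    alpha: float = 0.05,
) -> list[str]:
    """Retain markers separating PDD-HR from controls (two-sided MW-U, uncorrected).

    Exact null distribution when the combined sample is <= 20 without ties;
    normal approximation with midrank tie correction otherwise.  Markers with
    fewer than 2 values in either group are dropped with a warning.
    """
    df = table.data
    is_control = (df["group"] == CONTROL).to_numpy()
    is_hr = (df["risk_group"] == PDD_HR).to_numpy()
    retained = []
    for marker in marker_subset:
        vals = df[marker].to_numpy(dtype=float)
        hr = vals[is_hr & np.isfinite(vals)]
        ctl = vals[is_control & np.isfinite(vals)]
        if len(hr) < 2 or len(ctl) < 2:
            logger.warning("marker %r: group too small for screening; dropped", marker)
            continue
        pooled = np.concatenate([hr, ctl])
        has_ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(hr, ctl, alternative="two-sided", method=method)
        if res.pvalue < alpha:
            retained.append(marker)
    return retained
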