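"""Cohort table container and CSV I/O.

The cohort is a wide table: one row per subject, one column per biomarker,
plus covariates (age, gender, education), diagnostic group, risk group,
age at symptom onset and RBDSQ score.  Missing marker measurements are NaN
internally and blank cells on disk — distinguishable from zero throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CONTROL, PATIENT, PDD_HR, PDD_LR, UNASSIGNED, PipelineConfig
from .errors import ParseError, SchemaError, ValidationError

#: Non-marker columns expected in every cohort CSV.
MANDATORY_COLUMNS = ("subject_id", "group", "age", "gender", "education")
OPTIONAL_COLUMNS = ("risk_group", "age_at_onset", "rbdsq")

VALID_GROUPS = frozenset({CONTROL, PATIENT})
VALID_RISK_GROUPS = frozenset({CONTROL, PDD_LR, PDD_HR, UNASSIGNED})
VALID_GENDERS = frozenset({"female", "male"})


@dataclass
class CohortTable:
    """Subjects x markers measurements with covariates and group labels.

    ``data`` holds one row per subject; ``modality_of`` maps each modelled
    marker column to its modality tag.  Invariants are enforced at
    construction: unique subject ids, valid group labels, every marker in
    ``modality_of`` present as a numeric column.
    """

    data: pd.DataFrame
    modality_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data
        for col in MANDATORY_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"cohort table lacks mandatory column {col!r}")
        if df["subject_id"].duplicated().any():
            dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
            raise ValidationError(f"duplicate subject_id values: {dupes}")
        bad_groups = set(df["group"]) - VALID_GROUPS
        if bad_groups:
            raise ValidationError(f"invalid group labels: {sorted(bad_groups)}")
        if "risk_group" not in df.columns:
            df = df.copy()
            df["risk_group"] = np.where(df["group"] == CONTROL, CONTROL, UNASSIGNED)
            self.data = df
        bad_risk = set(df["risk_group"]) - VALID_RISK_GROUPS
        if bad_risk:
            raise ValidationError(f"invalid risk_group labels: {sorted(bad_risk)}")
        bad_gender = set(df["gender"].dropna()) - VALID_GENDERS
        if bad_gender:
            raise ValidationError(f"invalid gender labels: {sorted(bad_gender)}")
        if (df["age"].dropna() <= 0).any():
            raise ValidationError("age must be positive")
        if (df["education"].dropna() < 0).any():
            raise ValidationError("education must be non-negative")
        if "rbdsq" in df.columns and (df["rbdsq"].dropna() < 0).any():
            raise ValidationError("rbdsq must be non-negative")
        missing_cols = [m for m in self.modality_of if m not in df.columns]
        if missing_cols:
            raise SchemaError(f"markers declared but absent from table: {missing_cols}")

    @property
    def markers(self) -> list[str]:
        return list(self.modality_of)

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def is_control(self) -> np.ndarray:
        return (self.data["group"] == CONTROL).to_numpy()

    def marker_matrix(self, markers: list[str] | None = None) -> np.ndarray:
        """Float matrix (subjects x markers); missing values are NaN."""
        cols = markers if markers is not None else self.markers
        return self.data[cols].to_numpy(dtype=float)

    def copy(self) -> "CohortTable":
        return CohortTable(self.data.copy(), dict(self.modality_of))


def read_cohort_table(path: str, config: PipelineConfig) -> CohortTable:
    """Read and validate a wide cohort CSV.

    Blank marker cells become NaN (missing); marker columns are coerced to
    float with a :class:`ParseError` naming the first offending row/column.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "group": str})
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"cohort CSV lacks mandatory column {col!r}")
    declared = [m for m in config.modality_of if m != ""]
    absent = [m for m in declared if m not in df.columns]
    if absent:
        raise SchemaError(f"declared marker columns missing from CSV: {absent}")
    for col in declared + ["age", "education", "age_at_onset", "rbdsq"]:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col!r}, row {row}"
            )
        df[col] = coerced
    modality_of = {m: config.modality_of[m] for m in declared}
    return CohortTable(df, modality_of)


def write_cohort_table(table: CohortTable, path: str) -> None:
    """Write the cohort back to CSV; NaN marker cells become blank."""
    table.data.to_csv(path, index=False, float_format="%.12g")
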