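"""Core data model: per-subject morphometry and cohort tables.

A cohort is represented in two equivalent ways:

* a list of :class:`SubjectMorphometry` records (validated, explicit), or
* a :class:`pandas.DataFrame` with one row per subject and the canonical
  columns ``subject_id, age, sex, icv`` plus one column per analysis ROI
  and the optional clinical columns ``pta_weeks``,
  ``time_since_injury_months`` and ``group_label``.

All volumes are mm³, ages in years, posttraumatic-amnesia (PTA) duration in
integer weeks, time since injury in months.  Sex is dummy-coded male = 1,
female = 0, which lets sex-stratified regressions be fused into a single
equation.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .exceptions import CohortValidationError
from .rois import RoiId

#: Accepted spellings for the sex column, normalised to the 0/1 dummy code.
SEX_TOKENS = {
    "m": 1, "male": 1, "1": 1,
    "f": 0, "female": 0, "0": 0,
}

#: Canonical cohort-table columns, in write order.
CANONICAL_COLUMNS = (
    "subject_id", "age", "sex", "icv",
    "whole_brainstem", "medulla", "pons", "midbrain", "cerebrum",
    "pta_weeks", "time_since_injury_months", "group_label",
)

#: Accepted aliases for canonical column names (lower-cased match).
COLUMN_ALIASES = {
    "id": "subject_id",
    "subject": "subject_id",
    "etiv": "icv",
    "estimatedtotalintracranialvol": "icv",
    "pta": "pta_weeks",
    "tsi": "time_since_injury_months",
    "time_since_injury": "time_since_injury_months",
    "group": "group_label",
}


def normalize_sex(token) -> int:
    """Map a sex token (``M``/``F``/``male``/``female``/``0``/``1``) to the
    0/1 dummy code (male = 1, female = 0)."""
    key = str(token).strip().lower()
    if key not in SEX_TOKENS:
        raise CohortValidationError(f"unknown sex token {token!r}", column="sex")
    return SEX_TOKENS[key]


class SubjectMorphometry(BaseModel):
    """One subject's demographics, intracranial volume and ROI volumes.

    ``volumes`` maps :class:`~enhv.rois.RoiId` to mm³ and may contain both
    analysis and parse-only ROIs.  Invariants: ``icv > 0``; every volume is
    positive and strictly smaller than the ICV; ``sex`` is 0 or 1.
    """

    model_config = ConfigDict(frozen=False)

    subject_id: str
    age: float
    sex: int
    icv: float
    volumes: dict[RoiId, float] = {}
    pta_weeks: Optional[int] = None
    time_since_injury_months: Optional[float] = None
    group_label: Optional[str] = None

    @field_validator("age", "icv")
    @classmethod
    def _positive(cls, v, info):
        if not v > 0:
            raise ValueError(f"{info.field_name} must be positive, got {v}")
        return v

    @field_validator("sex")
    @classmethod
    def _sex_binary(cls, v):
        if v not in (0, 1):
            raise ValueError(f"sex must be 0 (female) or 1 (male), got {v}")
        return v

    @field_validator("pta_weeks")
    @classmethod
    def _pta_positive(cls, v):
        if v is not None and v < 1:
            raise ValueError(f"pta_weeks must be a positive integer, got {v}")
        return v

    @field_validator("group_label")
    @classmethod
    def _group_known(cls, v):
        if v is not None and v not in ("healthy", "dai"):
            raise ValueError(f"group_label must be 'healthy' or 'dai', got {v!r}")
        return v

    @model_validator(mode="after")
    def _volumes_physiologic(self):
        for roi, vol in self.volumes.items():
            if not vol > 0:
                raise ValueError(f"volume of {roi} must be positive, got {vol}")
            if not vol < self.icv:
                raise ValueError(
                    f"volume of {roi} ({vol}) must be smaller than ICV ({self.icv})"
                )
        return self


def subjects_to_frame(subjects: list[SubjectMorphometry]) -> pd.DataFrame:
    """Convert a list of subjects to the canonical cohort DataFrame."""
    rows = []
    for s in subjects:
        row = {
            "subject_id": s.subject_id,
            "age": s.age,
            "sex": s.sex,
            "icv": s.icv,
            "pta_weeks": s.pta_weeks,
            "time_since_injury_months": s.time_since_injury_months,
            "group_label": s.group_label,
        }
        for roi, vol in s.volumes.items():
            row[str(roi)] = vol
        rows.append(row)
    frame = pd.DataFrame(rows)
    ordered = [c for c in CANONICAL_COLUMNS if c in frame.columns]
    extra = [c for c in frame.columns if c not in ordered]
    return frame[ordered + extra]


def frame_to_subjects(frame: pd.DataFrame) -> list[SubjectMorphometry]:
    """Convert a canonical cohort DataFrame back to subject records."""
    subjects = []
    roi_cols = [r for r in RoiId if str(r) in frame.columns]
    for _, row in frame.iterrows():
        volumes = {
            roi: float(row[str(roi)])
            for roi in roi_cols
            if pd.notna(row[str(roi)])
        }
        pta = row.get("pta_weeks")
        tsi = row.get("time_since_injury_months")
        grp = row.get("group_label")
        subjects.append(
            SubjectMorphometry(
                subject_id=str(row["subject_id"]),
                age=float(row["age"]),
                sex=int(row["sex"]),
                icv=float(row["icv"]),
                volumes=volumes,
                pta_weeks=None if pd.isna(pta) else int(pta),
                time_since_injury_months=None if pd.isna(tsi) else float(tsi),
                group_label=None if grp is None or pd.isna(grp) else str(grp),
            )
        )
    return subjects


def require_columns(frame: pd.DataFrame, columns) -> None:
    """Raise :class:`CohortValidationError` if any column is absent."""
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise CohortValidationError(f"cohort table missing columns: {missing}")
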