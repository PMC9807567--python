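"""Readers and writers for FreeSurfer volumetric output and cohort tables.

The toolkit consumes two FreeSurfer text products per subject:

* ``aseg.stats`` — the subcortical segmentation summary written by
  ``recon-all``.  Its ``# Measure`` header lines carry the estimated total
  intracranial volume (eTIV) and the three cerebral tissue totals used to
  compose the cerebrum ROI.
* ``brainstemSsVolumes.v10.txt`` — the two-column (structure, mm³) table
  written by the brainstem-subfield segmentation pipeline.

Cohort tables are comma-separated UTF-8 text with '.' decimals, one header
row, and the canonical columns of :mod:`enhv.data`.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd

from .data import (
    CANONICAL_COLUMNS,
    COLUMN_ALIASES,
    SubjectMorphometry,
    normalize_sex,
    subjects_to_frame,
)
from .exceptions import CohortValidationError, EnhvError, FreeSurferParseError
from .rois import ANALYSIS_ROIS, RoiId

# aseg.stats "# Measure" keys -> parse-level fields. Keys are matched
# case-sensitively against FreeSurfer's canonical measure names (the first
# field after "# Measure").
ASEG_MEASURES = {
    "EstimatedTotalIntraCranialVol": "icv",
    "Cortex": RoiId.cortical_gm,
    "CerebralWhiteMatter": RoiId.cerebral_wm,
    "SubCortGray": RoiId.subcortical_gm,
}

# brainstemSsVolumes.v10.txt structure rows -> ROIs.
BRAINSTEM_ROWS = {
    "Medulla": RoiId.medulla,
    "Pons": RoiId.pons,
    "Midbrain": RoiId.midbrain,
    "SCP": RoiId.scp,
    "Whole_brainstem": RoiId.whole_brainstem,
}


def _split_measure_line(body: str) -> list[str]:
    """Split the payload of a '# Measure' line.

    FreeSurfer writes comma-separated fields; some post-processed variants
    use plain whitespace.  Both are accepted.
    """
    if "," in body:
        return [f.strip() for f in body.split(",")]
    return body.split()


def parse_aseg_stats(path) -> dict:
    """Parse an ``aseg.stats`` file.

    Returns a dict with key ``"icv"`` (mm³) and one key per cerebral tissue
    ROI (:attr:`RoiId.cortical_gm`, :attr:`RoiId.cerebral_wm`,
    :attr:`RoiId.subcortical_gm`).  The segmentation table below the header
    is not needed and is ignored.

    Raises
    ------
    FreeSurferParseError
        If a required measure line is absent (the error names the missing
        measure) or a measure value is non-numeric (the error carries the
        1-based line number).
    """
    path = Path(path)
    found: dict = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("#"):
                continue
            body = line.lstrip("#").strip()
            if not body.startswith("Measure"):
                continue
            fields = _split_measure_line(body[len("Measure"):].strip())
            if not fields:
                continue
            key = fields[0]
            if key not in ASEG_MEASURES:
                continue
            # value is the last numeric-looking field (unit trails it)
            value = None
            for token in reversed(fields):
                try:
                    value = float(token)
                    break
                except ValueError:
                    continue
            if value is None:
                raise FreeSurferParseError(
                    f"non-numeric value for measure {key!r} at line {lineno} of {path}",
                    path=path, line=lineno,
                )
            found[ASEG_MEASURES[key]] = value
    missing = [k for k, v in ASEG_MEASURES.items() if v not in found]
    if missing:
        raise FreeSurferParseError(
            f"{path}: missing required measure line(s): {', '.join(missing)}",
            path=path, missing=missing,
        )
    return found


def parse_brainstem_volumes(path) -> dict[RoiId, float]:
    """Parse a ``brainstemSsVolumes.v10.txt`` file.

    Returns a map with the medulla, pons, midbrain, SCP and whole-brainstem
    volumes in mm³.  The SCP is returned for completeness but is *not* an
    analysis ROI (see :mod:`enhv.rois`).

    Raises
    ------
    FreeSurferParseError
        If a structure row is missing (named in the error) or a volume is
        non-numeric.
    """
    path = Path(path)
    found: dict[RoiId, float] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) < 2 or parts[0] not in BRAINSTEM_ROWS:
                continue
            try:
                value = float(parts[1])
            except ValueError:
                raise FreeSurferParseError(
                    f"non-numeric volume for {parts[0]!r} at line {lineno} of {path}",
                    path=path, line=lineno,
                ) from None
            found[BRAINSTEM_ROWS[parts[0]]] = value
    missing = [name for name, roi in BRAINSTEM_ROWS.items() if roi not in found]
    if missing:
        raise FreeSurferParseError(
            f"{path}: missing structure row(s): {', '.join(missing)}",
            path=path, missing=missing,
        )
    return found


def compose_cerebrum(cortical_gm: float, cerebral_wm: float, subcortical_gm: float) -> float:
    """Cerebrum volume: cortical gray + cerebral white + subcortical gray.

    The cerebrum ROI is defined as the sum of the three ``aseg.stats``
    summary measures (thalamus through amygdala included via the
    subcortical-gray total; cerebellum and brainstem excluded).
    """
    for name, v in (("cortical_gm", cortical_gm),
                    ("cerebral_wm", cerebral_wm),
                    ("subcortical_gm", subcortical_gm)):
        if not v > 0:
            raise EnhvError(f"{name} must be positive, got {v}")
    return cortical_gm + cerebral_wm + subcortical_gm


def read_subject_dir(directory, subject_id=None, age=None, sex=None, **extra) -> SubjectMorphometry:
    """Read one subject's ``aseg.stats`` + ``brainstemSsVolumes.v10.txt``
    from ``directory`` and assemble a :class:`SubjectMorphometry`.

    Demographics are not stored in the FreeSurfer files and must be
    supplied by the caller.
    """
    directory = Path(directory)
    aseg = parse_aseg_stats(directory / "aseg.stats")
    stem = parse_brainstem_volumes(directory / "brainstemSsVolumes.v10.txt")
    volumes = dict(stem)
    volumes[RoiId.cortical_gm] = aseg[RoiId.cortical_gm]
    volumes[RoiId.cerebral_wm] = aseg[RoiId.cerebral_wm]
    volumes[RoiId.subcortical_gm] = aseg[RoiId.subcortical_gm]
    volumes[RoiId.cerebrum] = compose_cerebrum(
        aseg[RoiId.cortical_gm], aseg[RoiId.cerebral_wm], aseg[RoiId.subcortical_gm]
    )
    return SubjectMorphometry(
        subject_id=subject_id or directory.name,
        age=age, sex=sex, icv=aseg["icv"], volumes=volumes, **extra,
    )


def _canonicalize_columns(frame: pd.DataFrame) -> pd.DataFrame:
    renames = {}
    for col in frame.columns:
        key = col.strip().lower()
        if key in COLUMN_ALIASES:
            renames[col] = COLUMN_ALIASES[key]
        elif key != col:
            renames[col] = key
    return frame.rename(columns=renames)


def read_cohort_table(path) -> list[SubjectMorphometry]:
    """Read a cohort CSV into validated subject records.

    Required columns: ``subject_id, age, sex, icv`` and the five analysis
    ROIs.  Sex accepts M/F/male/female/0/1 and is normalised to the 0/1
    dummy code.  Raises :class:`CohortValidationError` (with the 1-based
    data-row number) on duplicate subject ids, volumes ≥ ICV, or unknown
    sex tokens.
    """
    frame = pd.read_csv(path, dtype={"subject_id": str})
    frame = _canonicalize_columns(frame)
    required = ["subject_id", "age", "sex", "icv"] + [str(r) for r in ANALYSIS_ROIS]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise CohortValidationError(f"{path}: missing columns {missing}")

    seen: set[str] = set()
    subjects = []
    for i, (_, row) in enumerate(frame.iterrows(), start=1):
        sid = str(row["subject_id"])
        if sid in seen:
            raise CohortValidationError(f"duplicate subject_id {sid!r} at row {i}", row=i)
        seen.add(sid)
        try:
            sex = normalize_sex(row["sex"])
        except CohortValidationError as err:
            raise CohortValidationError(f"row {i}: {err}", row=i, column="sex") from None
        volumes = {}
        for roi in RoiId:
            col = str(roi)
            if col in frame.columns and pd.notna(row[col]):
                volumes[roi] = float(row[col])
        pta = row.get("pta_weeks")
        tsi = row.get("time_since_injury_months")
        grp = row.get("group_label")
        try:
            subjects.append(
                SubjectMorphometry(
                    subject_id=sid,
                    age=float(row["age"]),
                    sex=sex,
                    icv=float(row["icv"]),
                    volumes=volumes,
                    pta_weeks=None if pta is None or pd.isna(pta) else int(pta),
                    time_since_injury_months=None if tsi is None or pd.isna(tsi) else float(tsi),
                    group_label=None if grp is None or pd.isna(grp) else str(grp),
                )
            )
        except ValueError as err:
            raise CohortValidationError(f"row {i}: {err}", row=i) from None
    return subjects


def write_cohort_table(subjects: list[SubjectMorphometry], path) -> None:
    """Write subjects to a canonical cohort CSV.

    Floats are written with :func:`repr` precision so that
    ``read_cohort_table(write_cohort_table(s)) == s`` field-for-field.
    """
    frame = subjects_to_frame(subjects)
    # drop parse-only columns that are entirely absent
    frame = frame.dropna(axis=1, how="all")
    frame.to_csv(path, index=False, float_format=None)


def ingest_subjects_dir(subjects_dir, demographics: pd.DataFrame) -> list[SubjectMorphometry]:
    """Collect per-subject FreeSurfer stats files under ``subjects_dir``.

    ``demographics`` must carry ``subject_id, age, sex`` (and optionally
    clinical columns); each subject's files are expected at
    ``subjects_dir/<subject_id>/``.
    """
    demographics = _canonicalize_columns(demographics)
    subjects = []
    for _, row in demographics.iterrows():
        sid = str(row["subject_id"])
        extra = {}
        for col in ("pta_weeks", "time_since_injury_months", "group_label"):
            if col in demographics.columns and pd.notna(row[col]):
                extra[col] = row[col]
        subjects.append(
            read_subject_dir(
                os.path.join(subjects_dir, sid),
                subject_id=sid,
                age=float(row["age"]),
                sex=normalize_sex(row["sex"]),
                **extra,
            )
        )
    return subjects
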