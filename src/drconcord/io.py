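"""CSV ingestion and validation for the tidy grading file dialects.

Three input files drive an analysis:

* ``grades.csv`` — one row per (patient, eye, grader):
  ``patient_id,laterality,grader_id,grade,n_images`` with ``grade`` in 0-4 or
  the token ``NA`` for an ungradable (insufficient-quality) decision;
* ``ai.csv`` — one row per patient: ``patient_id,ai_grade`` with ``ai_grade``
  in 0-3 or ``NA``;
* ``adjudications.csv`` (optional) — eye-level final grades from an
  adjudication round: ``patient_id,laterality,final_grade`` (0-4, never NA).

The contract is strict: every patient appearing in ``grades.csv`` must have a
row in ``ai.csv`` and vice versa (an automated grader that failed on quality
is recorded as ``NA``, not omitted); duplicated keys are rejected with the
offending key named.  Loaders report schema violations with the 1-based data
row and column name.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

import pandas as pd

from .grades import (
    LATERALITIES,
    UNGRADABLE,
    EyeAssessment,
    GradeError,
    PatientRecord,
    format_grade,
    parse_grade,
)

__all__ = [
    "SchemaError",
    "load_grades",
    "load_ai",
    "load_adjudications",
    "records_from_frames",
    "adjudication_lookup_from_frame",
    "write_worklist",
    "run_analysis",
]

GRADES_COLUMNS = ["patient_id", "laterality", "grader_id", "grade", "n_images"]
AI_COLUMNS = ["patient_id", "ai_grade"]
ADJUDICATION_COLUMNS = ["patient_id", "laterality", "final_grade"]


class SchemaError(ValueError):
    """An input file violates the expected schema."""


def _read_raw(path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != columns:
        raise SchemaError(
            f"{path.name}: header must be {','.join(columns)}, got {','.join(df.columns)}"
        )
    return df


def _fail(path, row: int, column: str, message: str) -> None:
    raise SchemaError(f"{Path(path).name}, data row {row}, column {column!r}: {message}")


def load_grades(path) -> pd.DataFrame:
    """Load and validate a grades.csv into a tidy DataFrame.

    Returns columns ``patient_id, laterality, grader_id, grade, n_images``
    with ``grade`` as a nullable integer (``pd.NA`` = ungradable).
    """
    raw = _read_raw(path, GRADES_COLUMNS)
    grades: list = []
    n_images: list[int] = []
    for i, row in enumerate(raw.itertuples(index=False), start=1):
        if not row.patient_id:
            _fail(path, i, "patient_id", "empty patient id")
        if row.laterality not in LATERALITIES:
            _fail(path, i, "laterality", f"must be one of {LATERALITIES}, got {row.laterality!r}")
        if not row.grader_id:
            _fail(path, i, "grader_id", "empty grader id")
        try:
            g = parse_grade(row.grade, k=5)
        except GradeError as exc:
            _fail(path, i, "grade", str(exc))
        grades.append(pd.NA if g is UNGRADABLE else int(g))
        try:
            n = int(row.n_images)
        except ValueError:
            n = 0
        if n < 1:
            _fail(path, i, "n_images", f"must be a positive integer, got {row.n_images!r}")
        n_images.append(n)
    dup = raw.duplicated(subset=["patient_id", "laterality", "grader_id"])
    if dup.any():
        first = raw[dup].iloc[0]
        raise SchemaError(
            f"{Path(path).name}: duplicate assessment for key "
            f"({first.patient_id!r}, {first.laterality!r}, {first.grader_id!r})"
        )
    out = raw[["patient_id", "laterality", "grader_id"]].copy()
    out["grade"] = pd.array(grades, dtype="Int64")
    out["n_images"] = pd.array(n_images, dtype="int64")
    return out


def load_ai(path) -> pd.DataFrame:
    """Load and validate an ai.csv (patient-level automated 4-point grades)."""
    raw = _read_raw(path, AI_COLUMNS)
    grades: list = []
    for i, row in enumerate(raw.itertuples(index=False), start=1):
        if not row.patient_id:
            _fail(path, i, "patient_id", "empty patient id")
        try:
            g = parse_grade(row.ai_grade, k=4)
        except GradeError as exc:
            _fail(path, i, "ai_grade", str(exc))
        grades.append(pd.NA if g is UNGRADABLE else int(g))
    dup = raw.duplicated(subset=["patient_id"])
    if dup.any():
        raise SchemaError(
            f"{Path(path).name}: duplicate patient {raw[dup].iloc[0].patient_id!r}"
        )
    out = raw[["patient_id"]].copy()
    out["ai_grade"] = pd.array(grades, dtype="Int64")
    return out


def load_adjudications(path) -> pd.DataFrame:
    """Load and validate an adjudications.csv (eye-level final grades, 0-4)."""
    raw = _read_raw(path, ADJUDICATION_COLUMNS)
    finals: list[int] = []
    for i, row in enumerate(raw.itertuples(index=False), start=1):
        if not row.patient_id:
            _fail(path, i, "patient_id", "empty patient id")
        if row.laterality not in LATERALITIES:
            _fail(path, i, "laterality", f"must be one of {LATERALITIES}, got {row.laterality!r}")
        try:
            g = parse_grade(row.final_grade, k=5)
        except GradeError as exc:
            _fail(path, i, "final_grade", str(exc))
        if g is UNGRADABLE:
            _fail(path, i, "final_grade", "adjudicated final grade cannot be NA")
        finals.append(int(g))
    dup = raw.duplicated(subset=["patient_id", "laterality"])
    if dup.any():
        first = raw[dup].iloc[0]
        raise SchemaError(
            f"{Path(path).name}: duplicate adjudication for "
            f"({first.patient_id!r}, {first.laterality!r})"
        )
    out = raw[["patient_id", "laterality"]].copy()
    out["final_grade"] = pd.array(finals, dtype="int64")
    return out


def records_from_frames(grades: pd.DataFrame, ai: pd.DataFrame) -> list[PatientRecord]:
    """Assemble validated DataFrames into PatientRecord objects, sorted by patient id.

    Every patient must appear in both frames; ``pd.NA`` grades become the
    UNGRADABLE token.
    """
    ai_map: dict[str, object] = {}
    for row in ai.itertuples(index=False):
        ai_map[str(row.patient_id)] = (
            UNGRADABLE if pd.isna(row.ai_grade) else int(row.ai_grade)
        )
    assessments: dict[str, list[EyeAssessment]] = {}
    for row in grades.itertuples(index=False):
        pid = str(row.patient_id)
        grade = UNGRADABLE if pd.isna(row.grade) else int(row.grade)
        assessments.setdefault(pid, []).append(
            EyeAssessment(
                patient_id=pid,
                laterality=str(row.laterality),
                grader_id=str(row.grader_id),
                grade=grade,
                n_images=int(row.n_images),
            )
        )
    missing_ai = sorted(set(assessments) - set(ai_map))
    if missing_ai:
        raise SchemaError(f"patients with grades but no automated-grade row: {missing_ai[:5]}")
    missing_grades = sorted(set(ai_map) - set(assessments))
    if missing_grades:
        raise SchemaError(f"patients with an automated grade but no eye grades: {missing_grades[:5]}")
    return [
        PatientRecord(patient_id=pid, eye_assessments=tuple(assessments[pid]), ai_grade=ai_map[pid])
        for pid in sorted(assessments)
    ]


def adjudication_lookup_from_frame(
    adjudications: pd.DataFrame | None,
) -> dict[tuple[str, str], int]:
    """Turn an adjudications DataFrame into the (patient_id, laterality) -> grade lookup."""
    if adjudications is None:
        return {}
    return {
        (str(row.patient_id), str(row.laterality)): int(row.final_grade)
        for row in adjudications.itertuples(index=False)
    }


def write_worklist(
    worklist: Iterable[tuple[str, str, tuple[int, ...]]], path
) -> Path:
    """Write unresolved discordant eyes as an adjudication worklist CSV."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "laterality", "grade_1", "grade_2", "grade_3"])
        for patient_id, laterality, grades in worklist:
            writer.writerow([patient_id, laterality, *[format_grade(g) for g in grades]])
    return path


def run_analysis(
    grades: pd.DataFrame,
    ai: pd.DataFrame,
    adjudications: pd.DataFrame | None = None,
    rdr_cutoff: int = 2,
    kappa_weighting: str = "none",
):
    """Run the full concordance pipeline and return the StudyReport.

    Thin functional wrapper over :class:`drconcord.model.GradingConcordance`.
    """
    from .model import GradingConcordance

    model = GradingConcordance(
        grades, ai, adjudications, rdr_cutoff=rdr_cutoff, kappa_weighting=kappa_weighting
    )
    return model.fit().report
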