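"""Ordinal diabetic-retinopathy severity grades and the deterministic transforms between them.

The package works with two ordinal severity scales:

* the 5-point ICDR scale used by human graders reading individual eyes
  (0 = no DR, 1 = mild, 2 = moderate, 3 = severe non-proliferative,
  4 = proliferative), and
* a compressed 4-point scale matching the output granularity of automated
  patient-level screening software, where the two most severe ICDR levels are
  merged into a single "sight-threatening DR" category
  (0 = no DR, 1 = mild, 2 = moderate, 3 = sight-threatening).

Grades are plain 0-based integers everywhere; the name <-> integer mapping is
defined once here (:data:`GRADE5_NAMES`, :data:`GRADE4_NAMES`).  An eye or
patient whose images were of insufficient quality for a grading decision
carries the distinguished token :data:`UNGRADABLE`.  UNGRADABLE is a quality
outcome, not a missing value: a grader who never assessed an eye is simply
absent from the dataset, while a grader who looked and declined to grade is
recorded as UNGRADABLE.  In CSV files UNGRADABLE is serialized as the literal
token ``NA``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Union

__all__ = [
    "UNGRADABLE",
    "Grade",
    "GradeError",
    "NoGradableEyeError",
    "GRADE5_LEVELS",
    "GRADE4_LEVELS",
    "GRADE5_NAMES",
    "GRADE4_NAMES",
    "RDR_CUTOFF",
    "is_ungradable",
    "validate_grade",
    "parse_grade",
    "format_grade",
    "compress_5_to_4",
    "patient_grade",
    "binarize_rdr",
    "EyeAssessment",
    "PatientRecord",
    "LATERALITIES",
]


class GradeError(ValueError):
    """An invalid severity grade or an UNGRADABLE grade where one is not allowed."""


class NoGradableEyeError(GradeError):
    """Patient-level aggregation was attempted with no gradable eye."""


class _Ungradable:
    """Singleton sentinel for a quality failure ("ungradable") grading outcome."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "UNGRADABLE"

    def __reduce__(self):
        return (_Ungradable, ())


#: The distinguished "insufficient image quality" grading outcome.
UNGRADABLE = _Ungradable()

#: A severity grade: an integer level or the UNGRADABLE token.
Grade = Union[int, _Ungradable]

GRADE5_LEVELS: tuple[int, ...] = (0, 1, 2, 3, 4)
GRADE4_LEVELS: tuple[int, ...] = (0, 1, 2, 3)

GRADE5_NAMES: dict[int, str] = {
    0: "no DR",
    1: "mild DR",
    2: "moderate DR",
    3: "severe non-proliferative DR",
    4: "proliferative DR",
}
GRADE4_NAMES: dict[int, str] = {
    0: "no DR",
    1: "mild DR",
    2: "moderate DR",
    3: "sight-threatening DR",
}

#: Referable-DR threshold: moderate DR and above is referable, on either scale.
RDR_CUTOFF: int = 2

#: Valid eye lateralities (OD = right eye, OS = left eye).
LATERALITIES: tuple[str, str] = ("OD", "OS")


def is_ungradable(grade: Grade) -> bool:
    """Return True if ``grade`` is the UNGRADABLE token."""
    return grade is UNGRADABLE


def validate_grade(grade: Grade, k: int = 5, allow_ungradable: bool = True) -> Grade:
    """Validate a grade on a ``k``-point scale and return it.

    Raises :class:`GradeError` for anything that is not an integer in
    ``0..k-1`` or (when allowed) the UNGRADABLE token.  Booleans are rejected
    even though they subclass int.
    """
    if grade is UNGRADABLE:
        if not allow_ungradable:
            raise GradeError("UNGRADABLE grade not allowed here")
        return grade
    if isinstance(grade, bool):
        raise GradeError(f"not a severity grade: {grade!r}")
    if not isinstance(grade, int):
        # numpy integer scalars are accepted via their __index__ protocol
        try:
            grade = int(grade.__index__())  # type: ignore[union-attr]
        except (AttributeError, TypeError):
            raise GradeError(f"not a severity grade: {grade!r}") from None
    if not 0 <= grade < k:
        raise GradeError(f"grade {grade!r} outside the {k}-point scale 0..{k - 1}")
    return int(grade)


def parse_grade(token: str, k: int = 5) -> Grade:
    """Parse a serialized grade token: ``"0"``..``str(k-1)`` or ``"NA"``."""
    token = token.strip()
    if token == "NA":
        return UNGRADABLE
    try:
        value = int(token)
    except ValueError:
        raise GradeError(f"unknown grade token {token!r}") from None
    return validate_grade(value, k=k)


def format_grade(grade: Grade) -> str:
    """Serialize a grade to its CSV token (``"NA"`` for UNGRADABLE)."""
    return "NA" if grade is UNGRADABLE else str(int(grade))


def compress_5_to_4(grade: Grade) -> Grade:
    """Compress a 5-point ICDR grade to the 4-point patient-level scale.

    Severe non-proliferative (3) and proliferative (4) DR are merged into the
    single top category "sight-threatening DR" (3); lower levels map to
    themselves.  UNGRADABLE passes through unchanged.  The map is total,
    monotone and surjective onto {0, 1, 2, 3}.
    """
    if grade is UNGRADABLE:
        return UNGRADABLE
    grade = validate_grade(grade, k=5)
    return min(grade, 3)


def patient_grade(eye_grades: Iterable[Grade], k: int = 5) -> int:
    """Aggregate one grader's per-eye grades into a single patient-level grade.

    The patient grade is the *highest* severity among the gradable eyes (e.g.
    a right eye graded 4 and a left eye graded 2 give a patient grade of 4).
    UNGRADABLE eyes are ignored; if every supplied eye is UNGRADABLE (or the
    collection is empty) a :class:`NoGradableEyeError` is raised.
    """
    gradable = [validate_grade(g, k=k) for g in eye_grades if g is not UNGRADABLE]
    if not gradable:
        raise NoGradableEyeError("no gradable eye: cannot form a patient-level grade")
    return max(gradable)


def binarize_rdr(grade: Grade, cutoff: int = RDR_CUTOFF, k: int = 5) -> bool:
    """Collapse a severity grade to the referable-DR binary.

    Referable DR (rDR) is *more than mild* DR: moderate and above, i.e.
    ``level >= cutoff`` with the default cutoff of 2 on either the 5-point or
    the 4-point scale.  Returns True for rDR, False for no rDR.  UNGRADABLE
    input is an error; quality exclusion happens upstream.
    """
    grade = validate_grade(grade, k=k, allow_ungradable=False)
    return grade >= cutoff


@dataclass(frozen=True)
class EyeAssessment:
    """One grader's severity grade for one eye of one patient.

    ``n_images`` is the number of fundus photographs behind the decision
    (screening encounters routinely capture two or more fields per eye).
    """

    patient_id: str
    laterality: str
    grader_id: str
    grade: Grade
    n_images: int = 1

    def __post_init__(self) -> None:
        if self.laterality not in LATERALITIES:
            raise ValueError(f"laterality must be one of {LATERALITIES}, got {self.laterality!r}")
        validate_grade(self.grade, k=5)
        if not isinstance(self.n_images, int) or self.n_images < 1:
            raise ValueError(f"n_images must be a positive integer, got {self.n_images!r}")


@dataclass(frozen=True)
class PatientRecord:
    """All graders' eye assessments for one patient plus the automated patient-level grade.

    ``ai_grade`` is on the 4-point scale (or UNGRADABLE): automated screening
    software emits a single grade per patient, not per eye.
    """

    patient_id: str
    eye_assessments: tuple[EyeAssessment, ...]
    ai_grade: Grade

    def __post_init__(self) -> None:
        object.__setattr__(self, "eye_assessments", tuple(self.eye_assessments))
        for a in self.eye_assessments:
            if a.patient_id != self.patient_id:
                raise ValueError(
                    f"assessment for patient {a.patient_id!r} inside record {self.patient_id!r}"
                )
        keys = [(a.laterality, a.grader_id) for a in self.eye_assessments]
        if len(keys) != len(set(keys)):
            raise ValueError(f"duplicate (laterality, grader) assessment in {self.patient_id!r}")
        validate_grade(self.ai_grade, k=4)

    @property
    def grader_ids(self) -> tuple[str, ...]:
        """Sorted unique grader ids appearing in this record."""
        return tuple(sorted({a.grader_id for a in self.eye_assessments}))

    @property
    def lateralities(self) -> tuple[str, ...]:
        """Lateralities assessed by at least one grader, in OD, OS order."""
        present = {a.laterality for a in self.eye_assessments}
        return tuple(l for l in LATERALITIES if l in present)

    def assessment(self, laterality: str, grader_id: str) -> EyeAssessment | None:
        """The assessment of one eye by one grader, or None if absent."""
        for a in self.eye_assessments:
            if a.laterality == laterality and a.grader_id == grader_id:
                return a
        return None

    def eye_grades(self, grader_id: str) -> dict[str, Grade]:
        """Mapping laterality -> grade for one grader (absent eyes omitted)."""
        return {
            a.laterality: a.grade for a in self.eye_assessments if a.grader_id == grader_id
        }
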