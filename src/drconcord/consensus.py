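"""Quality exclusion, eye-level consensus with adjudication, and agreement taxonomies.

A screening encounter is read independently by three human graders (one
5-point grade per eye) and by an automated grader (one 4-point grade per
patient).  This module implements the bookkeeping between those raw grades and
a final reference grade per eye:

* patients are excluded when any rater flagged insufficient image quality
  (:func:`apply_quality_exclusion`, with a mutually exclusive exclusion-flow
  accounting);
* each eye's three human grades are classified as unanimous (3:0), majority
  (2:1) or fully discordant (1:1:1) (:func:`classify_agreement_3`);
* unanimous/majority eyes resolve to the modal grade, while fully discordant
  eyes require an external adjudication entry — in the motivating study a
  teleconference consensus of the graders (:func:`consensus_eye`);
* at patient level the automated grader joins as a fourth rater and the
  four-grade multiset is classified into the seven 4-rater agreement patterns,
  distinguishing whether the automated grader sits inside or outside the
  agreeing block (:func:`classify_agreement_4`).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .grades import (
    LATERALITIES,
    UNGRADABLE,
    Grade,
    GradeError,
    validate_grade,
)

__all__ = [
    "AgreementClass3",
    "AgreementClass4",
    "ConsensusSource",
    "ConsensusEye",
    "ExclusionFlow",
    "MissingAdjudicationError",
    "classify_agreement_3",
    "classify_agreement_4",
    "consensus_eye",
    "adjudication_worklist",
    "apply_quality_exclusion",
]

logger = logging.getLogger(__name__)


class AgreementClass3(Enum):
    """Agreement pattern of three human graders on one unit (eye or patient)."""

    UNANIMOUS_3_0 = "3:0"
    MAJORITY_2_1 = "2:1"
    DISCORDANT_1_1_1 = "1:1:1"


class AgreementClass4(Enum):
    """Agreement pattern of three human graders plus the automated grader.

    The partition of the four-grade multiset is refined by where the automated
    grader's grade falls: e.g. a 3:1 split is reported differently depending on
    whether the automated grader agrees with two humans (it is *inside* the
    majority triple) or stands alone against three agreeing humans.
    """

    P4_0 = "4:0"
    P3_1_AI_WITH_MAJORITY = "3:1 (AI in majority)"
    P3_1_AI_SINGLETON = "3:1 (AI alone)"
    P2_2 = "2:2"
    P2_1_1_AI_IN_PAIR = "2:1:1 (AI in majority)"
    P2_1_1_AI_SINGLETON = "2:1:1 (AI alone)"
    P1_1_1_1 = "1:1:1:1"


class ConsensusSource(Enum):
    """Provenance of a final eye grade."""

    UNANIMOUS = "unanimous"
    MAJORITY = "majority"
    ADJUDICATED = "adjudicated"


@dataclass(frozen=True)
class ConsensusEye:
    """Final reference grade for one eye, with its agreement class and provenance."""

    patient_id: str
    laterality: str
    agreement_class: AgreementClass3
    final_grade: int
    source: ConsensusSource


@dataclass(frozen=True)
class ExclusionFlow:
    """Mutually exclusive accounting of the patient-selection flow.

    Every patient in the input lands in exactly one bucket, applied in order:
    malformed record (``n_incomplete``), all raters ungradable
    (``n_ungradable_all``), at least one human quality flag
    (``n_excluded_human_quality``), automated grader ungradable with full human
    grading (``n_excluded_ai_only_ungradable``), else analyzable.
    """

    n_total: int
    n_ungradable_all: int
    n_excluded_human_quality: int
    n_excluded_ai_only_ungradable: int
    n_incomplete: int
    n_analyzed: int

    def __post_init__(self) -> None:
        parts = (
            self.n_ungradable_all
            + self.n_excluded_human_quality
            + self.n_excluded_ai_only_ungradable
            + self.n_incomplete
            + self.n_analyzed
        )
        if parts != self.n_total:
            raise ValueError(
                f"exclusion flow does not partition the input: {parts} != {self.n_total}"
            )

    def as_dict(self) -> dict[str, int]:
        return {
            "n_total": self.n_total,
            "n_ungradable_all": self.n_ungradable_all,
            "n_excluded_human_quality": self.n_excluded_human_quality,
            "n_excluded_ai_only_ungradable": self.n_excluded_ai_only_ungradable,
            "n_incomplete": self.n_incomplete,
            "n_analyzed": self.n_analyzed,
        }


class MissingAdjudicationError(GradeError):
    """A fully discordant eye has no adjudication entry.

    Carries the worklist of unresolved eyes as ``worklist``: a list of
    ``(patient_id, laterality, grades)`` tuples.
    """

    def __init__(self, worklist: Sequence[tuple[str, str, tuple[int, ...]]]):
        self.worklist = list(worklist)
        ids = ", ".join(f"{p}/{l}" for p, l, _ in self.worklist[:5])
        more = "..." if len(self.worklist) > 5 else ""
        super().__init__(
            f"{len(self.worklist)} fully discordant eye(s) need adjudication: {ids}{more}"
        )


def _checked(grades: Iterable[Grade], k: int) -> tuple[int, ...]:
    out = []
    for g in grades:
        if g is UNGRADABLE:
            raise GradeError("UNGRADABLE grade in agreement classification; exclude upstream")
        out.append(validate_grade(g, k=k, allow_ungradable=False))
    return tuple(out)


def classify_agreement_3(g1: Grade, g2: Grade, g3: Grade, k: int = 5) -> AgreementClass3:
    """Classify three graders' grades for one unit by their agreement pattern.

    All equal -> 3:0 (unanimous); exactly two equal -> 2:1 (majority); all
    distinct -> 1:1:1 (fully discordant).  Symmetric in its three arguments.
    UNGRADABLE input is an error (quality exclusion happens upstream).
    """
    grades = _checked((g1, g2, g3), k)
    distinct = len(set(grades))
    if distinct == 1:
        return AgreementClass3.UNANIMOUS_3_0
    if distinct == 2:
        return AgreementClass3.MAJORITY_2_1
    return AgreementClass3.DISCORDANT_1_1_1


def classify_agreement_4(
    h1: Grade, h2: Grade, h3: Grade, ai: Grade, k: int = 4
) -> AgreementClass4:
    """Classify three human grades plus the automated grade (4-point scale).

    The partition pattern of the multiset {h1, h2, h3, ai} is refined by the
    automated grader's position: for 3:1, whether it is inside the agreeing
    triple; for 2:1:1, whether it is inside the agreeing pair.  Symmetric under
    permutation of the three human positions, but not under swapping the
    automated grader with a human.
    """
    humans = _checked((h1, h2, h3), k)
    ai = _checked((ai,), k)[0]
    counts = Counter((*humans, ai))
    sizes = sorted(counts.values(), reverse=True)
    if sizes == [4]:
        return AgreementClass4.P4_0
    if sizes == [3, 1]:
        if counts[ai] == 3:
            return AgreementClass4.P3_1_AI_WITH_MAJORITY
        return AgreementClass4.P3_1_AI_SINGLETON
    if sizes == [2, 2]:
        return AgreementClass4.P2_2
    if sizes == [2, 1, 1]:
        if counts[ai] == 2:
            return AgreementClass4.P2_1_1_AI_IN_PAIR
        return AgreementClass4.P2_1_1_AI_SINGLETON
    return AgreementClass4.P1_1_1_1


def consensus_eye(
    patient_id: str,
    laterality: str,
    grades: Sequence[Grade],
    adjudication_lookup: Mapping[tuple[str, str], int] | None = None,
    k: int = 5,
) -> ConsensusEye:
    """Resolve one eye's three grades to a final reference grade.

    Unanimous and majority eyes take the modal grade.  Fully discordant eyes
    take the grade from ``adjudication_lookup`` (keyed by ``(patient_id,
    laterality)``) with source ADJUDICATED; a discordant eye with no entry
    raises :class:`MissingAdjudicationError`.  An explicit adjudication entry,
    when present, always overrides the modal grade — adjudication is the
    stronger evidence, and this also covers studies that re-adjudicated
    majority eyes of otherwise discordant patients.
    """
    grades = _checked(grades, k)
    if len(grades) != 3:
        raise GradeError(f"eye-level consensus needs exactly 3 grades, got {len(grades)}")
    cls = classify_agreement_3(*grades, k=k)
    lookup = adjudication_lookup or {}
    key = (patient_id, laterality)
    if key in lookup:
        final = validate_grade(lookup[key], k=k, allow_ungradable=False)
        if cls is not AgreementClass3.DISCORDANT_1_1_1:
            logger.info(
                "adjudication override for %s/%s: modal grade %s replaced by %s",
                patient_id,
                laterality,
                Counter(grades).most_common(1)[0][0],
                final,
            )
        return ConsensusEye(patient_id, laterality, cls, final, ConsensusSource.ADJUDICATED)
    if cls is AgreementClass3.DISCORDANT_1_1_1:
        raise MissingAdjudicationError([(patient_id, laterality, grades)])
    modal = Counter(grades).most_common(1)[0][0]
    source = (
        ConsensusSource.UNANIMOUS
        if cls is AgreementClass3.UNANIMOUS_3_0
        else ConsensusSource.MAJORITY
    )
    return ConsensusEye(patient_id, laterality, cls, modal, source)


def adjudication_worklist(
    eyes: Iterable[tuple[str, str, Sequence[Grade]]],
    adjudication_lookup: Mapping[tuple[str, str], int] | None = None,
    k: int = 5,
) -> list[tuple[str, str, tuple[int, ...]]]:
    """List the fully discordant eyes that still lack an adjudication entry.

    ``eyes`` yields ``(patient_id, laterality, grades)``; the result is in
    stable (patient_id, laterality) order, ready to be written as a worklist
    CSV for a human adjudication round.
    """
    lookup = adjudication_lookup or {}
    out = []
    for patient_id, laterality, grades in eyes:
        grades = _checked(grades, k)
        if (
            classify_agreement_3(*grades, k=k) is AgreementClass3.DISCORDANT_1_1_1
            and (patient_id, laterality) not in lookup
        ):
            out.append((patient_id, laterality, grades))
    out.sort(key=lambda item: (item[0], item[1]))
    return out


def _record_completeness(record, expected_graders: Sequence[str] | None = None) -> bool:
    """A record is complete when every expected grader assessed every eye that anyone assessed."""
    graders = tuple(expected_graders) if expected_graders is not None else record.grader_ids
    eyes = record.lateralities
    if not graders or not eyes:
        return False
    return all(
        record.assessment(lat, g) is not None for lat in eyes for g in graders
    )


def apply_quality_exclusion(
    records: Iterable, expected_graders: Sequence[str] | None = None
) -> tuple[list, ExclusionFlow]:
    """Drop patients with any quality failure; account for every exclusion once.

    A patient is analyzable iff no human grader marked any assessed eye
    UNGRADABLE *and* the automated grade is not UNGRADABLE.  Excluded patients
    are counted in exactly one bucket, with precedence: malformed/incomplete
    record, all raters ungradable, any human quality flag, automated grader
    only.  Each exclusion is logged with the patient id so the selection flow
    can be audited from logs.  ``expected_graders``, when given, is the full
    grader panel: a record missing any panel member is malformed even if its
    own graders are internally consistent.
    """
    retained: list = []
    n_total = n_incomplete = n_all = n_human = n_ai = 0
    for record in records:
        n_total += 1
        if not _record_completeness(record, expected_graders):
            n_incomplete += 1
            logger.warning("malformed record %s: missing grader assessments", record.patient_id)
            continue
        human_grades = [a.grade for a in record.eye_assessments]
        all_human_ungradable = all(g is UNGRADABLE for g in human_grades)
        any_human_ungradable = any(g is UNGRADABLE for g in human_grades)
        ai_ungradable = record.ai_grade is UNGRADABLE
        if all_human_ungradable and ai_ungradable:
            n_all += 1
            logger.info("excluded %s: ungradable by all raters", record.patient_id)
        elif any_human_ungradable:
            n_human += 1
            logger.info("excluded %s: human quality flag", record.patient_id)
        elif ai_ungradable:
            n_ai += 1
            logger.info("excluded %s: automated grader ungradable", record.patient_id)
        else:
            retained.append(record)
    flow = ExclusionFlow(
        n_total=n_total,
        n_ungradable_all=n_all,
        n_excluded_human_quality=n_human,
        n_excluded_ai_only_ungradable=n_ai,
        n_incomplete=n_incomplete,
        n_analyzed=len(retained),
    )
    return retained, flow
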