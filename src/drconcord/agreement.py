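"""Chance-corrected agreement statistics: contingency tables, Cohen's kappa,
grade-distribution tables, and the referable-DR binary post hoc analysis.

Cohen's kappa is computed from a fixed-K contingency table so that unobserved
categories still contribute zero rows/columns — kappas stay comparable across
graders regardless of which grades each grader happened to use.  The weighted
generalizations (linear, quadratic) are provided, but the headline analysis is
unweighted kappa on the 5-point per-eye scale.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np

from .grades import RDR_CUTOFF, binarize_rdr

__all__ = [
    "ContingencyTable",
    "build_contingency",
    "cohen_kappa",
    "KappaReport",
    "kappa_vs_final",
    "pairwise_kappa_summary",
    "DistributionTable",
    "distribution_table",
    "RdrSummary",
    "rdr_analysis",
    "round_half_up",
]

WEIGHTINGS = ("none", "linear", "quadratic")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention used for report percentages)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable:
    """K x K joint count grid between two raters (rows: rater A, cols: rater B)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError(f"contingency table must be square, got shape {counts.shape}")
        if (counts < 0).any():
            raise ValueError("contingency table counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.counts.T.copy())


def build_contingency(
    ratings_a: Sequence[int], ratings_b: Sequence[int], k: int
) -> ContingencyTable:
    """Cross-tabulate two aligned rating sequences onto a fixed K x K grid.

    K is fixed by the scale, not the data, so categories never observed stay
    as zero rows/columns.  Length mismatch or out-of-range values are errors.
    """
    a = np.asarray(ratings_a, dtype=np.int64)
    b = np.asarray(ratings_b, dtype=np.int64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"rating sequences must be 1-D and aligned, got {a.shape} vs {b.shape}")
    for name, arr in (("a", a), ("b", b)):
        bad = (arr < 0) | (arr >= k)
        if bad.any():
            idx = int(np.argmax(bad))
            raise ValueError(
                f"rating {arr[idx]} of sequence {name} at position {idx} outside 0..{k - 1}"
            )
    counts = np.bincount(a * k + b, minlength=k * k).reshape(k, k)
    return ContingencyTable(counts)


def _weight_matrix(k: int, weighting: str) -> np.ndarray:
    i, j = np.indices((k, k))
    if weighting == "none":
        return (i != j).astype(float)
    d = np.abs(i - j) / max(k - 1, 1)
    if weighting == "linear":
        return d
    if weighting == "quadratic":
        return d**2
    raise ValueError(f"weighting must be one of {WEIGHTINGS}, got {weighting!r}")


def cohen_kappa(table: ContingencyTable, weighting: str = "none") -> float:
    """Cohen's kappa (optionally linear/quadratic weighted) from a contingency table.

    Unweighted kappa is (p_o - p_e) / (1 - p_e) where p_o is the diagonal
    proportion and p_e the chance agreement from the marginals.  Weighted kappa
    is 1 - (observed weighted disagreement)/(expected weighted disagreement),
    which reduces to the same formula for 0/1 disagreement weights.  If the
    expected disagreement is zero (both raters constant and equal) kappa is 1
    by convention.
    """
    if table.n < 1:
        raise ValueError("empty contingency table")
    p = table.counts / table.n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    w = _weight_matrix(table.k, weighting)
    observed = float((w * p).sum())
    expected = float((w * np.outer(row, col)).sum())
    if expected == 0.0:
        return 1.0
    return 1.0 - observed / expected


@dataclass(frozen=True)
class KappaReport:
    """Kappa summaries for a grader panel.

    ``per_grader_vs_final`` holds each grader's kappa against the final
    (adjudicated) grades; ``pairwise`` holds kappa per unordered grader pair;
    ``per_grader_mean_pairwise`` averages each grader's pairwise kappas.
    """

    per_grader_vs_final: dict[str, float] = field(default_factory=dict)
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)
    per_grader_mean_pairwise: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v in itertools.chain(
            self.per_grader_vs_final.values(),
            self.pairwise.values(),
            self.per_grader_mean_pairwise.values(),
        ):
            if not -1.0 - 1e-12 <= v <= 1.0 + 1e-12:
                raise ValueError(f"kappa {v} outside [-1, 1]")


def kappa_vs_final(
    grader_ratings: Mapping[str, Sequence[int]],
    final_ratings: Sequence[int],
    k: int = 5,
    weighting: str = "none",
) -> dict[str, float]:
    """Kappa of each grader against the final reference grades (aligned per eye)."""
    out: dict[str, float] = {}
    for grader_id in sorted(grader_ratings):
        table = build_contingency(grader_ratings[grader_id], final_ratings, k)
        out[grader_id] = cohen_kappa(table, weighting)
    return out


def pairwise_kappa_summary(
    grader_ratings: Mapping[str, Sequence[int]],
    k: int = 5,
    weighting: str = "none",
) -> tuple[dict[tuple[str, str], float], dict[str, float]]:
    """Kappa for each unordered grader pair, plus each grader's mean pairwise kappa."""
    graders = sorted(grader_ratings)
    if len(graders) < 2:
        raise ValueError("pairwise kappas need at least two graders")
    pairwise: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(graders, 2):
        table = build_contingency(grader_ratings[a], grader_ratings[b], k)
        pairwise[(a, b)] = cohen_kappa(table, weighting)
    means = {
        g: float(np.mean([v for pair, v in pairwise.items() if g in pair])) for g in graders
    }
    return pairwise, means


@dataclass(frozen=True)
class DistributionTable:
    """Counts and percentages per grade level, zero-count levels included."""

    counts: dict[int, int]
    percentages: dict[int, float]
    total: int

    def count_at_or_above(self, level: int) -> int:
        return sum(c for g, c in self.counts.items() if g >= level)

    def share_at_or_above(self, level: int, ndigits: int = 2) -> float:
        """Percentage of units at or above ``level`` (half-up rounded)."""
        if self.total == 0:
            return 0.0
        return round_half_up(100.0 * self.count_at_or_above(level) / self.total, ndigits)


def distribution_table(grades: Sequence[int], k: int) -> DistributionTable:
    """Tabulate final grades into counts and half-up 2-decimal percentages."""
    arr = np.asarray(list(grades), dtype=np.int64) if len(grades) else np.empty(0, np.int64)
    if arr.size and ((arr < 0) | (arr >= k)).any():
        raise ValueError(f"grade outside 0..{k - 1} in distribution input")
    counts = {level: int((arr == level).sum()) for level in range(k)}
    total = int(arr.size)
    percentages = {
        level: (round_half_up(100.0 * c / total) if total else 0.0)
        for level, c in counts.items()
    }
    return DistributionTable(counts=counts, percentages=percentages, total=total)


@dataclass(frozen=True)
class RdrSummary:
    """Referable-DR binary post hoc analysis of the *original* (pre-adjudication) grades.

    On the two-level referable / non-referable scale three graders always have
    at least a majority, so no adjudication is needed; the analysis therefore
    uses each grader's original grades.  Eye level: counts of unanimous and
    2:1 eyes.  Patient level (each grader's own max-of-eyes grade, binarized):
    unanimous and 2:1 patients; for 2:1 patients, whether the automated grader
    sided with or against the human majority; for unanimous patients, how often
    the automated grader disagreed, split by direction.
    """

    n_patients: int
    n_eyes: int
    eye_full_agreement: int
    eye_majority: int
    patient_full_agreement: int
    patient_majority: int
    majority_ai_with_majority: int
    majority_ai_against_majority: int
    full_agreement_ai_disagreements: int
    ai_referable_disagreements: int
    ai_nonreferable_disagreements: int

    def __post_init__(self) -> None:
        if self.eye_full_agreement + self.eye_majority != self.n_eyes:
            raise ValueError("eye-level rDR agreement classes do not partition the eyes")
        if self.patient_full_agreement + self.patient_majority != self.n_patients:
            raise ValueError("patient-level rDR agreement classes do not partition the patients")

    def as_dict(self) -> dict[str, int]:
        return {
            "n_patients": self.n_patients,
            "n_eyes": self.n_eyes,
            "eye_full_agreement": self.eye_full_agreement,
            "eye_majority": self.eye_majority,
            "patient_full_agreement": self.patient_full_agreement,
            "patient_majority": self.patient_majority,
            "majority_ai_with_majority": self.majority_ai_with_majority,
            "majority_ai_against_majority": self.majority_ai_against_majority,
            "full_agreement_ai_disagreements": self.full_agreement_ai_disagreements,
            "ai_referable_disagreements": self.ai_referable_disagreements,
            "ai_nonreferable_disagreements": self.ai_nonreferable_disagreements,
        }


def rdr_analysis(
    eye_triples: Mapping[tuple[str, str], Sequence[int]],
    ai_grades: Mapping[str, int],
    cutoff: int = RDR_CUTOFF,
) -> RdrSummary:
    """Binary referable-DR agreement analysis on the original human grades.

    ``eye_triples`` maps (patient_id, laterality) to the three human 5-point
    grades in a fixed grader order; ``ai_grades`` maps patient_id to the
    automated 4-point grade.  Patient-level human grades are each grader's
    maximum over their own eyes (binarizing before or after the maximum is
    equivalent because the cutoff map is monotone).
    """
    eye_full = eye_maj = 0
    per_patient: dict[str, list[Sequence[int]]] = {}
    for (patient_id, _lat), triple in sorted(eye_triples.items()):
        if len(triple) != 3:
            raise ValueError("rDR analysis is defined for exactly three human graders")
        bits = tuple(binarize_rdr(g, cutoff=cutoff) for g in triple)
        if len(set(bits)) == 1:
            eye_full += 1
        else:
            eye_maj += 1
        per_patient.setdefault(patient_id, []).append(triple)

    pat_full = pat_maj = maj_with = maj_against = full_dis = ai_ref = ai_nonref = 0
    for patient_id, triples in sorted(per_patient.items()):
        if patient_id not in ai_grades:
            raise KeyError(f"no automated grade for patient {patient_id!r}")
        per_grader = [max(t[i] for t in triples) for i in range(3)]
        bits = [binarize_rdr(g, cutoff=cutoff) for g in per_grader]
        ai_bit = binarize_rdr(ai_grades[patient_id], cutoff=cutoff, k=4)
        n_ref = sum(bits)
        if n_ref in (0, 3):
            pat_full += 1
            majority = n_ref == 3
            if ai_bit != majority:
                full_dis += 1
                if ai_bit:
                    ai_ref += 1
                else:
                    ai_nonref += 1
        else:
            pat_maj += 1
            majority = n_ref == 2
            if ai_bit == majority:
                maj_with += 1
            else:
                maj_against += 1

    return RdrSummary(
        n_patients=len(per_patient),
        n_eyes=len(eye_triples),
        eye_full_agreement=eye_full,
        eye_majority=eye_maj,
        patient_full_agreement=pat_full,
        patient_majority=pat_maj,
        majority_ai_with_majority=maj_with,
        majority_ai_against_majority=maj_against,
        full_agreement_ai_disagreements=full_dis,
        ai_referable_disagreements=ai_ref,
        ai_nonreferable_disagreements=ai_nonref,
    )
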