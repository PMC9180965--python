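"""Statsmodels-style front end: a concordance model fitted to a grading dataset.

:class:`GradingConcordance` is constructed from the three tidy inputs (per-eye
human grades, patient-level automated grades, optional eye-level adjudication
entries) and ``fit()`` runs the whole pipeline in the study order — quality
exclusion, eye-level consensus with adjudication, per-patient aggregation and
scale compression, agreement taxonomies, kappa analyses, and the referable-DR
post hoc on the original grades — returning a :class:`ConcordanceResults`
object that carries every table, a ``summary()``, and writers.

Example
-------
>>> from drconcord import GradingConcordance, simulate_dataset, default_config
>>> sim = simulate_dataset(default_config(n_patients=200, seed=7))
>>> res = GradingConcordance.from_simulation(sim).fit()
>>> print(res.summary())                                   # doctest: +SKIP
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from . import io as _io
from .agreement import (
    distribution_table,
    kappa_vs_final,
    pairwise_kappa_summary,
    rdr_analysis,
)
from .consensus import (
    AgreementClass3,
    AgreementClass4,
    MissingAdjudicationError,
    adjudication_worklist,
    apply_quality_exclusion,
    classify_agreement_4,
    consensus_eye,
)
from .grades import compress_5_to_4, patient_grade
from .report import StudyReport, render_report

__all__ = ["GradingConcordance", "ConcordanceResults"]


def _distribution_payload(grades: Sequence[int], k: int) -> dict:
    dist = distribution_table(grades, k)
    return {
        "counts": {str(level): dist.counts[level] for level in range(k)},
        "percentages": {str(level): dist.percentages[level] for level in range(k)},
        "total": dist.total,
    }


class GradingConcordance:
    """Multi-grader grading concordance model for one screening dataset.

    Parameters
    ----------
    grades : DataFrame
        Tidy per-eye human grades (``patient_id, laterality, grader_id,
        grade, n_images``; ``grade`` nullable integer, NA = ungradable).
    ai : DataFrame
        Patient-level automated grades (``patient_id, ai_grade``; 4-point,
        NA = ungradable).
    adjudications : DataFrame, optional
        Eye-level adjudicated final grades (``patient_id, laterality,
        final_grade``).  Required whenever any analyzable eye is fully
        discordant; an explicit entry overrides the modal grade of its eye.
    rdr_cutoff : int
        Referable-DR threshold (default 2 = moderate DR and above).
    kappa_weighting : str
        ``"none"`` (default, the headline statistic), ``"linear"`` or
        ``"quadratic"``.
    """

    def __init__(
        self,
        grades: pd.DataFrame,
        ai: pd.DataFrame,
        adjudications: pd.DataFrame | None = None,
        rdr_cutoff: int = 2,
        kappa_weighting: str = "none",
    ) -> None:
        self.grades = grades
        self.ai = ai
        self.adjudications = adjudications
        self.rdr_cutoff = int(rdr_cutoff)
        self.kappa_weighting = kappa_weighting
        self._records = _io.records_from_frames(grades, ai)
        self.grader_ids: tuple[str, ...] = tuple(
            sorted({a.grader_id for r in self._records for a in r.eye_assessments})
        )
        if len(self.grader_ids) < 2:
            raise ValueError("concordance analysis needs at least two human graders")

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_csv(
        cls,
        grades_path,
        ai_path,
        adjudications_path=None,
        **kwargs,
    ) -> "GradingConcordance":
        """Build the model from the three CSV files (adjudications optional)."""
        grades = _io.load_grades(grades_path)
        ai = _io.load_ai(ai_path)
        adjudications = (
            _io.load_adjudications(adjudications_path) if adjudications_path else None
        )
        return cls(grades, ai, adjudications, **kwargs)

    @classmethod
    def from_simulation(cls, sim, **kwargs) -> "GradingConcordance":
        """Build the model from a :class:`~drconcord.simulate.SimulatedDataset`."""
        return cls(sim.grades, sim.ai, sim.adjudications, **kwargs)

    # -- fitting -----------------------------------------------------------
    def fit(self) -> "ConcordanceResults":
        """Run the pipeline and return the results.

        Raises :class:`~drconcord.consensus.MissingAdjudicationError` (with
        the worklist attached) if any analyzable eye is fully discordant and
        has no adjudication entry.
        """
        retained, flow = apply_quality_exclusion(self._records, self.grader_ids)
        adj_lookup = _io.adjudication_lookup_from_frame(self.adjudications)

        if len(self.grader_ids) != 3:
            report = self._fit_generic(retained, flow)
            return ConcordanceResults(self, report)

        # one entry per analyzable eye: (patient_id, laterality, grade triple, images)
        eyes: list[tuple[str, str, tuple[int, int, int], int]] = []
        for record in retained:
            for lat in record.lateralities:
                triple = tuple(
                    record.assessment(lat, g).grade for g in self.grader_ids
                )
                images = max(record.assessment(lat, g).n_images for g in self.grader_ids)
                eyes.append((record.patient_id, lat, triple, images))

        missing = adjudication_worklist(
            ((pid, lat, triple) for pid, lat, triple, _ in eyes), adj_lookup
        )
        if missing:
            raise MissingAdjudicationError(missing)

        consensus = {
            (pid, lat): consensus_eye(pid, lat, triple, adj_lookup)
            for pid, lat, triple, _ in eyes
        }

        # -- eye-level agreement tables (eyes and images, per laterality) --
        agreement3 = {
            scope: {
                cls.name: {"eyes": 0, "images": 0} for cls in AgreementClass3
            }
            for scope in ("both", "OD", "OS")
        }
        full_eyes = {str(g): {"eyes": 0, "images": 0} for g in range(5)}
        majority_eyes = {str(g): {"eyes": 0, "images": 0} for g in range(5)}
        for pid, lat, triple, images in eyes:
            ce = consensus[(pid, lat)]
            for scope in ("both", lat):
                agreement3[scope][ce.agreement_class.name]["eyes"] += 1
                agreement3[scope][ce.agreement_class.name]["images"] += images
            if ce.agreement_class is AgreementClass3.UNANIMOUS_3_0:
                full_eyes[str(ce.final_grade)]["eyes"] += 1
                full_eyes[str(ce.final_grade)]["images"] += images
            elif ce.agreement_class is AgreementClass3.MAJORITY_2_1:
                majority_eyes[str(ce.final_grade)]["eyes"] += 1
                majority_eyes[str(ce.final_grade)]["images"] += images

        # -- per-patient aggregation (set 2) and 4-rater taxonomy ----------
        final_patient_grades: list[int] = []
        full_patients = {str(g): 0 for g in range(4)}
        agreement4 = {cls.name: 0 for cls in AgreementClass4}
        eye_triples: dict[tuple[str, str], tuple[int, int, int]] = {}
        ai_map: dict[str, int] = {}
        for record in retained:
            lats = record.lateralities
            finals = [consensus[(record.patient_id, lat)].final_grade for lat in lats]
            final_patient_grades.append(compress_5_to_4(patient_grade(finals)))
            own = [
                compress_5_to_4(patient_grade(record.eye_grades(g).values()))
                for g in self.grader_ids
            ]
            if len(set(own)) == 1:
                full_patients[str(own[0])] += 1
            agreement4[classify_agreement_4(*own, record.ai_grade).name] += 1
            for lat in lats:
                eye_triples[(record.patient_id, lat)] = tuple(
                    record.assessment(lat, g).grade for g in self.grader_ids
                )
            ai_map[record.patient_id] = record.ai_grade

        # -- kappa analyses (per-eye 5-point grades, both eyes pooled) -----
        ordered_eyes = sorted(consensus)
        grader_ratings = {
            g: [eye_triples[key][i] for key in ordered_eyes]
            for i, g in enumerate(self.grader_ids)
        }
        final_ratings = [consensus[key].final_grade for key in ordered_eyes]
        vs_final = kappa_vs_final(
            grader_ratings, final_ratings, k=5, weighting=self.kappa_weighting
        )
        pairwise, mean_pairwise = pairwise_kappa_summary(
            grader_ratings, k=5, weighting=self.kappa_weighting
        )

        rdr = rdr_analysis(eye_triples, ai_map, cutoff=self.rdr_cutoff) if eye_triples else None

        report = StudyReport(
            exclusion_flow=flow.as_dict(),
            distribution_5pt_by_eye=_distribution_payload(final_ratings, 5),
            distribution_4pt_by_patient=_distribution_payload(final_patient_grades, 4),
            agreement3=agreement3,
            full_agreement_eyes=full_eyes,
            full_agreement_patients=full_patients,
            majority_eyes=majority_eyes,
            agreement4=agreement4,
            kappa={
                "vs_final": vs_final,
                "pairwise": {f"{a}|{b}": v for (a, b), v in pairwise.items()},
                "mean_pairwise": mean_pairwise,
            },
            rdr=rdr.as_dict() if rdr is not None else {},
            n_graders=3,
            kappa_weighting=self.kappa_weighting,
            rdr_cutoff=self.rdr_cutoff,
        )
        return ConcordanceResults(self, report)

    def _fit_generic(self, retained, flow) -> StudyReport:
        """Reduced report for grader panels other than three.

        Without the 3-rater consensus there is no final reference grade, so
        only the exclusion flow, the multiset partition counts of the human
        grades per eye, and the pairwise kappas are reported.
        """
        agreement3 = {scope: {} for scope in ("both", "OD", "OS")}
        ratings: dict[str, list[int]] = {g: [] for g in self.grader_ids}
        for record in retained:
            for lat in record.lateralities:
                grades = [record.assessment(lat, g).grade for g in self.grader_ids]
                from collections import Counter

                sizes = sorted(Counter(grades).values(), reverse=True)
                sig = ":".join(map(str, sizes)) + (":0" if len(sizes) == 1 else "")
                images = max(record.assessment(lat, g).n_images for g in self.grader_ids)
                for scope in ("both", lat):
                    cell = agreement3[scope].setdefault(sig, {"eyes": 0, "images": 0})
                    cell["eyes"] += 1
                    cell["images"] += images
                for g, v in zip(self.grader_ids, grades):
                    ratings[g].append(v)
        pairwise, mean_pairwise = (
            pairwise_kappa_summary(ratings, k=5, weighting=self.kappa_weighting)
            if any(ratings.values())
            else ({}, {})
        )
        return StudyReport(
            exclusion_flow=flow.as_dict(),
            distribution_5pt_by_eye={"counts": {}, "percentages": {}, "total": 0},
            distribution_4pt_by_patient={"counts": {}, "percentages": {}, "total": 0},
            agreement3=agreement3,
            full_agreement_eyes={},
            full_agreement_patients={},
            majority_eyes={},
            agreement4={},
            kappa={
                "vs_final": {},
                "pairwise": {f"{a}|{b}": v for (a, b), v in pairwise.items()},
                "mean_pairwise": mean_pairwise,
            },
            rdr={},
            n_graders=len(self.grader_ids),
            kappa_weighting=self.kappa_weighting,
            rdr_cutoff=self.rdr_cutoff,
        )


class ConcordanceResults:
    """Results of a fitted :class:`GradingConcordance`.

    Wraps the :class:`~drconcord.report.StudyReport` with convenient accessors,
    a text ``summary()``, file writers, and a small agreement plot.
    """

    def __init__(self, model: GradingConcordance, report: StudyReport) -> None:
        self.model = model
        self.report = report

    # -- accessors ---------------------------------------------------------
    @property
    def exclusion_flow(self) -> dict[str, int]:
        return self.report.exclusion_flow

    @property
    def n_analyzed(self) -> int:
        return self.report.exclusion_flow["n_analyzed"]

    @property
    def kappa_vs_final(self) -> dict[str, float]:
        """Each grader's unweighted (or configured-weighting) kappa against final grades."""
        return dict(self.report.kappa.get("vs_final", {}))

    @property
    def kappa_pairwise(self) -> dict[tuple[str, str], float]:
        return {
            tuple(key.split("|")): v for key, v in self.report.kappa.get("pairwise", {}).items()
        }

    @property
    def kappa_mean_pairwise(self) -> dict[str, float]:
        return dict(self.report.kappa.get("mean_pairwise", {}))

    @property
    def agreement3_eye_counts(self) -> dict[str, int]:
        """Eyes per 3-rater agreement class, both lateralities pooled."""
        return {
            name: cell["eyes"] for name, cell in self.report.agreement3.get("both", {}).items()
        }

    @property
    def agreement4_counts(self) -> dict[str, int]:
        """Patients per 4-rater (3 humans + automated) agreement pattern."""
        return dict(self.report.agreement4)

    @property
    def rdr(self) -> dict[str, int]:
        return dict(self.report.rdr)

    # -- presentation ------------------------------------------------------
    def summary(self) -> str:
        """Fixed-width text summary of the headline results."""
        return self.report.summary_text()

    def save(self, out_dir) -> dict[str, Path]:
        """Write the full report (CSV tables, JSON bundle, text summary)."""
        return render_report(self.report, out_dir)

    def to_json(self) -> str:
        return self.report.to_json()

    def plot_agreement(self, ax=None):
        """Bar chart of the 3-rater eye-level agreement classes (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3))
        counts = self.agreement3_eye_counts
        names = [AgreementClass3[n].value if n in AgreementClass3.__members__ else n for n in counts]
        ax.bar(names, list(counts.values()), color="#4878d0")
        ax.set_ylabel("eyes")
        ax.set_title("Eye-level grader agreement")
        return ax

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<ConcordanceResults: {self.n_analyzed} patients analyzed, "
            f"{len(self.model.grader_ids)} graders>"
        )
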