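"""Packaged reference data.

Two kinds of data ship with the package:

* ``load_study_tables()`` — the published summary tables of a three-grader
  diabetic-retinopathy screening study (335 analyzable patients, 670 eyes,
  1501 fundus images, three retina-specialist graders plus a patient-level
  automated grader).  These are *summary counts*, not raw grades — the raw
  per-eye grades of that study were never deposited — and they serve as
  cross-consistency fixtures: the counts of different tables must tie out
  (e.g. the severity breakdown of unanimous eyes must sum to the unanimous
  row of the agreement-by-laterality table).
* ``load_discordant_quartet()`` — the four fully worked patients from the
  same study in which every rater (three humans and the automated grader)
  assigned a different patient-level grade, together with their eye-level
  adjudicated finals.  This is the one piece of raw grade data the study
  printed, and it exercises the whole pipeline end to end.  The study did not
  print per-eye image counts for these patients, so the fixture carries a
  synthetic ``n_images`` of 2 per eye.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from . import io as _io

__all__ = [
    "load_study_tables",
    "load_discordant_quartet",
    "cross_table_checks",
]


def _data_path(name: str):
    return resources.files("drconcord").joinpath("data", name)


def _read(name: str) -> pd.DataFrame:
    with resources.as_file(_data_path(name)) as path:
        return pd.read_csv(path)


def load_study_tables() -> dict[str, pd.DataFrame]:
    """Load the packaged summary tables of the reference screening study.

    Returns a dict with keys:

    - ``patient_distribution`` — final adjudicated patient grades (4-point):
      ``grade, patients``;
    - ``agreement_by_laterality`` — eye-level 3-rater agreement classes by
      scope (both/OD/OS), in images and eyes;
    - ``full_agreement_eyes`` — severity breakdown of unanimous eyes
      (5-point): ``grade, images, eyes``;
    - ``full_agreement_patients`` — severity breakdown of patients whose
      three per-grader patient-level grades coincide (4-point);
    - ``majority_eyes`` — severity breakdown of 2:1 majority eyes (5-point);
    - ``patient_agreement_patterns`` — patients per 4-rater pattern.
    """
    return {
        "patient_distribution": _read("study_patient_distribution.csv"),
        "agreement_by_laterality": _read("study_agreement_by_laterality.csv"),
        "full_agreement_eyes": _read("study_full_agreement_eyes.csv"),
        "full_agreement_patients": _read("study_full_agreement_patients.csv"),
        "majority_eyes": _read("study_majority_eyes.csv"),
        "patient_agreement_patterns": _read("study_patient_agreement_patterns.csv"),
    }


def load_discordant_quartet() -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Load the four fully discordant patients (grades, ai, adjudications).

    Returns validated DataFrames ready for :class:`~drconcord.model.GradingConcordance`.
    The per-eye image counts are synthetic (2 per eye); every other value is
    as printed by the reference study.
    """
    with resources.as_file(_data_path("discordant_quartet_grades.csv")) as p:
        grades = _io.load_grades(p)
    with resources.as_file(_data_path("discordant_quartet_ai.csv")) as p:
        ai = _io.load_ai(p)
    with resources.as_file(_data_path("discordant_quartet_adjudications.csv")) as p:
        adjudications = _io.load_adjudications(p)
    return grades, ai, adjudications


def cross_table_checks(tables: dict[str, pd.DataFrame] | None = None) -> dict[str, int]:
    """Recompute the sums that tie the study's summary tables together.

    Returns a dict of independently computed totals; consistency of the
    published tables means e.g. ``unanimous_eyes_from_breakdown ==
    unanimous_eyes_from_laterality``.
    """
    t = tables if tables is not None else load_study_tables()
    lat = t["agreement_by_laterality"].set_index(["scope", "pattern"])
    full = t["full_agreement_eyes"]
    maj = t["majority_eyes"]
    both = lat.xs("both")
    return {
        "unanimous_eyes_from_breakdown": int(full["eyes"].sum()),
        "unanimous_eyes_from_laterality": int(both.loc["UNANIMOUS_3_0", "eyes"]),
        "unanimous_images_from_breakdown": int(full["images"].sum()),
        "unanimous_images_from_laterality": int(both.loc["UNANIMOUS_3_0", "images"]),
        "majority_eyes_from_breakdown": int(maj["eyes"].sum()),
        "majority_eyes_from_laterality": int(both.loc["MAJORITY_2_1", "eyes"]),
        "total_images": int(both["images"].sum()),
        "discordant_eyes_both": int(both.loc["DISCORDANT_1_1_1", "eyes"]),
        "discordant_eyes_by_laterality": int(
            lat.loc[("OD", "DISCORDANT_1_1_1"), "eyes"]
            + lat.loc[("OS", "DISCORDANT_1_1_1"), "eyes"]
        ),
        "total_patients": int(t["patient_distribution"]["patients"].sum()),
    }
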