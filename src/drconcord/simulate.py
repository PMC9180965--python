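"""Synthetic multi-grader screening datasets with known generating parameters.

The generator emulates the statistical structure of an eye-level DR screening
study read by several human graders and one patient-level automated grader:

* a true 5-point severity per eye, drawn from a prevalence vector, with
  left/right eyes correlated through a copy mixture (the second eye copies the
  first with probability ``inter_eye_concordance``, otherwise is drawn fresh);
* each human grader assigns a grade drawn from the row of their 5x5
  row-stochastic confusion matrix indexed by the true grade, independently of
  the other graders given the truth;
* each grader independently flags each eye ungradable with a per-grader
  quality-failure probability;
* the automated grader emits one 4-point patient grade drawn from its own 4x4
  confusion matrix applied to the compressed true patient grade, or is
  ungradable with its own probability;
* adjudication entries are emitted for every eye, equal to the true grade
  (policy ``"truth"``) or to the median of the three drawn grades
  (policy ``"grader_median"``, for sensitivity checks).

Conditional independence of raters given the truth is what makes exact
analytic expectations possible (:func:`analytic_kappa`,
:func:`expected_agreement_frequencies`), which the test suite uses as oracles
for parameter recovery.  A single master seed deterministically derives an
independent substream per source of randomness (truth, each grader's grades,
each grader's quality flags, the automated grader, image counts), so adding a
grader does not perturb the other streams.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .consensus import AgreementClass3
from .grades import LATERALITIES

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "SimulatedDataset",
    "simulate_dataset",
    "analytic_kappa",
    "expected_agreement_frequencies",
    "banded_confusion",
    "default_config",
]

def banded_confusion(diagonal: float, k: int = 5) -> np.ndarray:
    """A row-stochastic confusion matrix confining errors to adjacent severity levels.

    Each row puts ``diagonal`` mass on the true level and splits the remainder
    equally between the neighbouring levels (edge rows give it all to their
    single neighbour).  A convenient one-parameter family of plausible ordinal
    graders.
    """
    if not 0.0 < diagonal <= 1.0:
        raise ValueError(f"diagonal mass must be in (0, 1], got {diagonal}")
    m = np.zeros((k, k))
    off = 1.0 - diagonal
    for t in range(k):
        m[t, t] = diagonal
        neighbours = [j for j in (t - 1, t + 1) if 0 <= j < k]
        for j in neighbours:
            m[t, j] += off / len(neighbours)
    return m


def _as_prob_vector(v, name: str, length: int) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.shape != (length,):
        raise ValueError(f"{name} must have length {length}, got shape {arr.shape}")
    if (arr < 0).any() or (arr > 1).any():
        raise ValueError(f"{name} entries must be probabilities in [0, 1]")
    if abs(arr.sum() - 1.0) > 1e-6:
        raise ValueError(f"{name} must sum to 1, got {arr.sum()}")
    return arr / arr.sum()


def _as_confusion(m, name: str, k: int) -> np.ndarray:
    arr = np.asarray(m, dtype=float)
    if arr.shape != (k, k):
        raise ValueError(f"{name} must be {k}x{k}, got shape {arr.shape}")
    for t in range(k):
        _as_prob_vector(arr[t], f"{name} row {t}", k)
    return arr / arr.sum(axis=1, keepdims=True)


def _as_probability(p, name: str) -> float:
    p = float(p)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {p}")
    return p


@dataclass
class SimConfig:
    """Full parameterization of the synthetic grader world.

    Defaults describe a plausible opportunistic screening intake read by three
    untrained retina specialists and a conservatively-tuned automated grader;
    they are a plausibility preset, not fitted to any particular study (real
    grader error structures are outputs of such studies, not published inputs).
    """

    n_patients: int = 495
    prevalence: Sequence[float] = (0.78, 0.11, 0.07, 0.025, 0.015)
    inter_eye_concordance: float = 0.75
    grader_confusions: Mapping[str, np.ndarray] = field(
        default_factory=lambda: {
            "grader1": banded_confusion(0.75),
            "grader2": banded_confusion(0.90),
            "grader3": banded_confusion(0.80),
        }
    )
    quality_fail: Mapping[str, float] = field(
        default_factory=lambda: {"grader1": 0.025, "grader2": 0.025, "grader3": 0.025}
    )
    ai_confusion: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [0.70, 0.15, 0.10, 0.05],
                [0.10, 0.70, 0.15, 0.05],
                [0.05, 0.10, 0.75, 0.10],
                [0.02, 0.03, 0.15, 0.80],
            ]
        )
    )
    ai_ungradable: float = 0.15
    images_per_eye: tuple[int, int] = (2, 3)
    adjudication_policy: str = "truth"
    seed: int = 0

    def validate(self) -> "SimConfig":
        """Validate every field; raise ValueError before any sampling happens."""
        if not isinstance(self.n_patients, int) or self.n_patients < 1:
            raise ValueError(f"n_patients must be a positive integer, got {self.n_patients!r}")
        self.prevalence = _as_prob_vector(self.prevalence, "prevalence", 5)
        self.inter_eye_concordance = _as_probability(
            self.inter_eye_concordance, "inter_eye_concordance"
        )
        if not self.grader_confusions:
            raise ValueError("at least one grader confusion matrix is required")
        self.grader_confusions = {
            gid: _as_confusion(m, f"grader_confusions[{gid}]", 5)
            for gid, m in self.grader_confusions.items()
        }
        if set(self.quality_fail) != set(self.grader_confusions):
            raise ValueError("quality_fail must cover exactly the graders in grader_confusions")
        self.quality_fail = {
            gid: _as_probability(p, f"quality_fail[{gid}]") for gid, p in self.quality_fail.items()
        }
        self.ai_confusion = _as_confusion(self.ai_confusion, "ai_confusion", 4)
        self.ai_ungradable = _as_probability(self.ai_ungradable, "ai_ungradable")
        lo, hi = self.images_per_eye
        if not (isinstance(lo, int) and isinstance(hi, int) and 1 <= lo <= hi):
            raise ValueError(f"images_per_eye must be an integer range (lo, hi), got {self.images_per_eye!r}")
        self.images_per_eye = (lo, hi)
        if self.adjudication_policy not in ("truth", "grader_median"):
            raise ValueError(
                f"adjudication_policy must be 'truth' or 'grader_median', got {self.adjudication_policy!r}"
            )
        self.seed = int(self.seed)
        return self

    @property
    def grader_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.grader_confusions))

    # -- YAML round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "prevalence": [float(p) for p in np.asarray(self.prevalence, float)],
            "inter_eye_concordance": float(self.inter_eye_concordance),
            "grader_confusions": {
                gid: np.asarray(m, float).tolist() for gid, m in self.grader_confusions.items()
            },
            "quality_fail": {gid: float(p) for gid, p in self.quality_fail.items()},
            "ai_confusion": np.asarray(self.ai_confusion, float).tolist(),
            "ai_ungradable": float(self.ai_ungradable),
            "images_per_eye": [int(self.images_per_eye[0]), int(self.images_per_eye[1])],
            "adjudication_policy": self.adjudication_policy,
            "seed": int(self.seed),
        }

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "images_per_eye" in d:
            d["images_per_eye"] = tuple(d["images_per_eye"])
        return cls(**d).validate()

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_config(n_patients: int = 495, seed: int = 0) -> SimConfig:
    """The default plausibility preset with a chosen size and seed."""
    return SimConfig(n_patients=n_patients, seed=seed).validate()


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth behind a simulated dataset.

    One row per patient: true 5-point grade per eye and the true 4-point
    patient grade (compressed maximum over eyes).
    """

    patients: pd.DataFrame  # patient_id, true_od, true_os, true_patient_grade4

    def eye_grade(self, patient_id: str, laterality: str) -> int:
        row = self.patients.set_index("patient_id").loc[patient_id]
        return int(row["true_od" if laterality == "OD" else "true_os"])


@dataclass(frozen=True)
class SimulatedDataset:
    """A simulated dataset in the same tidy CSV dialects the analysis reads."""

    config: SimConfig
    grades: pd.DataFrame  # patient_id, laterality, grader_id, grade, n_images
    ai: pd.DataFrame  # patient_id, ai_grade
    adjudications: pd.DataFrame  # patient_id, laterality, final_grade
    truth: SyntheticTruth

    def write(self, out_dir) -> dict[str, Path]:
        """Write grades.csv, ai.csv, adjudications.csv and truth.csv (UNGRADABLE as NA)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, frame in (
            ("grades", self.grades),
            ("ai", self.ai),
            ("adjudications", self.adjudications),
            ("truth", self.truth.patients),
        ):
            path = out / f"{name}.csv"
            frame.to_csv(path, index=False, na_rep="NA")
            paths[name] = path
        return paths


def _stream(seed: int, label: str) -> np.random.Generator:
    """An independent, label-addressed random substream of the master seed."""
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(label.encode())]))


def _categorical(rng: np.random.Generator, probs_rows: np.ndarray) -> np.ndarray:
    """Draw one category per row of a row-stochastic matrix of probabilities."""
    cum = np.cumsum(probs_rows, axis=1)
    u = rng.random(probs_rows.shape[0])
    return (u[:, None] > cum).sum(axis=1)


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Sample a full synthetic dataset; reproducible given ``config.seed``."""
    config.validate()
    n = config.n_patients
    prev = np.asarray(config.prevalence, float)
    pad = max(5, len(str(n)))
    patient_ids = np.array([f"P{i:0{pad}d}" for i in range(1, n + 1)])

    rng_truth = _stream(config.seed, "truth")
    true_od = _categorical(rng_truth, np.tile(prev, (n, 1)))
    fresh_os = _categorical(rng_truth, np.tile(prev, (n, 1)))
    copy_mask = rng_truth.random(n) < config.inter_eye_concordance
    true_os = np.where(copy_mask, true_od, fresh_os)
    true_eye = {"OD": true_od, "OS": true_os}
    true_patient4 = np.minimum(np.maximum(true_od, true_os), 3)

    rng_images = _stream(config.seed, "images")
    lo, hi = config.images_per_eye
    n_images = {lat: rng_images.integers(lo, hi + 1, size=n) for lat in LATERALITIES}

    grade_frames = []
    drawn: dict[tuple[str, str], np.ndarray] = {}
    for gid in config.grader_ids:
        conf = config.grader_confusions[gid]
        rng_g = _stream(config.seed, f"grader:{gid}")
        rng_q = _stream(config.seed, f"quality:{gid}")
        for lat in LATERALITIES:
            g = _categorical(rng_g, conf[true_eye[lat]])
            drawn[(gid, lat)] = g
            fail = rng_q.random(n) < config.quality_fail[gid]
            grade_col = pd.array(g, dtype="Int64")
            grade_col[fail] = pd.NA
            grade_frames.append(
                pd.DataFrame(
                    {
                        "patient_id": patient_ids,
                        "laterality": lat,
                        "grader_id": gid,
                        "grade": grade_col,
                        "n_images": n_images[lat],
                    }
                )
            )
    grades = (
        pd.concat(grade_frames, ignore_index=True)
        .sort_values(["patient_id", "laterality", "grader_id"], kind="mergesort")
        .reset_index(drop=True)
    )

    rng_ai = _stream(config.seed, "ai")
    ai_draw = _categorical(rng_ai, config.ai_confusion[true_patient4])
    ai_fail = rng_ai.random(n) < config.ai_ungradable
    ai_col = pd.array(ai_draw, dtype="Int64")
    ai_col[ai_fail] = pd.NA
    ai = pd.DataFrame({"patient_id": patient_ids, "ai_grade": ai_col})

    adj_rows = []
    for lat in LATERALITIES:
        if config.adjudication_policy == "truth":
            final = true_eye[lat]
        else:  # median of the three drawn grades, quality flags ignored
            stacked = np.stack([drawn[(gid, lat)] for gid in config.grader_ids])
            final = np.median(stacked, axis=0).astype(np.int64)
        adj_rows.append(
            pd.DataFrame({"patient_id": patient_ids, "laterality": lat, "final_grade": final})
        )
    adjudications = (
        pd.concat(adj_rows, ignore_index=True)
        .sort_values(["patient_id", "laterality"], kind="mergesort")
        .reset_index(drop=True)
    )

    truth = SyntheticTruth(
        pd.DataFrame(
            {
                "patient_id": patient_ids,
                "true_od": true_od,
                "true_os": true_os,
                "true_patient_grade4": true_patient4,
            }
        )
    )
    return SimulatedDataset(
        config=config, grades=grades, ai=ai, adjudications=adjudications, truth=truth
    )


def analytic_kappa(
    true_dist: Sequence[float],
    confusion_a: np.ndarray,
    confusion_b: np.ndarray | None = None,
) -> float:
    """Exact unweighted Cohen's kappa implied by a truth distribution and two confusion matrices.

    Under conditional independence given the truth, the joint category
    distribution of two raters is P(a=i, b=j) = sum_t pi_t A[t,i] B[t,j]; the
    kappa of that joint distribution is returned.  With ``confusion_b=None``
    the second rater is the truth itself (identity confusion), giving the
    kappa of rater A against the true grades.
    """
    k = len(true_dist)
    pi = _as_prob_vector(true_dist, "true_dist", k)
    a = _as_confusion(confusion_a, "confusion_a", k)
    b = np.eye(k) if confusion_b is None else _as_confusion(confusion_b, "confusion_b", k)
    joint = np.einsum("t,ti,tj->ij", pi, a, b)
    p_o = float(np.trace(joint))
    p_e = float(joint.sum(axis=1) @ joint.sum(axis=0))
    if p_e == 1.0:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def expected_agreement_frequencies(
    config: SimConfig | None = None,
    *,
    true_dist: Sequence[float] | None = None,
    confusions: Sequence[np.ndarray] | None = None,
) -> dict[AgreementClass3, float]:
    """Exact expected proportions of 3:0 / 2:1 / 1:1:1 eyes under the generator.

    Enumerates truth x three grader outcomes (5^4 terms).  Quality flags and
    the inter-eye copy mechanism do not change per-eye marginals, so these are
    also the expected class frequencies among analyzable eyes.  Accepts either
    a three-grader :class:`SimConfig` or explicit (true_dist, confusions).
    """
    if config is not None:
        config.validate()
        if len(config.grader_ids) != 3:
            raise ValueError("3-rater agreement frequencies need exactly three graders")
        pi = np.asarray(config.prevalence, float)
        mats = [config.grader_confusions[g] for g in config.grader_ids]
    else:
        if true_dist is None or confusions is None or len(confusions) != 3:
            raise ValueError("provide a SimConfig or true_dist plus exactly three confusions")
        k = len(true_dist)
        pi = _as_prob_vector(true_dist, "true_dist", k)
        mats = [_as_confusion(m, f"confusion {i}", k) for i, m in enumerate(confusions)]
    k = len(pi)
    joint3 = np.einsum("t,ti,tj,tl->ijl", pi, *mats)
    out = {cls: 0.0 for cls in AgreementClass3}
    for i, j, l in itertools.product(range(k), repeat=3):
        distinct = len({i, j, l})
        cls = (
            AgreementClass3.UNANIMOUS_3_0
            if distinct == 1
            else AgreementClass3.MAJORITY_2_1
            if distinct == 2
            else AgreementClass3.DISCORDANT_1_1_1
        )
        out[cls] += float(joint3[i, j, l])
    return out
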