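"""Study report: the regenerable table set of a multi-grader concordance analysis.

A :class:`StudyReport` bundles everything the analysis computes — the
exclusion flow, final grade distributions, the 3-rater agreement tables at eye
level (overall and per laterality, in eyes and in images), the severity
breakdowns of unanimous and majority decisions, the 4-rater patient-level
taxonomy, the kappa report, and the referable-DR post hoc summary — as plain
JSON-serializable dictionaries.  :func:`render_report` writes one CSV per
table plus a JSON bundle and a human-readable text summary, with deterministic
ordering so regeneration from the same inputs is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any

from .agreement import round_half_up
from .consensus import AgreementClass3, AgreementClass4

__all__ = ["StudyReport", "render_report"]

_A3_ORDER = [c.name for c in AgreementClass3]
_A4_ORDER = [c.name for c in AgreementClass4]
_SCOPES = ("both", "OD", "OS")


@dataclass
class StudyReport:
    """All computed tables of one analysis run, in JSON-serializable form.

    Grade levels and agreement classes are keyed by strings so the report
    round-trips losslessly through JSON.
    """

    exclusion_flow: dict[str, int]
    distribution_5pt_by_eye: dict[str, Any]
    distribution_4pt_by_patient: dict[str, Any]
    agreement3: dict[str, dict[str, dict[str, int]]]
    full_agreement_eyes: dict[str, dict[str, int]]
    full_agreement_patients: dict[str, int]
    majority_eyes: dict[str, dict[str, int]]
    agreement4: dict[str, int]
    kappa: dict[str, Any]
    rdr: dict[str, int]
    n_graders: int = 3
    kappa_weighting: str = "none"
    rdr_cutoff: int = 2

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "StudyReport":
        return cls(**d)

    @classmethod
    def from_json(cls, text: str) -> "StudyReport":
        return cls.from_dict(json.loads(text))

    # -- text summary ------------------------------------------------------
    def summary_text(self) -> str:
        """A statsmodels-style fixed-width text summary of the headline results."""
        lines: list[str] = []
        w = 70
        lines.append("=" * w)
        lines.append("Multi-Grader DR Grading Concordance Analysis".center(w))
        lines.append("=" * w)
        f = self.exclusion_flow
        lines.append(f"Patients total:                {f['n_total']:>6d}")
        lines.append(f"  ungradable by all raters:    {f['n_ungradable_all']:>6d}")
        lines.append(f"  human quality exclusions:    {f['n_excluded_human_quality']:>6d}")
        lines.append(f"  AI-only ungradable:          {f['n_excluded_ai_only_ungradable']:>6d}")
        lines.append(f"  malformed records:           {f['n_incomplete']:>6d}")
        lines.append(f"Patients analyzed:             {f['n_analyzed']:>6d}")
        lines.append("-" * w)
        lines.append("Eye-level agreement (3 human graders, 5-point scale)")
        both = self.agreement3.get("both", {})
        total_eyes = sum(v["eyes"] for v in both.values()) or 1
        for name in _A3_ORDER:
            if name in both:
                e = both[name]["eyes"]
                lines.append(
                    f"  {AgreementClass3[name].value:>6s}: {e:>5d} eyes"
                    f" ({round_half_up(100 * e / total_eyes):6.2f}%)"
                    f"  {both[name]['images']:>5d} images"
                )
        lines.append("-" * w)
        lines.append("Patient-level agreement (3 graders + automated, 4-point scale)")
        total_pat = sum(self.agreement4.values()) or 1
        for name in _A4_ORDER:
            if name in self.agreement4:
                c = self.agreement4[name]
                lines.append(
                    f"  {AgreementClass4[name].value:>22s}: {c:>5d}"
                    f" ({round_half_up(100 * c / total_pat):6.2f}%)"
                )
        lines.append("-" * w)
        lines.append(f"Cohen's kappa (weighting: {self.kappa_weighting})")
        for gid, v in self.kappa.get("vs_final", {}).items():
            lines.append(f"  {gid} vs final grades:     {v:6.2f}")
        for gid, v in self.kappa.get("mean_pairwise", {}).items():
            lines.append(f"  {gid} mean pairwise:       {v:6.2f}")
        lines.append("-" * w)
        r = self.rdr
        if r:
            lines.append(f"Referable-DR post hoc (cutoff: grade >= {self.rdr_cutoff})")
            lines.append(
                f"  eyes: {r['eye_full_agreement']} full agreement, {r['eye_majority']} majority"
            )
            lines.append(
                f"  patients: {r['patient_full_agreement']} full agreement,"
                f" {r['patient_majority']} majority"
            )
            lines.append(
                f"  AI vs 2:1 patients: with majority {r['majority_ai_with_majority']},"
                f" against {r['majority_ai_against_majority']}"
            )
            lines.append(
                f"  AI vs unanimous patients: {r['full_agreement_ai_disagreements']} disagreements"
                f" ({r['ai_referable_disagreements']} AI-referable,"
                f" {r['ai_nonreferable_disagreements']} AI-non-referable)"
            )
        lines.append("=" * w)
        return "\n".join(lines) + "\n"


def _write_csv(path: Path, header: list[str], rows: list[list]) -> None:
    text = ",".join(header) + "\n"
    for row in rows:
        text += ",".join(str(v) for v in row) + "\n"
    path.write_text(text)


def render_report(report: StudyReport, out_dir) -> dict[str, Path]:
    """Write one CSV per report table plus report.json and summary.txt.

    Output is deterministic: fixed column order, fixed row order, sorted JSON
    keys — rerunning on the same inputs produces byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def csv(name: str, header: list[str], rows: list[list]) -> None:
        path = out / f"{name}.csv"
        _write_csv(path, header, rows)
        paths[name] = path

    csv(
        "exclusion_flow",
        ["category", "patients"],
        [[k, v] for k, v in report.exclusion_flow.items()],
    )
    for name, dist in (
        ("distribution_eye_5pt", report.distribution_5pt_by_eye),
        ("distribution_patient_4pt", report.distribution_4pt_by_patient),
    ):
        rows = [
            [level, dist["counts"][level], f"{dist['percentages'][level]:.2f}"]
            for level in sorted(dist["counts"], key=int)
        ]
        rows.append(["total", dist["total"], ""])
        csv(name, ["grade", "count", "percentage"], rows)
    csv(
        "agreement3",
        ["scope", "pattern", "eyes", "images"],
        [
            [scope, name, report.agreement3[scope][name]["eyes"], report.agreement3[scope][name]["images"]]
            for scope in _SCOPES
            if scope in report.agreement3
            for name in _A3_ORDER
            if name in report.agreement3[scope]
        ],
    )
    csv(
        "full_agreement_eyes",
        ["grade", "eyes", "images"],
        [
            [g, report.full_agreement_eyes[g]["eyes"], report.full_agreement_eyes[g]["images"]]
            for g in sorted(report.full_agreement_eyes, key=int)
        ],
    )
    csv(
        "full_agreement_patients",
        ["grade", "patients"],
        [[g, report.full_agreement_patients[g]] for g in sorted(report.full_agreement_patients, key=int)],
    )
    csv(
        "majority_eyes",
        ["grade", "eyes", "images"],
        [
            [g, report.majority_eyes[g]["eyes"], report.majority_eyes[g]["images"]]
            for g in sorted(report.majority_eyes, key=int)
        ],
    )
    csv(
        "agreement4",
        ["pattern", "patients"],
        [[name, report.agreement4[name]] for name in _A4_ORDER if name in report.agreement4],
    )
    kappa_rows: list[list] = []
    for gid in sorted(report.kappa.get("vs_final", {})):
        kappa_rows.append(["vs_final", gid, "", f"{report.kappa['vs_final'][gid]:.6f}"])
    for pair in sorted(report.kappa.get("pairwise", {})):
        a, b = pair.split("|")
        kappa_rows.append(["pairwise", a, b, f"{report.kappa['pairwise'][pair]:.6f}"])
    for gid in sorted(report.kappa.get("mean_pairwise", {})):
        kappa_rows.append(["mean_pairwise", gid, "", f"{report.kappa['mean_pairwise'][gid]:.6f}"])
    csv("kappa", ["kind", "grader_a", "grader_b", "kappa"], kappa_rows)
    csv("rdr", ["metric", "value"], [[k, v] for k, v in report.rdr.items()])

    bundle = out / "report.json"
    bundle.write_text(report.to_json())
    paths["report_json"] = bundle
    summary = out / "summary.txt"
    summary.write_text(report.summary_text())
    paths["summary"] = summary
    return paths
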