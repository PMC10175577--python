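"""Reproducible simulate -> analyze -> report pipeline.

Every run is a pure function of (config, seed): the simulator writes
byte-deterministic CSVs, the analyzer consumes only those files, and the
report renders only the analyzer's outputs, so re-running any stage with
the same inputs reproduces its artifacts exactly.  A JSON manifest
records the config hash, seed, package version, per-file row counts and
the exclusion log, making every dropped participant auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import CohortConfig, simulate_cohort, write_cohort
from .study import TrainingStudy

__all__ = ["StudyConfig", "cmd_simulate", "cmd_analyze", "cmd_report"]


@dataclass(frozen=True)
class StudyConfig:
    """Cohort settings plus analysis switches; YAML/JSON serialisable."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    fdr_family: str = "per-effect"
    outlier_sensitivity: bool = True

    def to_dict(self) -> dict:
        return {"cohort": dataclasses.asdict(self.cohort),
                "fdr_family": self.fdr_family,
                "outlier_sensitivity": self.outlier_sensitivity}

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        cohort_d = dict(d.pop("cohort", {}))
        valid = {f.name for f in dataclasses.fields(CohortConfig)}
        bad = sorted(set(cohort_d) - valid)
        top_valid = {"cohort", "fdr_family", "outlier_sensitivity"}
        bad += sorted(set(d) - top_valid)
        if bad:
            raise ValueError(f"unknown config keys: {bad}")
        return cls(cohort=CohortConfig(**cohort_d), **d)

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML superset also parses JSON
        return cls.from_dict(data or {})

    def with_seed(self, seed: int) -> "StudyConfig":
        return dataclasses.replace(
            self, cohort=dataclasses.replace(self.cohort, seed=seed))

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_manifest(out: Path, config: StudyConfig, stage: str,
                    row_counts: dict[str, int],
                    exclusions: list[dict] | None = None) -> Path:
    manifest = {
        "stage": stage,
        "package_version": __version__,
        "config_hash": config.hash(),
        "seed": config.cohort.seed,
        "row_counts": row_counts,
        "exclusions": exclusions if exclusions is not None else [],
    }
    f = out / f"manifest_{stage}.json"
    f.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return f


def cmd_simulate(config: StudyConfig, out: str | Path) -> dict[str, Path]:
    """Simulate a cohort and write participants.csv / sessions.csv."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(config.cohort)
    files = write_cohort(cohort, out)
    counts = {name: len(pd.read_csv(f)) for name, f in files.items()}
    files["manifest"] = _write_manifest(out, config, "simulate", counts)
    return files


def cmd_analyze(data_dir: str | Path, config: StudyConfig,
                out: str | Path) -> dict[str, Path]:
    """Run the full analysis of a simulated (or adapted) cohort directory."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    study = TrainingStudy.from_csv(
        data_dir, fdr_family=config.fdr_family,
        outlier_sensitivity=config.outlier_sensitivity)
    res = study.fit()

    files: dict[str, Path] = {}

    def save(name: str, frame: pd.DataFrame) -> None:
        f = out / f"{name}.csv"
        frame.to_csv(f, index=False, float_format="%.10g",
                     lineterminator="\n")
        files[name] = f

    save("baseline", res.baseline)
    for task, table in res.training_anovas.items():
        save(f"training_anova_{task}", table)
    for task, table in res.training_followups.items():
        save(f"training_followups_{task}", table)
    for task, table in res.sequential.items():
        save(f"sequential_{task}", table)
    for task, table in res.spline_comparison.items():
        save(f"spline_comparison_{task}", table)
    for measure, table in res.transfer_anovas.items():
        save(f"transfer_anova_{measure}", table)
    for measure, table in res.sensitivity.items():
        if table is not None:
            save(f"sensitivity_{measure}", table)
    for col, table in res.likert.items():
        save(f"anova_{col}", table)
    save("attrition_groups", res.attrition["per_group"])
    save("consistency", res.consistency)
    save("exclusions", res.exclusions)

    summary = {
        "attrition": {k: v for k, v in res.attrition.items()
                      if k != "per_group"},
        "questionnaire": res.questionnaire,
        "first_significant_session": {
            task: res.first_significant_session(task)
            for task in res.sequential},
        "notes": res.notes,
    }
    f = out / "analysis_summary.json"
    f.write_text(json.dumps(summary, indent=2, sort_keys=True,
                            default=float) + "\n")
    files["analysis_summary"] = f
    counts = {n: len(pd.read_csv(p)) for n, p in files.items()
              if p.suffix == ".csv"}
    files["manifest"] = _write_manifest(
        out, config, "analyze", counts,
        exclusions=res.exclusions.to_dict("records"))
    return files


REPORT_REQUIRED = ("analysis_summary.json", "exclusions.csv",
                   "consistency.csv")


def _md_table(frame: pd.DataFrame, floatfmt: str = "{:.3f}") -> str:
    if frame.empty:
        return "_(empty)_"
    show = frame.copy()
    for c in show.columns:
        if pd.api.types.is_float_dtype(show[c]):
            show[c] = show[c].map(
                lambda v: "" if pd.isna(v) else floatfmt.format(v))
    header = "| " + " | ".join(map(str, show.columns)) + " |"
    sep = "|" + "|".join(["---"] * len(show.columns)) + "|"
    body = ["| " + " | ".join(map(str, r)) + " |"
            for r in show.itertuples(index=False)]
    return "\n".join([header, sep] + body)


def cmd_report(results_dir: str | Path,
               out: str | Path | None = None) -> str:
    """Render the analysis bundle as a markdown report (idempotent)."""
    results_dir = Path(results_dir)
    missing = [n for n in REPORT_REQUIRED
               if not (results_dir / n).exists()]
    if missing:
        raise FileNotFoundError(
            f"incomplete results bundle, missing: {missing}")
    summary = json.loads((results_dir / "analysis_summary.json").read_text())

    lines = ["# Working-memory training study report", ""]

    def section(title: str, stem: str) -> None:
        f = results_dir / f"{stem}.csv"
        if f.exists():
            lines.extend([f"## {title}", "", _md_table(pd.read_csv(f)), ""])

    section("Baseline comparability", "baseline")
    for task in ("verbal", "spatial"):
        section(f"{task.capitalize()} n-back: treatment x schedule x "
                "session ANOVA", f"training_anova_{task}")
        section(f"{task.capitalize()} n-back: follow-up t-tests",
                f"training_followups_{task}")
        section(f"{task.capitalize()} n-back: sequential S1-vs-SN ANOVAs "
                "(FDR-corrected)", f"sequential_{task}")
        section(f"{task.capitalize()} n-back: learning-curve comparison",
                f"spline_comparison_{task}")
    for measure, label in (("dsf", "Digit span forward"),
                           ("dsb", "Digit span backward"),
                           ("rr", "Relational reasoning")):
        section(f"Transfer: {label}", f"transfer_anova_{measure}")
        section(f"Sensitivity rerun (outliers removed): {label}",
                f"sensitivity_{measure}")

    lines.append("## Attrition and acceptability")
    lines.append("")
    att = summary.get("attrition", {})
    if att:
        lines.append(
            f"{att.get('overall_not_completed')} of "
            f"{att.get('overall_assigned')} participants did not complete "
            f"the intervention: attrition rate "
            f"{att.get('overall_rate_pct', float('nan')):.2f}% "
            f"(chi-square = {att.get('chi2', float('nan')):.2f}, "
            f"p = {att.get('chi2_p', float('nan')):.3f}).")
        lines.append("")
    f = results_dir / "attrition_groups.csv"
    if f.exists():
        lines.extend([_md_table(pd.read_csv(f)), ""])
    q = summary.get("questionnaire", {})
    if q:
        pct = 100.0 * q["responders"] / q["completers"]
        lines.append(f"Questionnaire: {q['responders']} of "
                     f"{q['completers']} completers responded "
                     f"({pct:.0f}%).")
        lines.append("")
    fss = summary.get("first_significant_session", {})
    if fss:
        lines.append("## Learning onset")
        lines.append("")
        for task, n in fss.items():
            txt = (f"session {n}" if n else
                   "no FDR-significant improvement")
            lines.append(f"- {task} n-back: first FDR-significant "
                         f"improvement over session 1 at {txt}.")
        lines.append("")
    lines.append("## Consistency checks")
    lines.append("")
    lines.append(_md_table(pd.read_csv(results_dir / "consistency.csv")))
    lines.append("")
    lines.append("## Exclusions")
    lines.append("")
    lines.append(_md_table(pd.read_csv(results_dir / "exclusions.csv")))
    lines.append("")
    if summary.get("notes"):
        lines.append("## Notes")
        lines.append("")
        lines.extend(f"- {n}" for n in summary["notes"])
        lines.append("")

    text = "\n".join(lines)
    if out is not None:
        Path(out).write_text(text)
    return text
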