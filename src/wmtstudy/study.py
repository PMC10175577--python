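"""Study-level model: the full analysis of one (real or simulated) cohort.

``TrainingStudy`` is built from the two tidy data frames the generator
writes (participants, sessions); ``fit()`` runs the complete analysis and
returns a ``TrainingStudyResults`` carrying every table:

* baseline comparability across the four arms,
* per-task 2 (treatment) x 2 (schedule) x 2 (session: first/last) mixed
  ANOVAs of the training outcome, with follow-up t-tests gated on a
  significant treatment-by-session interaction,
* the sequential S1-vs-SN ANOVAs with FDR correction (Step 1),
* per-participant one-knot spline fits and their between-schedule
  Mann-Whitney comparison (Step 2),
* 2 x 2 x 2 mixed ANOVAs of the three transfer measures, with
  sensitivity reruns excluding extreme (3*IQR) outliers,
* attrition rates with a chi-square test, and Likert acceptability
  ANOVAs,
* an exclusion log accounting for every input participant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as co
from . import learning as ld
from . import stats as st

__all__ = ["TrainingStudy", "TrainingStudyResults", "attrition_rate"]

ALPHA = 0.05
TRANSFER_MEASURES = ("dsf", "dsb", "rr")


def attrition_rate(n_assigned: int, n_not_completed: int) -> float:
    """Attrition in percent: (did not complete / assigned) x 100."""
    if n_assigned <= 0 or not 0 <= n_not_completed <= n_assigned:
        raise ValueError("invalid counts")
    return 100.0 * n_not_completed / n_assigned
LIKERT_COLS = ("likert_challenging", "likert_engaging", "likert_adopt",
               "likert_schedule")


def _anova_frame(rows: pd.DataFrame, rename: dict[str, str]) -> pd.DataFrame:
    out = rows.copy()
    out["effect"] = out["effect"].map(lambda e: rename.get(e, e))
    return out


class TrainingStudy:
    """Analysis model for one cohort.

    Parameters
    ----------
    participants, sessions : DataFrame
        Tidy frames in the generator's schema (``participants.csv`` /
        ``sessions.csv``).
    fdr_family : str
        ``"per-effect"`` corrects the 15 sequential p-values within each
        effect family; ``"joint"`` corrects all 45 together.
    outlier_sensitivity : bool
        Rerun transfer ANOVAs without extreme outliers when any exist.
    """

    REQUIRED_PARTICIPANT_COLS = (
        "participant", "schedule", "treatment", "completed",
        "dsf_pre", "dsf_post", "dsb_pre", "dsb_post", "rr_pre", "rr_post")
    REQUIRED_SESSION_COLS = (
        "participant", "schedule", "treatment", "task", "session",
        "mean_nback")

    def __init__(self, participants: pd.DataFrame, sessions: pd.DataFrame,
                 fdr_family: str = "per-effect",
                 outlier_sensitivity: bool = True):
        missing = [c for c in self.REQUIRED_PARTICIPANT_COLS
                   if c not in participants.columns]
        missing += [c for c in self.REQUIRED_SESSION_COLS
                    if c not in sessions.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        self.participants = participants.reset_index(drop=True)
        self.sessions = sessions.reset_index(drop=True)
        self.fdr_family = fdr_family
        self.outlier_sensitivity = outlier_sensitivity

    @classmethod
    def from_cohort(cls, cohort: co.Cohort, **kw) -> "TrainingStudy":
        return cls(cohort.participants_frame(), cohort.sessions_frame(), **kw)

    @classmethod
    def from_csv(cls, directory: str | Path, **kw) -> "TrainingStudy":
        participants, sessions = co.read_cohort(directory)
        return cls(participants, sessions, **kw)

    # ---------------------------------------------------------------- fit

    def fit(self) -> "TrainingStudyResults":
        res = TrainingStudyResults(model=self)
        self._baseline(res)
        for task in co.TASKS:
            self._training_anova(res, task)
            self._sequential(res, task)
            self._splines(res, task)
        for measure in TRANSFER_MEASURES:
            self._transfer(res, measure)
        self._attrition(res)
        self._likert(res)
        self._consistency(res)
        res.exclusions = (pd.DataFrame(
            res._exclusion_rows,
            columns=["participant", "analysis", "reason"])
            if res._exclusion_rows else
            pd.DataFrame(columns=["participant", "analysis", "reason"]))
        return res

    # ------------------------------------------------------------ stages

    def _baseline(self, res: "TrainingStudyResults") -> None:
        """One-way ANOVA / chi-square comparability checks across arms."""
        p = self.participants
        groups = sorted((p["schedule"] + "-" + p["treatment"]).unique())
        key = p["schedule"] + "-" + p["treatment"]
        rows = []

        def anova_row(variable: str, values: pd.Series) -> None:
            by = [values[(key == g) & values.notna()].to_numpy(dtype=float)
                  for g in groups]
            if any(len(v) < 2 for v in by):
                return
            r = st.oneway_anova(by)
            rows.append({"variable": variable, "test": "one-way ANOVA",
                         "statistic": r.F, "df1": r.df1, "df2": r.df2,
                         "p": r.p})

        if "age" in p.columns:
            anova_row("age", p["age"])
        if "sex" in p.columns and p["sex"].nunique() > 1:
            table = pd.crosstab(p["sex"], key).to_numpy()
            chi2, df, pv = st.chi_square_independence(table)
            rows.append({"variable": "sex", "test": "chi-square",
                         "statistic": chi2, "df1": df, "df2": np.nan,
                         "p": pv})
        for m in TRANSFER_MEASURES:
            anova_row(f"{m}_pre", p[f"{m}_pre"])
        s1 = self.sessions[self.sessions["session"] == 1]
        for task in co.TASKS:
            sub = s1[s1["task"] == task].set_index("participant")["mean_nback"]
            aligned = p["participant"].map(sub)
            anova_row(f"{task}_nback_s1", aligned)
        res.baseline = pd.DataFrame(rows)

    def _training_data(self, task: str) -> tuple[pd.DataFrame, list[str]]:
        """S1/S16 long frame for one task plus ids lacking either session."""
        data = self.sessions[(self.sessions["task"] == task)
                             & (self.sessions["session"].isin([1, 16]))].copy()
        data = data.dropna(subset=["mean_nback"])
        counts = data.groupby("participant")["session"].nunique()
        complete = counts[counts == 2].index
        dropped = sorted(set(self.participants["participant"])
                         - set(complete))
        return data[data["participant"].isin(complete)], dropped

    def _training_anova(self, res: "TrainingStudyResults",
                        task: str) -> None:
        data, dropped = self._training_data(task)
        for pid in dropped:
            res.log_exclusion(pid, f"training_anova_{task}",
                              "missing first or final session")
        data = data.assign(
            session_lvl=np.where(data["session"] == 1, "a_first", "b_final"))
        table = st.mixed_anova(data, dv="mean_nback", within="session_lvl",
                               subject="participant",
                               between=["treatment", "schedule"])
        rename = {"session_lvl": "session",
                  "treatment:session_lvl": "treatment:session",
                  "schedule:session_lvl": "schedule:session",
                  "treatment:schedule:session_lvl":
                      "treatment:schedule:session"}
        res.training_anovas[task] = _anova_frame(table, rename)
        inter = res.training_anovas[task].query(
            "effect == 'treatment:session'")["p"].iloc[0]
        if inter < ALPHA:
            res.training_followups[task] = self._followups(data)

    def _followups(self, data: pd.DataFrame) -> pd.DataFrame:
        """The four follow-up t-tests on a significant interaction."""
        wide = data.pivot_table(index=["participant", "treatment"],
                                columns="session_lvl",
                                values="mean_nback").reset_index()
        wmt = wide[wide["treatment"] == "WMT"]
        ctl = wide[wide["treatment"] == "active-control"]
        rows = []
        for label, x, y, paired in (
                ("final: WMT vs control", wmt["b_final"], ctl["b_final"],
                 False),
                ("first: WMT vs control", wmt["a_first"], ctl["a_first"],
                 False),
                ("WMT: final vs first", wmt["b_final"], wmt["a_first"], True),
                ("control: final vs first", ctl["b_final"], ctl["a_first"],
                 True)):
            r = st.t_test(x.to_numpy(), y.to_numpy(), paired=paired)
            rows.append({"comparison": label, "t": r.t, "df": r.df,
                         "p": r.p, "g": r.g})
        return pd.DataFrame(rows)

    def _wmt_sessions(self, task: str) -> pd.DataFrame:
        s = self.sessions
        return s[(s["treatment"] == "WMT") & (s["task"] == task)]

    def _sequential(self, res: "TrainingStudyResults", task: str) -> None:
        data = self._wmt_sessions(task)
        try:
            res.sequential[task] = ld.sequential_session_anovas(
                data, task, fdr_family=self.fdr_family)
        except ValueError as err:
            res.sequential[task] = pd.DataFrame()
            res.notes.append(f"sequential ANOVAs skipped for {task}: {err}")

    def _splines(self, res: "TrainingStudyResults", task: str) -> None:
        data = self._wmt_sessions(task)
        fits: dict[str, list[ld.SplineFit]] = {s: [] for s in co.SCHEDULES}
        for pid, grp in data.groupby("participant"):
            grp = grp.sort_values("session")
            vals = grp["mean_nback"].to_numpy(dtype=float)
            if len(vals) != ld.N_SESSIONS or not np.all(np.isfinite(vals)):
                res.log_exclusion(pid, f"spline_{task}",
                                  "incomplete training series")
                continue
            try:
                fit = ld.LearningCurveModel(vals, participant=str(pid)).fit()
            except ld.FlatSeriesError:
                res.log_exclusion(pid, f"spline_{task}",
                                  "flat series, no knot selectable")
                continue
            fits[grp["schedule"].iloc[0]].append(fit.spline)
        res.spline_fits[task] = fits
        if all(len(v) >= 2 for v in fits.values()):
            res.spline_comparison[task] = ld.compare_learning_parameters(
                fits["distributed"], fits["intensive"],
                labels=("distributed", "intensive"))
        else:
            res.spline_comparison[task] = pd.DataFrame()
            res.notes.append(f"spline comparison skipped for {task}: "
                             "fewer than two fits in a schedule group")

    def _transfer_long(self, measure: str) -> tuple[pd.DataFrame, list[str]]:
        p = self.participants
        ok = p[[f"{measure}_pre", f"{measure}_post"]].notna().all(axis=1)
        dropped = sorted(p.loc[~ok, "participant"])
        sub = p[ok]
        long = pd.concat([
            sub.assign(session="a_pre", score=sub[f"{measure}_pre"]),
            sub.assign(session="b_post", score=sub[f"{measure}_post"]),
        ], ignore_index=True)
        return long[["participant", "treatment", "schedule", "session",
                     "score"]], dropped

    def _transfer(self, res: "TrainingStudyResults", measure: str) -> None:
        long, dropped = self._transfer_long(measure)
        for pid in dropped:
            res.log_exclusion(pid, f"transfer_{measure}",
                              "missing pre or post score")
        rename = {"session": "session",
                  "treatment:session": "treatment:session",
                  "schedule:session": "schedule:session",
                  "treatment:schedule:session": "treatment:schedule:session"}
        table = st.mixed_anova(long, dv="score", within="session",
                               subject="participant",
                               between=["treatment", "schedule"])
        res.transfer_anovas[measure] = _anova_frame(table, rename)
        if self.outlier_sensitivity:
            self._sensitivity(res, measure, long)

    def _sensitivity(self, res: "TrainingStudyResults", measure: str,
                     long: pd.DataFrame) -> None:
        """Rerun the ANOVA without participants scoring as 3*IQR outliers
        on either the pre or the post distribution."""
        flagged: set[str] = set()
        for lvl in ("a_pre", "b_post"):
            vals = long[long["session"] == lvl]
            report = st.extreme_outliers(vals["score"].to_numpy())
            flagged |= set(vals.iloc[list(report.indices)]["participant"])
        if not flagged:
            res.sensitivity[measure] = None
            return
        kept = long[~long["participant"].isin(flagged)]
        table = st.mixed_anova(kept, dv="score", within="session",
                               subject="participant",
                               between=["treatment", "schedule"])
        table = table.assign(excluded=", ".join(sorted(flagged)))
        res.sensitivity[measure] = table

    def _attrition(self, res: "TrainingStudyResults") -> None:
        p = self.participants
        key = p["schedule"] + "-" + p["treatment"]
        per_group = []
        for g in sorted(key.unique()):
            sub = p[key == g]
            assigned = len(sub)
            not_completed = int((~sub["completed"].astype(bool)).sum())
            per_group.append({
                "group": g, "assigned": assigned,
                "not_completed": not_completed,
                "attrition_rate_pct": attrition_rate(assigned,
                                                     not_completed)})
        overall_assigned = len(p)
        overall_nc = int((~p["completed"].astype(bool)).sum())
        table = pd.crosstab(p["completed"].astype(bool), key).to_numpy()
        if table.shape[0] < 2:  # nobody (or everybody) dropped out
            chi2, df, pv = np.nan, 0, np.nan
        else:
            chi2, df, pv = st.chi_square_independence(table)
        res.attrition = {
            "per_group": pd.DataFrame(per_group),
            "overall_assigned": overall_assigned,
            "overall_not_completed": overall_nc,
            "overall_rate_pct": attrition_rate(overall_assigned, overall_nc),
            "chi2": chi2, "chi2_df": df, "chi2_p": pv,
        }

    def _likert(self, res: "TrainingStudyResults") -> None:
        p = self.participants
        if "questionnaire_completed" not in p.columns:
            return
        q = p[p["questionnaire_completed"].astype(bool)]
        res.questionnaire = {
            "completers": len(self.participants[
                self.participants["completed"].astype(bool)]),
            "responders": len(q),
        }
        for col in LIKERT_COLS:
            if col not in p.columns or q[col].isna().all():
                continue
            try:
                res.likert[col] = st.between_anova(
                    q, dv=col, between=["treatment", "schedule"])
            except Exception as err:  # degenerate cells in tiny cohorts
                res.notes.append(f"likert ANOVA skipped for {col}: {err}")

    def _consistency(self, res: "TrainingStudyResults") -> None:
        """Cross-checks mirroring the exclusion-accounting discipline."""
        checks = []
        p = self.participants
        completers = p[p["completed"].astype(bool)]
        if "date" in self.sessions.columns:
            bad = []
            for pid, grp in self.sessions[
                    self.sessions["participant"].isin(
                        completers["participant"])].groupby("participant"):
                dates = sorted({date.fromisoformat(d)
                                for d in grp["date"] if isinstance(d, str)
                                and d})
                sched = grp["schedule"].iloc[0]
                if dates and not co.validate_schedule(dates, sched).valid:
                    bad.append(str(pid))
            checks.append({"check": "completer calendars schedule-valid",
                           "ok": not bad,
                           "detail": ", ".join(bad) if bad else ""})
        n_rows = len(self.sessions)
        expected = len(p) * len(co.TASKS) * co.N_SESSIONS
        checks.append({"check": "session table has one row per "
                               "participant x task x session",
                       "ok": n_rows == expected,
                       "detail": f"{n_rows} rows, expected {expected}"})
        res.consistency = pd.DataFrame(checks)


@dataclass
class TrainingStudyResults:
    """Container for every fitted table; see :class:`TrainingStudy`."""

    model: TrainingStudy
    baseline: pd.DataFrame = field(default_factory=pd.DataFrame)
    training_anovas: dict = field(default_factory=dict)
    training_followups: dict = field(default_factory=dict)
    sequential: dict = field(default_factory=dict)
    spline_fits: dict = field(default_factory=dict)
    spline_comparison: dict = field(default_factory=dict)
    transfer_anovas: dict = field(default_factory=dict)
    sensitivity: dict = field(default_factory=dict)
    attrition: dict = field(default_factory=dict)
    likert: dict = field(default_factory=dict)
    questionnaire: dict = field(default_factory=dict)
    consistency: pd.DataFrame = field(default_factory=pd.DataFrame)
    exclusions: pd.DataFrame = field(default_factory=pd.DataFrame)
    notes: list = field(default_factory=list)
    _exclusion_rows: list = field(default_factory=list)

    def log_exclusion(self, participant, analysis: str, reason: str) -> None:
        self._exclusion_rows.append(
            {"participant": str(participant), "analysis": analysis,
             "reason": reason})

    # ------------------------------------------------------------ output

    def first_significant_session(self, task: str) -> int | None:
        """Smallest N whose S1-vs-SN session effect survives FDR."""
        seq = self.sequential.get(task)
        if seq is None or seq.empty:
            return None
        hits = seq[(seq["effect"] == "session") & (seq["p_fdr"] < ALPHA)]
        return int(hits["N"].min()) if len(hits) else None

    def summary(self) -> str:
        lines = ["Working-memory training study: analysis summary",
                 "=" * 48]
        for task in co.TASKS:
            lines.append(f"\n{task.capitalize()} n-back "
                         "(treatment x schedule x session ANOVA)")
            lines.append(self.training_anovas[task].to_string(
                index=False,
                float_format=lambda v: f"{v:.3f}"))
            if task in self.training_followups:
                lines.append("Follow-up t-tests (interaction significant):")
                lines.append(self.training_followups[task].to_string(
                    index=False, float_format=lambda v: f"{v:.3f}"))
            n1 = self.first_significant_session(task)
            if n1 is not None:
                lines.append(
                    f"First session with FDR-significant improvement over "
                    f"S1: session {n1}")
            comp = self.spline_comparison.get(task)
            if comp is not None and not comp.empty:
                lines.append("Learning-curve comparison "
                             "(Mann-Whitney, distributed vs intensive):")
                lines.append(comp.to_string(
                    index=False, float_format=lambda v: f"{v:.3f}"))
        for measure in TRANSFER_MEASURES:
            lines.append(f"\nTransfer: {measure} "
                         "(treatment x schedule x session ANOVA)")
            lines.append(self.transfer_anovas[measure].to_string(
                index=False, float_format=lambda v: f"{v:.3f}"))
        att = self.attrition
        if att:
            lines.append(
                f"\nAttrition: {att['overall_not_completed']} of "
                f"{att['overall_assigned']} did not complete "
                f"({att['overall_rate_pct']:.2f}%); chi-square = "
                f"{att['chi2']:.2f}, p = {att['chi2_p']:.3f}")
        if self.questionnaire:
            q = self.questionnaire
            pct = 100.0 * q["responders"] / q["completers"]
            lines.append(f"Questionnaire: {q['responders']} of "
                         f"{q['completers']} completers responded "
                         f"({pct:.0f}%)")
        return "\n".join(lines)

    def plot_training_curves(self, ax=None):
        """Group-mean training trajectories per task and treatment arm."""
        import matplotlib.pyplot as plt

        sessions = self.model.sessions
        if ax is None:
            _, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
        else:
            axes = ax
        for axis, task in zip(np.atleast_1d(axes), co.TASKS):
            sub = sessions[sessions["task"] == task]
            for (treat, sched), grp in sub.groupby(
                    ["treatment", "schedule"]):
                means = grp.groupby("session")["mean_nback"].mean()
                axis.plot(means.index, means.values,
                          label=f"{sched}-{treat}")
            axis.set_title(f"{task} n-back")
            axis.set_xlabel("session")
        np.atleast_1d(axes)[0].set_ylabel("mean n-back level")
        np.atleast_1d(axes)[-1].legend(frameon=False, fontsize=8)
        return axes
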