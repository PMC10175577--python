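"""Learning-curve dynamics of the training series.

Two-step analysis of the 16 per-session training outcomes of the trained
participants:

Step 1 - for every later session N (2..16) a 2 x 2 mixed ANOVA contrasts
session 1 with session N (schedule group between, session within); the 15
p-values of each effect family (group, session, interaction) are corrected
with the Benjamini-Hochberg false-discovery-rate procedure.  This locates
the first session at which performance reliably exceeds session 1.

Step 2 - each participant's series is smoothed with the smallest sliding
window (adjacent-pair means, 16 -> 15 points) and fitted with a continuous
one-knot linear spline at every interior knot (data points 2..14); the
knot with the highest R-squared wins (ties go to the earliest knot).  The
first-segment slope (learning rate) and the knot location (onset of
asymptotic-like performance) are compared between schedule groups with
Mann-Whitney U tests.

The spline fit is exposed statsmodels-style: ``LearningCurveModel(series)``
with ``fit()`` / ``fit(knot=k)`` returning a ``LearningCurveResults``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import bh_fdr, hedges_g, mann_whitney_u, mixed_anova

__all__ = [
    "SmoothedSeries",
    "SplineFit",
    "FlatSeriesError",
    "LearningCurveModel",
    "LearningCurveResults",
    "smooth_series",
    "fit_spline_at_knot",
    "select_best_knot",
    "compare_learning_parameters",
    "sequential_session_anovas",
]

N_SESSIONS = 16
KNOT_RANGE = range(2, 15)  # interior data points of the 15-point series


class FlatSeriesError(ValueError):
    """A zero-variance series admits no knot selection."""


@dataclass(frozen=True)
class SmoothedSeries:
    """Adjacent-pair means of one participant's 16 session outcomes."""

    participant: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != N_SESSIONS - 1:
            raise ValueError("smoothed series must have 15 points")


@dataclass(frozen=True)
class SplineFit:
    """A continuous one-knot piecewise-linear OLS fit.

    ``slope1``/``slope2`` are the segment slopes in load-level units per
    data point; ``r_squared`` is None for a flat (zero-variance) series.
    """

    knot_index: int
    intercept: float
    slope1: float
    slope2: float
    r_squared: float | None

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        hinge = np.maximum(0.0, t - self.knot_index)
        return (self.intercept + self.slope1 * t
                + (self.slope2 - self.slope1) * hinge)


def smooth_series(raw, participant: str = "") -> SmoothedSeries:
    """Sliding-window (adjacent-pair) smoothing: 16 outcomes -> 15 means."""
    v = np.asarray(raw, dtype=float)
    if v.shape != (N_SESSIONS,) or not np.all(np.isfinite(v)):
        raise ValueError("need exactly 16 finite session outcomes")
    sm = (v[:-1] + v[1:]) / 2.0
    return SmoothedSeries(participant=participant,
                          values=tuple(float(x) for x in sm))


def fit_spline_at_knot(points: SmoothedSeries, k: int) -> SplineFit:
    """OLS fit of the smoothed series on the basis {1, t, max(0, t-k)}.

    ``t`` runs 1..15 (1-based data-point number).  slope1 is the
    coefficient of t, slope2 adds the hinge coefficient, and R-squared is
    1 - SS_res/SS_tot, undefined (None) for a zero-variance series.
    """
    if k not in KNOT_RANGE:
        raise ValueError(f"knot must lie in {KNOT_RANGE}, got {k}")
    y = np.asarray(points.values, dtype=float)
    t = np.arange(1, len(y) + 1, dtype=float)
    X = np.column_stack([np.ones_like(t), t, np.maximum(0.0, t - k)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = None if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return SplineFit(knot_index=k, intercept=float(beta[0]),
                     slope1=float(beta[1]),
                     slope2=float(beta[1] + beta[2]), r_squared=r2)


def select_best_knot(points: SmoothedSeries) -> SplineFit:
    """Fit every interior knot (2..14) and keep the highest R-squared.

    Ties break toward the smallest knot.  A flat series raises
    :class:`FlatSeriesError` (the participant is excluded upstream).
    """
    best: SplineFit | None = None
    for k in KNOT_RANGE:
        fit = fit_spline_at_knot(points, k)
        if fit.r_squared is None:
            raise FlatSeriesError(
                f"participant {points.participant!r}: zero-variance series")
        if best is None or fit.r_squared > best.r_squared:
            best = fit
    assert best is not None
    return best


class LearningCurveModel:
    """One participant's learning curve as a fittable model.

    Parameters
    ----------
    series : array-like
        Either the 16 raw session outcomes (smoothed internally) or a
        pre-smoothed :class:`SmoothedSeries`.
    """

    def __init__(self, series, participant: str = ""):
        if isinstance(series, SmoothedSeries):
            self.smoothed = series
        else:
            self.smoothed = smooth_series(series, participant=participant)

    def fit(self, knot: int | None = None) -> "LearningCurveResults":
        """Fit at a fixed knot, or search knots 2..14 for the best fit."""
        if knot is None:
            best = select_best_knot(self.smoothed)
        else:
            best = fit_spline_at_knot(self.smoothed, knot)
        return LearningCurveResults(self, best)


@dataclass(frozen=True)
class LearningCurveResults:
    model: LearningCurveModel
    spline: SplineFit

    @property
    def knot_index(self) -> int:
        return self.spline.knot_index

    @property
    def slope1(self) -> float:
        return self.spline.slope1

    @property
    def slope2(self) -> float:
        return self.spline.slope2

    @property
    def rsquared(self) -> float | None:
        return self.spline.r_squared

    def fittedvalues(self) -> np.ndarray:
        t = np.arange(1, len(self.model.smoothed.values) + 1)
        return self.spline.predict(t)

    def summary(self) -> str:
        s = self.spline
        r2 = "undefined" if s.r_squared is None else f"{s.r_squared:.4f}"
        return ("One-knot linear spline fit\n"
                f"  knot location : data point {s.knot_index}\n"
                f"  first slope   : {s.slope1:+.4f} level/point\n"
                f"  second slope  : {s.slope2:+.4f} level/point\n"
                f"  R-squared     : {r2}")

    def plot(self, ax=None):
        """Plot the smoothed series with the fitted spline and knot."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        y = self.model.smoothed.values
        t = np.arange(1, len(y) + 1)
        ax.plot(t, y, "o", color="0.4", label="smoothed outcome")
        ax.plot(t, self.fittedvalues(), "-", color="C3", label="spline fit")
        ax.axvline(self.knot_index, ls=":", color="C3", alpha=0.7)
        ax.set_xlabel("data point (adjacent-session pair)")
        ax.set_ylabel("mean n-back level")
        ax.legend(frameon=False)
        return ax


def _describe(values: np.ndarray) -> dict[str, float]:
    return {"mean": float(np.mean(values)),
            "sd": float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
            "median": float(np.median(values))}


def compare_learning_parameters(fits_a: list[SplineFit],
                                fits_b: list[SplineFit],
                                labels: tuple[str, str] = ("groupA", "groupB"),
                                ) -> pd.DataFrame:
    """Between-group Mann-Whitney comparison of first slope and knot.

    Returns one row per measure with each group's mean, SD and median,
    the U statistic (first group), two-sided p, and Hedges' g.
    """
    if len(fits_a) < 2 or len(fits_b) < 2:
        raise ValueError("need at least two fits per group")
    rows = []
    for measure, get in (("first_slope", lambda f: f.slope1),
                         ("knot_location", lambda f: float(f.knot_index))):
        a = np.array([get(f) for f in fits_a], dtype=float)
        b = np.array([get(f) for f in fits_b], dtype=float)
        U, p = mann_whitney_u(a, b)
        da, db = _describe(a), _describe(b)
        rows.append({
            "measure": measure,
            f"{labels[0]}_mean": da["mean"], f"{labels[0]}_sd": da["sd"],
            f"{labels[0]}_median": da["median"],
            f"{labels[1]}_mean": db["mean"], f"{labels[1]}_sd": db["sd"],
            f"{labels[1]}_median": db["median"],
            "U": U, "p": p, "g": hedges_g(a, b),
            f"n_{labels[0]}": len(a), f"n_{labels[1]}": len(b),
        })
    return pd.DataFrame(rows)


def sequential_session_anovas(sessions: pd.DataFrame, task: str,
                              fdr_family: str = "per-effect",
                              ) -> pd.DataFrame:
    """Step-1 sequential S1-vs-SN mixed ANOVAs with FDR correction.

    ``sessions`` is long format with columns participant, task, session
    (1..16), schedule and mean_nback, already restricted to trained
    (WMT) participants.  For each N in 2..16 a 2 x 2 mixed ANOVA
    (schedule between, session within) contrasts S1 with SN; pairs
    missing either session are dropped per contrast.  BH-FDR runs across
    the 15 p-values of each effect family separately (``per-effect``) or
    across all 45 at once (``joint``).
    """
    if fdr_family not in ("per-effect", "joint"):
        raise ValueError("fdr_family must be 'per-effect' or 'joint'")
    data = sessions[sessions["task"] == task]
    rows = []
    for n in range(2, N_SESSIONS + 1):
        pair = data[data["session"].isin([1, n])].copy()
        # lexicographic within-level labels keep S1 first for any N
        pair["session_lvl"] = np.where(pair["session"] == 1, "a_S1", "b_SN")
        table = mixed_anova(pair.dropna(subset=["mean_nback"]),
                            dv="mean_nback", within="session_lvl",
                            subject="participant", between=["schedule"])
        for _, r in table.iterrows():
            effect = {"schedule": "group", "session_lvl": "session",
                      "schedule:session_lvl": "group:session"}[r["effect"]]
            rows.append({"contrast": f"S1-S{n}", "N": n, "effect": effect,
                         "F": r["F"], "df1": r["df1"], "df2": r["df2"],
                         "p_raw": r["p"]})
    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    if fdr_family == "per-effect":
        for effect in ("group", "session", "group:session"):
            mask = out["effect"] == effect
            out.loc[mask, "p_fdr"] = bh_fdr(out.loc[mask, "p_raw"].values)
    else:
        out["p_fdr"] = bh_fdr(out["p_raw"].values)
    return out
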