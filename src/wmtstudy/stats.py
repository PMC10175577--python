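"""Classical statistics used by every analysis stage.

The workhorse is a mixed factorial ANOVA for designs with up to two
two-level between-subject factors and a single two-level within-subject
factor (pre/post or first/last session).  With exactly two within levels
the split-plot decomposition is exact: averaging the two measurements per
subject isolates the between-subject effects, and differencing them
isolates every effect involving the within factor (whose main effect is
the intercept of the difference model).  Both halves are fitted by OLS
with sum-to-zero coding and Type III sums of squares, which is what the
mainstream statistics packages report for unbalanced cell sizes.

Also here: pooled-variance and paired t-tests with Hedges' g,
Mann-Whitney U (exact for small untied samples), Benjamini-Hochberg FDR,
Pearson chi-square, the 3*IQR extreme-outlier screen, and a
noncentral-F power computation for the group-by-time interaction of a
repeated-measures design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EffectRow",
    "OutlierReport",
    "TTestResult",
    "mixed_anova",
    "oneway_anova",
    "between_anova",
    "t_test",
    "hedges_g",
    "mann_whitney_u",
    "bh_fdr",
    "chi_square_independence",
    "extreme_outliers",
    "rm_power_sample_size",
]


@dataclass(frozen=True)
class EffectRow:
    """One ANOVA effect: F statistic, degrees of freedom, p, partial eta^2."""

    effect: str
    F: float
    df1: int
    df2: int
    p: float
    eta_p_sq: float


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    g: float


@dataclass(frozen=True)
class OutlierReport:
    """Indices outside the Tukey 3*IQR fences (extreme outliers)."""

    indices: tuple[int, ...]
    fences: tuple[float, float]


def _partial_eta_sq(F: float, df1: float, df2: float) -> float:
    # eta_p^2 = SS_effect / (SS_effect + SS_error) = F*df1 / (F*df1 + df2)
    return float(F * df1 / (F * df1 + df2))


def _sum_coded_formula(dv: str, factors: list[str]) -> str:
    terms = " * ".join(f"C({f}, Sum)" for f in factors)
    return f"{dv} ~ {terms}"


def _pretty_effect(term: str, within: str | None = None) -> str:
    if term == "Intercept":
        return within or "Intercept"
    parts = [p[2:].split(",")[0] for p in term.split(":")]
    if within is not None:
        parts.append(within)
    return ":".join(parts)


def _type3_rows(df: pd.DataFrame, dv: str, factors: list[str],
                within: str | None) -> list[EffectRow]:
    """Type III ANOVA rows of an OLS fit with sum-to-zero coding.

    When ``within`` is given the dependent variable is a per-subject
    within-contrast, so the intercept row is the within main effect and
    every factor row is that factor's interaction with the within factor.
    """
    model = smf.ols(_sum_coded_formula(dv, factors), data=df).fit()
    table = sm.stats.anova_lm(model, typ=3)
    rows = []
    for term, line in table.iterrows():
        if term == "Residual":
            continue
        if term == "Intercept" and within is None:
            continue
        F = float(line["F"])
        df1 = int(line["df"])
        df2 = int(table.loc["Residual", "df"])
        p = float(line["PR(>F)"])
        rows.append(EffectRow(effect=_pretty_effect(str(term), within),
                              F=F, df1=df1, df2=df2, p=p,
                              eta_p_sq=_partial_eta_sq(F, df1, df2)))
    return rows


def mixed_anova(data: pd.DataFrame, dv: str, within: str, subject: str,
                between: list[str]) -> pd.DataFrame:
    """Mixed factorial ANOVA (<=2 two-level between factors, 1 two-level
    within factor) with Type III sums of squares.

    ``data`` is long format with one row per subject x within-level.
    Subjects missing either within level are dropped.  Returns a frame
    with columns effect, F, df1, df2, p, eta_p_sq: between effects first,
    then the within main effect and its interactions.
    """
    if not 1 <= len(between) <= 2:
        raise ValueError("between must list one or two factors")
    wlevels = sorted(data[within].astype(str).unique())
    if len(wlevels) != 2:
        raise ValueError(f"within factor must have 2 levels, got {wlevels}")
    for b in between:
        if data[b].nunique() != 2:
            raise ValueError(f"between factor {b!r} must have 2 levels")

    wide = (data.assign(**{within: data[within].astype(str)})
            .pivot_table(index=[subject] + between, columns=within,
                         values=dv, aggfunc="mean")
            .dropna(subset=wlevels)
            .reset_index())
    if wide.empty:
        raise ValueError("no subject has both within-factor levels")
    counts = wide.groupby(between, observed=True)[subject].count()
    if (counts < 2).any() or len(counts) < 2 ** len(between):
        raise ValueError("need >= 2 subjects in every between cell")

    wide["_avg"] = (wide[wlevels[0]] + wide[wlevels[1]]) / 2.0
    wide["_diff"] = wide[wlevels[1]] - wide[wlevels[0]]

    rows = _type3_rows(wide, "_avg", between, within=None)
    rows += _type3_rows(wide, "_diff", between, within=within)
    return pd.DataFrame(rows)


def between_anova(data: pd.DataFrame, dv: str,
                  between: list[str]) -> pd.DataFrame:
    """Purely between-subjects factorial ANOVA (Type III, sum coding)."""
    sub = data.dropna(subset=[dv] + between)
    return pd.DataFrame(_type3_rows(sub, dv, between, within=None))


def oneway_anova(groups: list[np.ndarray]) -> EffectRow:
    """One-way ANOVA across k groups (baseline comparability checks)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    F, p = sps.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    return EffectRow(effect="group", F=float(F), df1=df1, df2=df2,
                     p=float(p), eta_p_sq=_partial_eta_sq(F, df1, df2))


def hedges_g(x: np.ndarray, y: np.ndarray, paired: bool = False) -> float:
    """Bias-corrected standardised mean difference.

    Independent samples: pooled-SD Cohen's d times the small-sample
    correction J = 1 - 3/(4*df - 1) with df = n1 + n2 - 2.  Paired
    samples: mean difference over the SD of the differences, corrected
    with df = n - 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        d = x - y
        df = len(d) - 1
        denom = np.std(d, ddof=1)
        if denom == 0:
            return 0.0
        raw = float(np.mean(d) / denom)
    else:
        n1, n2 = len(x), len(y)
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / df
        if sp2 == 0:
            return 0.0
        raw = float((np.mean(x) - np.mean(y)) / np.sqrt(sp2))
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    return j * raw


def t_test(x: np.ndarray, y: np.ndarray, paired: bool = False) -> TTestResult:
    """Student's t-test with Hedges' g.

    Independent comparisons use the pooled-variance test with
    df = n1 + n2 - 2; paired comparisons use the within-subject test with
    df = n - 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least two observations per sample")
    if paired:
        if len(x) != len(y):
            raise ValueError("paired samples must have equal length")
        if np.var(x - y, ddof=1) == 0 and np.all(x == y):
            return TTestResult(t=0.0, df=len(x) - 1, p=1.0, g=0.0)
        t, p = sps.ttest_rel(x, y)
        df = len(x) - 1
    else:
        n1, n2 = len(x), len(y)
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / df
        if sp2 == 0:
            raise ValueError("zero pooled variance")
        t, p = sps.ttest_ind(x, y, equal_var=True)
    return TTestResult(t=float(t), df=int(df), p=float(p),
                       g=hedges_g(x, y, paired=paired))


def mann_whitney_u(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney U for the first sample with a two-sided p.

    Exact p by enumeration when n1*n2 <= 400 and there are no ties across
    the pooled sample; otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (no_ties and len(x) * len(y) <= 400) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


def chi_square_independence(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal total")
    chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def extreme_outliers(values: np.ndarray) -> OutlierReport:
    """Flag extreme outliers outside [Q1 - 3*IQR, Q3 + 3*IQR].

    Quartiles use linear interpolation between order statistics (the
    default of the mainstream statistical software); fence membership can
    differ slightly under Tukey hinges.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 4:
        raise ValueError("need at least four values")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 3.0 * iqr, q3 + 3.0 * iqr
    idx = np.nonzero((v < lo) | (v > hi))[0]
    return OutlierReport(indices=tuple(int(i) for i in idx),
                         fences=(float(lo), float(hi)))


def rm_power_sample_size(eta_p_sq: float, alpha: float = 0.05,
                         power: float = 0.80, groups: int = 2,
                         measurements: int = 2,
                         corr: float = 0.5) -> int:
    """Smallest total N (multiple of ``groups``) giving the requested power
    for the group-by-time interaction of a repeated-measures design.

    Cohen's f^2 = eta_p^2 / (1 - eta_p^2); the noncentrality is
    lambda = f^2 * N * m / (1 - rho) with m repeated measurements and
    within-subject correlation rho, tested on
    ((groups-1)(m-1), (N-groups)(m-1)) degrees of freedom.
    """
    if not 0 < eta_p_sq < 1:
        raise ValueError("eta_p_sq must be in (0, 1)")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    f2 = eta_p_sq / (1.0 - eta_p_sq)
    df1 = (groups - 1) * (measurements - 1)

    def achieved(n: int) -> float:
        df2 = (n - groups) * (measurements - 1)
        lam = f2 * n * measurements / (1.0 - corr)
        crit = sps.f.ppf(1.0 - alpha, df1, df2)
        return float(sps.ncf.sf(crit, df1, df2, lam))

    n = 2 * groups
    while n <= 10_000_000:
        if achieved(n) >= power:
            return n
        n += groups
    raise ValueError("requested power unattainable")
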