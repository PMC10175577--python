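"""Independent brute-force / closed-form oracles used by the test suite.

Everything here is deliberately written from first principles (definitions,
enumeration, explicit normal equations) and never calls the implementation
code paths it is used to check.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


# ---------------------------------------------------------------- n-back


def block_violations(block, config) -> list[str]:
    """Re-check every block invariant directly from the definition."""
    v = []
    n = block.level
    stim = list(block.stimuli)
    targ = list(block.is_target)
    if len(stim) != config.critical_screens + n or len(targ) != len(stim):
        v.append("wrong length")
        return v
    if sum(targ) != config.targets_per_block:
        v.append(f"{sum(targ)} targets")
    if any(targ[:n]):
        v.append("target in lead-in")
    for i in range(n, len(stim)):
        repeat = stim[i] == stim[i - n]
        if targ[i] and not repeat:
            v.append(f"target at {i} is not a repeat")
        if not targ[i] and repeat:
            v.append(f"non-target at {i} repeats the n-back stimulus")
    if any(s < 0 or s >= config.alphabet_size for s in stim):
        v.append("stimulus outside alphabet")
    return v


# ---------------------------------------------------------------- spline


def spline_normal_equations(y, k):
    """Solve the one-knot spline OLS by explicit 3x3 normal equations."""
    y = np.asarray(y, dtype=float)
    t = np.arange(1, len(y) + 1, dtype=float)
    h = np.maximum(0.0, t - k)
    X = np.column_stack([np.ones_like(t), t, h])
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = None if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return {"intercept": beta[0], "slope1": beta[1],
            "slope2": beta[1] + beta[2], "r_squared": r2}


# ------------------------------------------------------------------ FDR


def bh_stepup(p):
    """Literal Benjamini-Hochberg step-up: adj_(i) = min_{j>=i} m p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    adj = np.empty(m)
    running = np.inf
    for i in range(m - 1, -1, -1):
        running = min(running, m * sorted_p[i] / (i + 1))
        adj[i] = min(running, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


# --------------------------------------------------------- Mann-Whitney


def mw_enumeration(x, y):
    """Exact Mann-Whitney U and two-sided p by full rank enumeration.

    Assumes no ties.  U counts, for the first sample, the pairs
    (xi, yj) with xi > yj; the two-sided p doubles the smaller tail of
    the exact permutation distribution (capped at 1), matching the
    standard exact convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    pooled = np.concatenate([x, y])
    ranks_all = np.argsort(np.argsort(pooled))  # 0-based ranks, no ties
    counts = np.zeros(n1 * n2 + 1, dtype=np.int64)
    for combo in itertools.combinations(range(n1 + n2), n1):
        r = ranks_all[list(combo)]
        # U = sum of ranks of first sample minus its minimum possible value
        u = int(np.sum(r)) - n1 * (n1 - 1) // 2
        counts[u] += 1
    total = comb(n1 + n2, n1)
    cdf = counts.cumsum()
    p_le = cdf[u_obs] / total
    p_ge = (total - (cdf[u_obs - 1] if u_obs > 0 else 0)) / total
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


# -------------------------------------------------- balanced mixed ANOVA


def mixed_anova_cellmeans(y, a, b):
    """Closed-form balanced 2x2x2 mixed ANOVA from cell quantities.

    ``y`` has shape (n_subjects, 2): the two within-level measurements;
    ``a``, ``b`` are +/-1 codes of the two between factors, with equal
    cell sizes.  Uses the orthogonality of +/-1 contrasts on the
    per-subject average (between effects) and difference (within
    effects): SS_effect = N * coef^2 where coef is the signed mean.
    Returns {effect: F}.
    """
    y = np.asarray(y, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = len(y)
    avg = y.mean(axis=1)
    diff = y[:, 1] - y[:, 0]
    out = {}
    for part, label_suffix in ((avg, ""), (diff, ":w")):
        cols = {"a" + label_suffix: a, "b" + label_suffix: b,
                "a:b" + label_suffix: a * b}
        if label_suffix:
            cols = {"w": np.ones(n), **cols}
        # orthogonal +/-1 design: coefficient = mean of signed values
        X = np.column_stack([np.ones(n), a, b, a * b])
        beta = (X.T @ part) / n
        fitted = X @ beta
        sse = float(np.sum((part - fitted) ** 2))
        dfe = n - 4
        mse = sse / dfe
        for name, col in cols.items():
            coef = float(np.mean(part * col))  # since sum(col^2) = n
            ss = n * coef ** 2
            out[name] = ss / mse
    return out, n - 4


# ----------------------------------------------------------- digit span


def legal_span_patterns(n_lengths):
    """Every legal administration pattern over ``n_lengths`` lengths.

    A pattern is a tuple of per-length (t1, t2) booleans; administration
    stops after the first length with both trials failed, otherwise
    continues to the last length.
    """
    per_length = [(False, False), (False, True), (True, False), (True, True)]
    patterns = []

    def extend(prefix):
        depth = len(prefix)
        if depth and prefix[-1] == (False, False):
            patterns.append(tuple(prefix))
            return
        if depth == n_lengths:
            patterns.append(tuple(prefix))
            return
        for pl in per_length:
            extend(prefix + [pl])

    extend([])
    return [p for p in patterns if p]


def span_literal(pattern, min_length):
    """Score a pattern by the literal rule: the maximum administered
    length with at least one of two trials correct, else min - 1."""
    best = min_length - 1
    for i, (t1, t2) in enumerate(pattern):
        if t1 or t2:
            best = min_length + i
    return best
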