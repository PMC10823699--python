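"""Independent oracles used by the tests.

Everything here is deliberately written without touching the package's own
code paths: interval-halving bisection for the staircase, explicit
normal-equations arithmetic for the linear models, and raw-normal
simulation for the noncentral F tail.
"""

from __future__ import annotations

import numpy as np


def bisection_bracket(choices, lo=0.0, hi=1000.0):
    """Track the bracketing interval of an interval-halving search.

    Each offer is the midpoint of the current bracket; a "future" choice
    means the present offer was rejected (indifference above the offer), a
    "present" choice means it was accepted (indifference below).
    Returns the final (lo, hi) bracket.
    """
    for c in choices:
        mid = (lo + hi) / 2.0
        if c == "future":
            lo = mid
        else:
            hi = mid
    return lo, hi


def bisection_estimate(choices, lo=0.0, hi=1000.0):
    """Midpoint of the final bracket: the bisection indifference estimate."""
    lo, hi = bisection_bracket(choices, lo, hi)
    return (lo + hi) / 2.0


def choices_for_indifference(v, n_steps=6, lo=0.0, hi=1000.0):
    """Choice sequence a value-maximiser with indifference value v produces.

    Ties (offer exactly equal to v) go to "future", matching the agents'
    documented convention.
    """
    out = []
    for _ in range(n_steps):
        mid = (lo + hi) / 2.0
        if v >= mid:
            out.append("future")
            lo = mid
        else:
            out.append("present")
            hi = mid
    return out


def ols_normal_equations(X, y):
    """Explicit least squares: beta, residual SS, coefficient covariance."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    sse = float(resid @ resid)
    df_resid = X.shape[0] - X.shape[1]
    cov = sse / df_resid * np.linalg.inv(XtX)
    return beta, sse, cov


def ancova_oracle(y, groups, age, group_order):
    """One-factor ANCOVA by explicit matrix arithmetic.

    Returns (F, df_num, df_den, ss_group, sse_full, beta, cov, adjusted_means).
    """
    y = np.asarray(y, dtype=float)
    age = np.asarray(age, dtype=float)
    n = len(y)
    g = len(group_order)
    X = np.ones((n, g + 1))
    for j, lev in enumerate(group_order[1:], start=1):
        X[:, j] = [1.0 if gr == lev else 0.0 for gr in groups]
    X[:, -1] = age
    beta, sse_full, cov = ols_normal_equations(X, y)
    Xr = np.column_stack([np.ones(n), age])
    _, sse_red, _ = ols_normal_equations(Xr, y)
    df_num = g - 1
    df_den = n - (g + 1)
    ss_group = sse_red - sse_full
    F = (ss_group / df_num) / (sse_full / df_den)
    xbar = age.mean()
    adjusted = {}
    for i, lev in enumerate(group_order):
        c = np.zeros(g + 1)
        c[0] = 1.0
        if i >= 1:
            c[i] = 1.0
        c[-1] = xbar
        adjusted[lev] = float(c @ beta)
    return F, df_num, df_den, ss_group, sse_full, beta, cov, adjusted


def noncentral_f_tail_mc(df_num, df_den, noncentrality, crit, n_draws, seed):
    """Monte-Carlo P(F' > crit) simulated from raw normals and chi-squares."""
    rng = np.random.default_rng(seed)
    shifted = rng.normal(np.sqrt(noncentrality), 1.0, size=n_draws) ** 2
    if df_num > 1:
        shifted += rng.chisquare(df_num - 1, size=n_draws)
    denom = rng.chisquare(df_den, size=n_draws)
    f = (shifted / df_num) / (denom / df_den)
    return float(np.mean(f > crit))
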