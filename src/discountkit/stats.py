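"""Group-comparison statistics for the delay-discounting outcome.

The inference stack mirrors the study's analysis plan:

* :class:`GroupAncova` — a one-factor ANCOVA of (ln)k on group with age as
  covariate, fitted by OLS.  ``fit()`` returns :class:`AncovaResults`
  carrying the omnibus group F (Type II sum of squares), its p-value,
  partial eta squared, age-adjusted (estimated-marginal) group means, and
  Bonferroni-corrected pairwise t-tests on those adjusted means with
  Hedges' g effect sizes.
* :class:`PresentationRegression` — OLS of (ln)k on the three ARFID
  presentation flags, controlling for age.
* :func:`achieved_power` — post-hoc power from partial eta squared via the
  noncentral F distribution.

For a single factor plus one covariate, Type II and Type III group sums of
squares coincide under the default coding; the group SS is computed as the
residual-SS drop from adding the group indicators to the covariate-only
model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import EstimationError


# ---------------------------------------------------------------------------
# effect sizes and power
# ---------------------------------------------------------------------------

def partial_eta_squared(F: float, df_num: int, df_den: int) -> float:
    """Partial eta squared from an F statistic via the sum-of-squares identity.

    eta_p^2 = (F * df_num) / (F * df_num + df_den), i.e.
    SS_effect / (SS_effect + SS_error).
    """
    if F < 0:
        raise ValueError("F must be non-negative")
    if df_num < 1 or df_den < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return (F * df_num) / (F * df_num + df_den)


def hedges_g(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> float:
    """Hedges' g: Cohen's d with the small-sample correction J.

    g = J * (mean1 - mean2) / s_pooled, with
    s_pooled = sqrt(((n1-1)sd1^2 + (n2-1)sd2^2) / (n1+n2-2)) and
    J = 1 - 3 / (4(n1+n2) - 9).  Antisymmetric under swapping the samples.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs n >= 2")
    s_pooled = math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    if s_pooled == 0:
        raise ValueError("degenerate pooled standard deviation")
    J = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    return J * (mean1 - mean2) / s_pooled


@dataclass(frozen=True)
class PowerResult:
    """Post-hoc power of the omnibus group test at a given effect size."""

    eta_p2_input: float
    f2: float
    noncentrality: float
    df_num: int
    df_den: int
    critical_F: float
    alpha: float
    power: float


def achieved_power(
    eta_p2: float,
    n_total: int,
    n_groups: int,
    n_covariates: int = 1,
    alpha: float = 0.05,
) -> PowerResult:
    """Achieved power of the ANCOVA omnibus F test via the noncentral F.

    Cohen's f^2 = eta_p2/(1 - eta_p2); noncentrality lambda = f^2 * N;
    numerator df = groups - 1; denominator df = N - groups - covariates.
    Power is the probability mass of F'(df_num, df_den, lambda) beyond the
    central-F critical value at ``alpha``.
    """
    if not (0 < eta_p2 < 1):
        raise ValueError("eta_p2 must lie strictly in (0, 1)")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie strictly in (0, 1)")
    if n_total <= n_groups + n_covariates:
        raise ValueError("N must exceed groups + covariates")
    f2 = eta_p2 / (1.0 - eta_p2)
    lam = f2 * n_total
    df_num = n_groups - 1
    df_den = n_total - n_groups - n_covariates
    crit = sps.f.isf(alpha, df_num, df_den)
    power = float(sps.ncf.sf(crit, df_num, df_den, lam))
    return PowerResult(
        eta_p2_input=eta_p2,
        f2=f2,
        noncentrality=lam,
        df_num=df_num,
        df_den=df_den,
        critical_F=float(crit),
        alpha=alpha,
        power=power,
    )


# ---------------------------------------------------------------------------
# ANCOVA model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairwiseResult:
    """One age-adjusted pairwise contrast between two groups."""

    contrast: tuple[str, str]
    difference: float  # adjusted mean of A minus adjusted mean of B
    se: float
    t: float
    df: int
    p_uncorrected: float
    p_bonferroni: float
    hedges_g: float


class GroupAncova:
    """ANCOVA comparing group means of an outcome while adjusting for a
    continuous covariate.

    Parameters
    ----------
    data : DataFrame with the outcome, group and covariate columns.
    outcome, group, covariate : column names (defaults "ln_k", "group", "age").
    group_order : optional explicit group ordering (default: order of first
        appearance); the first group is the OLS reference level, which does
        not affect any reported statistic.

    Examples
    --------
    >>> model = GroupAncova.from_dataframe(df)
    >>> res = model.fit()
    >>> res.F, res.p_value, res.eta_p2            # doctest: +SKIP
    >>> res.pairwise()                            # doctest: +SKIP
    """

    def __init__(
        self,
        data: pd.DataFrame,
        outcome: str = "ln_k",
        group: str = "group",
        covariate: str = "age",
        group_order: Optional[Sequence[str]] = None,
    ):
        for col in (outcome, group, covariate):
            if col not in data.columns:
                raise EstimationError(f"column {col!r} not found in data")
        data = data[[outcome, group, covariate]].dropna()
        self.outcome, self.group, self.covariate = outcome, group, covariate
        if group_order is None:
            group_order = list(dict.fromkeys(data[group]))
        self.group_order = list(group_order)
        if len(self.group_order) < 2:
            raise EstimationError("need at least 2 groups")
        counts = data[group].value_counts()
        small = [g for g in self.group_order if counts.get(g, 0) < 2]
        if small:
            raise EstimationError(f"groups with fewer than 2 observations: {small}")
        if data[covariate].nunique() < 2:
            raise EstimationError(f"covariate {covariate!r} is constant")
        self.data = data.reset_index(drop=True)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "GroupAncova":
        return cls(data, **kwargs)

    def _design(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        y = self.data[self.outcome].to_numpy(dtype=float)
        x_cov = self.data[self.covariate].to_numpy(dtype=float)
        n = len(y)
        g_levels = self.group_order
        # intercept | group dummies (ref = first level) | covariate
        X = np.ones((n, 1 + (len(g_levels) - 1) + 1))
        for j, lev in enumerate(g_levels[1:], start=1):
            X[:, j] = (self.data[self.group] == lev).to_numpy(dtype=float)
        X[:, -1] = x_cov
        X_red = np.column_stack([np.ones(n), x_cov])
        return y, X, X_red

    def fit(self) -> "AncovaResults":
        y, X, X_red = self._design()
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise EstimationError(
                "singular ANCOVA design: group indicators and covariate are "
                "collinear (is the covariate confounded with group?)"
            )
        full = sm.OLS(y, X).fit()
        reduced = sm.OLS(y, X_red).fit()
        g = len(self.group_order)
        df_num = g - 1
        df_den = int(full.df_resid)
        ss_group = reduced.ssr - full.ssr  # Type II == Type III here
        ms_group = ss_group / df_num
        ms_resid = full.ssr / df_den
        F = ms_group / ms_resid
        p = float(sps.f.sf(F, df_num, df_den))
        eta_p2 = ss_group / (ss_group + full.ssr)

        xbar = float(self.data[self.covariate].mean())
        cov_params = np.asarray(full.cov_params())
        adjusted, adj_se = {}, {}
        for i, lev in enumerate(self.group_order):
            c = np.zeros(X.shape[1])
            c[0] = 1.0
            if i >= 1:
                c[i] = 1.0
            c[-1] = xbar
            adjusted[lev] = float(c @ full.params)
            adj_se[lev] = float(np.sqrt(c @ cov_params @ c))

        raw = self.data.groupby(self.group)[self.outcome]
        return AncovaResults(
            model=self,
            F=float(F),
            df_num=df_num,
            df_den=df_den,
            p_value=p,
            eta_p2=float(eta_p2),
            ss_group=float(ss_group),
            ss_resid=float(full.ssr),
            adjusted_means=pd.Series(adjusted, name="adjusted_mean"),
            adjusted_se=pd.Series(adj_se, name="adjusted_se"),
            residual_variance=float(ms_resid),
            covariate_coefficient=float(full.params[-1]),
            grand_mean_covariate=xbar,
            group_sizes=raw.size().reindex(self.group_order),
            group_means=raw.mean().reindex(self.group_order),
            group_sds=raw.std(ddof=1).reindex(self.group_order),
            _ols=full,
        )


@dataclass
class AncovaResults:
    """Fitted ANCOVA: omnibus test, effect size, adjusted means, contrasts."""

    model: GroupAncova
    F: float
    df_num: int
    df_den: int
    p_value: float
    eta_p2: float
    ss_group: float
    ss_resid: float
    adjusted_means: pd.Series
    adjusted_se: pd.Series
    residual_variance: float
    covariate_coefficient: float
    grand_mean_covariate: float
    group_sizes: pd.Series
    group_means: pd.Series
    group_sds: pd.Series
    _ols: object = field(repr=False, default=None)

    def pairwise(
        self,
        n_comparisons: Optional[int] = None,
        g_on_adjusted: bool = False,
    ) -> list[PairwiseResult]:
        """Bonferroni-corrected t-tests on differences of age-adjusted means.

        Contrast standard errors use the coefficient covariance of the single
        fitted three-group model (not per-pair refits); the Bonferroni factor
        defaults to the number of contrasts.  Hedges' g is computed from the
        raw group mean/SD of the outcome by default; ``g_on_adjusted=True``
        substitutes the adjusted-mean difference in the numerator.
        """
        order = self.model.group_order
        pairs = list(combinations(order, 2))
        m = n_comparisons if n_comparisons is not None else len(pairs)
        cov_params = np.asarray(self._ols.cov_params())
        k_params = cov_params.shape[0]
        out = []
        for a, b in pairs:
            c = np.zeros(k_params)
            ia, ib = order.index(a), order.index(b)
            if ia >= 1:
                c[ia] = 1.0
            if ib >= 1:
                c[ib] -= 1.0
            diff = self.adjusted_means[a] - self.adjusted_means[b]
            se = float(np.sqrt(c @ cov_params @ c))
            t = diff / se
            p_raw = float(2.0 * sps.t.sf(abs(t), self.df_den))
            if g_on_adjusted:
                m1, m2 = self.adjusted_means[a], self.adjusted_means[b]
            else:
                m1, m2 = self.group_means[a], self.group_means[b]
            g_val = hedges_g(
                m1,
                self.group_sds[a],
                int(self.group_sizes[a]),
                m2,
                self.group_sds[b],
                int(self.group_sizes[b]),
            )
            out.append(
                PairwiseResult(
                    contrast=(a, b),
                    difference=float(diff),
                    se=se,
                    t=float(t),
                    df=self.df_den,
                    p_uncorrected=p_raw,
                    p_bonferroni=min(1.0, m * p_raw),
                    hedges_g=g_val,
                )
            )
        return out

    def power(self, alpha: float = 0.05) -> PowerResult:
        """Post-hoc achieved power at the fitted partial eta squared."""
        n = int(self.group_sizes.sum())
        return achieved_power(
            self.eta_p2, n, len(self.model.group_order), n_covariates=1, alpha=alpha
        )

    def summary(self) -> str:
        """Human-readable table: group summaries, omnibus test, contrasts."""
        lines = []
        lines.append("ANCOVA of %s on %s, adjusting for %s" % (
            self.model.outcome, self.model.group, self.model.covariate))
        lines.append("=" * 64)
        lines.append(f"{'group':<8}{'n':>5}{'M':>10}{'SD':>8}{'adj. M':>10}{'SE':>8}")
        for g in self.model.group_order:
            lines.append(
                f"{g:<8}{int(self.group_sizes[g]):>5}"
                f"{self.group_means[g]:>10.2f}{self.group_sds[g]:>8.2f}"
                f"{self.adjusted_means[g]:>10.2f}{self.adjusted_se[g]:>8.2f}"
            )
        lines.append("-" * 64)
        lines.append(
            f"F({self.df_num}, {self.df_den}) = {self.F:.2f}, "
            f"p = {self.p_value:.3f}, partial eta^2 = {self.eta_p2:.2f}"
        )
        lines.append(
            f"covariate ({self.model.covariate}) coefficient = "
            f"{self.covariate_coefficient:.3f}; adjusted means at "
            f"{self.model.covariate} = {self.grand_mean_covariate:.2f}"
        )
        lines.append("-" * 64)
        lines.append("Bonferroni-corrected pairwise t-tests on adjusted means")
        lines.append(f"{'contrast':<14}{'diff':>8}{'t':>8}{'p (corr.)':>11}{'g':>8}")
        for pw in self.pairwise():
            lines.append(
                f"{pw.contrast[0] + '-' + pw.contrast[1]:<14}"
                f"{pw.difference:>8.2f}{pw.t:>8.2f}"
                f"{pw.p_bonferroni:>11.3f}{pw.hedges_g:>8.2f}"
            )
        return "\n".join(lines)

    def plot_adjusted_means(self, ax=None):
        """Bar chart of age-adjusted group means with SEM error bars."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        order = self.model.group_order
        ax.bar(
            order,
            [self.adjusted_means[g] for g in order],
            yerr=[self.adjusted_se[g] for g in order],
            capsize=4,
            color="0.7",
            edgecolor="black",
        )
        ax.set_ylabel(f"age-adjusted {self.model.outcome}")
        ax.set_xlabel(self.model.group)
        return ax


# ---------------------------------------------------------------------------
# presentation regression
# ---------------------------------------------------------------------------

class PresentationRegression:
    """OLS of the outcome on binary presentation flags, controlling for age.

    Intended for the ARFID subgroup: (ln)k regressed on the three
    presentation indicators (0/1, co-occurrence allowed) plus the covariate,
    with an intercept.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        outcome: str = "ln_k",
        flags: Sequence[str] = (
            "sensory_sensitivity",
            "fear_of_aversive_consequences",
            "lack_of_interest",
        ),
        covariate: str = "age",
    ):
        cols = [outcome, *flags, covariate]
        for col in cols:
            if col not in data.columns:
                raise EstimationError(f"column {col!r} not found in data")
        data = data[cols].dropna()
        if len(data) < 6:
            raise EstimationError("need at least 6 observations")
        constant = [f for f in flags if data[f].nunique() < 2]
        if constant:
            raise EstimationError(f"constant flag columns: {constant}")
        self.data = data.reset_index(drop=True)
        self.outcome = outcome
        self.flags = list(flags)
        self.covariate = covariate

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "PresentationRegression":
        return cls(data, **kwargs)

    def fit(self) -> "RegressionResults":
        names = ["intercept", *self.flags, self.covariate]
        X = np.column_stack(
            [np.ones(len(self.data))]
            + [self.data[c].to_numpy(dtype=float) for c in names[1:]]
        )
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # identify a minimal collinear set by dropping columns
            collinear = [
                names[j]
                for j in range(X.shape[1])
                if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
            ]
            raise EstimationError(f"rank-deficient design; collinear columns: {collinear}")
        y = self.data[self.outcome].to_numpy(dtype=float)
        ols = sm.OLS(y, X).fit()
        return RegressionResults(
            names=names,
            coefficients=pd.Series(ols.params, index=names),
            p_values=pd.Series(ols.pvalues, index=names),
            standard_errors=pd.Series(ols.bse, index=names),
            F=float(ols.fvalue),
            p_overall=float(ols.f_pvalue),
            r2=float(ols.rsquared),
            adjusted_r2=float(ols.rsquared_adj),
            df_resid=int(ols.df_resid),
            _ols=ols,
        )


@dataclass
class RegressionResults:
    """Fitted presentation regression."""

    names: list[str]
    coefficients: pd.Series
    p_values: pd.Series
    standard_errors: pd.Series
    F: float
    p_overall: float
    r2: float
    adjusted_r2: float
    df_resid: int
    _ols: object = field(repr=False, default=None)

    def summary(self) -> str:
        lines = []
        lines.append("OLS regression of (ln)k on presentation flags + age")
        lines.append("=" * 52)
        lines.append(f"{'term':<32}{'B':>8}{'p':>8}")
        for name in self.names:
            lines.append(
                f"{name:<32}{self.coefficients[name]:>8.2f}{self.p_values[name]:>8.3f}"
            )
        lines.append("-" * 52)
        lines.append(
            f"F = {self.F:.2f}, p = {self.p_overall:.3f}, "
            f"adjusted R^2 = {self.adjusted_r2:.2f}"
        )
        return "\n".join(lines)
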