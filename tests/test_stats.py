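"""Inference stack: ANCOVA, contrasts, effect sizes, regression, power."""

import math

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from discountkit import (
    GroupAncova,
    PresentationRegression,
    achieved_power,
    hedges_g,
    partial_eta_squared,
)
from discountkit.errors import EstimationError
from oracles import ancova_oracle, noncentral_f_tail_mc, ols_normal_equations


class TestPartialEtaSquared:
    def test_printed_omnibus_statistic(self):
        assert partial_eta_squared(5.93, 2, 101) == pytest.approx(0.1051, abs=5e-4)
        assert round(partial_eta_squared(5.93, 2, 101), 2) == 0.11

    def test_null_and_symmetry(self):
        assert partial_eta_squared(0.0, 2, 101) == 0.0
        assert partial_eta_squared(10.0, 1, 10) == 0.5

    @given(
        F=st.floats(0.0, 100.0),
        dfn=st.integers(1, 10),
        dfd=st.integers(1, 500),
    )
    @settings(deadline=None)
    def test_ss_identity(self, F, dfn, dfd):
        """eta_p2 from (F, df) always equals SS_effect/(SS_effect+SS_error)."""
        ss_e, ss_r = F * dfn, float(dfd)  # any SS pair with this F reduces so
        eta = partial_eta_squared(F, dfn, dfd)
        assert eta == pytest.approx(ss_e / (ss_e + ss_r), rel=1e-12, abs=1e-12)


class TestHedgesG:
    def test_abstract_group_summaries(self):
        assert hedges_g(-6.10, 2.00, 57, -7.26, 1.73, 28) == pytest.approx(0.600, abs=5e-4)

    def test_equal_means_zero(self):
        assert hedges_g(1.0, 1.0, 10, 1.0, 2.0, 15) == 0.0

    def test_antisymmetry(self):
        a = hedges_g(-6.1, 2.0, 57, -5.4, 1.5, 19)
        b = hedges_g(-5.4, 1.5, 19, -6.1, 2.0, 57)
        assert a == -b

    def test_correction_shrinks_cohens_d(self):
        d = (2.0 - 1.0) / math.sqrt(((9 * 1.0) + (9 * 1.0)) / 18)
        g = hedges_g(2.0, 1.0, 10, 1.0, 1.0, 10)
        assert abs(g) < abs(d)
        assert g == pytest.approx(d * (1 - 3 / (4 * 20 - 9)), rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            hedges_g(1.0, 0.0, 10, 0.0, 1.0, 10)
        with pytest.raises(ValueError):
            hedges_g(1.0, 1.0, 1, 0.0, 1.0, 10)


class TestGroupAncova:
    def test_matches_normal_equations_oracle(self, small_ancova_fixture):
        res = GroupAncova.from_dataframe(small_ancova_fixture).fit()
        F, dfn, dfd, ssg, sse, beta, cov, adjusted = ancova_oracle(
            small_ancova_fixture.ln_k,
            small_ancova_fixture.group,
            small_ancova_fixture.age,
            res.model.group_order,
        )
        assert res.F == pytest.approx(F, abs=1e-10)
        assert (res.df_num, res.df_den) == (dfn, dfd)
        assert res.ss_group == pytest.approx(ssg, abs=1e-10)
        assert res.ss_resid == pytest.approx(sse, abs=1e-10)
        assert res.covariate_coefficient == pytest.approx(beta[-1], abs=1e-10)
        for g in res.model.group_order:
            assert res.adjusted_means[g] == pytest.approx(adjusted[g], abs=1e-10)

    def test_matches_pingouin(self, small_ancova_fixture):
        res = GroupAncova.from_dataframe(small_ancova_fixture).fit()
        pg_tab = pg.ancova(
            data=small_ancova_fixture, dv="ln_k", covar="age", between="group"
        ).set_index("Source")
        assert res.F == pytest.approx(pg_tab.loc["group", "F"], rel=1e-9)
        assert res.p_value == pytest.approx(pg_tab.loc["group", "p_unc"], rel=1e-9)
        assert res.eta_p2 == pytest.approx(pg_tab.loc["group", "np2"], rel=1e-9)

    def test_eta_identity_holds_for_fit(self, small_ancova_fixture):
        res = GroupAncova.from_dataframe(small_ancova_fixture).fit()
        assert res.eta_p2 == pytest.approx(
            partial_eta_squared(res.F, res.df_num, res.df_den), abs=1e-14
        )

    def test_reduces_to_anova_when_covariate_inert(self):
        """With identical within-group age patterns and age-balanced outcomes
        the fitted age coefficient is exactly 0, so the group and residual
        sums of squares coincide with one-way ANOVA."""
        df = pd.DataFrame(
            {
                "ln_k": [-6.0, -6.0, -6.4, -6.4, -7.0, -7.0, -7.6, -7.6, -5.0, -5.0, -5.2, -5.2],
                "group": ["A"] * 4 + ["B"] * 4 + ["C"] * 4,
                "age": [15.0, 20.0, 15.0, 20.0] * 3,
            }
        )
        res = GroupAncova.from_dataframe(df).fit()
        assert res.covariate_coefficient == pytest.approx(0.0, abs=1e-12)
        f_anova = sps.f_oneway(*(df[df.group == g].ln_k for g in "ABC"))
        groups = [df[df.group == g].ln_k for g in "ABC"]
        ssb = sum(len(g) * (g.mean() - df.ln_k.mean()) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        assert res.ss_group == pytest.approx(ssb, abs=1e-10)
        assert res.ss_resid == pytest.approx(ssw, abs=1e-10)
        # F differs from one-way ANOVA only through the covariate's df
        assert res.F == pytest.approx(f_anova.statistic * (12 - 4) / (12 - 3), rel=1e-10)

    def test_singular_design_raises(self):
        df = pd.DataFrame(
            {
                "ln_k": [-6.0, -6.1, -7.0, -7.2, -5.0, -5.3],
                "group": ["A", "A", "B", "B", "C", "C"],
                "age": [10.0, 10.0, 20.0, 20.0, 30.0, 30.0],  # age == f(group)
            }
        )
        with pytest.raises(EstimationError):
            GroupAncova.from_dataframe(df).fit()

    def test_requires_two_groups_and_varying_covariate(self):
        base = pd.DataFrame({"ln_k": [-6.0, -6.1], "group": ["A", "A"], "age": [10.0, 12.0]})
        with pytest.raises(EstimationError):
            GroupAncova.from_dataframe(base)
        df = pd.DataFrame(
            {"ln_k": [-6, -6.1, -7, -7.1], "group": list("AABB"), "age": [15.0] * 4}
        )
        with pytest.raises(EstimationError):
            GroupAncova.from_dataframe(df)


class TestPairwise:
    def test_contrast_t_matches_matrix_oracle(self, small_ancova_fixture):
        res = GroupAncova.from_dataframe(small_ancova_fixture).fit()
        order = res.model.group_order
        _, _, _, _, _, beta, cov, adjusted = ancova_oracle(
            small_ancova_fixture.ln_k,
            small_ancova_fixture.group,
            small_ancova_fixture.age,
            order,
        )
        for pw in res.pairwise():
            a, b = pw.contrast
            c = np.zeros(len(order) + 1)
            if order.index(a) >= 1:
                c[order.index(a)] = 1.0
            if order.index(b) >= 1:
                c[order.index(b)] -= 1.0
            t_oracle = (c @ beta) / math.sqrt(c @ cov @ c)
            assert pw.t == pytest.approx(t_oracle, abs=1e-10)
            assert pw.difference == pytest.approx(adjusted[a] - adjusted[b], abs=1e-10)

    def test_bonferroni_triples_and_caps(self, small_ancova_fixture):
        res = GroupAncova.from_dataframe(small_ancova_fixture).fit()
        for pw in res.pairwise():
            assert pw.p_bonferroni == min(1.0, 3.0 * pw.p_uncorrected)

    def test_identical_groups_give_null_contrast(self):
        half = pd.DataFrame({"ln_k": [-6.0, -6.5, -7.0, -5.5], "age": [12.0, 15.0, 20.0, 25.0]})
        df = pd.concat(
            [half.assign(group="A"), half.assign(group="B")], ignore_index=True
        )
        res = GroupAncova.from_dataframe(df).fit()
        (pw,) = res.pairwise()
        assert pw.difference == pytest.approx(0.0, abs=1e-12)
        assert pw.p_bonferroni == pytest.approx(1.0, abs=1e-12)
        assert pw.hedges_g == pytest.approx(0.0, abs=1e-12)

    def test_g_on_adjusted_flag_changes_numerator(self, small_ancova_fixture):
        res = GroupAncova.from_dataframe(small_ancova_fixture).fit()
        raw = {pw.contrast: pw.hedges_g for pw in res.pairwise()}
        adj = {pw.contrast: pw.hedges_g for pw in res.pairwise(g_on_adjusted=True)}
        assert set(raw) == set(adj)
        # same pooled SD, numerators swap from raw to adjusted differences
        for (a, b), g_adj in adj.items():
            ratio = (res.adjusted_means[a] - res.adjusted_means[b]) / (
                res.group_means[a] - res.group_means[b]
            )
            assert g_adj == pytest.approx(raw[(a, b)] * ratio, rel=1e-9)

    def test_summary_renders(self, small_ancova_fixture):
        text = GroupAncova.from_dataframe(small_ancova_fixture).fit().summary()
        assert "partial eta^2" in text and "Bonferroni" in text

    def test_adjusted_means_bar_chart(self, small_ancova_fixture):
        import matplotlib

        matplotlib.use("Agg")
        res = GroupAncova.from_dataframe(small_ancova_fixture).fit()
        ax = res.plot_adjusted_means()
        assert len(ax.patches) == 3
        import matplotlib.pyplot as plt

        plt.close("all")


class TestPresentationRegression:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(8)
        n = 30
        flags = rng.integers(0, 2, size=(n, 3))
        flags[flags.sum(axis=1) == 0, 0] = 1
        age = rng.uniform(10, 30, n)
        y = -6.0 - 1.0 * flags[:, 0] + 0.4 * flags[:, 2] + 0.05 * age + rng.normal(0, 1, n)
        df = pd.DataFrame(
            {
                "ln_k": y,
                "sensory_sensitivity": flags[:, 0],
                "fear_of_aversive_consequences": flags[:, 1],
                "lack_of_interest": flags[:, 2],
                "age": age,
            }
        )
        res = PresentationRegression.from_dataframe(df).fit()
        X = np.column_stack([np.ones(n), flags, age])
        beta, sse, cov = ols_normal_equations(X, y)
        np.testing.assert_allclose(res.coefficients.to_numpy(), beta, atol=1e-10)
        se = np.sqrt(np.diag(cov))
        np.testing.assert_allclose(res.standard_errors.to_numpy(), se, atol=1e-10)
        assert res.adjusted_r2 <= res.r2

    def test_single_flag_orthogonal_to_age_recovers_group_difference(self):
        """With one flag and age identical across flag groups, the flag
        coefficient is exactly the difference of flag-group means."""
        df = pd.DataFrame(
            {
                "ln_k": [-5.0, -5.5, -6.0, -7.0, -7.5, -8.0],
                "sensory_sensitivity": [1, 1, 1, 0, 0, 0],
                "age": [12.0, 18.0, 24.0, 12.0, 18.0, 24.0],
            }
        )
        res = PresentationRegression.from_dataframe(
            df, flags=("sensory_sensitivity",)
        ).fit()
        expected = df[df.sensory_sensitivity == 1].ln_k.mean() - df[
            df.sensory_sensitivity == 0
        ].ln_k.mean()
        assert res.coefficients["sensory_sensitivity"] == pytest.approx(expected, abs=1e-12)

    def test_constant_response_gives_zero_slopes(self):
        df = pd.DataFrame(
            {
                "ln_k": [-6.0] * 8,
                "sensory_sensitivity": [1, 0, 1, 0, 1, 0, 1, 1],
                "age": [11.0, 14.0, 17.0, 20.0, 23.0, 26.0, 29.0, 12.0],
            }
        )
        res = PresentationRegression.from_dataframe(
            df, flags=("sensory_sensitivity",)
        ).fit()
        assert res.coefficients["sensory_sensitivity"] == pytest.approx(0.0, abs=1e-12)
        assert res.adjusted_r2 <= 0.0 or math.isnan(res.adjusted_r2)

    def test_rank_deficiency_names_columns(self):
        df = pd.DataFrame(
            {
                "ln_k": [-6.0, -6.5, -7.0, -5.5, -6.2, -6.8],
                "sensory_sensitivity": [1, 0, 1, 0, 1, 0],
                "fear_of_aversive_consequences": [1, 0, 1, 0, 1, 0],  # duplicate
                "age": [12.0, 14.0, 16.0, 18.0, 20.0, 22.0],
            }
        )
        with pytest.raises(EstimationError, match="sensory_sensitivity"):
            PresentationRegression.from_dataframe(
                df, flags=("sensory_sensitivity", "fear_of_aversive_consequences")
            ).fit()

    def test_minimum_observations_and_constant_flags(self):
        df = pd.DataFrame(
            {
                "ln_k": [-6.0, -6.5, -7.0],
                "sensory_sensitivity": [1, 0, 1],
                "age": [12.0, 14.0, 16.0],
            }
        )
        with pytest.raises(EstimationError):
            PresentationRegression.from_dataframe(df, flags=("sensory_sensitivity",))
        df2 = pd.DataFrame(
            {
                "ln_k": [-6.0, -6.5, -7.0, -5.5, -6.2, -6.8],
                "sensory_sensitivity": [1, 1, 1, 1, 1, 1],
                "age": [12.0, 14.0, 16.0, 18.0, 20.0, 22.0],
            }
        )
        with pytest.raises(EstimationError):
            PresentationRegression.from_dataframe(df2, flags=("sensory_sensitivity",))


class TestAchievedPower:
    def test_published_configuration(self):
        res = achieved_power(0.11, 104, 3, 1, 0.05)
        assert res.f2 == pytest.approx(0.11 / 0.89, rel=1e-12)
        assert res.noncentrality == pytest.approx(0.11 / 0.89 * 104, rel=1e-12)
        assert (res.df_num, res.df_den) == (2, 100)
        assert 0.87 <= res.power <= 0.91

    def test_null_limit_is_alpha(self):
        assert achieved_power(1e-12, 104, 3, 1, 0.05).power == pytest.approx(0.05, abs=1e-6)

    def test_monotone_in_n(self):
        powers = [achieved_power(0.11, n, 3, 1, 0.05).power for n in (30, 60, 120)]
        assert powers[0] < powers[1] < powers[2]

    def test_matches_monte_carlo_noncentral_f(self):
        """Tail probability agrees with a raw-normal simulation of the
        noncentral F at 10^6 draws (MC SE ~3e-4)."""
        res = achieved_power(0.11, 104, 3, 1, 0.05)
        mc = noncentral_f_tail_mc(
            res.df_num, res.df_den, res.noncentrality, res.critical_F,
            n_draws=1_000_000, seed=314,
        )
        assert res.power == pytest.approx(mc, abs=0.005)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            achieved_power(0.0, 104, 3)
        with pytest.raises(ValueError):
            achieved_power(0.11, 104, 3, alpha=1.5)
        with pytest.raises(ValueError):
            achieved_power(0.11, 4, 3, 1)
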