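"""ANOVA battery: F test, Levene, studentized residuals, KS, runs test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oenotype.exceptions import OenotypeError
from oenotype.h2s import (
    count_runs,
    expected_runs,
    ks_normality,
    levene_test,
    one_way_anova,
    raw_residuals,
    runs_distribution,
    runs_test,
    studentized_residuals,
)
from oracles import runs_distribution_by_enumeration


def tidy(*groups):
    rows = [{"group": f"g{i}", "response": v}
            for i, g in enumerate(groups) for v in g]
    return pd.DataFrame(rows)


class TestAnova:
    def test_definitional_sums_of_squares(self):
        # SSB = 3*(2-3.5)^2 + 3*(5-3.5)^2 = 13.5, SSW = 4, F = (13.5/1)/(4/4)
        rep = one_way_anova(tidy([1, 2, 3], [4, 5, 6]), "group")
        assert rep.f_statistic == pytest.approx(13.5)
        assert (rep.df_between, rep.df_within) == (1, 4)
        assert rep.p_value == pytest.approx(stats.f.sf(13.5, 1, 4))

    def test_zero_f_for_identical_groups(self):
        rep = one_way_anova(tidy([1, 2, 3], [1, 2, 3]), "group")
        assert rep.f_statistic == pytest.approx(0.0)

    def test_planted_shift_detected(self, rng):
        a = rng.normal(0, 0.5, 25)
        b = rng.normal(3, 0.5, 25)
        rep = one_way_anova(tidy(a, b), "group")
        assert rep.significant

    def test_insufficient_replication_rejected(self):
        with pytest.raises(OenotypeError):
            one_way_anova(tidy([1.0], [2.0, 3.0]), "group")


class TestLevene:
    def test_zero_statistic_for_translated_copies(self):
        g1 = [0.0, 1.0, 3.0, 4.0]
        g2 = [10.0, 11.0, 13.0, 14.0]  # same spread, shifted
        stat, _ = levene_test(tidy(g1, g2), "group")
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_equals_anova_of_absolute_deviations(self, rng):
        g1, g2 = rng.normal(0, 1, 12), rng.normal(0, 3, 12)
        stat, p = levene_test(tidy(g1, g2), "group")
        f_ref, p_ref = stats.f_oneway(np.abs(g1 - g1.mean()), np.abs(g2 - g2.mean()))
        assert stat == pytest.approx(f_ref)
        assert p == pytest.approx(p_ref)

    def test_detects_scaled_group(self, rng):
        g1, g2 = rng.normal(0, 1, 60), rng.normal(0, 10, 60)
        _, p = levene_test(tidy(g1, g2), "group")
        assert p < 0.05


class TestStudentizedResiduals:
    def test_group_sums_zero_and_symmetry(self):
        df = tidy([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        raw = raw_residuals(df, "group")
        assert raw[:3].sum() == pytest.approx(0.0)
        assert raw[3:].sum() == pytest.approx(0.0)
        t = studentized_residuals(df, "group")
        np.testing.assert_allclose(np.sort(t), -np.sort(t)[::-1])

    def test_matches_delete_one_refit_oracle(self, rng):
        df = tidy([0.4, 1.9, 3.2], [3.9, 5.5, 6.1])
        t = studentized_residuals(df, "group")
        n, k = len(df), 2
        for i in range(n):
            rest = df.drop(index=i)
            means = rest.groupby("group")["response"].mean()
            e_rest = rest["response"] - rest["group"].map(means)
            s2 = (e_rest**2).sum() / (len(rest) - k)
            n_g = (df["group"] == df.loc[i, "group"]).sum()
            e_i = df.loc[i, "response"] - df[df["group"] == df.loc[i, "group"]]["response"].mean()
            expected = e_i / np.sqrt(s2 * (1 - 1 / n_g))
            assert t[i] == pytest.approx(expected, rel=1e-9)

    def test_singleton_group_rejected(self):
        df = pd.DataFrame({"group": ["a", "a", "b"], "response": [1.0, 2.0, 3.0]})
        with pytest.raises(OenotypeError):
            studentized_residuals(df, "group")


class TestKs:
    def test_normal_quantiles_give_small_statistic(self):
        n = 40
        r = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        d, p = ks_normality(r)
        assert d < 0.05 and p > 0.9

    def test_degenerate_residuals_rejected(self):
        with pytest.raises(OenotypeError):
            ks_normality([1.0, 1.0, 1.0])

    def test_statistic_in_unit_interval(self, rng):
        d, _ = ks_normality(rng.uniform(size=30))
        assert 0.0 <= d <= 1.0


class TestRuns:
    def test_run_counting(self):
        assert count_runs(np.array([1, 1, -1, -1, 1])) == 3

    def test_expected_runs_closed_form(self):
        assert expected_runs(5, 5) == pytest.approx(6.0)

    @pytest.mark.parametrize("n_pos,n_neg", [(3, 3), (4, 5), (6, 6), (2, 8)])
    def test_exact_distribution_matches_enumeration(self, n_pos, n_neg):
        closed = runs_distribution(n_pos, n_neg)
        brute = runs_distribution_by_enumeration(n_pos, n_neg)
        assert set(closed) == set(brute)
        for r in closed:
            assert closed[r] == pytest.approx(brute[r], rel=1e-12)

    def test_alternating_signs_extreme_p(self):
        x = np.array([1.0, -1.0] * 5)  # 10 runs out of 10 observations
        n_runs, p = runs_test(x)
        assert n_runs == 10
        dist = runs_distribution_by_enumeration(5, 5)
        expected = min(1.0, 2.0 * dist[10])
        assert p == pytest.approx(expected, rel=1e-12)

    def test_all_same_sign_rejected(self):
        with pytest.raises(OenotypeError):
            runs_test([1.0, 1.0, 1.0, 1.0] )

    def test_normal_approximation_matches_statsmodels(self, rng):
        from statsmodels.sandbox.stats.runs import runstest_1samp

        x = rng.normal(size=60)
        n_runs, p = runs_test(x)
        _, p_sm = runstest_1samp(x, cutoff="median", correction=False)
        assert p == pytest.approx(p_sm, rel=1e-9)


def test_full_battery_on_well_behaved_data(rng):
    df = tidy(rng.normal(0, 1, 30), rng.normal(0.2, 1, 30), rng.normal(-0.1, 1, 30))
    rep = one_way_anova(df, "group")
    assert 0 <= rep.p_value <= 1
    assert set(rep.assumptions) == {"homoscedastic", "normal_errors", "independent_errors"}
    d = rep.to_dict()
    assert d["df_between"] == 2 and d["df_within"] == 87
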