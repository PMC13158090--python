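"""Cohort statistics cross-checked against independent implementations."""

import numpy as np
import pytest
from scipy import stats
from statsmodels.stats.power import TTestIndPower

from regioncontrast import (
    GroupSample,
    SummaryStats,
    UndefinedCorrelationError,
    ks_normality,
    mwu_test,
    noninferiority_test,
    pearson_with_ci,
    posthoc_power,
    welch_test,
)


def _group(label, values):
    return GroupSample(label=label, values=np.asarray(values, dtype=float))


class TestWelch:
    def test_identical_groups(self):
        a = _group("a", [0.1, 0.2, 0.3, 0.4])
        res = welch_test(a, _group("b", [0.1, 0.2, 0.3, 0.4]))
        assert res.mean_diff == pytest.approx(0.0)
        assert res.p_two_sided == pytest.approx(1.0)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(21)
        a = _group("a", rng.normal(0.0, 1.0, 10))
        b = _group("b", rng.normal(1.0, 2.0, 14))
        res = welch_test(a, b)
        ref = stats.ttest_ind(a.values, b.values, equal_var=False)
        assert res.t == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p_two_sided == pytest.approx(ref.pvalue, abs=1e-10)
        ci = ref.confidence_interval(0.95)
        assert res.ci95[0] == pytest.approx(ci.low, abs=1e-10)
        assert res.ci95[1] == pytest.approx(ci.high, abs=1e-10)

    def test_ci_reconstructable_from_pieces(self):
        rng = np.random.default_rng(4)
        a = _group("a", rng.normal(0, 1, 12))
        b = _group("b", rng.normal(0.5, 1, 9))
        res = welch_test(a, b)
        tcrit = stats.t.ppf(0.975, res.df)
        assert res.ci95[0] == pytest.approx(res.mean_diff - tcrit * res.se)
        assert res.ci95[1] == pytest.approx(res.mean_diff + tcrit * res.se)

    def test_zero_variance_degenerate(self):
        res = welch_test(_group("a", [1.0, 1.0, 1.0]), _group("b", [1.0, 1.0]))
        assert res.degenerate and res.p_two_sided == 1.0


class TestNonInferiority:
    def test_equal_groups_ample_n_non_inferior(self):
        rng = np.random.default_rng(30)
        values = rng.normal(0.5, 0.12, 78)
        new = _group("new", rng.normal(0.5, 0.12, 61))
        res = noninferiority_test(new, _group("ref", values), margin=-0.1)
        assert res.verdict == "non_inferior"
        assert res.p_noninferiority < 0.001

    def test_large_true_deficit_not_shown(self):
        rng = np.random.default_rng(31)
        ref = _group("ref", rng.normal(0.5, 0.12, 78))
        new = _group("new", rng.normal(0.25, 0.12, 17))
        res = noninferiority_test(new, ref, margin=-0.1)
        assert res.verdict == "inferior_not_shown"
        assert res.p_noninferiority > 0.5

    def test_p_rule_and_ci_rule_agree(self):
        rng = np.random.default_rng(32)
        for _ in range(200):
            ref = _group("ref", rng.normal(0.5, 0.12, 20))
            new = _group("new", rng.normal(0.42, 0.12, 15))
            res = noninferiority_test(new, ref, margin=-0.1, alpha=0.025)
            ci_verdict = res.ci95[0] > res.noninferiority_margin
            assert (res.verdict == "non_inferior") == ci_verdict
            assert res.ci95[0] <= res.mean_diff <= res.ci95[1]

    def test_positive_margin_rejected(self):
        with pytest.raises(ValueError):
            noninferiority_test(_group("a", [1.0, 2.0]), _group("b", [1.0, 2.0]), margin=0.1)


class TestPosthocPower:
    def test_null_effect_gives_alpha(self):
        a = SummaryStats(mean=0.0, sd=1.0, n=30)
        b = SummaryStats(mean=0.0, sd=1.0, n=30)
        assert posthoc_power(a, b, alpha=0.05, sided="one-sided") == pytest.approx(0.05, abs=1e-9)
        assert posthoc_power(a, b, alpha=0.05, sided="two-sided") == pytest.approx(0.05, abs=0.003)

    def test_huge_effect_saturates(self):
        a = SummaryStats(mean=3.0, sd=1.0, n=20)
        b = SummaryStats(mean=0.0, sd=1.0, n=20)
        assert posthoc_power(a, b) > 0.99

    def test_matches_statsmodels_with_pooled_df(self):
        a = SummaryStats(mean=0.5, sd=1.0, n=61)
        b = SummaryStats(mean=0.0, sd=1.0, n=78)
        mine = posthoc_power(a, b, alpha=0.05, sided="two-sided", df_mode="pooled")
        ref = TTestIndPower().power(effect_size=0.5, nobs1=61, ratio=78 / 61, alpha=0.05)
        assert mine == pytest.approx(ref, abs=1e-6)


class TestMWU:
    def test_exact_small_sample(self):
        u, p = mwu_test(_group("a", [1, 2, 3]), _group("b", [4, 5, 6]))
        # U convention: pairs where a > b (plus half-ties); fully separated -> 0
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        vals = np.arange(10.0)
        _, p = mwu_test(_group("a", vals), _group("b", vals))
        assert p > 0.9


class TestKSNormality:
    def test_normal_sample_accepted(self):
        rng = np.random.default_rng(40)
        res = ks_normality(_group("a", rng.normal(0, 1, 1000)))
        assert res.p > 0.05

    def test_exponential_sample_rejected(self):
        rng = np.random.default_rng(41)
        res = ks_normality(_group("a", rng.exponential(1.0, 1000)))
        assert res.p < 0.01

    def test_lilliefors_variant_more_conservative(self):
        rng = np.random.default_rng(42)
        sample = _group("a", rng.normal(0, 1, 200))
        assert ks_normality(sample, lilliefors=True).p <= ks_normality(sample).p + 1e-9

    def test_constant_sample_degenerate(self):
        res = ks_normality(_group("a", np.full(10, 3.0)))
        assert res.degenerate


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        res = pearson_with_ci(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.ci95[1] == pytest.approx(1.0)
        res_neg = pearson_with_ci(x, -x)
        assert res_neg.r == pytest.approx(-1.0)

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_with_ci(np.ones(10), np.arange(10.0))

    def test_fisher_ci_formula(self):
        rng = np.random.default_rng(50)
        x = rng.normal(0, 1, 61)
        y = -0.5 * x + rng.normal(0, np.sqrt(0.75), 61)
        res = pearson_with_ci(x, y)
        z = np.arctanh(res.r)
        half = stats.norm.ppf(0.975) / np.sqrt(61 - 3)
        assert res.ci95 == pytest.approx((np.tanh(z - half), np.tanh(z + half)))
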