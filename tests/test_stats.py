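"""Tests for the strategy-comparison statistics, against independent oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from vitalsched.stats import (
    bootstrap_median_diff,
    prop_test_cc,
    ratio_of_means_ci,
    ratio_of_proportions_ci,
    two_sample_t,
    wilcoxon_signed_rank,
)


def wilcoxon_sign_enumeration(diffs):
    """Exhaustive two-sided signed-rank p over all 2^n sign patterns."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        ranks[list(signs)].sum() if any(signs) else 0.0
        for signs in itertools.product([False, True], repeat=n)
    ]
    ws = np.array(ws)
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2 * min(p_le, p_ge))


class TestTwoSampleT:
    def test_identical_groups(self):
        res = two_sample_t([1.0, 2, 3], [1.0, 2, 3])
        assert res.estimate == 0.0 and res.p_value == pytest.approx(1.0)

    def test_shifted_three_point_groups(self):
        res = two_sample_t([1.0, 2, 3], [11.0, 12, 13])
        assert res.estimate == pytest.approx(-10.0)
        assert res.p_value < 0.01

    def test_matches_textbook_welch_on_fixed_sample(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0.6, 0.2, 10), rng.normal(0.5, 0.3, 10)
        res = two_sample_t(a, b)
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se = math.sqrt(va / 10 + vb / 10)
        t = (a.mean() - b.mean()) / se
        df = se**4 / ((va / 10) ** 2 / 9 + (vb / 10) ** 2 / 9)
        assert res.p_value == pytest.approx(2 * sps.t.sf(abs(t), df))
        assert res.ci_low == pytest.approx(res.estimate - sps.t.ppf(0.975, df) * se)
        assert res.ci_low <= res.estimate <= res.ci_high

    def test_zero_variance_equal_means_flagged(self):
        res = two_sample_t([2.0, 2, 2], [2.0, 2, 2])
        assert res.p_value == 1.0 and "zero_variance" in res.flags

    def test_pooled_switch_matches_scipy_student(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        res = two_sample_t(a, b, equal_var=True)
        assert res.p_value == pytest.approx(sps.ttest_ind(a, b, equal_var=True).pvalue)


class TestRatioOfMeans:
    def test_identical_groups_ratio_one(self):
        x = [0.4, 0.5, 0.6, 0.7]
        res = ratio_of_means_ci(x, x)
        assert res.estimate == pytest.approx(1.0)
        assert res.ci_low <= 1.0 <= res.ci_high

    def test_doubled_group_large_n(self):
        rng = np.random.default_rng(2)
        b = rng.uniform(0.5, 1.0, 400)
        res = ratio_of_means_ci(2 * b, b)
        assert res.estimate == pytest.approx(2.0)
        assert res.ci_low > 1.0
        assert res.p_value < 1e-6

    def test_matches_parametric_bootstrap_oracle(self):
        """Fieller endpoints agree with a large parametric bootstrap of the
        ratio of means on a fixed small dataset."""
        rng = np.random.default_rng(0)
        a = rng.normal(0.65, 0.15, 30)
        b = rng.normal(0.45, 0.20, 30)
        res = ratio_of_means_ci(a, b)
        B = 100_000
        ma = rng.normal(a.mean(), a.std(ddof=1) / math.sqrt(30), B)
        mb = rng.normal(b.mean(), b.std(ddof=1) / math.sqrt(30), B)
        lo, hi = np.percentile(ma / mb, [2.5, 97.5])
        assert res.ci_low == pytest.approx(lo, abs=0.03)
        assert res.ci_high == pytest.approx(hi, abs=0.03)

    def test_unbounded_ci_flagged_when_denominator_noisy(self):
        rng = np.random.default_rng(3)
        a = rng.normal(1.0, 0.1, 5)
        b = np.array([0.01, 2.0, -1.5, 1.4, 0.2])  # mean barely positive
        res = ratio_of_means_ci(a, b)
        assert "unbounded_ci" in res.flags
        assert np.isinf(res.ci_high)


class TestPropTest:
    def test_equal_proportions(self):
        res = prop_test_cc(50, 100, 50, 100)
        assert res.p_value == pytest.approx(1.0)
        assert res.estimate == 0.0

    def test_hand_computed_yates_chi2(self):
        # table [[90,10],[10,90]]: all expected counts 50,
        # chi2 = 4 * (|40| - 0.5)^2 / 50 = 124.82
        res = prop_test_cc(90, 100, 10, 100)
        assert res.p_value == pytest.approx(sps.chi2.sf(4 * 39.5**2 / 50, df=1))
        assert res.p_value < 0.001

    def test_zero_margin_convention(self):
        res = prop_test_cc(0, 20, 0, 30)
        assert res.p_value == 1.0 and "zero_margin" in res.flags

    @pytest.mark.parametrize("x1,n1,x2,n2", [(8, 10, 2, 10), (1, 12, 9, 14), (5, 8, 5, 9)])
    def test_significance_direction_matches_fisher(self, x1, n1, x2, n2):
        res = prop_test_cc(x1, n1, x2, n2)
        fisher_p = sps.fisher_exact([[x1, n1 - x1], [x2, n2 - x2]]).pvalue
        assert (res.p_value < 0.05) == (fisher_p < 0.05)


class TestRatioOfProportions:
    def test_equal_proportions_ci_contains_one(self):
        res = ratio_of_proportions_ci(30, 100, 30, 100)
        assert res.estimate == pytest.approx(1.0)
        assert res.ci_low < 1.0 < res.ci_high
        assert res.p_value == pytest.approx(1.0)

    def test_converges_to_uncorrected_score_when_skewness_vanishes(self):
        """In the balanced large-n case the skewness correction is negligible
        and the corrected limits approach the plain score (Koopman) limits."""
        corrected = ratio_of_proportions_ci(5000, 10000, 5000, 10000)
        plain = ratio_of_proportions_ci(5000, 10000, 5000, 10000, skew_corrected=False)
        assert corrected.ci_low == pytest.approx(plain.ci_low, abs=1e-5)
        assert corrected.ci_high == pytest.approx(plain.ci_high, abs=1e-5)
        # at smaller n the two differ, bracketing from the same side
        c_small = ratio_of_proportions_ci(12, 40, 8, 40)
        p_small = ratio_of_proportions_ci(12, 40, 8, 40, skew_corrected=False)
        assert abs(c_small.ci_low - p_small.ci_low) > 1e-4

    def test_zero_numerator_lower_bound_zero(self):
        res = ratio_of_proportions_ci(0, 50, 10, 50)
        assert res.ci_low == 0.0 and res.estimate == 0.0
        assert np.isfinite(res.ci_high)

    def test_zero_denominator_unbounded(self):
        res = ratio_of_proportions_ci(10, 50, 0, 50)
        assert np.isinf(res.estimate) and np.isinf(res.ci_high)

    def test_ci_contains_estimate(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n1, n2 = int(rng.integers(5, 200)), int(rng.integers(5, 200))
            x1, x2 = int(rng.integers(1, n1 + 1)), int(rng.integers(1, n2 + 1))
            res = ratio_of_proportions_ci(x1, n1, x2, n2)
            assert res.ci_low <= res.estimate <= res.ci_high


class TestWilcoxon:
    def test_all_ties_p_one(self):
        res = wilcoxon_signed_rank([3.0, 4, 5], [3.0, 4, 5])
        assert res.p_value == 1.0 and "all_zero_diffs" in res.flags

    def test_six_positive_differences_exact(self):
        res = wilcoxon_signed_rank([5.0, 6, 7, 8, 9, 10], [1.0, 2, 3, 4, 5, 6])
        assert res.p_value == pytest.approx(1 / 32)

    def test_exact_branch_matches_sign_enumeration(self):
        rng = np.random.default_rng(5)
        for n in (4, 6, 8, 10):
            for _ in range(5):
                d = rng.normal(0.3, 1.0, n)
                while len(np.unique(np.abs(d))) < n or (d == 0).any():
                    d = rng.normal(0.3, 1.0, n)
                res = wilcoxon_signed_rank(d, np.zeros(n))
                assert res.p_value == pytest.approx(wilcoxon_sign_enumeration(d))

    def test_exact_and_approx_agree_at_boundary(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            d = rng.normal(0.4, 1.0, 25)
            p_exact = sps.wilcoxon(d, method="exact").pvalue
            p_approx = sps.wilcoxon(d, method="approx", correction=True).pvalue
            assert abs(p_exact - p_approx) < 0.015


class TestBootstrapMedianDiff:
    def test_constant_samples(self):
        res = bootstrap_median_diff(np.full(10, 3.0), np.full(12, 3.0), 500, seed=1)
        assert res.estimate == 0.0
        assert res.ci_low == 0.0 and res.ci_high == 0.0

    def test_shift_recovered(self):
        rng = np.random.default_rng(7)
        x = rng.normal(50, 10, 300)
        res = bootstrap_median_diff(x + 31, x, 2000, seed=2)
        assert res.ci_low <= 31 <= res.ci_high
        assert res.estimate == pytest.approx(31.0)

    def test_bit_exact_reproducibility(self):
        rng = np.random.default_rng(8)
        a, b = rng.exponential(40, 60), rng.exponential(30, 80)
        r1 = bootstrap_median_diff(a, b, 3000, seed=9)
        r2 = bootstrap_median_diff(a, b, 3000, seed=9)
        assert (r1.ci_low, r1.ci_high, r1.p_value) == (r2.ci_low, r2.ci_high, r2.p_value)

    def test_paired_variant_tightens_ci_for_correlated_data(self):
        rng = np.random.default_rng(9)
        base = rng.normal(60, 20, 80)
        a, b = base + rng.normal(5, 2, 80), base
        unpaired = bootstrap_median_diff(a, b, 3000, seed=3)
        paired = bootstrap_median_diff(a, b, 3000, seed=3, paired=True)
        assert (paired.ci_high - paired.ci_low) < (unpaired.ci_high - unpaired.ci_low)
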