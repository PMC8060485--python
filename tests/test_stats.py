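"""2x2 statistics, exact tests against enumeration oracles, logistic fits."""

import math
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from cvflow.stats import (
    Contingency2x2,
    DegenerateSampleError,
    SeparationError,
    association_test_2x2,
    fmt_count_pct,
    fmt_median_iqr,
    group_compare_continuous,
    logistic_regression,
    odds_ratio_woolf,
)

cells = st.integers(min_value=1, max_value=25)


class TestWoolfOddsRatio:
    def test_velocity_collateral_printed_table(self):
        # poor-fast 11, poor-slow 3, good-fast 8, good-slow 14
        r = odds_ratio_woolf(Contingency2x2(11, 3, 8, 14))
        assert round(r.odds_ratio, 2) == 6.42
        assert (round(r.ci_low, 2), round(r.ci_high, 2)) == (1.37, 30.05)
        assert r.method == "woolf"

    def test_outcome_printed_interval(self):
        # good & two-vein-absent 1/25 vs poor 6/11
        r = odds_ratio_woolf(Contingency2x2(1, 24, 6, 5))
        assert round(r.ci_low, 3) == 0.003
        assert round(r.ci_high, 2) == 0.36

    def test_balanced_table_is_unity(self):
        assert odds_ratio_woolf(Contingency2x2(1, 1, 1, 1)).odds_ratio == pytest.approx(1.0)

    def test_haldane_correction_by_hand(self):
        r = odds_ratio_woolf(Contingency2x2(5, 0, 3, 7))
        assert r.method == "woolf_haldane"
        assert r.odds_ratio == pytest.approx((5.5 * 7.5) / (0.5 * 3.5))

    @given(cells, cells, cells, cells)
    @settings(max_examples=100, deadline=None)
    def test_exposure_flip_reciprocity(self, a, b, c, d):
        fwd = odds_ratio_woolf(Contingency2x2(a, b, c, d))
        rev = odds_ratio_woolf(Contingency2x2(b, a, d, c))
        assert fwd.odds_ratio * rev.odds_ratio == pytest.approx(1.0)
        assert fwd.ci_low * rev.ci_high == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            Contingency2x2(0, 0, 0, 0)


def fisher_oracle(a, b, c, d):
    """Independent exhaustive enumeration over tables with fixed margins,
    using exact integer combinatorics (different code path from the
    implementation's Fraction map)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    obs = math.comb(r1, a) * math.comb(r2, c)
    total = 0
    for k in range(0, min(r1, c1) + 1):
        if c1 - k > r2:
            continue
        w = math.comb(r1, k) * math.comb(r2, c1 - k)
        if w <= obs:
            total += w
    return total / denom


class TestAssociation2x2:
    def test_independent_table_chi2_zero(self):
        r = association_test_2x2(Contingency2x2(10, 10, 10, 10), mode="pearson")
        assert r.statistic == pytest.approx(0.0) and r.p_value == pytest.approx(1.0)

    def test_pearson_closed_form(self):
        a, b, c, d = 8, 14, 11, 3
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        r = association_test_2x2(Contingency2x2(a, b, c, d), mode="pearson")
        assert r.statistic == pytest.approx(expected, rel=1e-12)

    def test_pearson_matches_generic_rxc_chi_square(self):
        # oracle: direct expected-count sum over the 2x2
        t = Contingency2x2(7, 12, 15, 4)
        obs = t.matrix
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        chi2 = ((obs - exp) ** 2 / exp).sum()
        r = association_test_2x2(t, mode="pearson")
        assert r.statistic == pytest.approx(chi2, rel=1e-12)

    def test_fisher_against_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        tables = [(1, 9, 9, 1), (2, 3, 4, 5), (1, 1, 1, 1), (5, 0, 0, 5), (3, 7, 2, 8)]
        tables += [tuple(rng.integers(0, 11, 4)) for _ in range(40)]
        for a, b, c, d in tables:
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            p = association_test_2x2(Contingency2x2(a, b, c, d), mode="fisher").p_value
            assert p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-12)

    def test_fisher_cross_checked_against_scipy(self):
        for table in [(1, 9, 9, 1), (8, 2, 1, 5), (3, 3, 4, 4)]:
            a, b, c, d = table
            ours = association_test_2x2(Contingency2x2(a, b, c, d), mode="fisher").p_value
            ref = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
            assert ours == pytest.approx(ref, rel=1e-9)

    def test_yates_correction_shrinks_statistic(self):
        t = Contingency2x2(12, 5, 6, 14)
        plain = association_test_2x2(t, mode="pearson").statistic
        corrected = association_test_2x2(t, mode="yates").statistic
        assert 0 < corrected < plain
        ref = sps.chi2_contingency(t.matrix, correction=True)
        assert corrected == pytest.approx(ref.statistic, rel=1e-10)

    def test_auto_picks_fisher_for_small_expected_cells(self):
        small = association_test_2x2(Contingency2x2(1, 2, 3, 4))
        big = association_test_2x2(Contingency2x2(20, 20, 20, 20))
        assert small.method == "fisher" and big.method == "pearson"

    def test_zero_margin_is_degenerate(self):
        r = association_test_2x2(Contingency2x2(0, 0, 5, 5))
        assert r.degenerate and r.p_value == 1.0 and r.statistic == 0.0


def mann_whitney_oracle(x, y):
    """Full permutation enumeration over all group labelings of the pooled
    sample, recomputing the U statistic from scratch for each labeling."""
    from itertools import combinations

    pooled = list(x) + list(y)
    nx = len(x)
    idx_all = range(len(pooled))

    def u_of(indices):
        xs = [pooled[i] for i in indices]
        ys = [pooled[i] for i in idx_all if i not in set(indices)]
        u = 0.0
        for xi in xs:
            for yi in ys:
                u += 1.0 if xi > yi else (0.5 if xi == yi else 0.0)
        return u

    u_obs = u_of(tuple(range(nx)))
    us = [u_of(comb) for comb in combinations(idx_all, nx)]
    p_le = sum(u <= u_obs + 1e-12 for u in us) / len(us)
    p_ge = sum(u >= u_obs - 1e-12 for u in us) / len(us)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestGroupCompare:
    def test_identical_samples_exact_p_is_one(self):
        r = group_compare_continuous([1, 2, 3], [1, 2, 3], mode="mann_whitney")
        assert r.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "x, y",
        [([1, 2], [3, 4]), ([1, 5, 2], [4, 4, 6]), ([1, 1, 2], [2, 3]), ([10, 12, 9, 14], [8, 7])],
    )
    def test_exact_p_matches_permutation_oracle(self, x, y):
        r = group_compare_continuous(x, y, mode="mann_whitney")
        assert r.p_value == pytest.approx(mann_whitney_oracle(x, y), abs=1e-12)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 30), rng.normal(1, 1, 25)
        ours = group_compare_continuous(x, y, mode="mann_whitney")
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert ours.p_value == pytest.approx(ref.pvalue)

    def test_pooled_t_matches_scipy(self):
        x, y = [1.0, 2.0, 3.0, 5.0], [2.5, 4.0, 6.0]
        r = group_compare_continuous(x, y, mode="t")
        stat, p = sps.ttest_ind(x, y, equal_var=True)
        assert (r.statistic, r.p_value) == pytest.approx((stat, p))

    def test_degenerate_zero_variance(self):
        with pytest.raises(DegenerateSampleError):
            group_compare_continuous([1, 1, 1], [1, 1], mode="t")

    def test_type_one_error_rate_under_null(self):
        # 2000 null replicates at alpha = 0.05: rejection rate within 0.05 +/- 0.015
        rng = np.random.default_rng(2021)
        n_rej = 0
        reps = 2000
        for _ in range(reps):
            x, y = rng.normal(0, 1, 20), rng.normal(0, 1, 20)
            if group_compare_continuous(x, y, mode="t").p_value < 0.05:
                n_rej += 1
        assert abs(n_rej / reps - 0.05) <= 0.015


class TestLogistic:
    @given(cells, cells, cells, cells)
    @settings(max_examples=40, deadline=None)
    def test_saturated_two_by_two_equals_cross_product(self, a, b, c, d):
        # outcome = case, predictor = exposure; fitted OR must equal ad/bc
        y = np.r_[np.ones(a + b), np.zeros(c + d)]
        x = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        fit = logistic_regression(y, x, names=("exposed",))
        assert fit.odds_ratios[1] == pytest.approx((a * d) / (b * c), rel=1e-6)

    def test_wald_interval_matches_woolf_on_2x2(self):
        a, b, c, d = 11, 3, 8, 14
        y = np.r_[np.ones(a + b), np.zeros(c + d)]
        x = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        fit = logistic_regression(y, x)
        woolf = odds_ratio_woolf(Contingency2x2(a, b, c, d))
        assert fit.ci_low[1] == pytest.approx(woolf.ci_low, rel=1e-4)
        assert fit.ci_high[1] == pytest.approx(woolf.ci_high, rel=1e-4)

    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(5), np.zeros(15)]  # prevalence 0.25
        fit = logistic_regression(y, np.zeros((20, 0)), names=(), add_intercept=True)
        assert fit.coefficients[0] == pytest.approx(np.log(0.25 / 0.75), abs=1e-8)

    def test_perfect_separation_raises(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        x = np.r_[np.ones(10), np.zeros(10)]  # predictor == outcome
        with pytest.raises(SeparationError):
            logistic_regression(y, x)

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError):
            logistic_regression(np.ones(10), np.arange(10.0))


class TestFormatting:
    @pytest.mark.parametrize(
        "k, n, expected",
        [(8, 22, "8 (36%)"), (11, 14, "11 (79%)"), (0, 7, "0 (0%)"), (1, 8, "1 (13%)")],
    )
    def test_count_percent(self, k, n, expected):
        assert fmt_count_pct(k, n) == expected

    def test_median_iqr(self):
        out = fmt_median_iqr([1, 2, 3, 4, 5], decimals=1)
        assert out == "3.0 (2.0–4.0)"
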