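"""Statistical layer: rank-sum, chi-square, ANOVA, 2D KDE, condition reports."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from focimetry.io import Channel
from focimetry.stats import (
    anova_oneway,
    chi2_2x2,
    compare_conditions,
    kde2d,
    wilcoxon_rank_sum,
)


def _exact_wilcoxon_p(x, y):
    """Oracle: full enumeration of the rank-sum null over all label splits."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    n1n2 = n1 * len(y)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        us.append(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2)
    us = np.array(us)
    # two-sided: as or more extreme in either tail, measured from n1n2/2
    return np.mean(np.abs(us - n1n2 / 2) >= abs(u_obs - n1n2 / 2) - 1e-12)


class TestWilcoxon:
    def test_identical_samples_symmetric(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = wilcoxon_rank_sum(x, x)
        assert res.statistic == len(x) ** 2 / 2
        assert res.p_value == pytest.approx(1.0)

    def test_fully_separated_small_samples(self):
        # only 2 of the C(6,3) = 20 splits are as extreme -> p = 0.1
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1)
        assert "exact" in res.method

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_exact_path_matches_full_enumeration(self, n, rng):
        for _ in range(4):
            pooled = rng.permutation(np.arange(1.0, 2 * n + 1))  # tie-free
            x, y = pooled[:n], pooled[n:]
            res = wilcoxon_rank_sum(x, y)
            assert res.p_value == pytest.approx(_exact_wilcoxon_p(x, y), abs=1e-12)

    def test_swap_invariance(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=40) + 0.5
        a, b = wilcoxon_rank_sum(x, y), wilcoxon_rank_sum(y, x)
        assert a.p_value == pytest.approx(b.p_value)

    def test_large_shifted_samples_highly_significant(self, rng):
        x = rng.normal(size=2000)
        y = rng.normal(size=2000) + 1.0
        assert wilcoxon_rank_sum(x, y).p_value < 1e-10

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestChi2:
    def test_worked_example_with_and_without_yates(self):
        # E = 15 everywhere: uncorrected 4*(5^2/15), Yates 4*(4.5^2/15)
        assert chi2_2x2(10, 20, 20, 10, yates=False).statistic == pytest.approx(20 / 3)
        assert chi2_2x2(10, 20, 20, 10, yates=True).statistic == pytest.approx(5.4)

    def test_equal_proportions_give_zero(self):
        for yates in (True, False):
            assert chi2_2x2(30, 70, 60, 140, yates=yates).statistic == 0.0

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi2_2x2(0, 0, 5, 5)

    def test_uncorrected_matches_brute_force_and_scipy(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(1, 500, size=4)
            res = chi2_2x2(a, b, c, d, yates=False)
            O = np.array([[a, b], [c, d]], dtype=float)
            E = np.outer(O.sum(1), O.sum(0)) / O.sum()
            brute = ((O - E) ** 2 / E).sum()
            assert abs(res.statistic - brute) <= 1e-9 * max(brute, 1.0)
            scipy_stat = sps.chi2_contingency(O, correction=False).statistic
            assert res.statistic == pytest.approx(scipy_stat)

    def test_yates_matches_scipy_correction(self, rng):
        for _ in range(20):
            a, b, c, d = rng.integers(5, 500, size=4)
            res = chi2_2x2(a, b, c, d, yates=True)
            scipy_stat = sps.chi2_contingency(
                np.array([[a, b], [c, d]]), correction=True
            ).statistic
            assert res.statistic == pytest.approx(scipy_stat)

    def test_column_swap_invariance(self):
        a = chi2_2x2(12, 34, 56, 78)
        b = chi2_2x2(34, 12, 78, 56)
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_value == pytest.approx(b.p_value)


class TestAnova:
    def test_hand_computed_example(self):
        # group means 2,3,4; grand 3: SSB = 6, SSW = 6, F = (6/2)/(6/6) = 3
        res = anova_oneway([np.array([1.0, 2, 3]), np.array([2.0, 3, 4]), np.array([3.0, 4, 5])])
        assert res.ss_between == pytest.approx(6.0)
        assert res.ss_within == pytest.approx(6.0)
        assert res.statistic == pytest.approx(3.0)
        assert (res.df_between, res.df_within) == (2, 6)

    def test_matches_scipy_f_oneway(self, rng):
        groups = [rng.normal(loc=i * 0.1, size=20) for i in range(4)]
        res = anova_oneway(groups)
        ref = sps.f_oneway(*groups)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_group_order_invariance(self, rng):
        groups = [rng.normal(size=10) for _ in range(3)]
        assert anova_oneway(groups).statistic == pytest.approx(
            anova_oneway(groups[::-1]).statistic
        )

    def test_identical_values_flagged_degenerate(self):
        res = anova_oneway([np.full(3, 2.0), np.full(4, 2.0)])
        assert res.degenerate
        assert np.isnan(res.statistic)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match=">= 2 values"):
            anova_oneway([np.array([1.0]), np.array([1.0, 2.0])])

    def test_type_i_error_calibrated(self, rng):
        # groups from one distribution: rejection rate at alpha=.05 is ~5%
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            groups = [rng.normal(size=15) for _ in range(3)]
            rejections += anova_oneway(groups).p_value < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.03)


class TestKde2d:
    def test_grid_integral_is_one(self, rng):
        grid = kde2d(rng.normal(size=500), rng.normal(size=500) * 2 + 1)
        assert grid.integral() == pytest.approx(1.0, abs=0.01)

    def test_mode_near_origin_for_standard_normal(self, rng):
        grid = kde2d(
            rng.standard_normal(20_000), rng.standard_normal(20_000),
            grid_size=(256, 256), bandwidth=(0.4, 0.4),
        )
        mx, my = grid.mode()
        assert abs(mx) < 0.1 and abs(my) < 0.1

    def test_zero_variance_axis_rejected(self):
        with pytest.raises(ValueError, match="bandwidth"):
            kde2d([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_matches_direct_kernel_sum(self, rng):
        # oracle: explicit double loop over data points and grid nodes
        x, y = rng.standard_normal(60), rng.standard_normal(60)
        hx, hy = 0.4, 0.7
        grid = kde2d(x, y, bandwidth=(hx, hy), grid_size=(16, 16))
        ref = np.zeros((16, 16))
        for j, gy in enumerate(grid.y):
            for i, gx in enumerate(grid.x):
                k = np.exp(-0.5 * ((gx - x) / hx) ** 2 - 0.5 * ((gy - y) / hy) ** 2)
                ref[j, i] = k.sum() / (len(x) * 2 * np.pi * hx * hy)
        assert np.allclose(grid.density, ref, rtol=1e-9, atol=1e-12)


def _table(values, treatment="ETP") -> pd.DataFrame:
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        {
            "treatment": treatment,
            "sum_spot_53bp1": values,
            "mean_gh2ax": values * 0.5 + 3,
        }
    )


class TestCompareConditions:
    def test_self_comparison_is_null(self, rng):
        cells = _table(rng.normal(size=300) ** 2)
        report = compare_conditions(cells, cells)
        for marker in (Channel.M53BP1, Channel.GH2AX):
            assert report.wilcoxon[marker].p_value == pytest.approx(1.0, abs=0.01)
            assert report.contingency[marker].statistic == 0.0
            assert report.median_difference[marker] == 0.0

    def test_shifted_condition_detected(self, rng):
        control = _table(rng.normal(size=500) ** 2, "DMSO")
        treated = _table(rng.normal(size=500) ** 2 * 4 + 2, "ETP")
        report = compare_conditions(treated, control)
        for marker in (Channel.M53BP1, Channel.GH2AX):
            assert report.median_difference[marker] > 0
            assert report.wilcoxon[marker].p_value < 1e-10
            assert (
                report.positive_fraction_treated[marker]
                > report.positive_fraction_control[marker]
            )

    def test_empty_condition_rejected(self):
        cells = _table([1.0, 2.0])
        with pytest.raises(ValueError, match="non-empty"):
            compare_conditions(cells, cells.iloc[:0])
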