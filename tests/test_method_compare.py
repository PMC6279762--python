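"""Method-comparison and assay-validation statistics."""

import numpy as np
import pytest

from ovuconfirm.method_compare import (
    bland_altman,
    cross_reactivity,
    freeze_thaw_change,
    passing_bablok,
    pearson_log,
    precision_anova,
    recovery_analysis,
)


def pb_oracle_slope(x, y):
    """Brute-force Passing-Bablok slope: explicit double loop, same K-shift."""
    slopes = []
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            if x[j] != x[i]:
                s = (y[j] - y[i]) / (x[j] - x[i])
                if s != -1.0:
                    slopes.append(s)
    slopes.sort()
    big_n = len(slopes)
    k = sum(s < -1.0 for s in slopes)
    if big_n % 2 == 1:
        return slopes[(big_n + 1) // 2 + k - 1]
    return 0.5 * (slopes[big_n // 2 + k - 1] + slopes[big_n // 2 + k])


class TestPearsonLog:
    def test_exact_power_law_gives_r_1(self):
        x = np.array([0.5, 1.0, 2.0, 4.0, 9.0])
        y = 3.0 * x**1.7
        r, p = pearson_log(x, y)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_independent_data_r_near_zero(self, rng):
        x = rng.lognormal(size=4000)
        y = rng.lognormal(size=4000)
        r, _ = pearson_log(x, y)
        assert abs(r) < 0.05

    def test_hand_computed_log_covariance(self):
        x = [1.0, 2.0, 4.0, 8.0, 16.0]
        y = [2.0, 3.0, 10.0, 12.0, 40.0]
        lx, ly = np.log(x), np.log(y)
        expected = np.cov(lx, ly)[0, 1] / (lx.std(ddof=1) * ly.std(ddof=1))
        r, _ = pearson_log(x, y)
        assert r == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_pairs_dropped_and_too_few_rejected(self):
        with pytest.raises(ValueError):
            pearson_log([0.0, 1.0, 2.0], [1.0, 2.0, 3.0])


class TestBlandAltman:
    def test_identity_has_zero_bias_and_degenerate_loa(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = bland_altman(x, x)
        assert res.mean_difference == 0.0
        assert res.loa_lower == res.loa_upper == 0.0
        assert res.proportional_bias_slope == pytest.approx(0.0)

    def test_constant_offset(self):
        x = np.array([1.0, 2.0, 3.0])
        res = bland_altman(x, x + 1.0)
        assert res.mean_difference == pytest.approx(-1.0)
        assert res.sd_differences == pytest.approx(0.0)

    def test_proportional_error_slope_closed_form(self):
        # y = 1.1 x → d = −0.1x, m = 1.05x → slope = −0.1/1.05 = −2·0.1/2.1
        x = np.linspace(1.0, 10.0, 12)
        res = bland_altman(x, 1.1 * x)
        assert res.proportional_bias_slope == pytest.approx(-2 * 0.1 / 2.1)

    def test_loa_contain_bias(self, rng):
        x = rng.normal(10, 2, 50)
        y = x + rng.normal(0.5, 1.0, 50)
        res = bland_altman(x, y)
        assert res.loa_lower <= res.mean_difference <= res.loa_upper

    def test_loa_cover_95_percent_of_normal_differences(self, rng):
        """At n=2000 the 95% LoA cover ≈95% of the differences (±2 pp)."""
        x = rng.normal(50, 5, 2000)
        y = x + rng.normal(1.0, 2.0, 2000)
        res = bland_altman(x, y)
        d = x - y
        coverage = np.mean((d >= res.loa_lower) & (d <= res.loa_upper))
        assert abs(coverage - 0.95) <= 0.02


class TestPassingBablok:
    def test_exact_proportionality(self):
        x = np.array([1, 2, 3, 5, 8, 13.0])
        res = passing_bablok(x, 2.0 * x)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(0.0)

    def test_exact_offset(self):
        x = np.array([1, 2, 4, 7, 11.0])
        res = passing_bablok(x, x + 3.0)
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(3.0)

    def test_matches_brute_force_oracle_on_random_fixtures(self, rng):
        for _ in range(100):
            x = rng.lognormal(1.0, 0.6, 15)
            y = 1.2 * x + rng.normal(0, 0.4, 15)
            res = passing_bablok(x, y)
            assert res.slope == pytest.approx(pb_oracle_slope(x, y), rel=1e-12)

    def test_point_order_invariance(self, rng):
        x = rng.lognormal(1.0, 0.5, 12)
        y = 0.8 * x + 1.0 + rng.normal(0, 0.2, 12)
        perm = rng.permutation(12)
        a = passing_bablok(x, y)
        b = passing_bablok(x[perm], y[perm])
        assert a.slope == pytest.approx(b.slope)
        assert a.intercept == pytest.approx(b.intercept)

    def test_axis_swap_inverts_slope(self, rng):
        x = rng.lognormal(1.0, 0.5, 15)
        y = 1.5 * x + rng.normal(0, 0.1, 15)
        forward = passing_bablok(x, y)
        backward = passing_bablok(y, x)
        assert backward.slope == pytest.approx(1.0 / forward.slope, rel=0.05)

    def test_slope_ci_brackets_estimate(self, rng):
        x = rng.lognormal(1.0, 0.5, 20)
        y = 1.3 * x + rng.normal(0, 0.3, 20)
        res = passing_bablok(x, y)
        lo, hi = res.slope_ci_95
        assert lo <= res.slope <= hi

    def test_all_x_identical_rejected(self):
        with pytest.raises(ValueError):
            passing_bablok([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestRecovery:
    def test_perfect_recovery_everywhere(self):
        res = recovery_analysis(12.5, [1, 2, 4, 8],
                                [[12.5, 12.5], [6.25], [3.125], [1.5625]])
        assert res.percent_recovery == pytest.approx([100.0] * 4)
        assert res.linearity_r == pytest.approx(1.0)

    def test_170_percent_over_recovery_at_spike(self):
        res = recovery_analysis(12.5, [1], [[21.25, 21.25, 21.25]])
        assert res.percent_recovery[0] == pytest.approx(170.0)

    def test_constant_proportional_bias_gives_flat_recovery(self):
        expected = np.array([12.5, 6.25, 3.125, 1.5625])
        res = recovery_analysis(12.5, [1, 2, 4, 8],
                                [[1.13 * e] for e in expected])
        assert res.percent_recovery == pytest.approx([113.0] * 4)

    def test_zero_expected_rejected(self):
        with pytest.raises(ValueError):
            recovery_analysis(0.0, [1], [[1.0]])


class TestPrecisionAnova:
    def test_identical_measurements_give_zero_cvs(self):
        res = precision_anova([[5.0, 5.0, 5.0], [5.0, 5.0, 5.0]])
        assert res.within_run_cv == 0.0
        assert res.between_run_cv == 0.0

    def test_hand_computed_two_run_table(self):
        # runs {10,10} and {12,12}: MSw=0, SSb=2·1+2·1=4, MSb=4,
        # between component (4−0)/2 = 2 → CV = 100·√2/11
        res = precision_anova([[10.0, 10.0], [12.0, 12.0]])
        assert res.within_run_cv == 0.0
        assert res.ms_between == pytest.approx(4.0)
        assert res.between_run_cv == pytest.approx(100.0 * np.sqrt(2.0) / 11.0)

    def test_between_component_truncated_at_zero(self):
        # group means equal but within-run spread → MSb < MSw → component 0
        res = precision_anova([[9.0, 13.0], [10.0, 12.0]])
        assert res.between_run_cv == 0.0
        assert res.within_run_cv > 0.0

    def test_recovers_generating_cvs(self, rng):
        """20 runs × 10 replicates recover the generating CVs within 20%."""
        true_within, true_between = 0.03, 0.05
        mean = 100.0
        runs = [
            mean * (1 + rng.normal(0, true_between))
            * (1 + rng.normal(0, true_within, 10))
            for _ in range(20)
        ]
        res = precision_anova(runs)
        assert res.within_run_cv == pytest.approx(100 * true_within, rel=0.20)
        assert res.between_run_cv == pytest.approx(100 * true_between, rel=0.35)

    def test_too_few_runs_rejected(self):
        with pytest.raises(ValueError):
            precision_anova([[1.0, 2.0]])


class TestFreezeThaw:
    def test_no_change_when_equal_to_index(self):
        res = freeze_thaw_change({0: [100.0] * 3, 1: [100.0] * 3, 2: [100.0] * 3})
        assert res.mean_percent_change == pytest.approx([0.0, 0.0, 0.0])

    def test_single_cycle_loss_percent(self):
        # index mean 247; one cycle at 247·(1−0.0261) → −2.61%
        res = freeze_thaw_change({0: [247.0] * 3, 1: [247.0 * (1 - 0.0261)] * 3})
        assert res.mean_percent_change[1] == pytest.approx(-2.61)

    def test_linear_two_percent_per_cycle(self):
        groups = {c: [100.0 - 2.0 * c] for c in range(6)}
        res = freeze_thaw_change(groups)
        assert res.mean_percent_change == pytest.approx([0, -2, -4, -6, -8, -10])

    def test_missing_index_group_rejected(self):
        with pytest.raises(ValueError):
            freeze_thaw_change({1: [100.0]})


class TestCrossReactivity:
    def test_identical_groups_give_zero(self):
        res = cross_reactivity([1.0, 1.0], [1.0, 1.0], 100.0)
        assert res.percent_cross_reactivity == pytest.approx(0.0)

    def test_spiked_excess_over_spike_concentration(self):
        res = cross_reactivity([0.59] * 3, [0.0] * 3, 100.0)
        assert res.percent_cross_reactivity == pytest.approx(0.59)

    def test_unspiked_background_subtracted(self):
        res = cross_reactivity([0.64] * 3, [0.1] * 3, 100.0)
        assert res.percent_cross_reactivity == pytest.approx(0.54)

    def test_nonpositive_spike_rejected(self):
        with pytest.raises(ValueError):
            cross_reactivity([1.0], [0.5], 0.0)
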