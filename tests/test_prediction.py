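"""Prediction models, Doppler MRR, regression and agreement statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coromrr import (
    FULL_COHORT,
    NON_ISCHEMIC,
    DopplerRecord,
    PredictionCoefficients,
    bland_altman,
    classify_cmd,
    fit_linear,
    fit_quadratic,
    mrr_doppler,
    pearson,
    predict_mrr_linear,
    predict_mrr_quadratic,
    predict_ratio_from_as,
)


class TestLinearPrediction:
    def test_full_cohort_preset(self):
        assert predict_mrr_linear(2.7778) == pytest.approx(
            1.0422 + 0.5122 * 2.7778, rel=1e-12)
        assert predict_mrr_linear(2.7778) == pytest.approx(2.4650, abs=1e-4)

    def test_zero_slope_is_constant(self):
        coefs = PredictionCoefficients(linear_intercept=3.0, linear_slope=0.0)
        assert predict_mrr_linear(1.0, coefs) == predict_mrr_linear(9.0, coefs) == 3.0

    def test_non_ischemic_subgroup_preset(self):
        assert predict_mrr_linear(2.0, NON_ISCHEMIC) == pytest.approx(0.69 + 0.64 * 2)


class TestRatioFromStenosis:
    def test_printed_coefficients_at_zero(self):
        assert predict_ratio_from_as(0.0) == pytest.approx(0.004717)

    def test_mid_range_evaluation(self):
        assert predict_ratio_from_as(50.0) == pytest.approx(
            0.004717 + 0.006787 * 50 + 0.00003998 * 2500, rel=1e-12)
        assert predict_ratio_from_as(50.0) == pytest.approx(0.4440, abs=1e-4)

    def test_clamped_to_unit_interval(self):
        assert predict_ratio_from_as(99.0) == 1.0
        unclamped = PredictionCoefficients(clamp_ratio=False)
        assert predict_ratio_from_as(99.0, unclamped) > 1.0


class TestQuadraticPrediction:
    def test_ratio_extremes_return_bounds(self):
        zero = PredictionCoefficients(ratio_a0=0.0, ratio_a1=0.0, ratio_a2=0.0)
        one = PredictionCoefficients(ratio_a0=1.0, ratio_a1=0.0, ratio_a2=0.0)
        assert predict_mrr_quadratic(2.0, 4.0, 50.0, zero) == 4.0
        assert predict_mrr_quadratic(2.0, 4.0, 50.0, one) == 2.0

    def test_composed_borderline_example(self):
        # bounds from the borderline case, AS% 50 -> ratio 0.444017
        mrr_pq = predict_mrr_quadratic(1.8634, 2.7778, 50.0)
        assert mrr_pq == pytest.approx(2.7778 - 0.444017 * (2.7778 - 1.8634), rel=1e-6)
        assert mrr_pq == pytest.approx(2.3718, abs=1e-3)

    def test_degenerate_interval_returns_bound(self):
        assert predict_mrr_quadratic(3.0, 3.0, 60.0) == 3.0


class TestDopplerMrr:
    def test_velocity_ratio_times_pressure_ratio(self):
        d = DopplerRecord(apv_rest=20.0, apv_hyp=50.0)
        assert mrr_doppler(d, Pa_rest=90.0, Pd_hyp=72.0) == pytest.approx(3.125)

    def test_unity_case(self):
        d = DopplerRecord(30.0, 30.0)
        assert mrr_doppler(d, 85.0, 85.0) == pytest.approx(1.0)

    def test_invariant_to_velocity_scale(self):
        a = mrr_doppler(DopplerRecord(20, 50), 90, 72)
        b = mrr_doppler(DopplerRecord(40, 100), 90, 72)
        assert a == pytest.approx(b, rel=1e-14)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            DopplerRecord(0.0, 30.0)
        with pytest.raises(ValueError):
            mrr_doppler(DopplerRecord(20, 40), 90.0, 0.0)


class TestFits:
    def test_exact_line_recovered(self):
        x = np.linspace(1, 5, 10)
        fit = fit_linear(x, 2 * x + 1)
        assert fit.coefficients == pytest.approx((1.0, 2.0), abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_orthogonal_data_zero_slope(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        y = np.array([1.0, -1.0, 0.0, -1.0, 1.0])  # even function: zero covariance
        fit = fit_linear(x, y)
        assert fit.coefficients[1] == pytest.approx(0.0, abs=1e-12)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            fit_linear(np.ones(5), np.arange(5.0))

    def test_exact_parabola_recovered(self):
        x = np.linspace(0, 4, 12)
        fit = fit_quadratic(x, x**2)
        assert fit.coefficients == pytest.approx((0.0, 0.0, 1.0), abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_y_zero_r_squared(self):
        x = np.linspace(0, 4, 8)
        fit = fit_quadratic(x, np.full_like(x, 3.0))
        assert fit.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_rank_deficient_design_rejected(self):
        with pytest.raises(ValueError):
            fit_quadratic(np.array([1.0, 1.0, 1.0, 1.0]), np.arange(4.0))

    def test_noise_free_self_consistency(self):
        """Fitting data generated by the fitted model reproduces it exactly."""
        x = np.linspace(1.2, 6.0, 23)
        y = FULL_COHORT.linear_intercept + FULL_COHORT.linear_slope * x
        fit = fit_linear(x, y)
        assert fit.coefficients[0] == pytest.approx(FULL_COHORT.linear_intercept, abs=1e-10)
        assert fit.coefficients[1] == pytest.approx(FULL_COHORT.linear_slope, abs=1e-10)

    def test_noisy_parameter_recovery_within_ci(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(1.5, 6.0, size=23)
        y = 1.0422 + 0.5122 * x + rng.normal(0, 0.4, size=23)
        fit = fit_linear(x, y)
        se_slope = 0.4 / (np.std(x, ddof=1) * np.sqrt(22))  # rough scale check
        assert abs(fit.coefficients[1] - 0.5122) < 4 * se_slope


class TestPearson:
    def test_perfect_correlations(self):
        x = np.linspace(0, 1, 20)
        assert pearson(x, 3 * x + 2)[0] == pytest.approx(1.0)
        assert pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_null_simulation_near_zero(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=(2, 10_000))
        r, p = pearson(x, y)
        assert abs(r) < 0.1

    @settings(derandomize=True, max_examples=25)
    @given(
        a=st.floats(min_value=0.1, max_value=5),
        b=st.floats(min_value=-10, max_value=10),
    )
    def test_affine_invariance(self, a, b):
        x = np.linspace(0, 1, 15)
        y = np.sin(np.linspace(0, 3, 15))
        assert pearson(a * x + b, y)[0] == pytest.approx(pearson(x, y)[0], rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson(np.ones(5), np.arange(5.0))


class TestBlandAltman:
    def test_identical_series(self):
        x = np.array([1.0, 2.5, 3.7])
        stats = bland_altman(x, x)
        assert stats.bias == 0.0
        assert (stats.loa_low, stats.loa_high) == (0.0, 0.0)

    def test_unit_sd_differences(self):
        ref = np.array([0.0, 1.0, 2.0])
        test = np.array([1.0, 1.0, 1.0])  # diffs -1, 0, 1; sample SD = 1
        stats = bland_altman(ref, test)
        assert stats.bias == pytest.approx(0.0)
        assert stats.loa_low == pytest.approx(-1.96)
        assert stats.loa_high == pytest.approx(1.96)

    @settings(derandomize=True, max_examples=25)
    @given(c=st.floats(min_value=-5, max_value=5))
    def test_translation_equivariance(self, c):
        rng = np.random.default_rng(0)
        ref = rng.normal(3, 1, size=10)
        test = ref + rng.normal(0, 0.2, size=10)
        base = bland_altman(ref, test)
        shifted = bland_altman(ref + c, test)
        assert shifted.bias == pytest.approx(base.bias + c, rel=1e-9, abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bland_altman(np.ones(3), np.ones(4))


class TestCmdClassification:
    @pytest.mark.parametrize(
        "mrr, expected", [(2.4, True), (2.5, False), (5.0, False), (0.0, True)]
    )
    def test_strict_threshold(self, mrr, expected):
        assert classify_cmd(mrr) is expected

    def test_negative_mrr_rejected(self):
        with pytest.raises(ValueError):
            classify_cmd(-0.1)
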