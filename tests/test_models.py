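import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import waggledance as wd
from waggledance.models import (
    CalibrationError,
    DegenerateFitError,
    OutOfRangeError,
    runs_test_pvalue,
)

import helpers
from conftest import WAGGLE_SEGMENTED, WAGGLE_VFK

D_GRID = np.array([0.1 + 0.2 * i for i in range(9)])


class TestPredict:
    def test_vfk_at_zero_is_intercept(self):
        m = wd.VonFrischKratkyCalibration.from_params(0.2, 2.0, 0.7)
        assert m.predict([0.0])[0] == pytest.approx(0.2, abs=1e-12)

    def test_vfk_nonpositive_c_rejected(self):
        with pytest.raises(CalibrationError):
            wd.VonFrischKratkyCalibration.from_params(0.2, 2.0, -1.0)

    def test_segmented_zero_slope_change_is_linear(self):
        seg = wd.SegmentedCalibration.from_params(0.3, 1.2, 0.0, 1.0)
        lin = wd.LinearCalibration.from_params(0.3, 1.2)
        d = np.linspace(0, 3, 50)
        np.testing.assert_allclose(seg.predict(d), lin.predict(d), atol=1e-12)

    def test_vfk_small_c_approaches_line(self):
        m = wd.VonFrischKratkyCalibration.from_params(0.2, 1.5, 1e-6)
        d = np.linspace(0, 10, 101)
        assert np.max(np.abs(m.predict(d) - (0.2 + 1.5 * d))) < 1e-4

    def test_remodelled_historical_pieces_agree_at_joint(self):
        # published piecewise waggle calibration is continuous at 1.4 km
        vfk = wd.VonFrischKratkyCalibration.from_params(0.1096, 1.7208, 0.6272)
        lin = wd.LinearCalibration.from_params(0.7198069, 0.70947)
        assert abs(vfk.predict([1.4])[0] - lin.predict([1.4])[0]) < 1e-3

    def test_monotone_increasing_with_positive_slopes(self):
        d = np.linspace(0, 5, 400)
        for m in (
            wd.LinearCalibration.from_params(0.4, 1.1),
            wd.VonFrischKratkyCalibration.from_params(**WAGGLE_VFK),
            wd.SegmentedCalibration.from_segments(**WAGGLE_SEGMENTED),
        ):
            assert np.all(np.diff(m.predict(d)) > 0)


class TestFitLinear:
    def test_interpolating_line(self):
        f = wd.fit_linear([0, 1, 2], [1, 2, 3])
        assert (f.alpha_, f.beta_) == pytest.approx((1.0, 1.0), abs=1e-12)
        assert f.rss_ == pytest.approx(0.0, abs=1e-20)
        assert f.degenerate_  # zero-RSS likelihood is unbounded

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(3)
        d = rng.uniform(0.1, 2.0, 30)
        t = 0.5 + 1.2 * d + rng.normal(0, 0.1, 30)
        f = wd.fit_linear(d, t)
        alpha, beta = helpers.ols_normal_equations(d, t)
        assert f.alpha_ == pytest.approx(alpha, abs=1e-10)
        assert f.beta_ == pytest.approx(beta, abs=1e-10)

    def test_constant_distances_rank_error(self):
        with pytest.raises(np.linalg.LinAlgError):
            wd.fit_linear([1, 1, 1], [1, 2, 3])


class TestFitVfk:
    def test_recovers_noiseless_truth(self):
        truth = wd.VonFrischKratkyCalibration.from_params(0.2, 2.0, 0.7)
        f = wd.fit_vfk(D_GRID, truth.predict(D_GRID))
        assert f.a_ == pytest.approx(0.2, abs=1e-4)
        assert f.b_ == pytest.approx(2.0, abs=1e-4)
        assert f.c_ == pytest.approx(0.7, abs=1e-4)

    def test_linear_data_hits_lower_bound_with_warning(self):
        t = 0.4 + 1.1 * D_GRID
        f = wd.fit_vfk(D_GRID, t)
        assert f.boundary_warning_
        ols = wd.fit_linear(D_GRID, t)
        np.testing.assert_allclose(f.fitted_, ols.fitted_, atol=1e-3)

    def test_fit_predict_consistency(self, study_fits):
        f = study_fits["vfk"]
        np.testing.assert_allclose(f.fitted_, f.predict(f.X_), atol=1e-12)


class TestFitSegmented:
    def test_recovers_noiseless_break(self):
        truth = wd.SegmentedCalibration.from_segments(0.3, 2.0, 1.0, 0.5)
        f = wd.fit_segmented(D_GRID, truth.predict(D_GRID))
        assert f.psi_ == pytest.approx(1.0, abs=1e-6)
        assert f.beta1_ == pytest.approx(2.0, abs=1e-6)
        assert f.segment2_slope_ == pytest.approx(0.5, abs=1e-6)

    def test_pure_line_is_nested(self):
        t = 0.4 + 1.1 * D_GRID + np.sin(np.arange(9)) * 0.01
        seg = wd.fit_segmented(D_GRID, t)
        lin = wd.fit_linear(D_GRID, t)
        assert seg.rss_ <= lin.rss_ + 1e-9

    def test_matches_exhaustive_grid_oracle_small_n(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            n = int(rng.integers(8, 13))
            d = np.sort(rng.uniform(0.1, 2.0, n))
            truth = wd.SegmentedCalibration.from_segments(0.3, 1.8, 1.0, 0.6)
            t = truth.predict(d) + rng.normal(0, 0.08, n)
            f = wd.fit_segmented(d, t)
            bounds = (float(np.unique(d)[1]), float(np.unique(d)[-2]))
            _, rss_oracle = helpers.segmented_grid_oracle(d, t, bounds)
            assert f.rss_ <= rss_oracle + 1e-8

    def test_custom_bounds_one_sided_break_rejected(self):
        d = np.array([0.1, 0.3, 0.5, 0.7, 0.9, 1.1])
        t = 0.3 + 2.0 * d
        t[-1] += 0.5  # pull the break next to the last point
        with pytest.raises(wd.models.UnstableBreakError):
            wd.fit_segmented(d, t, psi_bounds=(1.05, 1.09))


class TestLikelihoodAndCorrelation:
    def test_gaussian_loglik_unit_variance(self):
        n = 8
        assert wd.gaussian_loglik(rss=n, n=n) == pytest.approx(
            -(n / 2) * (math.log(2 * math.pi) + 1))

    def test_gaussian_loglik_hand_case(self):
        # n=4, rss=2: -(4/2) * (log(2*pi*2/4) + 1) = -2*(log(pi) + 1)
        assert wd.gaussian_loglik(2.0, 4) == pytest.approx(
            -2.0 * (math.log(math.pi) + 1.0), abs=1e-12)

    def test_gaussian_loglik_degenerate(self):
        with pytest.raises(DegenerateFitError):
            wd.gaussian_loglik(0.0, 10)

    def test_pearson_perfect_fit(self):
        x = [0.1, 0.5, 1.2, 1.7]
        assert wd.pearson_fit_r(x, x) == pytest.approx(1.0)

    def test_pearson_hand_case(self):
        fitted = np.array([1.0, 2.0, 3.0, 4.0])
        obs = np.array([1.1, 1.9, 3.2, 3.8])
        num = np.sum((fitted - fitted.mean()) * (obs - obs.mean()))
        den = math.sqrt(np.sum((fitted - fitted.mean()) ** 2)
                        * np.sum((obs - obs.mean()) ** 2))
        assert wd.pearson_fit_r(fitted, obs) == pytest.approx(num / den,
                                                              abs=1e-12)

    def test_pearson_constant_vector_undefined(self):
        with pytest.raises(CalibrationError):
            wd.pearson_fit_r([1, 1, 1], [1, 2, 3])


class TestBiasCheck:
    def test_zero_residuals_unbiased(self):
        f = wd.fit_linear([0, 1, 2, 3], [1, 2, 3, 4])
        assert not wd.bias_check(f)["biased"]

    def test_line_through_saturating_curve_is_biased(self):
        truth = wd.VonFrischKratkyCalibration.from_params(**WAGGLE_VFK)
        d = np.repeat(D_GRID, 6)
        t = truth.predict(d)
        lin = wd.fit_linear(d, t)
        assert wd.bias_check(lin)["biased"]
        vfk = wd.fit_vfk(d, t)
        assert not wd.bias_check(vfk)["biased"]

    def test_runs_test_alternating_signs_not_flagged(self):
        assert runs_test_pvalue([1, -1, 1, -1, 1, -1, 1, -1]) > 0.5

    def test_runs_test_clustered_signs_flagged(self):
        p = runs_test_pvalue([1, 1, 1, 1, 1, -1, -1, -1, -1, -1])
        assert p < 0.05


@settings(max_examples=60, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_rss_nesting_inequalities(seed):
    """The richer families never fit worse than the straight line."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(8, 20))
    d = np.sort(rng.uniform(0.05, 2.0, n))
    d += np.linspace(0, 1e-3, n)  # ensure distinct
    t = 0.3 + rng.uniform(0.5, 2.0) * d + rng.normal(0, 0.15, n)
    lin = wd.fit_linear(d, t)
    seg = wd.fit_segmented(d, t)
    # a small lower c-bound lets the saturating family reach its linear limit
    vfk = wd.fit_vfk(d, t, c_bounds=(1e-8, 10.0))
    assert seg.rss_ <= lin.rss_ + 1e-9
    assert vfk.rss_ <= lin.rss_ * (1 + 1e-6) + 1e-12


def test_fit_serialization_roundtrip(study_fits):
    for f in study_fits.values():
        payload = f.to_dict()
        clone = wd.make_calibration(payload["family"], payload["params"])
        d = np.linspace(0.1, 1.7, 17)
        np.testing.assert_allclose(clone.predict(d), f.predict(d), atol=1e-12)
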