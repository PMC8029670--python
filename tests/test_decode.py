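import numpy as np
import pytest

import waggledance as wd
from waggledance.decode import Piece, PiecewiseCalibration
from waggledance.models import CalibrationError, OutOfRangeError

from conftest import WAGGLE_SEGMENTED, WAGGLE_VFK

PRINTED_VFK = wd.VonFrischKratkyCalibration.from_params(**WAGGLE_VFK)
PRINTED_SEG = wd.SegmentedCalibration.from_segments(**WAGGLE_SEGMENTED)


class TestInvert:
    @pytest.mark.parametrize(
        "model",
        [
            wd.LinearCalibration.from_params(0.4475, 1.1152),
            PRINTED_VFK,
            PRINTED_SEG,
        ],
        ids=["linear", "vfk", "segmented"],
    )
    def test_invert_predict_identity(self, model):
        for d in np.linspace(0.1, 1.7, 33):
            t = model.predict([d])[0]
            assert model.invert(t) == pytest.approx(d, abs=1e-9)

    def test_vfk_at_intercept_gives_zero(self):
        assert PRINTED_VFK.invert(WAGGLE_VFK["a"]) == pytest.approx(0.0,
                                                                    abs=1e-12)

    def test_vfk_asymptote_not_decodable(self):
        asym = WAGGLE_VFK["a"] + WAGGLE_VFK["b"] / WAGGLE_VFK["c"]
        for t in (asym, asym + 0.5, 4.0):
            with pytest.raises(OutOfRangeError, match="asymptote"):
                PRINTED_VFK.invert(t)

    def test_below_curve_at_origin_rejected(self):
        with pytest.raises(OutOfRangeError, match="d=0"):
            PRINTED_VFK.invert(0.05)


class TestStudyCalibration:
    def test_monotone_over_long_range(self):
        cal = wd.build_study_calibration(PRINTED_VFK, PRINTED_SEG,
                                         switch_km=1.7)
        d = np.linspace(0, 10, 2001)
        assert np.all(np.diff(cal.predict(d)) > 0)

    def test_offset_when_switching_at_breakpoint(self):
        psi = WAGGLE_SEGMENTED["psi"]
        cal = wd.build_study_calibration(PRINTED_VFK, PRINTED_SEG,
                                         switch_km=psi)
        expected = (PRINTED_VFK.predict([psi])[0]
                    - PRINTED_SEG.predict([psi])[0])
        assert cal.offset_s == pytest.approx(expected, abs=1e-9)

    def test_continuity_at_switch(self):
        cal = wd.build_study_calibration(PRINTED_VFK, PRINTED_SEG,
                                         switch_km=1.7)
        left = cal.predict([1.7 - 1e-9])[0]
        right = cal.predict([1.7 + 1e-9])[0]
        assert left == pytest.approx(right, abs=1e-6)

    def test_nonincreasing_second_segment_rejected(self):
        bad_seg = wd.SegmentedCalibration.from_segments(0.3, 2.0, 1.0, -0.1)
        with pytest.raises(CalibrationError, match="non-increasing"):
            wd.build_study_calibration(PRINTED_VFK, bad_seg)

    def test_json_roundtrip(self):
        cal = wd.build_study_calibration(PRINTED_VFK, PRINTED_SEG)
        clone = PiecewiseCalibration.from_dict(cal.to_dict())
        d = np.linspace(0, 5, 101)
        np.testing.assert_allclose(clone.predict(d), cal.predict(d),
                                   atol=1e-12)


class TestHistoricalCalibrations:
    def test_waggle_calibration_continuous_at_joint(self):
        fj, _ = wd.historical_calibrations()
        assert fj.response == "tw"
        left = fj.predict([1.4 - 1e-9])[0]
        right = fj.predict([1.4 + 1e-9])[0]
        assert abs(left - right) < 1e-3

    def test_waggle_calibration_at_origin(self):
        fj, _ = wd.historical_calibrations()
        assert fj.predict([0.0])[0] == pytest.approx(0.1096, abs=1e-12)

    def test_circuit_extrapolation_arithmetic(self):
        _, vf = wd.historical_calibrations()
        assert vf.response == "tc"
        assert vf.predict([2.0])[0] == pytest.approx(3.072032 + 1.6092,
                                                     abs=1e-9)


class TestDecodeDistance:
    def test_monotone_in_duration(self):
        cal = wd.build_study_calibration(PRINTED_VFK, PRINTED_SEG)
        ts = np.linspace(0.3, 4.5, 80)
        ds = [wd.decode_distance(cal, t).point_km for t in ts]
        assert np.all(np.diff(ds) > 0)

    def test_extrapolation_flag_beyond_training_range(self):
        cal = wd.build_study_calibration(PRINTED_VFK, PRINTED_SEG,
                                         switch_km=1.7)
        t_in = cal.predict([1.0])[0]
        t_out = cal.predict([3.0])[0]
        assert not wd.decode_distance(cal, t_in).extrapolated
        assert wd.decode_distance(cal, t_out).extrapolated

    def test_zero_noise_bootstrap_interval_collapses(self):
        cfg = wd.SimulationConfig(sigma_waggle=0.0, sigma_return=0.0,
                                  within_dance_sd=0.0, seed=3)
        dances = wd.summarize_dances(wd.generate_dances(cfg))
        d = np.array([s.d for s in dances])
        tw = np.array([s.tw for s in dances])
        cal = wd.build_study_calibration(wd.fit_vfk(d, tw, response="tw"),
                                         wd.fit_segmented(d, tw,
                                                          response="tw"))
        dec = wd.decode_distance(cal, float(np.median(tw)), dances=dances,
                                 n_boot=50, seed=0)
        lo, hi = dec.interval_km
        assert hi - lo < 1e-6
        assert lo <= dec.point_km <= hi

    def test_short_range_linear_calibration_underestimates_far_sites(self):
        # a line fit only to near-hive feeders decodes long durations to
        # systematically shorter distances than the saturating calibration
        truth = PRINTED_VFK
        d_short = np.linspace(0.1, 0.7, 12)
        lin = wd.fit_linear(d_short, truth.predict(d_short), response="tw")
        short_cal = PiecewiseCalibration(
            name="short_linear", response="tw",
            pieces=(Piece(0.0, np.inf, lin),), train_d_max=0.7)
        study = wd.build_study_calibration(PRINTED_VFK, PRINTED_SEG)
        for t in (2.0, 2.5, 3.0):
            assert short_cal.invert(t) < study.invert(t)

    def test_bootstrap_requires_refit_recipe(self):
        fj, _ = wd.historical_calibrations()
        with pytest.raises(CalibrationError, match="refit"):
            wd.decode_distance(fj, 1.0, dances=[
                wd.DanceSummary("b", 0.5, 1.0, 1.5)])


class TestPiecewiseValidation:
    def test_pieces_must_cover_from_zero_to_inf(self):
        lin = wd.LinearCalibration.from_params(0.4, 1.0)
        with pytest.raises(CalibrationError):
            PiecewiseCalibration("bad", "tw",
                                 (Piece(0.5, np.inf, lin),))
        with pytest.raises(CalibrationError):
            PiecewiseCalibration("bad", "tw", (Piece(0.0, 2.0, lin),))

    def test_decreasing_curve_rejected(self):
        lin = wd.LinearCalibration.from_params(2.0, -0.5)
        with pytest.raises(CalibrationError, match="increasing"):
            PiecewiseCalibration("bad", "tw", (Piece(0.0, np.inf, lin),))
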