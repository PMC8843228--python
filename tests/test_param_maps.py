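"""ADC fitting, DCE semi-quantitative maps and Tofts inversion."""

import numpy as np
import pytest

from necromap.core_io import AcquisitionParams, DCESeries, ImageGrid, MaskGrid
from necromap.param_maps import (auc_map, compute_adc,
                                 concentration_from_spgr_signal,
                                 contrast_arrival_index, extract_aif,
                                 fit_tofts_curves,
                                 spgr_signal_from_concentration,
                                 steepest_slope_map, subtraction_sequence,
                                 tofts_concentration, tofts_integral)
from necromap.phantom import AIFParams, population_aif

from oracles import discrete_tofts


def _series(values_per_frame, interval=19.5, acq=None):
    frames = [ImageGrid(np.full((2, 2), v)) for v in values_per_frame]
    t = np.arange(len(values_per_frame)) * interval
    return DCESeries(frames, t, sampling_interval=interval,
                     acquisition=acq or AcquisitionParams())


class TestADC:
    def test_exact_on_printed_example(self):
        # signals 1000*exp(-b*1e-3) at b = 0, 400, 800 s/mm^2
        sig = [1000.0, 1000 * np.exp(-0.4), 1000 * np.exp(-0.8)]
        dwi = [(b, ImageGrid(np.full((3, 3), s)))
               for b, s in zip((0.0, 400.0, 800.0), sig)]
        fit = compute_adc(dwi)
        assert np.allclose(fit.adc.values, 1.0e-3, rtol=1e-12)
        assert np.allclose(fit.s0.values, 1000.0, rtol=1e-10)
        assert np.allclose(fit.fit_residual.values, 0.0, atol=1e-12)

    def test_constant_signal_gives_zero_adc(self):
        dwi = [(b, ImageGrid(np.full((2, 2), 500.0))) for b in (0, 400, 800)]
        assert np.allclose(compute_adc(dwi).adc.values, 0.0, atol=1e-15)

    def test_requires_two_distinct_b_values(self):
        g = ImageGrid(np.ones((2, 2)))
        with pytest.raises(ValueError):
            compute_adc([(0.0, g)])
        with pytest.raises(ValueError):
            compute_adc([(400.0, g), (400.0, g)])

    def test_nonpositive_signals_clamped_and_flagged(self):
        arr = np.full((2, 2), 100.0)
        arr[0, 0] = -5.0
        dwi = [(0.0, ImageGrid(arr)), (800.0, ImageGrid(np.full((2, 2),
                                                                50.0)))]
        fit = compute_adc(dwi)
        assert fit.clamped[0, 0] and not fit.clamped[1, 1]
        assert np.isfinite(fit.adc.values).all()


class TestSubtractionAndSlope:
    def test_identical_frames_subtract_to_zero(self):
        sub = subtraction_sequence(_series([100.0, 100.0, 100.0]))
        for f in sub.frames:
            assert np.allclose(f.values, 0.0)

    def test_frame_zero_is_zero_and_count_preserved(self):
        sub = subtraction_sequence(_series(range(10)))
        assert sub.n_frames == 10
        assert np.allclose(sub.frames[0].values, 0.0)

    def test_slope_hand_example(self):
        # subtraction values (0, 50, 60), SI_base = 100, T = 19.5
        dce = _series([100.0, 150.0, 160.0])
        slope = steepest_slope_map(dce)
        assert np.allclose(slope.values, 50 * 100 / (100 * 19.5))

    def test_flat_pixel_has_zero_slope(self):
        assert np.allclose(steepest_slope_map(
            _series([80.0, 80.0, 80.0])).values, 0.0)

    def test_monotone_enhancement_nonnegative(self, rng):
        vals = np.sort(rng.uniform(100, 300, size=8))
        assert (steepest_slope_map(_series(list(vals))).values >= 0).all()

    def test_steepest_pair_invariant_to_global_offset(self):
        a = _series([100.0, 130.0, 190.0, 210.0])
        b = _series([150.0, 180.0, 240.0, 260.0])
        da = np.diff(subtraction_sequence(a).as_array(), axis=0)
        db = np.diff(subtraction_sequence(b).as_array(), axis=0)
        assert np.array_equal(da.argmax(axis=0), db.argmax(axis=0))


class TestAUC:
    def test_all_zero_series(self):
        sub = subtraction_sequence(_series([50.0] * 6))
        assert np.allclose(auc_map(sub).values, 0.0)

    def test_constant_enhancement_closed_form(self):
        # subtraction value 20 over frames at 0 .. 97.5 s
        dce = _series([100.0] + [120.0] * 9)
        sub = subtraction_sequence(dce)
        # trapezoid of (0,20,...,20) over 0..97.5: 20*97.5 - 19.5*20/2
        expected = 20 * 97.5 - 0.5 * 19.5 * 20
        assert np.allclose(auc_map(sub, horizon=100.0).values, expected)

    def test_frames_beyond_horizon_only(self):
        frames = [ImageGrid(np.full((2, 2), v)) for v in (0.0, 5.0)]
        sub = DCESeries(frames, [150.0, 170.0], 19.5)
        with pytest.warns(UserWarning):
            out = auc_map(sub, horizon=100.0)
        assert np.allclose(out.values, 0.0)

    def test_invariant_to_constant_frame_offset(self):
        a = _series([100.0, 140.0, 170.0, 180.0, 200.0, 205.0])
        b = _series([400.0, 440.0, 470.0, 480.0, 500.0, 505.0])
        assert np.allclose(auc_map(subtraction_sequence(a)).values,
                           auc_map(subtraction_sequence(b)).values)


class TestAIF:
    def test_defaults_match_protocol_constants(self):
        acq = AcquisitionParams()
        assert acq.t1_blood == pytest.approx(1.6)
        assert acq.relaxivity == pytest.approx(0.0039)

    def test_precontrast_only_series_gives_zero_concentration(self):
        dce = _series([200.0, 200.0, 200.0])
        mask = MaskGrid(np.ones((2, 2), bool))
        assert np.allclose(extract_aif(dce, mask), 0.0, atol=1e-9)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            extract_aif(_series([1.0, 2.0]), MaskGrid(np.zeros((2, 2),
                                                               bool)))

    def test_spgr_round_trip(self, rng):
        acq = AcquisitionParams()
        conc = rng.uniform(0, 2.0, size=20)
        sig = spgr_signal_from_concentration(conc, 200.0, acq.t1_tissue,
                                             acq)
        back = concentration_from_spgr_signal(sig, 200.0, acq.t1_tissue,
                                              acq)
        assert np.allclose(back, conc, atol=1e-8)

    def test_arrival_detection(self):
        aif = np.array([0.0, 0.0, 0.8, 0.7, 0.6])
        assert contrast_arrival_index(aif) == 2


class TestTofts:
    def setup_method(self):
        self.t = np.arange(0.0, 180.0, 19.5)
        self.cp = population_aif(self.t, AIFParams())

    def test_forward_model_matches_numerical_convolution(self):
        for kt, ve in ((0.05, 0.1), (0.3, 0.4)):
            ct = tofts_concentration(self.t, self.cp, kt, ve)[0]
            ref = discrete_tofts(self.t, self.cp, kt, ve)
            assert np.allclose(ct, ref, rtol=2e-3, atol=1e-5)

    @pytest.mark.parametrize("kt", [0.05, 0.1, 0.3])
    @pytest.mark.parametrize("ve", [0.1, 0.2, 0.4])
    def test_noiseless_recovery_within_five_percent(self, kt, ve):
        ct = tofts_concentration(self.t, self.cp, kt, ve)
        fit = fit_tofts_curves(self.t, self.cp, ct)
        assert fit.ktrans[0] == pytest.approx(kt, rel=0.05)
        assert fit.ve[0] == pytest.approx(ve, rel=0.05)

    def test_zero_aif_recovers_zero_ktrans(self):
        ct = np.zeros((1, self.t.size))
        fit = fit_tofts_curves(self.t, np.zeros_like(self.t), ct)
        assert fit.ktrans[0] == 0.0
        assert fit.qc_flag[0]  # v_e unidentifiable, flagged

    def test_integral_is_zero_for_zero_rate_limit(self):
        out = tofts_integral(self.t, self.cp, 0.0)
        # with kep = 0 the integral is the running integral of the AIF
        ref = np.concatenate([[0.0], np.cumsum(
            0.5 * (self.cp[1:] + self.cp[:-1]) * np.diff(self.t))])
        assert np.allclose(out[0], ref, rtol=1e-10)
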