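"""Pulsatile-ratio SpO2: amplitudes, ratio, smoothing, anchor calibration."""

import numpy as np
import pytest

from nirsdive.simulate import SimulationConfig, default_anchors, simulate_dive
from nirsdive.spo2 import (
    AnchorCalibrator,
    Spo2Estimator,
    anchor_calibrate,
    conventional_spo2,
    moving_average,
    pulsatile_amplitudes,
)
from nirsdive.types import Anchor, Spo2Series


class TestPulsatileAmplitudes:
    def test_unit_sinusoid_amplitude_two(self):
        # 1.25 Hz at 10 Hz: period 8 samples, crest and trough on-sample
        t = np.arange(96) / 10.0
        o2 = np.sin(2 * np.pi * 1.25 * t)
        hh = np.zeros_like(o2)
        beats = np.arange(2, 96, 8)  # one beat per period
        _, ac_o2, ac_hh, skipped = pulsatile_amplitudes(o2, hh, beats, 10.0)
        np.testing.assert_allclose(ac_o2, 2.0, atol=1e-9)
        np.testing.assert_allclose(ac_hh, 0.0, atol=1e-12)
        assert skipped == 0

    def test_equal_in_phase_sinusoids_equal_amplitudes(self):
        t = np.arange(96) / 10.0
        x = 0.4 * np.sin(2 * np.pi * 1.25 * t)
        beats = np.arange(2, 96, 8)
        _, ac_o2, ac_hh, _ = pulsatile_amplitudes(x, x.copy(), beats, 10.0)
        np.testing.assert_allclose(ac_o2, ac_hh, atol=1e-12)

    def test_short_cycles_skipped(self):
        x = np.sin(np.arange(50))
        beats = np.array([0, 1, 10, 20])
        _, _, _, skipped = pulsatile_amplitudes(x, x, beats, 10.0)
        assert skipped == 1

    def test_generator_ratio_recovered(self, dive42, dive42_chromo):
        """Amplitude ratio encodes the simulator's SaO2 within 5 %."""
        from nirsdive.heart_rate import HeartRateExtractor
        from nirsdive.heart_rate import bandpass_fir

        _, _, truth = dive42
        hrx = HeartRateExtractor().fit(dive42_chromo)
        hrx.transform(dive42_chromo)
        fs = dive42_chromo.sampling_rate
        o2 = bandpass_fir(dive42_chromo.o2hb[:, 0], fs=fs, low=0.5, high=4.0)
        hh = bandpass_fir(dive42_chromo.hhb[:, 0], fs=fs, low=0.5, high=4.0)
        t_cyc, ac_o2, ac_hh, _ = pulsatile_amplitudes(o2, hh, hrx.beat_indices_, fs)
        ratio = 100.0 * ac_o2 / (ac_o2 + ac_hh)
        truth_at = np.interp(t_cyc, truth.time, truth.sao2)
        assert np.mean(np.abs(ratio - truth_at)) < 5.0


class TestConventionalSpo2:
    def _series(self, ac_o2, ac_hh):
        n = len(ac_o2)
        t = np.arange(n, dtype=float)
        return conventional_spo2(t, np.asarray(ac_o2, float), np.asarray(ac_hh, float), t)

    def test_no_deoxy_pulsation_is_100(self):
        out = self._series([1.0, 1.0, 1.0], [0.0, 0.0, 0.0])
        np.testing.assert_allclose(out.spo2, 100.0)

    def test_equal_amplitudes_is_50(self):
        out = self._series([0.5] * 4, [0.5] * 4)
        np.testing.assert_allclose(out.spo2, 50.0)

    def test_scale_invariance(self):
        a = self._series([1.0, 2.0, 3.0], [0.5, 0.4, 0.3])
        b = self._series([7.0, 14.0, 21.0], [3.5, 2.8, 2.1])
        np.testing.assert_allclose(a.spo2, b.spo2, atol=1e-12)

    def test_descending_trajectory_recovered(self):
        """Simulated dive: trend falls monotonically during ascent and the
        end value lands within 3 % of the prescribed nadir."""
        rec, events, truth = simulate_dive(SimulationConfig(seed=11, depth_m=42.0))
        from nirsdive.heart_rate import HeartRateExtractor
        from nirsdive.mbll import MBLLTransformer

        chromo = MBLLTransformer().fit(rec).transform(rec)
        hrx = HeartRateExtractor().fit(chromo)
        hrx.transform(chromo)
        series = Spo2Estimator().fit(chromo).transform(chromo, beats=hrx.beat_indices_)
        ascent = events.end_time - events.depth / events.ascent_rate
        sel = (series.time >= ascent + 5) & (series.time <= events.end_time - 5)
        smoothed = series.spo2[sel]
        # monotone decreasing trend at 1-s resolution
        coarse = smoothed[:: int(chromo.sampling_rate)]
        assert np.all(np.diff(coarse) < 1.0)
        # compare the smoothed estimate against equally smoothed truth: the
        # 5-s moving average is part of the method and rounds the kink at
        # the nadir for truth and estimate alike
        truth_smooth = moving_average(truth.sao2, chromo.sampling_rate, 5.0)
        i_end = np.searchsorted(truth.time, events.end_time)
        at_end = np.interp(events.end_time, series.time, series.spo2)
        assert abs(at_end - truth_smooth[i_end]) < 3.0


class TestMovingAverage:
    def test_constant_unchanged(self):
        out = moving_average(np.full(80, 42.0), fs=10.0, window_s=5.0)
        np.testing.assert_allclose(out, 42.0)

    def test_step_becomes_ramp(self):
        x = np.zeros(200)
        x[100:] = 1.0
        out = moving_average(x, fs=10.0, window_s=5.0)
        ramp = out[75:125]
        assert np.all(np.diff(ramp) >= 0)
        assert out[74] == 0.0 and out[126] == 1.0
        # the transition spans the window width
        assert np.sum((out > 0.01) & (out < 0.99)) == pytest.approx(50, abs=2)

    def test_variance_reduced_on_white_noise(self, rng):
        x = rng.normal(size=2000)
        out = moving_average(x, fs=10.0, window_s=5.0)
        assert np.var(out) < 0.1 * np.var(x)

    def test_edges_use_truncated_window(self):
        x = np.arange(20, dtype=float)
        out = moving_average(x, fs=1.0, window_s=5.0)
        assert out[0] == pytest.approx(np.mean(x[:3]))
        assert out[-1] == pytest.approx(np.mean(x[-3:]))


class TestAnchorCalibration:
    def _trace(self, values):
        t = np.arange(len(values), dtype=float)
        return Spo2Series(time=t, spo2=np.asarray(values, float))

    def test_identity_when_anchors_on_trace(self):
        trace = self._trace(np.linspace(90, 60, 100))
        anchors = [Anchor(10.0, trace.spo2[10]), Anchor(80.0, trace.spo2[80])]
        cal = AnchorCalibrator(anchor_window_s=0.5).fit(trace, anchors)
        assert cal.slope_ == pytest.approx(1.0, abs=1e-9)
        assert cal.intercept_ == pytest.approx(0.0, abs=1e-7)

    def test_uniform_offset_absorbed_in_intercept(self):
        truth = np.linspace(95, 65, 100)
        trace = self._trace(truth + 10.0)
        anchors = [Anchor(float(i), float(truth[i])) for i in (5, 50, 95)]
        cal = AnchorCalibrator(anchor_window_s=0.5).fit(trace, anchors)
        assert cal.intercept_ == pytest.approx(-10.0, abs=1e-6)
        assert cal.slope_ == pytest.approx(1.0, abs=1e-6)

    def test_idempotent(self):
        trace = self._trace(np.linspace(97, 55, 200) * 0.9)
        anchors = [Anchor(20.0, 90.0), Anchor(180.0, 60.0)]
        once = anchor_calibrate(trace, anchors, anchor_window_s=1.0)
        twice = anchor_calibrate(once, anchors, anchor_window_s=1.0)
        np.testing.assert_allclose(twice.spo2, once.spo2, atol=1e-6)

    def test_refusal_with_single_anchor(self):
        trace = self._trace(np.linspace(90, 60, 50))
        with pytest.warns(UserWarning, match="refused"):
            out = anchor_calibrate(trace, [Anchor(10.0, 95.0)])
        assert out.method == "conventional"

    def test_calibration_beats_conventional_under_drift(self):
        """Pathlength drift biases the ratio; anchoring must lower RMSE."""
        from nirsdive.heart_rate import HeartRateExtractor
        from nirsdive.mbll import MBLLTransformer

        wins = 0
        for seed in (1, 2, 3):
            rec, _, truth = simulate_dive(
                SimulationConfig(seed=seed, distortion="pathlength-drift")
            )
            chromo = MBLLTransformer().fit(rec).transform(rec)
            hrx = HeartRateExtractor().fit(chromo)
            hrx.transform(chromo)
            conv = Spo2Estimator().fit(chromo).transform(chromo, beats=hrx.beat_indices_)
            cal = AnchorCalibrator().fit(conv, default_anchors(truth)).predict(conv)
            rmse = lambda s: np.sqrt(np.nanmean((s.spo2 - truth.sao2) ** 2))
            wins += rmse(cal) < rmse(conv)
        assert wins == 3
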