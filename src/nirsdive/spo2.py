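"""Arterial oxygen saturation from pulsatile NIRS amplitudes.

Each cardiac cycle modulates the optical signal in proportion to arterial
blood, so the per-beat peak-to-trough (AC) amplitudes of the cardiac-band
oxy- and deoxyhemoglobin traces carry the arterial saturation:

    SpO2 = 100 * AC_O2Hb / (AC_O2Hb + AC_HHb)

(the pulsatile ratio method).  The continuous trace can additionally be
calibrated against discrete arterial blood-gas SaO2 anchors with a
least-squares affine map — a deliberately simple stand-in for
self-calibrating pathlength models that exercises the same
ground-truth-anchoring idea.  A centered 5-s moving average smooths the
final trace.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin

from .heart_rate import bandpass_fir
from .types import Anchor, ChromophoreSeries, Spo2Series

logger = logging.getLogger(__name__)

DEFAULT_SMOOTHING_S = 5.0
MIN_CYCLE_SAMPLES = 3


def pulsatile_amplitudes(
    o2hb: np.ndarray, hhb: np.ndarray, beats: np.ndarray, fs: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Per-cycle AC amplitudes of the two chromophore traces.

    A cycle spans consecutive beat indices.  The systolic peak and
    diastolic trough instants are located on the oxyhemoglobin trace (the
    stronger arterial pulse) and both chromophores are read at those same
    two samples — the peak-to-trough amplitude at common beat landmarks,
    as pulse oximetry evaluates its ratio.  Reading the weaker trace at
    its own extrema would systematically inflate it by the noise envelope.

    Returns ``(cycle_mid_times, ac_o2hb, ac_hhb, n_skipped)``; cycles
    shorter than 3 samples are skipped and counted.
    """
    o2hb = np.asarray(o2hb, float)
    hhb = np.asarray(hhb, float)
    beats = np.asarray(beats, int)
    times, ac_o2, ac_hh = [], [], []
    skipped = 0
    for a, b in zip(beats[:-1], beats[1:]):
        if b - a < MIN_CYCLE_SAMPLES:
            skipped += 1
            continue
        seg_o2 = o2hb[a : b + 1]
        seg_hh = hhb[a : b + 1]
        i_peak = int(np.argmax(seg_o2))
        i_trough = int(np.argmin(seg_o2))
        times.append((a + b) / 2.0 / fs)
        ac_o2.append(float(seg_o2[i_peak] - seg_o2[i_trough]))
        ac_hh.append(float(seg_hh[i_peak] - seg_hh[i_trough]))
    if skipped:
        logger.info("pulsatile_amplitudes: skipped %d short cycles", skipped)
    return np.array(times), np.array(ac_o2), np.array(ac_hh), skipped


def conventional_spo2(
    cycle_times: np.ndarray,
    ac_o2hb: np.ndarray,
    ac_hhb: np.ndarray,
    grid: np.ndarray,
) -> Spo2Series:
    """Ratio method per beat, linearly interpolated to the recording grid.

    Beats with zero total amplitude are masked; the ratio is invariant to
    any common rescaling of the two AC series.
    """
    total = ac_o2hb + ac_hhb
    ok = total > 0
    spo2_beat = np.full(total.shape, np.nan)
    spo2_beat[ok] = 100.0 * ac_o2hb[ok] / total[ok]
    grid = np.asarray(grid, float)
    if np.count_nonzero(ok) >= 2:
        trace = np.interp(grid, cycle_times[ok], spo2_beat[ok])
        mask = np.zeros(grid.shape, dtype=bool)
    else:
        trace = np.full(grid.shape, np.nan)
        mask = np.ones(grid.shape, dtype=bool)
    clip_count = int(np.sum((trace < 0) | (trace > 100)))
    trace = np.clip(trace, 0.0, 100.0)
    return Spo2Series(
        time=grid,
        spo2=trace,
        method="conventional",
        clip_count=clip_count,
        mask=mask,
    )


def moving_average(x: np.ndarray, fs: float, window_s: float = DEFAULT_SMOOTHING_S) -> np.ndarray:
    """Centered moving mean with edge truncation (shrinking window).

    NaNs are ignored inside the window; output length equals input length.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    x = np.asarray(x, float)
    w = max(1, int(round(window_s * fs)))
    if w % 2 == 0:
        w += 1
    half = w // 2
    vals = np.where(np.isnan(x), 0.0, x)
    cnt = (~np.isnan(x)).astype(float)
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    ccnt = np.concatenate([[0.0], np.cumsum(cnt)])
    n = x.size
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + half + 1, 0, n)
    num = csum[hi] - csum[lo]
    den = ccnt[hi] - ccnt[lo]
    out = np.full(n, np.nan)
    np.divide(num, den, out=out, where=den > 0)
    return out


class AnchorCalibrator(BaseEstimator, RegressorMixin):
    """Affine calibration of an SpO2 trace against arterial SaO2 anchors.

    ``fit`` regresses anchor SaO2 on the trace value at each anchor time
    (mean over a +-2.5 s window); ``predict`` applies the fitted
    ``a * spo2 + b`` map.  With fewer than two usable anchors at distinct
    trace values, calibration is refused.

    Attributes
    ----------
    slope_, intercept_ : float
        Fitted affine coefficients.
    residuals_ : ndarray
        Anchor SaO2 minus calibrated prediction at each anchor.
    """

    def __init__(self, anchor_window_s: float = DEFAULT_SMOOTHING_S):
        self.anchor_window_s = anchor_window_s

    def fit(self, series: Spo2Series, anchors: list[Anchor]):
        half = self.anchor_window_s / 2.0
        xs, ys = [], []
        for anc in anchors:
            sel = (
                (series.time >= anc.time - half)
                & (series.time <= anc.time + half)
                & ~series.mask
                & ~np.isnan(series.spo2)
            )
            if not np.any(sel):
                continue
            xs.append(float(series.spo2[sel].mean()))
            ys.append(float(anc.sao2))
        xs, ys = np.array(xs), np.array(ys)
        if xs.size < 2 or np.ptp(xs) < 1e-12:
            raise ValueError(
                f"calibration needs >= 2 anchors at distinct trace values "
                f"(got {xs.size} usable)"
            )
        A = np.stack([xs, np.ones_like(xs)], axis=1)
        (a, b), *_ = np.linalg.lstsq(A, ys, rcond=None)
        self.slope_ = float(a)
        self.intercept_ = float(b)
        self.n_anchors_ = int(xs.size)
        self.residuals_ = ys - (a * xs + b)
        logger.info(
            "anchor calibration: a=%.4f b=%.2f on %d anchors, RMS residual %.2f",
            a,
            b,
            xs.size,
            float(np.sqrt(np.mean(self.residuals_**2))),
        )
        return self

    def predict(self, series: Spo2Series) -> Spo2Series:
        if not hasattr(self, "slope_"):
            raise ValueError("AnchorCalibrator is not fitted")
        mapped = self.slope_ * series.spo2 + self.intercept_
        clip_count = int(np.nansum((mapped < 0) | (mapped > 100)))
        mapped = np.clip(mapped, 0.0, 100.0)
        return Spo2Series(
            time=series.time.copy(),
            spo2=mapped,
            method="anchor-calibrated",
            smoothing_window_s=series.smoothing_window_s,
            anchors_used=self.n_anchors_,
            clip_count=series.clip_count + clip_count,
            mask=series.mask.copy(),
        )


def anchor_calibrate(
    series: Spo2Series, anchors: list[Anchor], anchor_window_s: float = DEFAULT_SMOOTHING_S
) -> Spo2Series:
    """Calibrate; on refusal, warn and return the input trace unchanged."""
    cal = AnchorCalibrator(anchor_window_s=anchor_window_s)
    try:
        cal.fit(series, anchors)
    except ValueError as exc:
        warnings.warn(f"anchor calibration refused: {exc}")
        return series
    return cal.predict(series)


class Spo2Estimator(BaseEstimator, TransformerMixin):
    """Chromophore series (+ beats) -> smoothed SpO2 trace.

    Composes cardiac-band filtering, per-cycle AC amplitudes, the pulsatile
    ratio, grid interpolation, optional anchor calibration and the centered
    moving average.
    """

    def __init__(
        self,
        channel_mm: float | None = None,
        smoothing_s: float = DEFAULT_SMOOTHING_S,
        low: float = 0.5,
        high: float = 4.0,
        anchors: list[Anchor] | None = None,
    ):
        self.channel_mm = channel_mm
        self.smoothing_s = smoothing_s
        self.low = low
        self.high = high
        self.anchors = anchors

    def fit(self, X: ChromophoreSeries, y=None):
        if self.channel_mm is None:
            self.channel_index_ = int(
                np.argmin([ch.distance_mm for ch in X.channels])
            )
        else:
            self.channel_index_ = X.channel_index(self.channel_mm)
        return self

    def transform(self, X: ChromophoreSeries, beats: np.ndarray | None = None) -> Spo2Series:
        if not hasattr(self, "channel_index_"):
            self.fit(X)
        j = self.channel_index_
        if beats is None:
            from .heart_rate import HeartRateExtractor

            hrx = HeartRateExtractor(
                channel_policy="explicit",
                channel_mm=X.channels[j].distance_mm,
            )
            hrx.fit(X)
            hrx.transform(X)
            beats = hrx.beat_indices_
        fs = X.sampling_rate
        o2 = bandpass_fir(X.o2hb[:, j], fs=fs, low=self.low, high=self.high)
        hh = bandpass_fir(X.hhb[:, j], fs=fs, low=self.low, high=self.high)
        t_cyc, ac_o2, ac_hh, _ = pulsatile_amplitudes(o2, hh, beats, fs)
        series = conventional_spo2(t_cyc, ac_o2, ac_hh, X.time)
        if self.anchors:
            series = anchor_calibrate(series, self.anchors)
        series.spo2 = moving_average(series.spo2, fs, self.smoothing_s)
        series.smoothing_window_s = self.smoothing_s
        return series


__all__ = [
    "pulsatile_amplitudes",
    "conventional_spo2",
    "moving_average",
    "anchor_calibrate",
    "AnchorCalibrator",
    "Spo2Estimator",
    "DEFAULT_SMOOTHING_S",
]
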