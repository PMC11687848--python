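"""Heart-rate extraction from the cardiac pulsation in NIRS signals.

Three stages, composed by :class:`HeartRateExtractor`:

1. a zero-phase bandpass FIR filter (default order 100, 0.1-4 Hz at 10 Hz)
   removes slow hemodynamic drift and high-frequency noise;
2. automatic multiscale-based peak detection (AMPD) finds the systolic
   peaks without a hand-tuned threshold: a local-maxima scalogram over
   window scales k = 1..ceil(n/2)-1 is reduced at the globally dominant
   scale, and a sample is a beat iff it is a local maximum at every scale
   up to that optimum;
3. peak-to-peak intervals become beats/min, and a sliding-window median
   rule replaces physiologically impossible or jumpy values.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .types import (
    HR_FLAG_CORRECTED,
    HR_FLAG_RAW,
    ChromophoreSeries,
    HeartRateSeries,
)

logger = logging.getLogger(__name__)

DEFAULT_ORDER = 100
DEFAULT_BAND = (0.1, 4.0)
HR_GATE = (20.0, 250.0)
DEFAULT_WINDOW_S = 10.0
DEFAULT_MAX_JUMP_FRAC = 0.30


def bandpass_fir(
    x: np.ndarray,
    fs: float = 10.0,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    order: int = DEFAULT_ORDER,
) -> np.ndarray:
    """Zero-phase bandpass FIR filtering.

    A linear-phase FIR of the stated order is designed with a Hamming
    window and applied forward-backward (``filtfilt``), which cancels the
    phase delay exactly at the cost of squaring the magnitude response
    (effective order doubles).  Output length equals input length.
    """
    x = np.asarray(x, dtype=float)
    if order % 2 != 0:
        raise ValueError("order must be even for a type-I bandpass FIR")
    if not 0.0 < low < high < fs / 2.0:
        raise ValueError(f"band ({low}, {high}) Hz invalid for fs={fs} Hz")
    if x.size < 3 * order:
        raise ValueError(
            f"signal length {x.size} too short for order-{order} zero-phase "
            "filtering (need >= 3x order)"
        )
    taps = sps.firwin(order + 1, [low, high], fs=fs, pass_zero=False)
    logger.debug("bandpass FIR: order=%d band=(%g, %g) Hz fs=%g", order, low, high, fs)
    # demean first: the low transition band is wide relative to the 0.1 Hz
    # edge, so a large DC offset would otherwise leak through and distort
    # the forward-backward edge handling
    return sps.filtfilt(taps, 1.0, x - x.mean())


def ampd_peaks(x: np.ndarray, max_scale: int | None = None) -> np.ndarray:
    """Automatic multiscale-based peak detection.

    For every scale ``k`` mark samples that strictly exceed both neighbours
    at lag ``k``; the dominant scale is the one with the most marks; a
    sample is a peak iff it is marked at every scale up to the dominant
    one.  Returns strictly increasing indices; an all-constant signal
    yields an empty array.

    ``max_scale`` optionally caps the scale search (samples); useful when
    the shortest plausible period is known, and the default scans up to
    ``ceil(n/2) - 1`` as the plain algorithm prescribes.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 samples")
    L = int(np.ceil(n / 2)) - 1
    if max_scale is not None:
        L = min(L, int(max_scale))
    if L < 1:
        return np.array([], dtype=int)
    counts = np.empty(L, dtype=int)
    marks = np.zeros((L, n), dtype=bool)
    for k in range(1, L + 1):
        m = np.zeros(n, dtype=bool)
        m[k : n - k] = (x[k : n - k] > x[: n - 2 * k]) & (x[k : n - k] > x[2 * k :])
        marks[k - 1] = m
        counts[k - 1] = int(m.sum())
    if counts.max() == 0:
        return np.array([], dtype=int)
    lam = int(np.argmax(counts)) + 1
    peaks = np.flatnonzero(marks[:lam].all(axis=0))
    return peaks.astype(int)


def refine_peaks(x: np.ndarray, peaks: np.ndarray) -> np.ndarray:
    """Sub-sample peak positions by parabolic interpolation.

    At 10 Hz a cardiac interval spans only 6-8 samples, so integer beat
    indices quantise instantaneous heart rate to a handful of values
    (e.g. 75 / 85.7 / 100 beats/min).  Fitting a parabola through the
    three samples around each detected peak recovers the fractional peak
    position and removes that quantisation.
    """
    x = np.asarray(x, dtype=float)
    peaks = np.asarray(peaks, dtype=int)
    refined = peaks.astype(float)
    inner = (peaks > 0) & (peaks < x.size - 1)
    ym = x[peaks[inner] - 1]
    y0 = x[peaks[inner]]
    yp = x[peaks[inner] + 1]
    denom = ym - 2.0 * y0 + yp
    delta = np.zeros(ym.shape)
    ok = denom < 0  # true local maximum curvature
    delta[ok] = 0.5 * (ym[ok] - yp[ok]) / denom[ok]
    refined[inner] += np.clip(delta, -0.5, 0.5)
    return refined


def peaks_to_hr(peaks: np.ndarray, fs: float) -> HeartRateSeries:
    """Beat positions (samples, possibly fractional) -> instantaneous heart
    rate at interval midpoints."""
    peaks = np.asarray(peaks, dtype=float)
    if peaks.size < 2:
        warnings.warn("fewer than 2 beats detected; empty heart-rate series")
        return HeartRateSeries(
            time=np.array([]), hr=np.array([]), flags=np.array([], dtype=object)
        )
    intervals = np.diff(peaks)
    hr = 60.0 * fs / intervals
    t = (peaks[:-1] + peaks[1:]) / 2.0 / fs
    flags = np.array([HR_FLAG_RAW] * hr.size, dtype=object)
    return HeartRateSeries(time=t, hr=hr, flags=flags)


def windowed_correction(
    series: HeartRateSeries,
    window_s: float = DEFAULT_WINDOW_S,
    max_jump_frac: float = DEFAULT_MAX_JUMP_FRAC,
    gate: tuple[float, float] = HR_GATE,
) -> HeartRateSeries:
    """Replace implausible beats by the local window median.

    A value is replaced when it falls outside the physiological gate
    (default 20-250 beats/min) or deviates from the median of its
    ``window_s`` neighbourhood by more than ``max_jump_frac`` of that
    median.  Replaced values are flagged ``window-corrected``.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    t, hr = series.time, series.hr.copy()
    flags = series.flags.copy()
    if hr.size == 0:
        return series
    half = window_s / 2.0
    for i in range(hr.size):
        sel = (t >= t[i] - half) & (t <= t[i] + half)
        sel[i] = False
        neighbours = series.hr[sel]
        med = float(np.median(neighbours)) if neighbours.size else float(series.hr[i])
        out_of_gate = not (gate[0] <= series.hr[i] <= gate[1])
        jumpy = med > 0 and abs(series.hr[i] - med) > max_jump_frac * med
        if out_of_gate or jumpy:
            hr[i] = np.clip(med, gate[0], gate[1])
            flags[i] = HR_FLAG_CORRECTED
    return HeartRateSeries(
        time=t.copy(), hr=hr, flags=flags, source_channel_mm=series.source_channel_mm
    )


def resample_hr(series: HeartRateSeries, time: np.ndarray) -> np.ndarray:
    """Linear interpolation of the beat-to-beat trace onto a uniform grid."""
    if len(series) == 0:
        return np.full(np.asarray(time).shape, np.nan)
    return np.interp(np.asarray(time, float), series.time, series.hr)


class HeartRateExtractor(BaseEstimator, TransformerMixin):
    """Chromophore series -> corrected heart-rate series.

    Parameters
    ----------
    channel_policy : {"shallowest", "least-noisy", "explicit"}
        Which source-detector separation carries the pulse.  The shallowest
        channel has the strongest skin/arterial pulsation and is the
        default; "least-noisy" picks the channel with the lowest
        high-frequency residual; "explicit" uses ``channel_mm``.
    signal : {"o2hb", "hhb", "thb"}
        Chromophore trace to detect beats on.
    """

    def __init__(
        self,
        channel_policy: str = "shallowest",
        channel_mm: float | None = None,
        signal: str = "o2hb",
        low: float = DEFAULT_BAND[0],
        high: float = DEFAULT_BAND[1],
        order: int = DEFAULT_ORDER,
        window_s: float = DEFAULT_WINDOW_S,
        max_jump_frac: float = DEFAULT_MAX_JUMP_FRAC,
    ):
        self.channel_policy = channel_policy
        self.channel_mm = channel_mm
        self.signal = signal
        self.low = low
        self.high = high
        self.order = order
        self.window_s = window_s
        self.max_jump_frac = max_jump_frac

    def _select_channel(self, chromo: ChromophoreSeries) -> int:
        if self.channel_policy == "explicit":
            if self.channel_mm is None:
                raise ValueError("explicit channel policy requires channel_mm")
            return chromo.channel_index(self.channel_mm)
        if self.channel_policy == "shallowest":
            return int(
                np.argmin([ch.distance_mm for ch in chromo.channels])
            )
        if self.channel_policy == "least-noisy":
            x = getattr(chromo, self.signal)
            # high-frequency residual as a noise proxy
            noise = np.std(np.diff(x, axis=0), axis=0)
            return int(np.argmin(noise))
        raise ValueError(f"unknown channel_policy {self.channel_policy!r}")

    def fit(self, X: ChromophoreSeries, y=None):
        if not isinstance(X, ChromophoreSeries):
            raise TypeError("HeartRateExtractor expects a ChromophoreSeries")
        self.channel_index_ = self._select_channel(X)
        self.channel_mm_ = float(X.channels[self.channel_index_].distance_mm)
        return self

    def transform(self, X: ChromophoreSeries) -> HeartRateSeries:
        if not hasattr(self, "channel_index_"):
            self.fit(X)
        x = getattr(X, self.signal)[:, self.channel_index_]
        try:
            filtered = bandpass_fir(
                x, fs=X.sampling_rate, low=self.low, high=self.high, order=self.order
            )
            # cap the AMPD scale search at the slowest plausible beat so a
            # long recording's respiratory residual cannot dominate
            max_scale = int(np.ceil(X.sampling_rate * 60.0 / HR_GATE[0] / 2))
            peaks = ampd_peaks(filtered, max_scale=max_scale)
            raw = peaks_to_hr(refine_peaks(filtered, peaks), X.sampling_rate)
        except ValueError as exc:
            raise ValueError(f"heart-rate extraction failed: {exc}") from exc
        self.beat_indices_ = peaks
        corrected = windowed_correction(
            raw, window_s=self.window_s, max_jump_frac=self.max_jump_frac
        )
        corrected.source_channel_mm = self.channel_mm_
        return corrected


def extract_heart_rate(
    chromo: ChromophoreSeries, channel_policy: str = "shallowest", **kwargs
) -> HeartRateSeries:
    """Functional wrapper around :class:`HeartRateExtractor`."""
    return HeartRateExtractor(channel_policy=channel_policy, **kwargs).fit(
        chromo
    ).transform(chromo)


__all__ = [
    "bandpass_fir",
    "ampd_peaks",
    "refine_peaks",
    "peaks_to_hr",
    "windowed_correction",
    "resample_hr",
    "extract_heart_rate",
    "HeartRateExtractor",
    "HR_GATE",
]
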