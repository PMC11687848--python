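"""Modified Beer-Lambert conversion: intensity -> attenuation -> chromophores.

Continuous-wave NIRS measures relative light-intensity loss only, so all
concentrations here are *changes* relative to a reference window:

    dA(lambda) = [eps_O2Hb(lambda) dC_O2Hb + eps_HHb(lambda) dC_HHb]
                 * DPF(lambda) * rho

with dA the base-10 optical-density change, eps the extinction coefficients
(cm^-1 per umol/L), DPF the differential pathlength factor and rho the
source-detector separation in cm.  Each channel's 2x2 wavelength system is
solved sample-by-sample; total hemoglobin is appended as the sum.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import extinction
from .types import AttenuationSeries, ChromophoreSeries, RawIntensityRecording

logger = logging.getLogger(__name__)

DEFAULT_DPF = 6.0
DEFAULT_REFERENCE_S = 30.0


def intensities_to_attenuation(
    rec: RawIntensityRecording,
    reference_window: tuple[float, float] | None = None,
) -> AttenuationSeries:
    """Convert raw intensities to attenuation change relative to a window.

    dA(t) = -log10( I(t) / mean(I over reference window) ) per channel and
    wavelength.  If the recording already carries attenuation, the reference
    mean is subtracted instead so the output is zero-mean over the window
    either way.
    """
    if reference_window is None:
        reference_window = (float(rec.time[0]), float(rec.time[0]) + DEFAULT_REFERENCE_S)
    t0, t1 = reference_window
    sel = (rec.time >= t0) & (rec.time <= t1)
    if not np.any(sel):
        raise ValueError(f"empty reference window ({t0}, {t1})")
    if rec.signal_kind == "intensity":
        ref = rec.values[sel].mean(axis=0)
        values = -np.log10(rec.values / ref)
    else:
        ref = rec.values[sel].mean(axis=0)
        values = rec.values - ref
    # re-zero exactly: -log10(I/mean I) has mean ~0 but not exactly 0
    values = values - values[sel].mean(axis=0)
    return AttenuationSeries(
        time=rec.time.copy(),
        values=values,
        channels=rec.channels,
        sampling_rate=rec.sampling_rate,
        reference_window=(float(t0), float(t1)),
        subject_id=rec.subject_id,
        dive_label=rec.dive_label,
    )


def forward_attenuation(
    o2hb: np.ndarray,
    hhb: np.ndarray,
    channels,
    dpf: float = DEFAULT_DPF,
) -> np.ndarray:
    """Forward MBLL: concentration changes (umol/L) -> dA array (n, n_ch, 2).

    The exact inverse of :func:`attenuation_to_chromophores`; used by the
    simulator and round-trip tests.
    """
    o2hb = np.atleast_2d(np.asarray(o2hb, dtype=float).T).T
    hhb = np.atleast_2d(np.asarray(hhb, dtype=float).T).T
    n, n_ch = o2hb.shape
    out = np.empty((n, n_ch, 2))
    for j, ch in enumerate(channels):
        E = extinction.extinction_matrix(ch.wavelengths_nm)
        path = dpf * ch.distance_cm
        conc = np.stack([o2hb[:, j], hhb[:, j]], axis=1)
        out[:, j, :] = conc @ E.T * path
    return out


def attenuation_to_chromophores(
    att: AttenuationSeries,
    dpf: float = DEFAULT_DPF,
    extinction_source: str = extinction.DEFAULT_SOURCE,
) -> ChromophoreSeries:
    """Invert the per-channel 2x2 MBLL system at every sample."""
    n, n_ch, _ = att.values.shape
    o2hb = np.empty((n, n_ch))
    hhb = np.empty((n, n_ch))
    for j, ch in enumerate(att.channels):
        E = extinction.extinction_matrix(ch.wavelengths_nm)
        logger.debug(
            "channel %.0f mm: extinction condition number %.2f",
            ch.distance_mm,
            np.linalg.cond(E),
        )
        path = dpf * ch.distance_cm
        sol = np.linalg.solve(E, att.values[:, j, :].T / path)
        o2hb[:, j] = sol[0]
        hhb[:, j] = sol[1]
    return ChromophoreSeries(
        time=att.time.copy(),
        o2hb=o2hb,
        hhb=hhb,
        thb=o2hb + hhb,
        channels=att.channels,
        sampling_rate=att.sampling_rate,
        reference_window=att.reference_window,
        extinction_source=extinction_source,
        dpf=dpf,
        subject_id=att.subject_id,
        dive_label=att.dive_label,
    )


class MBLLTransformer(BaseEstimator, TransformerMixin):
    """Raw recording -> chromophore concentration changes.

    Parameters
    ----------
    reference_window : (float, float) or None
        Baseline interval (s); None means the first 30 s of the recording.
    dpf : float
        Differential pathlength factor applied at both wavelengths.
    """

    def __init__(self, reference_window=None, dpf: float = DEFAULT_DPF):
        self.reference_window = reference_window
        self.dpf = dpf

    def fit(self, X: RawIntensityRecording, y=None):
        if not isinstance(X, RawIntensityRecording):
            raise TypeError("MBLLTransformer expects a RawIntensityRecording")
        win = self.reference_window
        if win is None:
            win = (float(X.time[0]), float(X.time[0]) + DEFAULT_REFERENCE_S)
        self.reference_window_ = (float(win[0]), float(win[1]))
        self.n_features_in_ = X.values.shape[1] * 2
        return self

    def transform(self, X: RawIntensityRecording) -> ChromophoreSeries:
        if not hasattr(self, "reference_window_"):
            self.fit(X)
        att = intensities_to_attenuation(X, self.reference_window_)
        return attenuation_to_chromophores(att, dpf=self.dpf)


__all__ = [
    "intensities_to_attenuation",
    "attenuation_to_chromophores",
    "forward_attenuation",
    "MBLLTransformer",
    "DEFAULT_DPF",
    "DEFAULT_REFERENCE_S",
]
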