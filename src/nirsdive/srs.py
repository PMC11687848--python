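"""Spatially resolved spectroscopy: tissue saturation index from the
attenuation slope across source-detector distances.

With attenuation measured at several separations rho, the diffusion
approximation for a semi-infinite homogeneous medium gives a scaled
absorption coefficient at each wavelength

    k mu_a = 1 / (3 (1 - h lambda)) * (ln10 * dA/drho - 2/rho_bar)^2

where h (1/nm) captures the assumed linear wavelength dependence of reduced
scattering and the unknown common factor k cancels in the saturation ratio.
Solving k mu_a(lambda) = ln10 [eps_O2Hb k[O2Hb] + eps_HHb k[HHb]] at the two
wavelength groups yields scaled concentrations, and

    TSI = 100 * k[O2Hb] / (k[O2Hb] + k[HHb]).

Samples where the scaled total hemoglobin is non-positive are masked rather
than reported.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import extinction
from .types import AttenuationSeries, RawIntensityRecording, TsiSeries

LN10 = np.log(10.0)

#: default reduced-scattering wavelength-dependence coefficient (1/nm)
DEFAULT_H = 6.3e-4


def raw_attenuation(rec: RawIntensityRecording) -> AttenuationSeries:
    """Absolute attenuation -log10(I), defined up to a distance-independent
    offset per wavelength (unknown source power / detector gain).

    The SRS slope is invariant to such offsets, so this is the input the
    TSI chain needs; it assumes the three channels are gain-matched, which
    the simulator guarantees and real hardware approximates by factory
    calibration.
    """
    if rec.signal_kind != "intensity":
        return AttenuationSeries(
            time=rec.time.copy(),
            values=rec.values.copy(),
            channels=rec.channels,
            sampling_rate=rec.sampling_rate,
            reference_window=None,
            subject_id=rec.subject_id,
            dive_label=rec.dive_label,
        )
    return AttenuationSeries(
        time=rec.time.copy(),
        values=-np.log10(rec.values),
        channels=rec.channels,
        sampling_rate=rec.sampling_rate,
        reference_window=None,
        subject_id=rec.subject_id,
        dive_label=rec.dive_label,
    )


def attenuation_slope(att: AttenuationSeries) -> tuple[np.ndarray, tuple[float, float]]:
    """Ordinary-least-squares slope of attenuation against distance.

    Returns ``(slopes, group_wavelengths)`` where ``slopes`` has shape
    ``(n_samples, 2)`` — columns (long, short) wavelength group, units
    OD/cm — and ``group_wavelengths`` are the mean nominal wavelengths of
    each group used for extinction lookup.
    """
    rho = np.array([ch.distance_cm for ch in att.channels])
    if np.unique(rho).size < 2:
        raise ValueError("need at least two distinct source-detector distances")
    long_wl = float(np.mean([ch.wavelengths_nm[0] for ch in att.channels]))
    short_wl = float(np.mean([ch.wavelengths_nm[1] for ch in att.channels]))
    # OLS slope on collinear abscissa: cov(rho, A)/var(rho), vectorised in time
    rho_c = rho - rho.mean()
    denom = np.sum(rho_c**2)
    slopes = np.einsum("ncw,c->nw", att.values, rho_c) / denom
    return slopes, (long_wl, short_wl)


def scaled_absorption(
    slope: np.ndarray,
    rho_bar_cm: float,
    h_per_nm: float,
    wavelength_nm: float,
) -> np.ndarray:
    """Scaled absorption coefficient k mu_a (1/cm, common scale k unknown)."""
    if rho_bar_cm <= 0:
        raise ValueError("rho_bar must be positive")
    if h_per_nm * wavelength_nm >= 1.0:
        raise ValueError(
            f"h * lambda = {h_per_nm * wavelength_nm:.3f} >= 1; "
            "scattering model invalid"
        )
    slope = np.asarray(slope, dtype=float)
    return (LN10 * slope - 2.0 / rho_bar_cm) ** 2 / (3.0 * (1.0 - h_per_nm * wavelength_nm))


def tsi_from_scaled_absorption(
    k_mua_long: np.ndarray,
    k_mua_short: np.ndarray,
    group_wavelengths: tuple[float, float],
    time: np.ndarray,
    h_per_nm: float,
    rho_bar_cm: float,
) -> TsiSeries:
    """Unmix scaled absorption at two wavelengths into scaled concentrations
    and form the saturation percentage."""
    E = extinction.extinction_matrix(group_wavelengths)
    kmua = np.stack([np.asarray(k_mua_long, float), np.asarray(k_mua_short, float)], axis=0)
    sol = np.linalg.solve(LN10 * E, kmua)
    k_o2hb, k_hhb = sol[0], sol[1]
    k_thb = k_o2hb + k_hhb
    mask = k_thb <= 0
    tsi = np.full(k_thb.shape, np.nan)
    np.divide(100.0 * k_o2hb, k_thb, out=tsi, where=~mask)
    # numeric spillover outside [0,100] is masked, not clipped: it signals an
    # SRS model violation rather than measurement noise
    bad = ~mask & ((tsi < 0.0) | (tsi > 100.0))
    tsi[bad] = np.nan
    mask = mask | bad
    return TsiSeries(
        time=np.asarray(time, float),
        tsi=tsi,
        k_o2hb=k_o2hb,
        k_hhb=k_hhb,
        mask=mask,
        h_per_nm=h_per_nm,
        rho_bar_cm=rho_bar_cm,
    )


def extract_tsi(
    att: AttenuationSeries,
    h_per_nm: float = DEFAULT_H,
    rho_bar_cm: float | None = None,
) -> TsiSeries:
    """Full SRS chain: slopes -> scaled absorption -> TSI."""
    slopes, group_wl = attenuation_slope(att)
    if rho_bar_cm is None:
        rho_bar_cm = float(np.mean([ch.distance_cm for ch in att.channels]))
    k_long = scaled_absorption(slopes[:, 0], rho_bar_cm, h_per_nm, group_wl[0])
    k_short = scaled_absorption(slopes[:, 1], rho_bar_cm, h_per_nm, group_wl[1])
    return tsi_from_scaled_absorption(
        k_long, k_short, group_wl, att.time, h_per_nm, rho_bar_cm
    )


class TSIExtractor(BaseEstimator, TransformerMixin):
    """Recording/attenuation -> tissue saturation index trace.

    Parameters
    ----------
    h : float
        Reduced-scattering wavelength-dependence coefficient (1/nm).
    rho_bar_cm : float or None
        Representative separation in the 2/rho offset term; None means the
        mean of the probe's separations.
    """

    def __init__(self, h: float = DEFAULT_H, rho_bar_cm=None):
        self.h = h
        self.rho_bar_cm = rho_bar_cm

    def fit(self, X, y=None):
        channels = X.channels
        if len({ch.distance_mm for ch in channels}) < 2:
            raise ValueError("SRS needs at least two distinct distances")
        self.rho_bar_cm_ = (
            self.rho_bar_cm
            if self.rho_bar_cm is not None
            else float(np.mean([ch.distance_cm for ch in channels]))
        )
        return self

    def transform(self, X) -> TsiSeries:
        if not hasattr(self, "rho_bar_cm_"):
            self.fit(X)
        if isinstance(X, RawIntensityRecording):
            X = raw_attenuation(X)
        return extract_tsi(X, h_per_nm=self.h, rho_bar_cm=self.rho_bar_cm_)


__all__ = [
    "raw_attenuation",
    "attenuation_slope",
    "scaled_absorption",
    "tsi_from_scaled_absorption",
    "extract_tsi",
    "TSIExtractor",
    "DEFAULT_H",
    "LN10",
]
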