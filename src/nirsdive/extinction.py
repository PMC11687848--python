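"""Hemoglobin extinction coefficients for near-infrared wavelengths.

Base-10 molar extinction coefficients of oxy- and deoxyhemoglobin between
740 and 860 nm from the standard compiled in-vitro spectra used throughout
continuous-wave NIRS work, tabulated at 10 nm steps and interpolated
linearly to nominal device wavelengths.  Values are stored in
cm^-1 (mol/L)^-1 and exposed in cm^-1 (umol/L)^-1, the unit the modified
Beer-Lambert inversion works in.
"""

from __future__ import annotations

import numpy as np

DEFAULT_SOURCE = "compiled-hb-740-860nm"

# wavelength nm, eps_HbO2, eps_HHb  [cm^-1 / (mol/L)], base-10
_TABLE = np.array(
    [
        [740.0, 446.0, 1115.88],
        [750.0, 518.0, 1405.24],
        [760.0, 586.0, 1548.52],
        [770.0, 650.0, 1311.88],
        [780.0, 710.0, 1075.44],
        [790.0, 756.0, 890.80],
        [800.0, 816.0, 761.72],
        [810.0, 864.0, 717.08],
        [820.0, 916.0, 693.04],
        [830.0, 974.0, 693.76],
        [840.0, 1022.0, 692.36],
        [850.0, 1058.0, 691.32],
        [860.0, 1103.3, 691.16],
    ]
)


def extinction_coefficients(wavelength_nm: float) -> tuple[float, float]:
    """Return (eps_O2Hb, eps_HHb) at ``wavelength_nm`` in cm^-1/(umol/L).

    Linear interpolation inside 740-860 nm; outside raises, since the
    tabulated range covers every supported probe wavelength.
    """
    wl = float(wavelength_nm)
    if not _TABLE[0, 0] <= wl <= _TABLE[-1, 0]:
        raise ValueError(f"wavelength {wl} nm outside tabulated 740-860 nm range")
    e_o2 = np.interp(wl, _TABLE[:, 0], _TABLE[:, 1]) * 1e-6
    e_hh = np.interp(wl, _TABLE[:, 0], _TABLE[:, 2]) * 1e-6
    return float(e_o2), float(e_hh)


def extinction_matrix(wavelengths_nm: tuple[float, float]) -> np.ndarray:
    """2x2 extinction matrix for a (long, short) wavelength pair.

    Row i corresponds to wavelength i, columns to (O2Hb, HHb); units
    cm^-1/(umol/L).  Raises if the pair is numerically singular.
    """
    E = np.array([extinction_coefficients(w) for w in wavelengths_nm])
    cond = np.linalg.cond(E)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"singular extinction matrix for wavelength pair {wavelengths_nm}"
        )
    return E


__all__ = ["extinction_coefficients", "extinction_matrix", "DEFAULT_SOURCE"]
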