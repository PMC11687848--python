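"""Core data containers for the dive-NIRS pipeline.

All time axes are seconds from recording start on a uniform grid (default
10 Hz).  Optical channels are source-detector separations in mm, each with a
(long, short) nominal wavelength pair.  Concentration changes are relative to
a stated reference window, in micromol/L.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

GRID_TOL_S = 1e-6

#: Default probe geometry: three separations, dual wavelength each.
DEFAULT_CHANNELS: tuple["ProbeChannel", ...]


@dataclass(frozen=True)
class ProbeChannel:
    """One source-detector pair: separation (mm) and its nominal wavelengths.

    ``wavelengths_nm`` is ordered (long, short).
    """

    distance_mm: float
    wavelengths_nm: tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.wavelengths_nm) != 2:
            raise ValueError("exactly two wavelengths per channel")
        if self.wavelengths_nm[0] <= self.wavelengths_nm[1]:
            raise ValueError("wavelengths must be ordered (long, short)")
        if self.distance_mm <= 0:
            raise ValueError("distance must be positive")

    @property
    def distance_cm(self) -> float:
        return self.distance_mm / 10.0


DEFAULT_CHANNELS = (
    ProbeChannel(30.0, (842.0, 761.0)),
    ProbeChannel(35.0, (841.0, 759.0)),
    ProbeChannel(40.0, (841.0, 758.0)),
)


def _check_uniform_time(time: np.ndarray) -> float:
    """Validate a strictly increasing uniform grid; return the step."""
    time = np.asarray(time, dtype=float)
    if time.ndim != 1 or time.size < 2:
        raise ValueError("time grid needs at least two samples")
    steps = np.diff(time)
    if np.any(steps <= 0):
        raise ValueError("time grid must be strictly increasing")
    if np.max(np.abs(steps - steps[0])) > GRID_TOL_S:
        raise ValueError(
            "non-uniform time grid (max deviation "
            f"{np.max(np.abs(steps - steps[0])):.3g} s); resampling is not "
            "performed implicitly"
        )
    return float(steps[0])


@dataclass
class RawIntensityRecording:
    """Multi-distance, dual-wavelength optical time series.

    ``values`` has shape ``(n_samples, n_channels, 2)``; the last axis is
    (long, short) wavelength.  ``signal_kind`` is ``"intensity"`` (arbitrary
    units, strictly positive) or ``"attenuation"`` (optical density change).
    """

    time: np.ndarray
    values: np.ndarray
    channels: tuple[ProbeChannel, ...] = DEFAULT_CHANNELS
    sampling_rate: float = 10.0
    signal_kind: str = "intensity"
    subject_id: str = ""
    dive_label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        step = _check_uniform_time(self.time)
        if abs(step - 1.0 / self.sampling_rate) > GRID_TOL_S:
            self.sampling_rate = 1.0 / step
        if self.values.shape != (self.time.size, len(self.channels), 2):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"(n={self.time.size}, channels={len(self.channels)}, 2)"
            )
        if self.signal_kind not in ("intensity", "attenuation"):
            raise ValueError(f"unknown signal_kind {self.signal_kind!r}")
        if self.signal_kind == "intensity" and np.any(self.values <= 0):
            bad = int(np.argwhere(self.values <= 0)[0][0])
            raise ValueError(f"non-positive intensity at row {bad}")

    @property
    def n_samples(self) -> int:
        return int(self.time.size)

    @property
    def duration_s(self) -> float:
        return float(self.time[-1] - self.time[0])

    def channel_index(self, distance_mm: float) -> int:
        for i, ch in enumerate(self.channels):
            if abs(ch.distance_mm - distance_mm) < 1e-9:
                return i
        raise KeyError(f"no channel at {distance_mm} mm")


@dataclass
class AttenuationSeries:
    """Attenuation dA(t), base-10 OD, with the same array layout as
    :class:`RawIntensityRecording`.

    When ``reference_window`` is set the values are changes relative to that
    window (zero-mean over it per channel/wavelength).  When it is None the
    values are absolute attenuation up to a distance-independent offset —
    the form the spatially-resolved slope works on.
    """

    time: np.ndarray
    values: np.ndarray
    channels: tuple[ProbeChannel, ...]
    sampling_rate: float
    reference_window: Optional[tuple[float, float]] = None
    subject_id: str = ""
    dive_label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        _check_uniform_time(self.time)


@dataclass
class ChromophoreSeries:
    """Relative chromophore concentration changes per channel (micromol/L).

    ``o2hb``, ``hhb`` and ``thb`` have shape ``(n_samples, n_channels)`` and
    are zero-mean over the reference window; ``thb = o2hb + hhb`` by
    construction.
    """

    time: np.ndarray
    o2hb: np.ndarray
    hhb: np.ndarray
    thb: np.ndarray
    channels: tuple[ProbeChannel, ...]
    sampling_rate: float
    reference_window: tuple[float, float]
    extinction_source: str = ""
    dpf: float = 6.0
    subject_id: str = ""
    dive_label: str = ""

    def channel_index(self, distance_mm: float) -> int:
        for i, ch in enumerate(self.channels):
            if abs(ch.distance_mm - distance_mm) < 1e-9:
                return i
        raise KeyError(f"no channel at {distance_mm} mm")


@dataclass
class TsiSeries:
    """Tissue saturation index trace (percent, [0, 100] where defined).

    ``mask`` is True where TSI is undefined (scaled total hemoglobin <= 0);
    masked samples hold NaN in ``tsi``.
    """

    time: np.ndarray
    tsi: np.ndarray
    k_o2hb: np.ndarray
    k_hhb: np.ndarray
    mask: np.ndarray
    h_per_nm: float
    rho_bar_cm: float

    @property
    def n_masked(self) -> int:
        return int(np.count_nonzero(self.mask))


#: quality flags for heart-rate samples
HR_FLAG_RAW = "raw"
HR_FLAG_CORRECTED = "window-corrected"


@dataclass
class HeartRateSeries:
    """Beat-to-beat heart rate in beats/min at interval-midpoint times."""

    time: np.ndarray
    hr: np.ndarray
    flags: np.ndarray
    source_channel_mm: Optional[float] = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.hr = np.asarray(self.hr, dtype=float)
        self.flags = np.asarray(self.flags, dtype=object)
        if self.time.size and np.any(np.diff(self.time) <= 0):
            raise ValueError("beat times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.time.size)


@dataclass
class Spo2Series:
    """Continuous arterial oxygen saturation estimate (percent)."""

    time: np.ndarray
    spo2: np.ndarray
    method: str = "conventional"
    smoothing_window_s: float = 0.0
    anchors_used: int = 0
    clip_count: int = 0
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.spo2 = np.asarray(self.spo2, dtype=float)
        if self.mask is None:
            self.mask = np.zeros(self.time.shape, dtype=bool)


@dataclass(frozen=True)
class Anchor:
    """A discrete ground-truth arterial saturation point (blood draw)."""

    time: float
    sao2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.sao2 <= 100.0:
            raise ValueError("sao2 must be within [0, 100]")


@dataclass
class DiveEvents:
    """Dive timing and geometry; times share the recording clock (s)."""

    start_time: float
    end_time: float
    depth: float
    bottom_arrival: Optional[float] = None
    ascent_start: Optional[float] = None
    descent_rate: float = 1.0
    ascent_rate: float = 1.0
    subject_id: str = ""
    dive_label: str = ""

    def __post_init__(self) -> None:
        if not self.start_time < self.end_time:
            raise ValueError("start_time must precede end_time")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.descent_rate <= 0 or self.ascent_rate <= 0:
            raise ValueError("rates must be positive")
        marks = [
            m
            for m in (
                self.start_time,
                self.bottom_arrival,
                self.ascent_start,
                self.end_time,
            )
            if m is not None
        ]
        if any(a > b + 1e-9 for a, b in zip(marks, marks[1:])):
            raise ValueError("event times out of order")


VALID_SAMPLING_POINTS = ("A", "B", "C", "D", "F", "G")


@dataclass
class StageSummary:
    """Per-dive absolute stage values and telescoping relative changes.

    ``absolute`` maps stage name (start/bottom/ascent_start/end) to the
    windowed mean of the trace at that stage; ``relative`` maps transitions
    (start_bottom, bottom_ascent, ascent_end) to differences of those means.
    Entries are NaN where the stage fell outside the trace, with the reason
    recorded in ``masked``.
    """

    absolute: dict
    relative: dict
    stage_window_s: float
    masked: dict = field(default_factory=dict)


@dataclass
class GroundTruth:
    """Simulator ground truth aligned with the emitted recording grid."""

    time: np.ndarray
    hr: np.ndarray
    sao2: np.ndarray
    tsi: np.ndarray
    o2hb: np.ndarray
    hhb: np.ndarray
    events: DiveEvents


__all__ = [
    "ProbeChannel",
    "DEFAULT_CHANNELS",
    "RawIntensityRecording",
    "AttenuationSeries",
    "ChromophoreSeries",
    "TsiSeries",
    "HeartRateSeries",
    "Spo2Series",
    "Anchor",
    "DiveEvents",
    "StageSummary",
    "GroundTruth",
    "VALID_SAMPLING_POINTS",
    "HR_FLAG_RAW",
    "HR_FLAG_CORRECTED",
]
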