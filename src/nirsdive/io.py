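"""CSV readers and writers for every tabular artifact the pipeline touches.

All files are RFC-4180 CSV, UTF-8, "." decimal separator.  Recording columns
follow the convention ``i_<distance>mm_<wavelength>nm`` (``a_`` prefix for
attenuation input); a column-mapping dialect (YAML) adapts vendor export
headers that deviate from it.  Floats are written with 17 significant digits
so write -> read round trips are lossless.
"""

from __future__ import annotations

import importlib.resources
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    DEFAULT_CHANNELS,
    VALID_SAMPLING_POINTS,
    Anchor,
    DiveEvents,
    ProbeChannel,
    RawIntensityRecording,
)

FLOAT_FMT = "%.17g"
_COLUMN_RE = re.compile(r"^([ia])_(\d+(?:\.\d+)?)mm_(\d+(?:\.\d+)?)nm$")


class ConfigurationError(ValueError):
    """A dialect/config problem (e.g. a mapped column is missing)."""


class DataError(ValueError):
    """A validity problem in the data itself."""


# ---------------------------------------------------------------- recordings


def _default_columns(channels, signal_kind: str) -> list[str]:
    prefix = "i" if signal_kind == "intensity" else "a"
    cols = []
    for ch in channels:
        for wl in ch.wavelengths_nm:
            cols.append(f"{prefix}_{ch.distance_mm:g}mm_{wl:g}nm")
    return cols


def write_recording(rec: RawIntensityRecording, path) -> None:
    cols = {"time": rec.time}
    names = _default_columns(rec.channels, rec.signal_kind)
    k = 0
    for j in range(len(rec.channels)):
        for w in range(2):
            cols[names[k]] = rec.values[:, j, w]
            k += 1
    pd.DataFrame(cols).to_csv(path, index=False, float_format=FLOAT_FMT)


def _parse_dialect(dialect) -> dict:
    """Accept a mapping or a YAML file path; normalise to a dict."""
    if dialect is None:
        return {}
    if isinstance(dialect, (str, Path)):
        with open(dialect, "r", encoding="utf-8") as fh:
            dialect = yaml.safe_load(fh)
    if not isinstance(dialect, dict):
        raise ConfigurationError("dialect must be a mapping or a YAML file path")
    return dialect


def read_recording(
    path,
    dialect=None,
    subject_id: str = "",
    dive_label: str = "",
) -> RawIntensityRecording:
    """Read a recording CSV into a validated :class:`RawIntensityRecording`.

    Without a dialect, columns must follow the default
    ``i_<dist>mm_<wl>nm`` convention.  A dialect maps arbitrary vendor
    headers::

        time_column: Sample time
        signal_kind: intensity
        columns:
          "Rx1 TX 842": {distance_mm: 30, wavelength_nm: 842}
          ...

    Non-uniform time grids are rejected, never resampled.
    """
    df = pd.read_csv(path)
    spec = _parse_dialect(dialect)
    time_col = spec.get("time_column", "time")
    if time_col not in df.columns:
        raise ConfigurationError(f"missing time column {time_col!r}")

    mapping: dict[str, tuple[float, float]] = {}
    signal_kind = spec.get("signal_kind")
    if "columns" in spec:
        for col, info in spec["columns"].items():
            if col not in df.columns:
                raise ConfigurationError(f"missing mapped column {col!r}")
            mapping[col] = (float(info["distance_mm"]), float(info["wavelength_nm"]))
        signal_kind = signal_kind or "intensity"
    else:
        kinds = set()
        for col in df.columns:
            m = _COLUMN_RE.match(col)
            if m:
                kinds.add("intensity" if m.group(1) == "i" else "attenuation")
                mapping[col] = (float(m.group(2)), float(m.group(3)))
        if not mapping:
            raise ConfigurationError(
                "no recognisable signal columns; provide a column-mapping dialect"
            )
        if len(kinds) > 1:
            raise ConfigurationError("mixed intensity and attenuation columns")
        signal_kind = signal_kind or kinds.pop()

    # group columns into channels by distance, wavelengths ordered long, short
    by_dist: dict[float, list[tuple[float, str]]] = {}
    for col, (dist, wl) in mapping.items():
        by_dist.setdefault(dist, []).append((wl, col))
    channels = []
    col_order = []
    for dist in sorted(by_dist):
        pairs = sorted(by_dist[dist], reverse=True)
        if len(pairs) != 2:
            raise DataError(
                f"channel at {dist:g} mm has {len(pairs)} wavelengths; need 2"
            )
        channels.append(ProbeChannel(dist, (pairs[0][0], pairs[1][0])))
        col_order.extend([pairs[0][1], pairs[1][1]])

    values = df[col_order].to_numpy(dtype=float).reshape(len(df), len(channels), 2)
    try:
        return RawIntensityRecording(
            time=df[time_col].to_numpy(dtype=float),
            values=values,
            channels=tuple(channels),
            signal_kind=signal_kind,
            subject_id=subject_id,
            dive_label=dive_label,
        )
    except ValueError as exc:
        raise DataError(str(exc)) from exc


# -------------------------------------------------------------------- events


def write_events(events_list, path) -> None:
    rows = []
    for ev in np.atleast_1d(events_list):
        rows.append(
            {
                "subject": ev.subject_id,
                "dive_label": ev.dive_label,
                "start": ev.start_time,
                "bottom": ev.bottom_arrival,
                "ascent_start": ev.ascent_start,
                "end": ev.end_time,
                "depth": ev.depth,
                "descent_rate": ev.descent_rate,
                "ascent_rate": ev.ascent_rate,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_events(path) -> list[DiveEvents]:
    df = pd.read_csv(path)
    required = {"start", "end", "depth"}
    if not required.issubset(df.columns):
        raise ConfigurationError(f"events file needs columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        def _opt(name):
            v = row.get(name)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)

        try:
            out.append(
                DiveEvents(
                    start_time=float(row["start"]),
                    end_time=float(row["end"]),
                    depth=float(row["depth"]),
                    bottom_arrival=_opt("bottom"),
                    ascent_start=_opt("ascent_start"),
                    descent_rate=float(row.get("descent_rate", 1.0) or 1.0),
                    ascent_rate=float(row.get("ascent_rate", 1.0) or 1.0),
                    subject_id=str(row.get("subject", "")),
                    dive_label=str(row.get("dive_label", "")),
                )
            )
        except ValueError as exc:
            raise DataError(f"invalid events row {_}: {exc}") from exc
    return out


# ----------------------------------------------------------------- blood gas


def read_blood_gas(path) -> pd.DataFrame:
    """Arterial blood-gas table: subject, point, pao2, paco2, sao2 [, hb].

    Sampling points are restricted to A-D, F, G (E was never drawn in the
    protocol this table layout comes from); duplicates per (subject, point)
    and out-of-range values are rejected.  An empty file yields an empty
    table — downstream tests then refuse with their own n < 2 message.
    """
    required = ["subject", "point", "pao2", "paco2", "sao2"]
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=required)
    missing = [c for c in required if c not in df.columns]
    if missing and len(df):
        raise ConfigurationError(f"blood-gas file missing columns {missing}")
    if df.empty:
        cols = required + (["hb"] if "hb" in df.columns else [])
        return pd.DataFrame(columns=cols)
    df = df.copy()
    df["point"] = df["point"].astype(str).str.strip().str.upper()
    bad = sorted(set(df["point"]) - set(VALID_SAMPLING_POINTS))
    if bad:
        raise DataError(f"unknown sampling point label(s) {bad}")
    dup = df.duplicated(subset=["subject", "point"])
    if dup.any():
        raise DataError(
            f"duplicate (subject, point) rows: {df.loc[dup, ['subject', 'point']].values.tolist()}"
        )
    for col in ("pao2", "paco2", "sao2") + (("hb",) if "hb" in df.columns else ()):
        df[col] = pd.to_numeric(df[col], errors="raise")
    if (df["sao2"] < 0).any() or (df["sao2"] > 100).any():
        raise DataError("sao2 outside [0, 100]")
    if (df["pao2"] <= 0).any() or (df["paco2"] <= 0).any():
        raise DataError("pao2/paco2 must be positive")
    return df


def packaged_blood_gas() -> pd.DataFrame:
    """The shipped six-freediver arterial blood-gas dataset (points A-G)."""
    ref = importlib.resources.files("nirsdive.data") / "freedive_blood_gas.csv"
    with importlib.resources.as_file(ref) as p:
        return read_blood_gas(p)


def packaged_subjects() -> pd.DataFrame:
    """Demographics of the six freedivers (sex, age, anthropometrics)."""
    ref = importlib.resources.files("nirsdive.data") / "freedive_subjects.csv"
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p)


def read_anchors(path) -> list[Anchor]:
    """Anchor CSV with columns time, sao2."""
    df = pd.read_csv(path)
    if not {"time", "sao2"}.issubset(df.columns):
        raise ConfigurationError("anchors file needs columns time, sao2")
    return [Anchor(float(r.time), float(r.sao2)) for r in df.itertuples()]


# ----------------------------------------------------------- derived outputs


def write_series(path, time: np.ndarray, **columns) -> None:
    """Generic tidy time-series writer (time plus named columns)."""
    pd.DataFrame({"time": time, **columns}).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


__all__ = [
    "ConfigurationError",
    "DataError",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "read_blood_gas",
    "packaged_blood_gas",
    "packaged_subjects",
    "read_anchors",
    "write_series",
]
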