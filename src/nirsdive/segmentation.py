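"""Dive-stage timing and stage-wise summaries of continuous traces.

A dive is summarised at four stage marks — start, bottom arrival, start of
ascent, end — with missing marks reconstructed from the sled's fixed travel
rates (depth / rate).  A stage "value" is the mean of the trace over a short
window centered on the mark (default 5 s), and relative changes between
consecutive stages telescope exactly to the end-minus-start difference.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .types import DiveEvents, StageSummary

DEFAULT_STAGE_WINDOW_S = 5.0
ANALYSIS_PAD_S = 45.0

STAGES = ("start", "bottom", "ascent_start", "end")
TRANSITIONS = (
    ("start_bottom", "start", "bottom"),
    ("bottom_ascent", "bottom", "ascent_start"),
    ("ascent_end", "ascent_start", "end"),
)


def ascent_start(events: DiveEvents, blood_draw_offset_s: float = 0.0) -> float:
    """Start-of-ascent time: recorded if present, else end - depth/rate.

    ``blood_draw_offset_s`` shifts the estimate earlier to account for an
    end-of-bottom blood draw that the travel-time reconstruction cannot see.
    """
    if events.ascent_start is not None:
        return float(events.ascent_start)
    est = events.end_time - events.depth / events.ascent_rate - blood_draw_offset_s
    if est < events.start_time:
        raise ValueError(
            f"estimated ascent start {est:.1f} s precedes dive start "
            f"{events.start_time:.1f} s"
        )
    return float(est)


def bottom_arrival(events: DiveEvents) -> float:
    """Bottom-arrival time: recorded if present, else start + depth/rate."""
    if events.bottom_arrival is not None:
        return float(events.bottom_arrival)
    est = events.start_time + events.depth / events.descent_rate
    if est > events.end_time:
        raise ValueError(
            f"estimated bottom arrival {est:.1f} s exceeds dive end "
            f"{events.end_time:.1f} s"
        )
    return float(est)


def analysis_window(
    events: DiveEvents,
    recording_extent: tuple[float, float] | None = None,
    pad_s: float = ANALYSIS_PAD_S,
) -> tuple[float, float, bool]:
    """(start - pad, end + pad), clipped to the recording; returns a clip flag."""
    lo = events.start_time - pad_s
    hi = events.end_time + pad_s
    clipped = False
    if recording_extent is not None:
        if lo < recording_extent[0]:
            lo, clipped = recording_extent[0], True
        if hi > recording_extent[1]:
            hi, clipped = recording_extent[1], True
    return float(lo), float(hi), clipped


def stage_times(events: DiveEvents, blood_draw_offset_s: float = 0.0) -> dict:
    """All four stage marks, reconstructing the missing ones."""
    b = bottom_arrival(events)
    a = ascent_start(events, blood_draw_offset_s)
    if b > a + 1e-9:
        raise ValueError(
            f"bottom arrival {b:.1f} s after ascent start {a:.1f} s; "
            "inconsistent events"
        )
    return {
        "start": float(events.start_time),
        "bottom": b,
        "ascent_start": a,
        "end": float(events.end_time),
    }


def stage_values(
    time: np.ndarray,
    trace: np.ndarray,
    events: DiveEvents,
    stage_window_s: float = DEFAULT_STAGE_WINDOW_S,
    blood_draw_offset_s: float = 0.0,
) -> StageSummary:
    """Windowed stage means and telescoping relative changes of a trace.

    Stages falling outside the trace (or fully masked) yield NaN with the
    reason recorded; relative changes involving them are NaN too.
    """
    time = np.asarray(time, float)
    trace = np.asarray(trace, float)
    marks = stage_times(events, blood_draw_offset_s)
    half = stage_window_s / 2.0
    absolute: dict[str, float] = {}
    masked: dict[str, str] = {}
    for name, tc in marks.items():
        sel = (time >= tc - half) & (time <= tc + half)
        vals = trace[sel]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            absolute[name] = float("nan")
            masked[name] = (
                "outside trace" if (tc < time[0] or tc > time[-1]) else "all-masked window"
            )
        else:
            absolute[name] = float(vals.mean())
    relative = {
        label: absolute[b] - absolute[a] for label, a, b in TRANSITIONS
    }
    return StageSummary(
        absolute=absolute,
        relative=relative,
        stage_window_s=stage_window_s,
        masked=masked,
    )


def with_estimated_times(events: DiveEvents) -> DiveEvents:
    """Events with both reconstructable marks filled in."""
    return replace(
        events,
        bottom_arrival=bottom_arrival(events),
        ascent_start=ascent_start(events),
    )


__all__ = [
    "ascent_start",
    "bottom_arrival",
    "analysis_window",
    "stage_times",
    "stage_values",
    "with_estimated_times",
    "DEFAULT_STAGE_WINDOW_S",
    "ANALYSIS_PAD_S",
    "STAGES",
    "TRANSITIONS",
]
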