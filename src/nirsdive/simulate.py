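"""Synthetic sled-dive generator with full ground truth.

Emits a three-distance, dual-wavelength 10 Hz intensity recording whose
physiology is known exactly, so every pipeline stage has an oracle:

* a piecewise-linear bradycardic heart-rate profile drives a sinusoidal
  cardiac pulsation;
* an arterial saturation profile (baseline ~99 %, compression plateau
  during descent/bottom, monotone decay during ascent to a configurable
  nadir) sets the O2Hb:HHb pulsation amplitude ratio to
  SaO2 : (100 - SaO2), the exact inverse of the pulsatile ratio method;
* a slow tissue compartment (total hemoglobin plus a saturation trajectory
  around the TSI baseline, lagged by the lung-to-brain circulation time)
  is pushed through the spatially-resolved forward model, so the
  attenuation slope across distances encodes the true TSI;
* the cardiac component is added through the forward modified
  Beer-Lambert path per channel, optional involuntary-breathing-movement
  bursts during ascent and Gaussian optical-density noise complete the
  signal.

The slow component uses the probe's group-mean wavelengths (the same
approximation the TSI chain makes), the pulsatile component each channel's
nominal pair.  A "pathlength-drift" distortion multiplies the oxyhemoglobin
pulsation by a slowly growing wavelength-dependent factor, emulating the
pathlength error that motivates anchor calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import extinction
from .mbll import forward_attenuation
from .srs import LN10
from .types import (
    DEFAULT_CHANNELS,
    Anchor,
    DiveEvents,
    GroundTruth,
    ProbeChannel,
    RawIntensityRecording,
)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic sled-assisted dive.

    Rates and stage structure mirror the sled protocol (~1 m/s travel,
    15 m or 42 m depth); heart-rate and saturation end-points mirror the
    observed stage means; amplitudes and noise are chosen at realistic
    continuous-wave NIRS magnitudes.
    """

    seed: int = 0
    depth_m: float = 42.0
    descent_rate: float = 1.0
    ascent_rate: float = 1.0
    bottom_hold_s: float = 30.0
    pre_pad_s: float = 60.0
    post_pad_s: float = 60.0
    sampling_rate: float = 10.0
    # heart rate profile (beats/min)
    hr_start: float = 95.0
    hr_bottom: float = 80.0
    hr_end: float = 77.0
    # arterial saturation profile (%)
    sao2_baseline: float = 99.0
    sao2_plateau: float = 99.5
    sao2_nadir: float = 65.0
    # tissue compartment
    tsi_baseline: float = 76.0
    tsi_descent_rise: float = 2.0
    tsi_end_drop: float = 3.0
    thb_total_uM: float = 60.0
    dthb_descent_uM: float = 3.0
    circulation_lag_s: float = 5.0
    # optics
    pulsation_amp_uM: float = 0.6
    noise_sd_od: float = 5e-4
    dpf: float = 6.0
    source_intensity: float = 1e5
    channels: tuple[ProbeChannel, ...] = DEFAULT_CHANNELS
    # artifacts / distortion
    ibm_bursts: int = 0
    ibm_amplitude_od: float = 0.02
    distortion: str = "none"  # "none" | "pathlength-drift"
    drift_base: float = 1.25
    drift_slope: float = 0.10
    # bookkeeping
    record_bottom_time: bool = True
    record_ascent_time: bool = False
    subject_id: str = "sim"
    dive_label: str = ""

    def __post_init__(self) -> None:
        if min(self.descent_rate, self.ascent_rate) <= 0:
            raise ValueError("travel rates must be positive")
        if self.depth_m <= 0 or self.bottom_hold_s < 0:
            raise ValueError("invalid dive geometry")
        if not self.sao2_nadir < self.sao2_baseline:
            raise ValueError("sao2 nadir must be below baseline")
        if self.pre_pad_s < 30.0:
            raise ValueError(
                "pre-dive padding must cover the 30 s reference window"
            )
        if self.distortion not in ("none", "pathlength-drift"):
            raise ValueError(f"unknown distortion {self.distortion!r}")

    @property
    def dive_duration_s(self) -> float:
        return (
            self.depth_m / self.descent_rate
            + self.bottom_hold_s
            + self.depth_m / self.ascent_rate
        )


def _profile(t: np.ndarray, nodes: list[tuple[float, float]]) -> np.ndarray:
    xs, ys = zip(*nodes)
    return np.interp(t, xs, ys)


def simulate_dive(
    config: SimulationConfig,
) -> tuple[RawIntensityRecording, DiveEvents, GroundTruth]:
    """Generate one dive; fully determined by ``config`` (incl. seed)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sampling_rate
    start = cfg.pre_pad_s
    bottom = start + cfg.depth_m / cfg.descent_rate
    ascent = bottom + cfg.bottom_hold_s
    end = ascent + cfg.depth_m / cfg.ascent_rate
    total = end + cfg.post_pad_s
    n = int(round(total * fs)) + 1
    t = np.arange(n) / fs

    lag = cfg.circulation_lag_s

    hr = _profile(
        t,
        [
            (0.0, cfg.hr_start),
            (start, cfg.hr_start),
            (bottom, cfg.hr_bottom),
            (ascent, cfg.hr_bottom),
            (end, cfg.hr_end),
            (end + 30.0, 0.5 * (cfg.hr_start + cfg.hr_end)),
            (total, 0.5 * (cfg.hr_start + cfg.hr_end)),
        ],
    )
    sao2 = _profile(
        t,
        [
            (0.0, cfg.sao2_baseline),
            (start, cfg.sao2_baseline),
            (bottom, cfg.sao2_plateau),
            (ascent, cfg.sao2_plateau),
            (end, cfg.sao2_nadir),  # monotone linear decay through ascent
            (end + 10.0, cfg.sao2_nadir),
            (end + 45.0, cfg.sao2_baseline),
            (total, cfg.sao2_baseline),
        ],
    )
    tsi = _profile(
        t,
        [
            (0.0, cfg.tsi_baseline),
            (start + lag, cfg.tsi_baseline),
            (bottom + lag, cfg.tsi_baseline + cfg.tsi_descent_rise),
            (ascent + lag, cfg.tsi_baseline + 0.7 * cfg.tsi_descent_rise),
            (end + lag, cfg.tsi_baseline - cfg.tsi_end_drop),
            (end + lag + 30.0, cfg.tsi_baseline),
            (total, cfg.tsi_baseline),
        ],
    )
    dthb = _profile(
        t,
        [
            (0.0, 0.0),
            (start + lag, 0.0),
            (bottom + lag, cfg.dthb_descent_uM),
            (ascent + lag, cfg.dthb_descent_uM),
            (end + lag, cfg.dthb_descent_uM - 1.0),
            (end + lag + 30.0, 0.0),
            (total, 0.0),
        ],
    )

    # ---- slow tissue compartment through the SRS forward model ----------
    thb = cfg.thb_total_uM + dthb
    c_o2_slow = tsi / 100.0 * thb
    c_hh_slow = (1.0 - tsi / 100.0) * thb

    chans = cfg.channels
    rho = np.array([ch.distance_cm for ch in chans])
    rho_bar = float(rho.mean())
    group_wl = (
        float(np.mean([ch.wavelengths_nm[0] for ch in chans])),
        float(np.mean([ch.wavelengths_nm[1] for ch in chans])),
    )
    from .srs import DEFAULT_H

    A = np.empty((n, len(chans), 2))
    for w, wl in enumerate(group_wl):
        e_o2, e_hh = extinction.extinction_coefficients(wl)
        mua = LN10 * (e_o2 * c_o2_slow + e_hh * c_hh_slow)  # 1/cm, natural log
        slope = (np.sqrt(3.0 * (1.0 - DEFAULT_H * wl) * mua) + 2.0 / rho_bar) / LN10
        A[:, :, w] = slope[:, None] * rho[None, :] + 0.5

    # ---- cardiac pulsation through the forward MBLL path ----------------
    phase = 2.0 * np.pi * np.cumsum(hr / 60.0) / fs
    s_frac = sao2 / 100.0
    pulse_o2 = cfg.pulsation_amp_uM * s_frac * np.cos(phase)
    pulse_hh = cfg.pulsation_amp_uM * (1.0 - s_frac) * np.cos(phase)
    if cfg.distortion == "pathlength-drift":
        gamma = cfg.drift_base + cfg.drift_slope * (t / total)
        pulse_o2_optical = gamma * pulse_o2
    else:
        pulse_o2_optical = pulse_o2
    po = np.repeat(pulse_o2_optical[:, None], len(chans), axis=1)
    ph = np.repeat(pulse_hh[:, None], len(chans), axis=1)
    A += forward_attenuation(po, ph, chans, dpf=cfg.dpf)

    # ---- artifacts and noise --------------------------------------------
    if cfg.ibm_bursts > 0:
        burst_times = rng.uniform(ascent, end, size=cfg.ibm_bursts)
        for bt in burst_times:
            A += (
                cfg.ibm_amplitude_od
                * np.exp(-0.5 * ((t - bt) / 0.4) ** 2)[:, None, None]
            )
    if cfg.noise_sd_od > 0:
        A += rng.normal(0.0, cfg.noise_sd_od, size=A.shape)

    intensities = cfg.source_intensity * 10.0 ** (-A)

    label = cfg.dive_label or f"sim-{cfg.depth_m:g}m-seed{cfg.seed}"
    rec = RawIntensityRecording(
        time=t,
        values=intensities,
        channels=chans,
        sampling_rate=fs,
        signal_kind="intensity",
        subject_id=cfg.subject_id,
        dive_label=label,
    )
    events = DiveEvents(
        start_time=start,
        end_time=end,
        depth=cfg.depth_m,
        bottom_arrival=bottom if cfg.record_bottom_time else None,
        ascent_start=ascent if cfg.record_ascent_time else None,
        descent_rate=cfg.descent_rate,
        ascent_rate=cfg.ascent_rate,
        subject_id=cfg.subject_id,
        dive_label=label,
    )
    ref = t <= 30.0
    truth = GroundTruth(
        time=t,
        hr=hr,
        sao2=sao2,
        tsi=tsi,
        o2hb=(c_o2_slow + pulse_o2) - (c_o2_slow + pulse_o2)[ref].mean(),
        hhb=(c_hh_slow + pulse_hh) - (c_hh_slow + pulse_hh)[ref].mean(),
        events=events,
    )
    return rec, events, truth


def default_anchors(truth: GroundTruth) -> list[Anchor]:
    """Blood-draw-like anchors: pre-dive, bottom arrival, dive end."""
    ev = truth.events
    out = []
    for when in (ev.start_time - 10.0, ev.bottom_arrival or ev.start_time + 5.0, ev.end_time):
        i = int(np.argmin(np.abs(truth.time - when)))
        out.append(Anchor(float(truth.time[i]), float(truth.sao2[i])))
    return out


def benchmark_suite(
    seeds,
    depth_m: float = 42.0,
    distortion: str = "none",
    **config_overrides,
):
    """Full-pipeline recovery errors over simulated dives.

    For each seed: simulate, run MBLL -> heart rate, SpO2 (conventional
    and, when anchors are available, anchor-calibrated), TSI, and stage
    summaries; report mean absolute errors against ground truth.  Returns
    a pandas DataFrame with one row per seed.
    """
    import pandas as pd

    from .heart_rate import HeartRateExtractor, resample_hr
    from .mbll import MBLLTransformer
    from .segmentation import stage_values, with_estimated_times
    from .spo2 import AnchorCalibrator, Spo2Estimator, moving_average
    from .srs import TSIExtractor

    seeds = list(seeds)
    if len(seeds) < 3:
        raise ValueError("benchmark needs at least 3 seeds")
    rows = []
    for seed in seeds:
        cfg = SimulationConfig(
            seed=int(seed), depth_m=depth_m, distortion=distortion, **config_overrides
        )
        rec, events, truth = simulate_dive(cfg)
        chromo = MBLLTransformer().fit(rec).transform(rec)

        hrx = HeartRateExtractor().fit(chromo)
        hr_series = hrx.transform(chromo)
        hr_grid = resample_hr(hr_series, truth.time)
        inside = (truth.time >= hr_series.time[0]) & (truth.time <= hr_series.time[-1])
        hr_mae = float(np.nanmean(np.abs(hr_grid[inside] - truth.hr[inside])))

        spx = Spo2Estimator().fit(chromo)
        spo2_series = spx.transform(chromo, beats=hrx.beat_indices_)
        err = spo2_series.spo2 - truth.sao2
        hi = truth.sao2 >= 70.0
        spo2_mae_hi = float(np.nanmean(np.abs(err[hi])))
        spo2_mae_lo = (
            float(np.nanmean(np.abs(err[~hi]))) if np.any(~hi) else float("nan")
        )
        spo2_rmse = float(np.sqrt(np.nanmean(err**2)))

        anchors = default_anchors(truth)
        try:
            cal = AnchorCalibrator().fit(spo2_series, anchors)
            calibrated = cal.predict(spo2_series)
            cal_err = calibrated.spo2 - truth.sao2
            cal_rmse = float(np.sqrt(np.nanmean(cal_err**2)))
        except ValueError:
            cal_rmse = float("nan")

        tsi_series = TSIExtractor().fit(rec).transform(rec)
        tsi_mae = float(np.nanmean(np.abs(tsi_series.tsi - truth.tsi)))

        ev = with_estimated_times(events)
        summ = stage_values(truth.time, tsi_series.tsi, ev)
        truth_summ = stage_values(truth.time, truth.tsi, ev)
        stage_err = float(
            np.nanmax(
                [
                    abs(summ.absolute[s] - truth_summ.absolute[s])
                    for s in summ.absolute
                ]
            )
        )
        rows.append(
            {
                "seed": seed,
                "hr_mae_bpm": hr_mae,
                "spo2_mae_high": spo2_mae_hi,
                "spo2_mae_low": spo2_mae_lo,
                "spo2_rmse_conventional": spo2_rmse,
                "spo2_rmse_calibrated": cal_rmse,
                "tsi_mae_pp": tsi_mae,
                "tsi_stage_max_err_pp": stage_err,
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "SimulationConfig",
    "simulate_dive",
    "default_anchors",
    "benchmark_suite",
]
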