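# Methods

This note documents the models behind each pipeline stage, the parameters
that matter, the design choices made where the procedure was genuinely
open, and what the synthetic benchmark does and does not demonstrate.

## Optical model

Continuous-wave NIRS measures relative light-intensity loss only, so all
hemoglobin quantities are changes relative to a reference window — by
default the first 30 s of the recording, assumed to be quiet surface
floating before the dive. The modified Beer–Lambert law relates the
base-10 attenuation change at wavelength λ to chromophore concentration
changes through the extinction coefficients ε (cm⁻¹ per µmol/L), the
source–detector separation ρ (cm) and the differential pathlength factor
(DPF):

    ΔA(λ) = [ε_O₂Hb(λ)·Δ[O₂Hb] + ε_HHb(λ)·Δ[HHb]] · DPF(λ) · ρ

Each channel's 2×2 wavelength system is solved sample-by-sample; the
extinction matrix condition number is logged. Assumptions: constant
scattering, homogeneous medium, and a known DPF. Defaults:

- **Extinction coefficients** — a standard compiled in-vitro Hb/HbO₂
  spectrum tabulated at 10 nm steps over 740–860 nm, interpolated linearly
  to each channel's nominal wavelengths. The table is configurable; vendor
  software uses its own (undisclosed) compilation, so absolute µmol/L
  amplitudes from this package and from vendor exports are not
  interchangeable, although dynamics are.
- **DPF = 6.0** at both wavelengths — a conventional adult-forehead value.
  DPF only scales amplitudes; it cancels from every ratio-based quantity
  (TSI, SpO₂) and from heart-rate timing.
- Each channel uses its own nominal wavelength pair (842/761, 841/759,
  841/758 nm): the 1–3 nm inter-channel spread is a real hardware fact.

## Tissue saturation index (spatially resolved spectroscopy)

With attenuation measured at three separations, the diffusion
approximation for a semi-infinite homogeneous medium gives a scaled
absorption coefficient per wavelength group:

    kμ_a = (ln10 · ∂A/∂ρ − 2/ρ̄)² / (3 · (1 − hλ))

where ∂A/∂ρ is the ordinary-least-squares slope of attenuation against
distance, ρ̄ the representative separation in the offset term, and h the
assumed linear wavelength dependence of reduced scattering. The two kμ_a
values are unmixed into scaled concentrations k[O₂Hb], k[HHb]; the common
factor k (which absorbs the unknown scattering amplitude) cancels in

    TSI = 100 · k[O₂Hb] / (k[O₂Hb] + k[HHb]).

Choices and caveats:

- The SRS chain consumes **absolute attenuation** −log₁₀(I), not the
  reference-subtracted change: the slope needs the inter-distance
  structure, which per-channel referencing would destroy. The unknown
  source power and detector gain are distance-independent and drop out of
  the slope, provided the three channels are gain-matched — true for the
  simulator, approximately true for factory-calibrated hardware.
- **h = 6.3×10⁻⁴ nm⁻¹** — a published adult-tissue wavelength-dependence
  value; configurable, and TSI shifts by well under a percentage point per
  10 % change in h at these wavelengths.
- **ρ̄ = 3.5 cm**, the mean of the three separations, enters the 2/ρ̄
  offset term; the slope itself uses all three distances.
- Extinction lookup uses the **group-mean wavelengths** (841.33 and
  759.33 nm) since the slope pools channels whose nominal wavelengths
  differ by ≤ 3 nm — negligible against extinction-curve curvature.
- Samples where k[tHb] ≤ 0 or the ratio leaves [0, 100] are masked with a
  reason, never clipped: they indicate an SRS model violation (motion,
  coupling loss), not measurement noise.

## Heart rate

1. **Zero-phase bandpass FIR**, order 100 (Hamming design), 0.1–4 Hz at
   10 Hz, applied forward–backward. Forward–backward application cancels
   phase delay exactly and squares the magnitude response (effective order
   doubles); the signal is demeaned first because the wide low-frequency
   transition band would otherwise leak a large DC offset.
2. **AMPD**: for every window scale k mark samples exceeding both
   neighbours at lag k; the dominant scale is the one with the most marks;
   a sample is a beat iff marked at every scale up to the dominant one.
   The scale search is capped at half the slowest plausible beat period
   (20 beats/min) so respiratory or hemodynamic cycles in long recordings
   cannot capture the scalogram.
3. **Parabolic sub-sample refinement** of each peak: at 10 Hz a cardiac
   interval spans 6–8 samples and integer peak indices quantise
   instantaneous heart rate to a handful of values (75/85.7/100
   beats/min); a three-point parabolic fit removes this quantisation.
4. **Peak-to-peak intervals** → beats/min at interval midpoints.
5. **Windowed correction**: within a sliding 10-s window, values outside
   the 20–250 beats/min physiological gate or deviating from the window
   median by more than 30 % are replaced by that median and flagged. The
   parameters are deliberately conservative and config-exposed.

The pulse is read from Δ[O₂Hb] of the shallowest channel (30 mm) by
default — the strongest arterial pulsation travels the shallowest
skin-to-cortex path; both the chromophore and the channel policy
(shallowest / least-noisy / explicit) are configurable.

## SpO₂

Per cardiac cycle (between consecutive detected beats) the systolic peak
and diastolic trough are located on the cardiac-band (0.5–4 Hz) Δ[O₂Hb]
trace, and both chromophores are read at those two instants; the
amplitudes give

    SpO₂ = 100 · AC_O₂Hb / (AC_O₂Hb + AC_HHb),

linearly interpolated to the recording grid, then smoothed with a centered
5-s moving average (edge windows shrink rather than pad). Reading the
weaker Δ[HHb] trace at its own extrema would inflate it by the noise
envelope and bias high saturations downward; evaluating both traces at
common beat landmarks is how pulse oximetry forms its ratio and removes
that bias. The ratio is invariant to any common rescaling of the two
traces, hence to DPF and ρ.

**Anchor calibration** regresses arterial SaO₂ values from blood draws on
the trace value at the anchor times (±2.5 s means) and applies the fitted
affine map. It is a deliberately simple stand-in for self-calibrating
wavelength-pathlength models: those address the physical mechanism
(saturation-dependent photon pathlength) inside the optical model, whereas
the affine map only exercises the same ground-truth-anchoring idea at the
output. It requires ≥ 2 anchors at distinct trace values, reports
residuals, and is idempotent. No empirical pulse-oximeter R-curve is
applied anywhere.

## Segmentation and stage statistics

Missing bottom-arrival and ascent-start marks are reconstructed from the
sled geometry (start + depth/descent rate; end − depth/ascent rate); a
recorded mark always wins, and inconsistent geometry raises rather than
silently reordering. An optional blood-draw-duration offset shifts the
estimated ascent start earlier, since the end-of-bottom draw (~5–10 s) is
invisible to the travel-time reconstruction (default 0). A stage "value"
is the trace mean over a 5-s window centered on the mark, suppressing
beat-scale noise; relative changes are differences of those means and
telescope exactly.

Paired contrasts run through a Shapiro–Wilk gate on the differences at
α = 0.05: normal → paired t; nonnormal → Wilcoxon signed-rank. The
Wilcoxon statistic is reported as V = sum of positive-difference ranks
(zeros dropped by default; Pratt handling available), with an exact
two-sided p for ≤ 25 tie-free nonzero differences and a tie-corrected
normal approximation otherwise; the p-method is logged because published
Wilcoxon p-values vary across software conventions while V does not. All
contrasts are tested at raw P < 0.05 with no multiplicity correction —
matching the protocol's analysis — but Holm step-down can be enabled for
the all-pairs hemoglobin battery. With identical differences everywhere
the gate is undefined and the comparison is reported degenerate.

Under a normal null with n = 6 pairs the gated procedure's empirical
type-I error is ~0.047–0.049 (10,000 replicates): slightly conservative,
because the ~5 % of samples the gate routes to the exact Wilcoxon can only
reject at p = 0.03125 (probability 1/32).

## Synthetic dives

The generator emits a 10 Hz three-distance dual-wavelength intensity
recording built from:

- a piecewise-linear **heart-rate profile** (95 beats/min at the start,
  80 at the bottom, 77 at the end — the bradycardic dive response);
- an **arterial SaO₂ profile**: 99 % baseline, small compression rise to a
  98–100 % plateau during descent and bottom (lung compression raises
  alveolar PO₂), monotone linear decay during ascent to a configurable
  nadir (default 65 %), recovery after surfacing;
- a **tissue compartment**: total hemoglobin ~60 µmol/L with a 3 µmol/L
  descent rise, and a tissue-saturation trajectory around the 76 % TSI
  baseline (+2 points by the bottom, −3 by the end), lagged 5 s behind the
  arterial profile for lung-to-brain circulation time;
- a **cardiac sinusoid** at the instantaneous heart rate whose
  O₂Hb : HHb amplitude split equals SaO₂ : (100 − SaO₂) (amplitude
  0.6 µmol/L, a realistic cortical pulsation);
- Gaussian optical-density noise (5×10⁻⁴ OD per sample, a mid-range
  CW-NIRS noise floor) and optional short high-amplitude bursts during
  ascent standing in for involuntary breathing movements (a placeholder
  stressor, not a validated artifact morphology).

Two forward paths are combined deliberately. The slow tissue compartment
goes through the **SRS forward model** (attenuation slope across distances
computed from the true μ_a at the group-mean wavelengths), so the TSI
chain has an exact inverse: noise-free recovery error is at machine
precision. The cardiac pulsation goes through the **forward MBLL path**
per channel, so the pulsatile ratio method has an exact inverse too.
A single fully SRS-consistent forward model could not provide both oracles
at once — the square root linking slope to μ_a would distort the pulsatile
amplitude ratio wavelength-dependently — and splitting the paths keeps
each oracle clean while the distortion mode reintroduces a controlled
version of exactly that effect: "pathlength-drift" multiplies the
oxyhemoglobin pulsation in the optics by a slowly growing factor
(1.25 → 1.35), biasing conventional SpO₂ so that anchor calibration has a
real error to remove.

What passing the benchmark does **not** show about real data: the
simulator has no motion artifacts, no scattering changes, no superficial
(scalp) contamination, a sinusoidal rather than PPG-shaped pulse, perfectly
gain-matched channels, and an SaO₂-to-ratio link that is exact by
construction in the undistorted case. Recovery errors on real recordings
will be larger and the conventional SpO₂ will carry the pathlength bias
the distortion mode only sketches.

## Problem sizes and determinism

The benchmark runs ten simulated 42-m dives (~234 s each at 10 Hz, ~2,340
samples) per condition, a scale at which every recovery metric is stable
across seeds; the null simulation uses 10,000 replicates of n = 6 pairs.
All randomness flows through `numpy.random.default_rng` seeded from a
single integer, and a fixed seed reproduces recordings byte-for-byte.

## Known limitations

- Concentrations are relative; no absolute quantification, no scattering-
  change or motion-artifact correction beyond the cardiac-band filtering.
- The SRS chain assumes gain-matched channels; per-channel gain errors
  tilt the slope and bias TSI.
- Anchor calibration cannot fix saturation-dependent nonlinearity, only
  affine error.
- Dive events are inputs; there is no automatic dive detection from depth
  logs.
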