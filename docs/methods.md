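# Methods

This note documents the models, estimators and numerical choices behind
`acoustopiv`, and what the synthetic-data generator does and does not
emulate.

## Measurement model

The package analyses grayscale videos of micrometre-scale particles
suspended in a steady microchannel flow (syringe-pump driven, 0.0001–0.005
mL/min through a 0.40 mm-wide channel) while an acousto-mechanical
perturbation — a speaker-driven vibration coupled into the supply tubing —
superposes a periodic velocity modulation. The stimulation follows an
ON–OFF scheme (default 1 s ON / 1 s OFF repeated for 60 s), so the
modulation period is 2 s and its fundamental is 0.5 Hz. The drive tone is a
musical pitch; the two presets are G♯0 (25.96 Hz) and G♯4 (415.30 Hz) in
equal temperament (f = 440·2^(s/12) Hz, s semitones from A4). Imaging is
modelled on a CCD at 57 FPS with 7.4 µm sensor pixels behind a 10×
objective, giving a 0.74 µm object-plane pitch and a 28.5 Hz Nyquist limit
for velocity spectra; analysis uses a 180 × 140 px region of interest with
x the flow-parallel image axis.

## DPIV estimator

Displacements between consecutive frames are estimated per interrogation
window by circular cross-correlation of the mean-subtracted patches,
computed with forward/inverse real FFTs; the correlation plane is shifted
so zero lag sits at the centre. The integer peak is refined per axis with
the three-point Gaussian estimator
δ = (ln c₋ − ln c₊) / (2 ln c₋ − 4 ln c₀ + 2 ln c₊),
which is exact for a sampled Gaussian peak; when any of the three samples
is non-positive the parabolic fit is used instead, and δ is clipped to
[−1, 1]. Peaks on the plane border and zero-variance windows mark the
vector invalid.

The multi-pass ladder defaults to three window sizes, 64 → 32 → 16 px at
50 % overlap. Each pass after the first offsets the second frame's windows
by the rounded displacement bilinearly interpolated from the previous
validated pass (clamped to keep windows inside the frame), so the residual
displacement seen by each correlation is small compared to the window and
the circular (non-zero-padded) correlation dialect is harmless. Outliers
are rejected by the normalized median test on the 8-neighborhood
(residual = |v − median| / (MAD + ε), ε = 0.1 px, threshold 2.0, per
component) and replaced by the local mean of valid neighbors — always
internally for predictor stability, and in the returned field unless
`replace_invalid` is disabled. Grids smaller than 3 × 3 skip validation
with a warning. The batched path computes in float32 (the ~1e-7 relative
FFT error is orders of magnitude below the sub-pixel estimator noise); the
public single-pair `cross_correlate` is float64 and matches a brute-force
spatial-domain correlation to better than 1e-8.

Calibration: v[mm/s] = d[px/frame-pair] · (sensor pixel / magnification)
·10⁻³ [mm/px] · frame rate [1/s]; 1 px/frame at the default calibration is
0.04218 mm/s. Consecutive-pair correlation gives a velocity sample rate of
57 Hz, hence usable spectra to 28.5 Hz. The interpretation of a
"three-step" scheme as a window-refinement ladder is a design choice; a
fixed-size multi-pass variant can be configured via `pass_window_sizes`.

## Response metrics

For each record the valid vectors are averaged per frame pair to V̄ₓ(t) and
V̄ᵧ(t) (frame pairs with no valid vector are linearly interpolated, never
dropped, to preserve uniform sampling). Metrics:

* **velocity range** r = max V̄ᵢ(t) − min V̄ᵢ(t), in mm/s;
* **amplitude spectrum**: mean removed, one-sided |DFT|·2/N (Nyquist bin of
  an even-length record ·1/N), rectangular window by default — the default
  60 s record holds an integer number of 2 s protocol periods so the
  0.5 Hz line is essentially leak-free; a Hann taper is available for
  other protocols. The DC bin is reported as zero: without mean removal
  the steady-flow term would trivially dominate any "maximum peak" search;
* **dominant peak** fₚ: the largest non-DC amplitude in a band (default
  0–2 Hz), ties toward the lower frequency;
* **band integrals** A[f₁, f₂): sums of bin amplitudes over half-open
  bands, so the touching presets 18–23 and 23–28 Hz are exactly additive;
  presets 10–15, 18–23, 23–28 Hz. The 10–28 Hz window is additionally
  summarised by its strongest line, the median in-band amplitude (a noise
  floor), and the amplitude at the longitudinal line's bin — the latter
  lets a transverse spectrum be tested for a co-located stimulus line;
* **replicates**: mean ± SEM with SEM = s/√n, sample standard deviation
  (ddof = 1), n = 3 by default.

Spectral amplitudes are reported in mm/s per bin; this normalization is a
package convention (any fixed rescaling would serve comparison purposes
equally), so fₚ values are comparable within and across `acoustopiv` runs
but not to data reduced with an unknown normalization.

Calibration traces (flow-sensor time series under the same protocol) are
summarised by phase-conditioned means (mean_on, mean_off), their
difference (modulation amplitude), and a residual offset: the mean over
the final 20 % of each OFF phase minus a reference level (a supplied
baseline, else the first OFF-phase tail), which quantifies incomplete
relaxation between pulses.

## Synthetic-data generator

The generator stands in for experimental recordings and defines the
conditions under which the pipeline is validated. Particles advance per
frame by v(t)·Δt with

* longitudinal: v_base·profile(y) + env(t)·G·(κₓ + Σⱼ aⱼ sin 2πfⱼt),
* transverse: env(t)·G·κ_y·Σⱼ aⱼ sin 2πfⱼt,
* plus isotropic Gaussian jitter (0.05 px/frame) on both axes,

where v_base = Q/(width·depth) converts the pump flow rate to a transport
speed (the channel depth is not part of the imaging geometry; a square
0.40 × 0.40 mm cross-section is assumed, which keeps simulated speeds in
the 0.01–0.5 mm/s regime of interest), profile(y) is a Poiseuille parabola
across the channel width normalized to 1 at the centerline (nearly flat
across the thin ROI), and env(t) is the stimulus envelope: a 0.3 s linear
ramp after each ON onset and a 0.3 s-τ exponential decay after OFF,
reproducing the delayed onset and gradual relaxation seen in stimulated
recordings. G = (Q/Q_ref)^α_flow · (f_tone/f_ref)^α_tone is the coupling
gain relative to the reference condition (Q_ref = 10⁻⁴ mL/min, f_ref =
25.96 Hz).

The drive tones (25.96 / 415.30 Hz) both lie at or beyond the 28.5 Hz
Nyquist limit of a 57 FPS camera, so the generator injects the acoustic
signature directly as in-band spectral lines (defaults at 12.5, 20.5 and
25.5 Hz — one line per analysis band) rather than modelling aliasing
physics; only in-band content is analysed downstream.

Preset couplings encode the rigid-vs-compliant contrast the pipeline must
resolve and were fixed once to land the metrics in a realistic regime
(absolute perturbation amplitudes of the physical system are not known, so
only orders of magnitude and trends are meaningful):

* **silica beads** (r = 3 µm, ρ = 1200 kg/m³): κₓ = 0.12 mm/s, hf lines
  (0.020, 0.015, 0.012) mm/s, α_flow = α_tone = 0, κ_y = 0 — a stable
  longitudinal response (r ≈ 0.17 mm/s) independent of flow rate and
  octave, with no transverse response;
* **yeast cells** (r = 2.5 µm, ρ = 1126 kg/m³): κₓ = 0.022 mm/s, hf lines
  (0.006, 0.005, 0.004) mm/s, α_flow = 0.5, α_tone = 0.3, κ_y = 0.6 — a
  response growing with flow rate and drive octave, with a transverse
  oscillatory component (r from ≈0.04 mm/s at the reference condition to
  ≈0.5 mm/s at 0.005 mL/min under the high octave).

Rendering: each particle is an isotropic Gaussian spot (σ = 1.2 px,
amplitude 110) on a background of 20 grey levels with additive read noise
(σ = 2), quantized to 8 bits. Seeding targets 80 particles per ROI — image
density, not physical concentration, is what matters for DPIV; with the
spot halo this yields ≈2.5 effective particles per final 16 px window, so
only a few percent of windows are empty (and are caught by validation).
Particles leaving the ROI wrap to the opposite edge, conserving density.
All randomness in a run flows from one seed; identical condition + seed
reproduce trajectories, frames and sensor traces bit-for-bit.

The flow-sensor emulator drives a first-order kinetic g(t) toward 1 while
ON (τ_rise = 0.1 s) and decays it with a configurable relaxation τ while
OFF; a relaxation slower than the OFF window leaves the trace above
baseline between pulses, and an explicit slowly-accumulating offset models
persistent excitation — emulating the qualitative difference between lowand
high-octave calibration behaviour.

**What the generator does not emulate**: acoustofluidic radiation forces
and standing waves, 3-D motion, sedimentation and rolling, depth-of-field
blur and illumination drift, out-of-plane loss of particles, aliasing of
the physical drive tone, and non-Gaussian sensor noise. Passing tests
therefore demonstrate that the estimator chain recovers known kinematics
and spectral structure from realistic images — not that any specific
biophysical coupling model is correct.

## Problem sizes and campaign plan

The full campaign preset pairs each particle × flow-rate combination
(beads at 0.0001/0.001 mL/min, yeast also at 0.005 mL/min) with a control
and the two drive octaves, three replicates each, with distinct derived
seeds. Trend validation runs this campaign at a reduced 20 s per record
(1140 frames; spectral resolution 0.05 Hz, ample for 0.5 Hz and in-band
line detection), which the package adopts as its standard desk-scale
configuration; the protocol-fundamental check uses the full 60 s record
(3420 frames, resolution 1/60 Hz). A 60 s record processes in under a
minute on one CPU at ~11 ms per frame pair.

## Degenerate inputs and edge conventions

Boundary instants of the ON–OFF schedule belong to the phase they open
(half-open intervals); the recording is assumed to start synchronized with
an ON onset — the schedule convention places t = 0 at a stimulus onset,
and the generator follows it. Zero-variance interrogation windows and
border correlation peaks yield masked vectors excluded from spatial means;
an all-invalid field raises rather than silently returning zeros. Traces
shorter than 16 samples refuse a spectrum; calibration requires at least
three full protocol periods. NO-AMP conditions are represented as a null
protocol; metrics still compute the 0–2 Hz peak so the absence of the
0.5 Hz line in controls is an assertable contrast (the stimulated peak
must exceed 5× the control amplitude at the same bin).

## Known limitations

* The transverse sign convention follows image coordinates (y down);
  transverse metrics use magnitudes and spectra, so the sign is
  immaterial.
* Circular correlation without window deformation limits accuracy for
  strong in-window shear; the generator's fields are nearly uniform per
  window, and real strongly-sheared flows would warrant a deformation
  scheme out of scope here.
* Ensemble correlation, particle tracking (PTV), 3-D/stereo PIV and GPU
  execution are out of scope.
* Absolute spectral amplitudes depend on the package's normalization
  convention (see above) and on the generator's free coupling amplitudes;
  only trends and frequencies are meant to transfer to other data.
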