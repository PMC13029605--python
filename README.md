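# acoustopiv

**DPIV analysis of acousto-mechanically perturbed microchannel particle flows.**

`acoustopiv` is a Python toolkit for quantifying how suspended
micro-particles (rigid silica beads vs. compliant yeast cells) respond when
a steady microchannel flow is perturbed by an acoustic drive gated by a
periodic ON–OFF protocol. It is aimed at microfluidics and acoustofluidics
researchers who record particle videos through a microscope and want a
reproducible video → velocity → metrics chain:

1. **DPIV** (`acoustopiv.dpiv`) — velocity-field extraction from grayscale
   frame stacks by three-pass FFT cross-correlation over shrinking
   interrogation windows (64 → 32 → 16 px, 50 % overlap), three-point
   Gaussian sub-pixel peak fitting, normalized-median vector validation,
   and calibration to mm/s.
2. **Metrics** (`acoustopiv.metrics`) — spatially averaged velocity traces
   V̄ₓ(t), V̄ᵧ(t); the velocity range r = max V̄ᵢ(t) − min V̄ᵢ(t); the
   one-sided amplitude spectrum V̄ᵢ(f) with its dominant non-DC peak
   fₚ = max V̄ᵢ(f) in 0–2 Hz; band integrals A[f₁,f₂) = Σ V̄ₓ(f) over
   10–15, 18–23 and 23–28 Hz; replicate aggregation as mean ± SEM
   (SEM = s/√n, n = 3); and ON/OFF calibration metrics for flow-sensor
   traces.
3. **Protocol** (`acoustopiv.protocol`) — the 1 s ON / 1 s OFF stimulation
   schedule (0.5 Hz fundamental) and equal-temperament drive tones
   (presets G♯0 = 25.96 Hz and G♯4 = 415.30 Hz).
4. **Synthetic data** (`acoustopiv.synthdata`) — a particle-video generator
   (57 FPS, 0.74 µm/px object-plane pitch, 180 × 140 px ROI) that renders
   bead-like and yeast-like populations with known ground-truth velocities,
   so the whole chain is testable without experimental recordings.
5. **Pipeline & CLI** (`acoustopiv.pipeline`, `acoustopiv` console script) —
   campaign plans (particle × flow rate × stimulation mode × replicates),
   tidy results tables, manifests, and mean ± SEM reports.

## Worked example

```python
import acoustopiv as ap

# a yeast-cell run: 0.001 mL/min steady flow, G#0 drive, 1 s ON / 1 s OFF, 20 s
cond = ap.ExperimentCondition(ap.yeast_cells(), 1e-3, ap.amp_low_protocol(20.0))
traj = ap.simulate_trajectories(cond, seed=0, duration=20.0)
seq = ap.render_frames(traj, seed=1)              # 1140-frame 8-bit stack
series = ap.piv_stack(seq)                        # 3-pass DPIV, mm/s fields
tx, ty = ap.spatial_mean(series)                  # V̄x(t), V̄y(t)
spec = ap.amplitude_spectrum(tx)
amp, freq = ap.dominant_peak(spec, (0.0, 2.0))
print(f"r = {ap.velocity_range(tx):.4f} mm/s, peak {amp:.4f} mm/s @ {freq:.3f} Hz")
print(f"A[10,15) = {ap.band_integral(spec, 10, 15):.4f} mm/s")
```

prints (exact values depend on the seed):

```
r = 0.1175 mm/s, peak 0.0362 mm/s @ 0.500 Hz
A[10,15) = 0.0537 mm/s
```

i.e. the spatially averaged longitudinal velocity swings over ≈0.12 mm/s,
its spectrum is dominated by the 0.5 Hz line imposed by the 2 s ON–OFF
protocol period, and the 10–15 Hz band integral picks up the in-band
acoustic signature. The same run without
stimulation (`protocol=None`) shows no 0.5 Hz line.

From the shell:

```bash
acoustopiv simulate --particle yeast --flow-rate 1e-3 --preset amp-low \
    --duration 20 --seed 0 --out run/
acoustopiv piv --stack run/stack.tif --out run/fields.csv
acoustopiv metrics --fields run/fields.csv
acoustopiv run-plan --duration 20 --replicates 3 --seed 1 --out campaign/
acoustopiv report --results campaign/results.csv
```

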