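# retinakit

Analysis tools for retinal electrophysiology: spike-triggered-average
(STA) receptive-field estimation and ON/OFF ganglion-cell classification
from checkerboard-stimulus multi-electrode recordings, plus
electroretinogram (ERG) a-/b-wave quantification — together with
synthetic-data generators that provide ground truth for every stage.

It is written for experimenters who have sorted ganglion-cell spike
trains recorded under binary checkerboard white noise (and/or in-vivo
ERG traces) and want a tested, reproducible pipeline from raw spike
tables to population-level statistics, and for methodologists who want
a controllable LN-Poisson test bed for reverse-correlation analyses.

## The methods in brief

**Receptive fields.** Under a binary white-noise checkerboard
(100 µm checkers, 60 frames/s), the mean stimulus preceding spikes
estimates the cell's linear spatiotemporal receptive field:

```
STA(k) = (1/N) Σ_i  s(t_i − k·Δt),     k = 1 … 18,  Δt = 16.67 ms
```

i.e. an 18-frame volume spanning 300 ms before each spike. The pixel of
maximal |deviation| locates the receptive-field center, refined by an
axis-aligned 2D Gaussian least-squares fit; a field is *valid* when its
peak stands ≥ 4 noise SDs (estimated from the longest, pre-response
lags) above the floor and the Gaussian fit converged to a resolvable
width. The center-pixel lag series (temporal profile), interpolated by a
cubic spline on a 1 ms grid, yields the time-to-peak latency and
time-to-zero-cross; the sign of the profile at its peak gives ON (+) or
OFF (−) identity, and PCA + k-means on the unit-normalized profiles
yields functional subgroups.

**LN-Poisson generator.** Synthetic cells drive spikes through a
separable filter (isotropic spatial Gaussian × biphasic
difference-of-gamma temporal kernel with an exact, configurable peak
latency), a rectified-linear rate `r(t) = max(0, b + g·x(t))`, and
per-frame Bernoulli spiking with `p = r·Δt`. A "blocker" condition
emulates connexin-channel blockade: longer latencies, ~0.53× firing.

**ERG.** Traces carry an early negative a-wave (photoreceptors) and a
later positive b-wave (ON bipolar cells). Amplitudes are measured
against the averaged 100 ms pre-stimulus baseline, each extremum refined
by a local 5th-order polynomial least-squares fit (±25 ms). The
generator produces parametric traces whose control b-amplitude follows a
Naka–Rushton intensity–response curve, `R(I) = Rmax·Iⁿ/(Iⁿ + σⁿ)`,
calibrated per species/adaptation state, with 1–100 Hz band-limited
noise and recorded ground truth.

## Worked example

```python
from retinakit import (make_checkerboard, GroundTruthCell, simulate_ln_cell,
                       compute_sta, fit_rf, extract_profile, spline_refine,
                       simulate_erg, measure_waves, relative_change)

stim = make_checkerboard(seed=1, frames=36_000)          # 10 min at 60 fps
cell = GroundTruthCell(cell_id="rgc0", polarity=-1,       # an OFF cell
                       spatial_center=(9.3, 7.7), peak_latency_ms=48.6,
                       base_rate_hz=6.2)
train = simulate_ln_cell(cell, stim, seed=7)
sta = compute_sta(stim, train)                            # 18 lags / 300 ms
fit = fit_rf(sta)
profile = spline_refine(extract_profile(sta, fit))
print(f"{train.n_spikes} spikes -> STA {sta.values.shape}, "
      f"valid RF: {fit.valid} (z = {fit.peak_z:.1f})")
print(f"RF center ({fit.gauss.center[0]:.2f}, {fit.gauss.center[1]:.2f}) "
      f"checkers, sigma {fit.gauss.sigmas[0]:.2f}")
print(f"{'ON' if profile.polarity > 0 else 'OFF'} cell, "
      f"time-to-peak {profile.time_to_peak_ms:.1f} ms")

ctrl = measure_waves(simulate_erg(1.82, "control", "rat_scotopic", seed=2))
blk = measure_waves(simulate_erg(1.82, "blocker", "rat_scotopic", seed=3))
print(f"b-wave {ctrl.b_amp_uv:.1f} -> {blk.b_amp_uv:.1f} uV "
      f"({relative_change(blk.b_amp_uv, ctrl.b_amp_uv):+.1f} %)")
```

prints

```
4023 spikes -> STA (18, 19, 19), valid RF: True (z = 14.9)
RF center (9.27, 7.74) checkers, sigma 1.15
OFF cell, time-to-peak 47.7 ms
b-wave 569.1 -> 281.5 uV (-50.5 %)
```

The simulated OFF cell's receptive-field center (truth: 9.3, 7.7
checkers) and latency (truth: 48.6 ms) are recovered from its spikes
alone; the ERG pair shows the blocker's b-wave suppression recovered
from the measured amplitudes.

A complete run — simulate control + blocker populations, fit all
receptive fields, classify, summarize latencies, and measure an ERG
intensity–response grid — is one call (or `retinakit demo` on the
command line):

```python
from retinakit import PipelineConfig, run_pipeline
run_pipeline(PipelineConfig(seed=0, n_on=4, n_off=16), "artifacts/")
```

It writes spike tables, RF-fit/profile/cluster tables, intensity-response
tables, a text report, and a `summary.json` embedding the resolved
configuration; reruns are byte-identical.

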