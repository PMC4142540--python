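# Methods

## Scope and model

retinakit implements a reverse-correlation pipeline for retinal ganglion
cells (GCs) recorded under binary checkerboard white noise, an ERG
a-/b-wave quantification, and population statistics comparing a control
condition with a connexin-blocker-like ("blocker") condition. Because
such studies rarely deposit raw recordings, the package includes
generators that produce all inputs synthetically with known ground
truth; every analysis stage is validated by parameter recovery against
that truth.

## Stimulus and spike model

The stimulus is an i.i.d. binary checkerboard: each checker (100 µm,
default 19×19 grid) is −1 or +1 with probability ½ on every frame
(60 frames/s, 16.67 ms frame interval). The default grid is a desk-scale
stand-in for a full projector image; positions are handled in checker
units throughout, with micrometers kept as metadata only, because the
mapping from projector pixels to retinal micrometers is
hardware-specific.

Synthetic GCs are linear–nonlinear–Poisson (LN-Poisson): the drive at
frame *t* is the stimulus filtered by a separable receptive field
(isotropic spatial Gaussian, peak weight 1, default σ = 1.2 checkers ≈
a 240 µm-diameter center; biphasic temporal kernel over lags 1–18), the
rate is the rectified-linear `r = max(0, base + gain·drive)` (an
exponential nonlinearity is available), and at most one spike per frame
is drawn with probability `r·Δt` (capped at 0.95), placed uniformly
within the frame. Per-frame Bernoulli generation matches the
frame-resolution analysis and makes the zero-gain case an (excellent)
binomial approximation of a homogeneous Poisson process, which the test
suite verifies by a dispersion test.

The temporal kernel is a difference of two gamma bumps with an exact,
configurable dominant-extremum latency. Two deliberate choices:

* the time axis is rescaled after construction so the *combined*
  extremum lands exactly on the requested latency (the raw difference
  peaks slightly off the primary bump because the opposite lobe is
  already rising), keeping ground-truth latency exact;
* the gamma order grows with latency so the primary lobe keeps a
  roughly constant Gaussian-equivalent width (default 25 ms) at any
  latency. Slowing a cell therefore translates its peak rather than
  dilating it, which matches how measured GC temporal filters behave;
  a purely time-rescaled kernel becomes so flat at ~100 ms latencies
  that frame-grid sampling makes spline latency estimates jitter by
  many milliseconds.

Population defaults: ON:OFF mix 20:80; control latencies
N(67.36, 12.06²) ms ON and N(48.60, 8.13²) ms OFF; blocker latencies
N(94.9, 19.3²) and N(61.5, 12.1²); control base rates 8.2 (ON) and
6.2 Hz (OFF) with gain 2.0, blocker rates scaled by ~0.53 — all taken
from the population statistics of diurnal-rodent recordings this
package is modeled on.

## STA and receptive-field validity

The STA volume averages the 18 stimulus frames (300 ms) preceding each
spike, assigning spikes to frames by `floor(t·fps)` and excluding spikes
with incomplete history. The theoretical stimulus mean (0) is
subtracted rather than the empirical mean — bias-free for the ±1
checkerboard and exactly linear under spike-train merging. The
window/lag count is configurable; 18 frames is the default because
300 ms comfortably spans GC integration times at 60 fps.

The receptive-field center is the coordinate of maximal |value| (ties:
earliest lag, then row-major), refined by an axis-aligned 2D Gaussian
(amplitude, center, two sigmas, offset) fit by `scipy.optimize.curve_fit`
initialized at the peak. Rotation is omitted: centers, not ellipse
orientations, are the quantity of interest downstream.

Validity rule (all parts must hold):

* peak z ≥ 4 (inclusive), with noise SD estimated from the pixel values
  of the two longest-lag frames (which precede temporal integration and
  contain only sampling noise);
* the Gaussian fit converged, with both sigmas in [0.65, grid/2]
  checkers, a center within 2 checkers of the peak pixel, and a fitted
  amplitude matching the peak's sign and reaching at least half its
  magnitude.

The 0.65-checker sigma floor encodes a physical requirement: a
receptive-field center narrower than a single 100 µm stimulus bin
cannot be resolved by this stimulus and is indistinguishable from a
one-pixel noise fluctuation. Without it (and the amplitude-consistency
check), maxima over the ~6500-pixel volume let single-pixel noise blobs
through at a measured ~7.5% rate on stimulus-independent cells; with
them the measured false-positive rate is 0/200 while strong cells
(z ≳ 15 at ~6000 spikes) and ~0.53-rate blocker cells still validate.

## Temporal profiles and classification

The temporal profile is the STA at the rounded fitted center, one value
per lag. A cubic interpolating spline evaluated on a 1 ms grid (always
including the knots, so sample-aligned peaks are preserved exactly)
refines time-to-peak — reported as positive ms before the spike — and
the zero crossing searched from the peak toward the spike and refined by
root bracketing; profiles that never cross report NaN and are excluded
from crossing-based summaries. Fewer than 4 samples fall back to the
frame-resolution peak with a warning flag.

Classification standardizes each profile to unit L2 norm — so
clustering reflects waveform shape, polarity and latency rather than
response strength, and is invariant to positive rescaling — projects
onto the leading principal components explaining ≥ 90% of variance
(capped at 5), and partitions with k-means (k = 5 by default for the
five functional groups typically reported, 20 restarts, fixed seed).
Per-lag z-scoring was rejected: it inflates the noise-dominated tail
lags and measurably degrades recovery of latency-defined groups. ON/OFF
identity is decided by each profile's own extremum sign, independent of
cluster membership; clusters are descriptive subtypes.

## ERG generation and measurement

Synthetic traces are a flat baseline plus an inverted-Gaussian a-wave
(scotopic: trough 20 ms, σ 6 ms; photopic: 15/5 ms) and a Gaussian
b-wave (70/20 ms scotopic, 50/15 ms photopic), sampled at 1 kHz from
−100 to 350 ms around onset. The control b-amplitude follows a
Naka–Rushton curve solved exactly through three calibration anchors per
species/adaptation profile; the blocker condition scales the b-wave
(default: the profile's treated/control ratio at the top anchor
intensity — above 1 for the light-adapted degu profile, where blockade
*increases* the b-wave) and leaves the photoreceptor-driven a-wave
unchanged. Noise is white Gaussian band-passed 1–100 Hz (the recording
band), normalized to the requested SD (default 5 µV). Ground-truth
amplitudes/times are measured on the noiseless trace.

Measurement: baseline = mean over the 100 ms pre-onset window; the
a-wave is the earliest post-onset local minimum below baseline by more
than ~2.5 pre-onset SDs, the b-wave the subsequent maximum; a lightly
smoothed copy (Savitzky–Golay, 21 ms) is used only to localize extrema
on noisy traces, and amplitudes come from the extremum of a 5th-order
polynomial least-squares fit to the raw samples within ±25 ms
(clipped windows are flagged). The ±25 ms window spans the peak without
swallowing the adjacent wave; amplitudes are baseline-to-extremum.
Oscillatory potentials are neither generated nor removed.

A measured property worth knowing: with 1–100 Hz band-limited trace
noise at SD 5 µV, the single-sweep b-amplitude estimate is unbiased with
an error floor of ≈ 3.1 µV MAE (600-seed measurement). The floor is set
by noise components inside the b-wave's own frequency band, which no
local polynomial fit (nor Savitzky–Golay prefiltering, wider or
asymmetric windows, or prewhitened least squares — all evaluated) can
average away; only whiter noise or sweep averaging reduces it. The
refinement still clearly beats the raw-sample argmax (≈ 4.8 µV MAE,
positively biased).

## Population statistics

Welch's t-test is implemented from summary statistics (mean, SD, n)
with Welch–Satterthwaite degrees of freedom; the raw-sample path
computes the summaries and calls the same code, so the two agree
exactly. Paired t-tests handle zero-variance differences explicitly
(identical vectors: t = 0, p = 1; constant shift: t = ±∞ with p
reported as 0 by convention). Latency increments are treated − control
in ms and percent of control; tables round half-away-from-zero to one
decimal. Latency summaries report both SD and s.e.m., since published
tables are often ambiguous about which follows the ± sign. Reports are
rendered deterministically (no timestamps); reruns are byte-identical.

## Validation studies and problem sizes

The experiments module fixes the study designs used for validation: a
balanced 20-cell LN population (60-minute recordings, ~24k spikes per
cell) for center/polarity recovery and for paired +30 ms (ON-like) /
+13 ms (OFF-like) latency-shift recovery (the single-pixel profile's
sampling noise makes per-cell latency jitter ~3 ms at 6k spikes, so
shorter runs cannot resolve a population-mean shift to the millisecond); 40 stimulus-independent cells
(200 s each) for the validity rule's false-positive rate; five latency
groups (40/55/70/90/110 ms, SD 3 ms, 40 cells each, mixed polarities)
for clustering recovery; and 120 noise seeds for ERG amplitude error.
These sizes give population-mean latency precision well under 1 ms and
binomial precision of a few percent on the rate estimates while keeping
any study under a minute on one core.

## Limitations

* The generators emulate stationary LN-Poisson cells with isotropic
  Gaussian centers and no surround, no refractoriness, no adaptation,
  and no correlations between cells; passing recovery tests demonstrates
  the pipeline's correctness, not that real retinas satisfy these
  assumptions.
* ERG components are stylized Gaussians without oscillatory potentials
  or PII/PIII decomposition; intensity labels are opaque (no photon-flux
  calibration).
* Spike sorting is out of scope: the pipeline consumes sorted spike
  tables (vendor exports must be converted to the two-column text
  format first).
* The spatial analysis stops at center localization; no mosaic/tiling
  or surround fitting.
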