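"""Synthetic retinal data with known ground truth.

Three generators cover the data types the analysis stages consume:

* binary checkerboard stimulus movies (reverse-correlation input),
* linear-nonlinear-Poisson (LN-Poisson) ganglion cells driven by those
  movies, producing spike trains whose receptive fields and latencies are
  known by construction,
* parametric electroretinogram (ERG) traces with an a-wave trough and a
  b-wave peak whose true amplitudes are recorded alongside the trace.

All generators are deterministic given their seed. A "blocker" condition
emulates the phenomenology of broad connexin-channel blockade: longer
temporal-filter latencies, suppressed firing, and a scaled ERG b-wave.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .errors import CalibrationError, ParameterError

__all__ = [
    "StimulusMovie",
    "GroundTruthCell",
    "SpikeTrain",
    "ERGTrace",
    "ERGGroundTruth",
    "make_checkerboard",
    "biphasic_kernel",
    "simulate_ln_cell",
    "make_population",
    "simulate_erg",
    "naka_rushton",
    "calibrate_intensity_response",
    "LATENCY_DEFAULTS",
    "RATE_DEFAULTS",
    "ERG_CALIBRATION_POINTS",
    "ERG_BLOCKER_SCALE",
    "ERG_WAVE_SHAPES",
]


# ---------------------------------------------------------------------------
# stimulus
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusMovie:
    """Frame-indexed binary contrast movie.

    ``values`` has shape (frames, rows, cols) with entries in {-1, +1};
    checkers are 100 um squares updated at 60 frames/s by default.
    """

    values: np.ndarray
    frame_rate_hz: float = 60.0
    checker_size_um: float = 100.0
    seed: int | None = None

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def grid_rows(self) -> int:
        return self.values.shape[1]

    @property
    def grid_cols(self) -> int:
        return self.values.shape[2]

    @property
    def frame_interval_ms(self) -> float:
        return 1000.0 / self.frame_rate_hz

    @property
    def dt_s(self) -> float:
        return 1.0 / self.frame_rate_hz

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz


def make_checkerboard(
    seed: int,
    frames: int,
    grid_rows: int = 19,
    grid_cols: int = 19,
    frame_rate_hz: float = 60.0,
    checker_size_um: float = 100.0,
) -> StimulusMovie:
    """Draw an i.i.d. binary checkerboard movie, each checker equiprobably
    -1 or +1 on every frame. Bit-exactly regenerable from (seed, dims)."""
    if frames < 1 or grid_rows < 1 or grid_cols < 1:
        raise ParameterError("frames and grid dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    values = rng.integers(0, 2, size=(frames, grid_rows, grid_cols), dtype=np.int8)
    values = (2 * values - 1).astype(np.int8)
    return StimulusMovie(values=values, frame_rate_hz=frame_rate_hz,
                         checker_size_um=checker_size_um, seed=seed)


# ---------------------------------------------------------------------------
# LN-Poisson ganglion cells
# ---------------------------------------------------------------------------

def _gamma_bump(t_ms: np.ndarray, peak_ms: float, order: float) -> np.ndarray:
    """Gamma-like bump (t/peak)^n exp(n (1 - t/peak)): peaks at ``peak_ms``
    with value 1, zero for t <= 0."""
    x = np.asarray(t_ms, dtype=float) / peak_ms
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = x[pos] ** order * np.exp(order * (1.0 - x[pos]))
    return out


def biphasic_kernel(
    t_ms,
    peak_latency_ms: float,
    undershoot: float = 0.3,
    undershoot_delay: float = 1.7,
    peak_width_ms: float = 25.0,
) -> np.ndarray:
    """Difference-of-gamma temporal filter, normalized so its dominant
    (positive) extremum is exactly 1 at exactly ``peak_latency_ms``.

    The gamma order is chosen so the primary lobe keeps a roughly constant
    Gaussian-equivalent width (``peak_width_ms``) regardless of latency:
    slowing a cell translates its peak instead of dilating it, which is
    how measured ganglion-cell temporal filters behave. The raw difference
    of two gamma bumps peaks slightly off the nominal primary-bump latency
    because the opposite-sign lobe is already rising; the time axis is
    rescaled so the combined extremum lands exactly on the requested
    latency.
    """
    if peak_latency_ms <= 0:
        raise ParameterError("peak_latency_ms must be positive")
    order = float(np.clip((peak_latency_ms / peak_width_ms) ** 2, 2.0, 40.0))

    def raw(s):
        return (_gamma_bump(s, peak_latency_ms, order)
                - undershoot * _gamma_bump(s, undershoot_delay * peak_latency_ms, order))

    fine = np.linspace(0.4 * peak_latency_ms, 1.6 * peak_latency_ms, 2401)
    t_star = fine[np.argmax(raw(fine))]
    scale = t_star / peak_latency_ms
    peak_val = float(raw(np.array([t_star]))[0])
    return raw(np.asarray(t_ms, dtype=float) * scale) / peak_val


@dataclass
class GroundTruthCell:
    """Parameters of one synthetic LN-Poisson ganglion cell.

    polarity +1 = ON (positive filter peak), -1 = OFF. The separable
    receptive field is an isotropic spatial Gaussian (peak weight 1) times
    a biphasic temporal kernel whose dominant extremum sits at
    ``peak_latency_ms`` before the spike.
    """

    cell_id: str
    polarity: int
    spatial_center: tuple[float, float]
    spatial_sigma: float = 1.2
    peak_latency_ms: float = 60.0
    base_rate_hz: float = 8.0
    gain: float = 2.0
    condition: str = "control"
    undershoot: float = 0.3
    undershoot_delay: float = 1.7

    def __post_init__(self):
        if self.polarity not in (-1, 1):
            raise ParameterError("polarity must be +1 (ON) or -1 (OFF)")
        if self.peak_latency_ms <= 0:
            raise ParameterError("peak_latency_ms must be positive")

    def temporal_kernel(self, lag_times_ms) -> np.ndarray:
        """Filter weight per pre-spike lag; sign of the dominant extremum
        equals ``polarity``."""
        k = biphasic_kernel(lag_times_ms, self.peak_latency_ms,
                            undershoot=self.undershoot,
                            undershoot_delay=self.undershoot_delay)
        return self.polarity * k

    def spatial_kernel(self, grid_rows: int, grid_cols: int) -> np.ndarray:
        rr, cc = np.mgrid[0:grid_rows, 0:grid_cols]
        r0, c0 = self.spatial_center
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        return np.exp(-d2 / (2.0 * self.spatial_sigma ** 2))


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times (seconds) of one unit."""

    cell_id: str
    spike_times_s: np.ndarray
    recording_duration_s: float

    def __post_init__(self):
        t = np.asarray(self.spike_times_s, dtype=float)
        object.__setattr__(self, "spike_times_s", t)
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0
                       or t[-1] > self.recording_duration_s):
            raise ParameterError(
                f"{self.cell_id}: spike times must be strictly increasing "
                "within [0, recording_duration_s]")

    @property
    def n_spikes(self) -> int:
        return self.spike_times_s.size


def _stimulus_projection(stim: StimulusMovie, weights: np.ndarray,
                         block: int = 8192) -> np.ndarray:
    """Per-frame inner product of the movie with a spatial weight map,
    chunked to keep the float temporary small."""
    w = weights.ravel().astype(np.float32)
    flat = stim.values.reshape(stim.n_frames, -1)
    out = np.empty(stim.n_frames, dtype=np.float64)
    for start in range(0, stim.n_frames, block):
        stop = min(start + block, stim.n_frames)
        out[start:stop] = flat[start:stop].astype(np.float32) @ w
    return out


def simulate_ln_cell(
    cell: GroundTruthCell,
    stim: StimulusMovie,
    seed: int,
    n_kernel_lags: int = 18,
    nonlinearity: str = "relu",
    max_spike_prob: float = 0.95,
) -> SpikeTrain:
    """Simulate an LN-Poisson cell driven by a checkerboard movie.

    The drive at frame t is sum_{k=1..K} w_k * s_{t-k} where s is the
    spatial projection of the movie and w the temporal kernel sampled at
    lags k * frame interval. The firing rate is ``max(0, base + gain*drive)``
    (or ``base * exp(gain*drive)`` with nonlinearity="exp") and at most one
    spike is drawn per frame with probability rate * dt (capped below 1),
    placed uniformly within the frame.
    """
    if stim.n_frames < 1 or stim.duration_s <= 0:
        raise ParameterError("stimulus must have positive duration")
    if n_kernel_lags < 1 or n_kernel_lags > stim.n_frames:
        raise ParameterError("n_kernel_lags must be in [1, n_frames]")
    lag_times_ms = np.arange(1, n_kernel_lags + 1) * stim.frame_interval_ms
    if cell.peak_latency_ms > lag_times_ms[-1]:
        raise ParameterError(
            f"{cell.cell_id}: peak latency {cell.peak_latency_ms:.1f} ms "
            f"exceeds the {lag_times_ms[-1]:.1f} ms kernel window")

    w = cell.temporal_kernel(lag_times_ms)
    s = _stimulus_projection(stim, cell.spatial_kernel(stim.grid_rows, stim.grid_cols))
    full = np.convolve(s, w)
    drive = np.zeros(stim.n_frames)
    drive[1:] = full[: stim.n_frames - 1]

    if nonlinearity == "relu":
        rate = np.maximum(0.0, cell.base_rate_hz + cell.gain * drive)
    elif nonlinearity == "exp":
        rate = cell.base_rate_hz * np.exp(cell.gain * drive)
    else:
        raise ParameterError(f"unknown nonlinearity {nonlinearity!r}")

    dt = stim.dt_s
    p = np.clip(rate * dt, 0.0, max_spike_prob)
    rng = np.random.default_rng(seed)
    fired = rng.random(stim.n_frames) < p
    idx = np.nonzero(fired)[0]
    times = (idx + rng.random(idx.size)) * dt
    return SpikeTrain(cell.cell_id, times, stim.duration_s)


#: time-to-peak distributions (ms) used when drawing populations; the
#: control/blocker means and SDs mirror typical diurnal-rodent ON/OFF
#: latencies and their slowdown under connexin blockade.
LATENCY_DEFAULTS = {
    "control": {"on_mean": 67.36, "on_sd": 12.06, "off_mean": 48.60, "off_sd": 8.13},
    "blocker": {"on_mean": 94.9, "on_sd": 19.3, "off_mean": 61.5, "off_sd": 12.1},
}

#: evoked-rate scale of the blocker condition is ~0.53 of control.
RATE_DEFAULTS = {
    "control": {"on_base": 8.2, "off_base": 6.2, "gain": 2.0},
    "blocker": {"on_base": 4.4, "off_base": 3.3, "gain": 1.06},
}


def make_population(
    n_on: int,
    n_off: int,
    stim: StimulusMovie,
    condition: str = "control",
    seed: int = 0,
    latency_params: dict | None = None,
    rate_params: dict | None = None,
    spatial_sigma: float = 1.2,
    center_margin: float = 3.0,
    n_kernel_lags: int = 18,
) -> list[tuple[GroundTruthCell, SpikeTrain]]:
    """Draw a labeled population of LN-Poisson cells and their spike trains.

    Latencies are drawn per type from normal distributions (defaults in
    ``LATENCY_DEFAULTS[condition]``), clipped to stay inside the kernel
    window; receptive-field centers are uniform inside the grid with a
    margin. Deterministic given ``seed``.
    """
    if n_on < 0 or n_off < 0:
        raise ParameterError("cell counts must be non-negative")
    if n_on + n_off < 1:
        raise ParameterError("population must contain at least one cell")
    if condition not in LATENCY_DEFAULTS:
        raise ParameterError(f"unknown condition {condition!r}")
    lat = dict(LATENCY_DEFAULTS[condition])
    if latency_params:
        lat.update(latency_params)
    rates = dict(RATE_DEFAULTS[condition])
    if rate_params:
        rates.update(rate_params)

    window_ms = n_kernel_lags * stim.frame_interval_ms
    rng = np.random.default_rng(seed)
    out: list[tuple[GroundTruthCell, SpikeTrain]] = []
    specs = [("on", 1, n_on, lat["on_mean"], lat["on_sd"], rates["on_base"]),
             ("off", -1, n_off, lat["off_mean"], lat["off_sd"], rates["off_base"])]
    for name, polarity, count, mean, sd, base in specs:
        for i in range(count):
            latency = float(np.clip(rng.normal(mean, sd), 15.0, window_ms - 20.0))
            r0 = rng.uniform(center_margin, stim.grid_rows - 1 - center_margin)
            c0 = rng.uniform(center_margin, stim.grid_cols - 1 - center_margin)
            cell = GroundTruthCell(
                cell_id=f"{condition}_{name}_{i:03d}",
                polarity=polarity,
                spatial_center=(float(r0), float(c0)),
                spatial_sigma=spatial_sigma,
                peak_latency_ms=latency,
                base_rate_hz=base,
                gain=rates["gain"],
                condition=condition,
            )
            child_seed = int(rng.integers(0, 2**31 - 1))
            out.append((cell, simulate_ln_cell(cell, stim, child_seed,
                                               n_kernel_lags=n_kernel_lags)))
    return out


# ---------------------------------------------------------------------------
# ERG traces
# ---------------------------------------------------------------------------

#: (log intensity, control b-wave amplitude uV) anchor points per species
#: and adaptation state; the saturating intensity-response curve is solved
#: to pass through all three anchors exactly.
ERG_CALIBRATION_POINTS = {
    "degu_scotopic": ((-0.88, 0.52, 1.82), (9.8, 38.4, 105.1)),
    "rat_scotopic": ((-0.88, 0.52, 1.82), (136.3, 526.7, 569.7)),
    "degu_photopic": ((1.03, 1.63, 2.33), (2.8, 17.4, 47.2)),
    "rat_photopic": ((1.03, 1.63, 2.33), (6.5, 23.2, 68.0)),
}

#: default blocker b-wave scale = treated/control at the highest anchor
#: intensity (>1 means the blocker increases the b-wave, as in the
#: light-adapted degu).
ERG_BLOCKER_SCALE = {
    "degu_scotopic": 57.8 / 105.1,
    "rat_scotopic": 272.4 / 569.7,
    "degu_photopic": 97.7 / 47.2,
    "rat_photopic": 25.7 / 68.0,
}

#: Gaussian component shapes (times/widths in ms): the a-wave is an early
#: inverted bump, the b-wave a later positive bump; photopic kinetics are
#: faster. a_frac sets the a-trough depth as a fraction of the control
#: b-amplitude.
ERG_WAVE_SHAPES = {
    "scotopic": {"a_time": 20.0, "a_sigma": 6.0, "b_time": 70.0, "b_sigma": 20.0,
                 "a_frac": 0.4},
    "photopic": {"a_time": 15.0, "a_sigma": 5.0, "b_time": 50.0, "b_sigma": 15.0,
                 "a_frac": 0.3},
}


def naka_rushton(intensity: np.ndarray, r_max: float, sigma: float, n: float) -> np.ndarray:
    """Saturating intensity-response R(I) = Rmax * I^n / (I^n + sigma^n)."""
    i_n = np.power(intensity, n)
    return r_max * i_n / (i_n + sigma**n)


_CALIBRATION_CACHE: dict[str, tuple[float, float, float]] = {}


def calibrate_intensity_response(species_profile: str) -> tuple[float, float, float]:
    """Solve (Rmax, sigma, n) so the Naka-Rushton curve passes exactly
    through the profile's three anchor points."""
    if species_profile not in ERG_CALIBRATION_POINTS:
        raise ParameterError(f"unknown species_profile {species_profile!r}")
    if species_profile in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[species_profile]
    log_i, amps = ERG_CALIBRATION_POINTS[species_profile]
    intensity = 10.0 ** np.asarray(log_i)
    amps = np.asarray(amps, dtype=float)

    def residual(log_params):
        r_max, sigma, n = np.exp(log_params)
        return np.log(naka_rushton(intensity, r_max, sigma, n)) - np.log(amps)

    x0 = np.log([1.5 * amps[-1], intensity[1], 1.0])
    sol = optimize.least_squares(residual, x0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
    params = tuple(float(v) for v in np.exp(sol.x))
    check = naka_rushton(intensity, *params)
    if not np.allclose(check, amps, rtol=1e-6):
        raise CalibrationError(
            f"{species_profile}: curve misses anchors ({check} vs {amps})")
    _CALIBRATION_CACHE[species_profile] = params
    return params


@dataclass(frozen=True)
class ERGGroundTruth:
    a_amp_uv: float
    b_amp_uv: float
    a_time_ms: float
    b_time_ms: float


@dataclass(frozen=True)
class ERGTrace:
    """One simulated ERG sweep on a uniform time grid (onset at t=0 ms)."""

    time_ms: np.ndarray
    voltage_uv: np.ndarray
    stimulus_onset_ms: float
    intensity_log: float
    condition: str
    species_profile: str
    ground_truth: ERGGroundTruth | None = None

    def __post_init__(self):
        dt = np.diff(self.time_ms)
        if dt.size and not np.allclose(dt, dt[0]):
            raise ParameterError("time grid must be uniform")
        if not (self.time_ms[0] <= self.stimulus_onset_ms <= self.time_ms[-1]):
            raise ParameterError("stimulus onset must lie within the time grid")


def _gauss(t, mu, sd):
    return np.exp(-0.5 * ((t - mu) / sd) ** 2)


def simulate_erg(
    intensity_log: float,
    condition: str = "control",
    species_profile: str = "degu_scotopic",
    seed: int = 0,
    noise_sd_uv: float = 5.0,
    b_scale: float | None = None,
    dt_ms: float = 1.0,
    t_min_ms: float = -100.0,
    t_max_ms: float = 350.0,
) -> ERGTrace:
    """Simulate one ERG sweep: inverted-Gaussian a-wave + Gaussian b-wave on
    a flat baseline, plus 1-100 Hz band-limited noise.

    The control b-amplitude follows the profile's calibrated saturating
    intensity-response curve; ``condition="blocker"`` scales the b-wave by
    ``b_scale`` (default: the profile's treated/control ratio at the top
    anchor intensity) while the photoreceptor-driven a-wave is unchanged.
    True component amplitudes/times, measured on the noiseless trace, are
    recorded in ``ground_truth``.
    """
    if condition not in ("control", "blocker"):
        raise ParameterError(f"unknown condition {condition!r}")
    log_i, _ = ERG_CALIBRATION_POINTS.get(species_profile, ((), ()))
    params = calibrate_intensity_response(species_profile)
    if not (min(log_i) - 1e-9 <= intensity_log <= max(log_i) + 1e-9):
        raise ParameterError(
            f"intensity_log {intensity_log} outside calibrated range "
            f"[{min(log_i)}, {max(log_i)}] of {species_profile}")

    shape = ERG_WAVE_SHAPES[species_profile.split("_")[1]]
    b_control = float(naka_rushton(10.0 ** intensity_log, *params))
    if b_scale is None:
        b_scale = ERG_BLOCKER_SCALE[species_profile]
    b_amp = b_control * (b_scale if condition == "blocker" else 1.0)
    a_amp = shape["a_frac"] * b_control

    t = np.arange(t_min_ms, t_max_ms + 0.5 * dt_ms, dt_ms)
    clean = (-a_amp * _gauss(t, shape["a_time"], shape["a_sigma"])
             + b_amp * _gauss(t, shape["b_time"], shape["b_sigma"]))

    post = t > 0
    i_min = int(np.argmin(clean[post]))
    i_max = int(np.argmax(clean[post]))
    truth = ERGGroundTruth(
        a_amp_uv=float(clean[post][i_min]),
        b_amp_uv=float(clean[post][i_max]),
        a_time_ms=float(t[post][i_min]),
        b_time_ms=float(t[post][i_max]),
    )

    v = clean
    if noise_sd_uv > 0:
        rng = np.random.default_rng(seed)
        white = rng.standard_normal(t.size)
        fs = 1000.0 / dt_ms
        sos = signal.butter(2, [1.0, 100.0], btype="bandpass", fs=fs, output="sos")
        band = signal.sosfiltfilt(sos, white)
        band = band * (noise_sd_uv / band.std())
        v = clean + band

    return ERGTrace(time_ms=t, voltage_uv=v, stimulus_onset_ms=0.0,
                    intensity_log=intensity_log, condition=condition,
                    species_profile=species_profile, ground_truth=truth)
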