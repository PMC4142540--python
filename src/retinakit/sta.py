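"""Spike-triggered-average receptive-field estimation.

Under binary white-noise stimulation the mean stimulus preceding spikes
(the STA) estimates a cell's linear spatiotemporal receptive field. The
volume spans ``n_lags`` frames before each spike (default 18 frames of
16.67 ms = 300 ms at 60 fps); the receptive-field center is the pixel of
maximal absolute deviation, refined by an axis-aligned 2D Gaussian fit;
a field counts as valid when its peak stands far enough above the noise
floor estimated from the longest (pre-response) lags and the Gaussian fit
converged to a plausible center and width.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import curve_fit

from .errors import NoSpikesError, ParameterError
from .synth import SpikeTrain, StimulusMovie

__all__ = [
    "STAVolume",
    "PeakLocation",
    "Gaussian2DFit",
    "RFFit",
    "compute_sta",
    "find_peak",
    "fit_gaussian2d",
    "fit_rf",
    "validate_rf",
]


@dataclass(frozen=True)
class STAVolume:
    """Mean-subtracted average stimulus around spikes, lags x rows x cols.

    ``values[i]`` is the average stimulus frame shown ``i + 1`` frames
    before the spike's frame; ``lag_times_ms[i] = (i + 1) * frame interval``.
    The theoretical stimulus mean (0 for a +/-1 checkerboard) is subtracted.
    """

    cell_id: str
    values: np.ndarray
    lag_times_ms: np.ndarray
    n_spikes_used: int
    n_spikes_excluded: int
    frame_rate_hz: float

    @property
    def n_lags(self) -> int:
        return self.values.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape[1], self.values.shape[2]


def default_n_lags(frame_rate_hz: float, window_ms: float = 300.0) -> int:
    """Number of pre-spike frames covering the analysis window
    (300 ms at 60 fps -> 18)."""
    return int(round(window_ms * frame_rate_hz / 1000.0))


def compute_sta(
    stim: StimulusMovie,
    spikes: SpikeTrain,
    n_lags: int | None = None,
    window_ms: float = 300.0,
) -> STAVolume:
    """Average the ``n_lags`` stimulus frames preceding each spike.

    Spikes are assigned to frames by floor(t * fps); spikes whose frame
    index is below ``n_lags`` (incomplete history) or beyond the movie are
    excluded and counted in ``n_spikes_excluded``.
    """
    if n_lags is None:
        n_lags = default_n_lags(stim.frame_rate_hz, window_ms)
    if n_lags < 1:
        raise ParameterError("n_lags must be >= 1")
    if n_lags > stim.n_frames:
        raise ParameterError("n_lags exceeds stimulus length")

    frames = np.floor(spikes.spike_times_s * stim.frame_rate_hz).astype(np.int64)
    usable = (frames >= n_lags) & (frames < stim.n_frames)
    f = frames[usable]
    n_used = int(f.size)
    if n_used == 0:
        raise NoSpikesError(f"{spikes.cell_id}: no usable spikes in window")

    acc = np.empty((n_lags, stim.grid_rows, stim.grid_cols))
    for k in range(1, n_lags + 1):
        acc[k - 1] = stim.values[f - k].mean(axis=0)

    lag_times_ms = np.arange(1, n_lags + 1) * stim.frame_interval_ms
    return STAVolume(cell_id=spikes.cell_id, values=acc, lag_times_ms=lag_times_ms,
                     n_spikes_used=n_used,
                     n_spikes_excluded=int(spikes.n_spikes - n_used),
                     frame_rate_hz=stim.frame_rate_hz)


class PeakLocation(NamedTuple):
    lag_index: int
    row: int
    col: int
    value: float
    degenerate: bool = False


def find_peak(sta: STAVolume) -> PeakLocation:
    """Coordinate of maximal absolute deviation in the volume.

    Ties resolve to the earliest lag index, then row-major order (the
    behavior of the first argmax occurrence). An all-zero volume is
    flagged degenerate.
    """
    if sta.values.size == 0:
        raise ParameterError("empty STA volume")
    absv = np.abs(sta.values)
    flat = int(np.argmax(absv))
    lag, row, col = np.unravel_index(flat, sta.values.shape)
    value = float(sta.values[lag, row, col])
    return PeakLocation(int(lag), int(row), int(col), value, degenerate=value == 0.0)


@dataclass(frozen=True)
class Gaussian2DFit:
    """Axis-aligned 2D Gaussian least-squares fit of one STA frame."""

    center: tuple[float, float]
    sigmas: tuple[float, float]
    amplitude: float
    offset: float
    rss: float
    converged: bool


def _gauss2d(coords, amplitude, r0, c0, sr, sc, offset):
    rr, cc = coords
    return (amplitude * np.exp(-((rr - r0) ** 2 / (2 * sr**2)
                                 + (cc - c0) ** 2 / (2 * sc**2)))
            + offset).ravel()


def fit_gaussian2d(frame: np.ndarray, init: tuple[int, int],
                   sigma_init: float = 1.5) -> Gaussian2DFit:
    """Least-squares amplitude * Gaussian + offset fit, initialized at the
    peak pixel. Non-convergence is reported via ``converged=False``, not
    raised."""
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.shape[0] < 3 or frame.shape[1] < 3:
        raise ParameterError("frame must be 2D and at least 3x3")
    if not np.all(np.isfinite(frame)):
        raise ParameterError("frame must be finite")
    r_init, c_init = init
    rows, cols = frame.shape
    if not (0 <= r_init < rows and 0 <= c_init < cols):
        raise ParameterError("init must lie inside the frame")

    failed = Gaussian2DFit(center=(float(r_init), float(c_init)),
                           sigmas=(np.nan, np.nan), amplitude=np.nan,
                           offset=np.nan, rss=np.nan, converged=False)
    if np.ptp(frame) == 0.0:
        return failed

    rr, cc = np.mgrid[0:rows, 0:cols]
    offset0 = float(np.median(frame))
    amp0 = float(frame[r_init, c_init] - offset0)
    if amp0 == 0.0:
        amp0 = float(np.ptp(frame)) or 1.0
    p0 = [amp0, float(r_init), float(c_init), sigma_init, sigma_init, offset0]
    span = float(max(rows, cols))
    bounds = ([-np.inf, -1.0, -1.0, 0.05, 0.05, -np.inf],
              [np.inf, rows, cols, 2 * span, 2 * span, np.inf])
    try:
        popt, _ = curve_fit(_gauss2d, (rr, cc), frame.ravel(), p0=p0,
                            bounds=bounds, maxfev=5000)
    except (RuntimeError, ValueError):
        return failed
    if not np.all(np.isfinite(popt)):
        return failed
    resid = frame.ravel() - _gauss2d((rr, cc), *popt)
    return Gaussian2DFit(center=(float(popt[1]), float(popt[2])),
                         sigmas=(float(popt[3]), float(popt[4])),
                         amplitude=float(popt[0]), offset=float(popt[5]),
                         rss=float(resid @ resid), converged=True)


@dataclass(frozen=True)
class RFFit:
    """Receptive-field localization + validity summary for one cell."""

    cell_id: str
    peak_lag_index: int
    peak_pixel: tuple[int, int]
    peak_value: float
    gauss: Gaussian2DFit | None
    noise_sd: float
    peak_z: float
    valid: bool
    degenerate: bool = False


def estimate_noise_sd(sta: STAVolume, n_noise_lags: int = 2) -> float:
    """Pixel SD over the longest-lag frames, which precede the cell's
    temporal integration window and so contain only sampling noise."""
    return float(np.std(sta.values[-n_noise_lags:]))


def validate_rf(
    peak_z: float,
    gauss: Gaussian2DFit | None,
    grid_shape: tuple[int, int],
    peak_pixel: tuple[int, int] | None = None,
    peak_value: float | None = None,
    z_min: float = 4.0,
    sigma_min: float = 0.65,
    sigma_max: float | None = None,
    center_max_dist: float = 2.0,
    min_amplitude_frac: float = 0.5,
) -> bool:
    """Validity rule: peak z-score >= ``z_min`` (inclusive) AND the Gaussian
    fit converged with both sigmas inside [sigma_min, sigma_max] and a
    center/amplitude consistent with the peak it was initialized at.

    The default sigma floor of 0.65 checkers rejects fields narrower than
    a single stimulus bin: a receptive-field center that cannot be
    resolved at the checker size is indistinguishable from a one-pixel
    noise fluctuation. The default upper bound is half the grid. When
    ``peak_value`` is given the fitted amplitude must match its sign and
    reach ``min_amplitude_frac`` of it, i.e. the Gaussian must actually
    account for the detected peak."""
    if not np.isfinite(peak_z) or peak_z < z_min:
        return False
    if gauss is None or not gauss.converged:
        return False
    if sigma_max is None:
        sigma_max = max(grid_shape) / 2.0
    sr, sc = gauss.sigmas
    if not (sigma_min <= sr <= sigma_max and sigma_min <= sc <= sigma_max):
        return False
    r0, c0 = gauss.center
    if not (-0.5 <= r0 <= grid_shape[0] - 0.5 and -0.5 <= c0 <= grid_shape[1] - 0.5):
        return False
    if peak_pixel is not None:
        dist = np.hypot(r0 - peak_pixel[0], c0 - peak_pixel[1])
        if dist > center_max_dist:
            return False
    if peak_value is not None:
        if np.sign(gauss.amplitude) != np.sign(peak_value):
            return False
        if abs(gauss.amplitude) < min_amplitude_frac * abs(peak_value):
            return False
    return True


def fit_rf(sta: STAVolume, z_min: float = 4.0, sigma_min: float = 0.65,
           sigma_max: float | None = None, center_max_dist: float = 2.0) -> RFFit:
    """Full localization chain: peak pixel -> 2D Gaussian fit at the peak
    lag -> z-score against the long-lag noise floor -> validity decision."""
    peak = find_peak(sta)
    if peak.degenerate:
        return RFFit(cell_id=sta.cell_id, peak_lag_index=peak.lag_index,
                     peak_pixel=(peak.row, peak.col), peak_value=peak.value,
                     gauss=None, noise_sd=0.0, peak_z=0.0, valid=False,
                     degenerate=True)
    gauss = fit_gaussian2d(sta.values[peak.lag_index], (peak.row, peak.col))
    noise_sd = estimate_noise_sd(sta)
    peak_z = abs(peak.value) / noise_sd if noise_sd > 0 else np.inf
    valid = validate_rf(peak_z, gauss, sta.grid_shape,
                        peak_pixel=(peak.row, peak.col), peak_value=peak.value,
                        z_min=z_min, sigma_min=sigma_min, sigma_max=sigma_max,
                        center_max_dist=center_max_dist)
    return RFFit(cell_id=sta.cell_id, peak_lag_index=peak.lag_index,
                 peak_pixel=(peak.row, peak.col), peak_value=peak.value,
                 gauss=gauss, noise_sd=noise_sd, peak_z=float(peak_z), valid=valid)
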