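"""Temporal receptive-field profiles and functional classification.

The temporal profile of a cell is the STA value at its receptive-field
center pixel as a function of pre-spike lag. A cubic interpolating spline
on a 1 ms grid refines the frame-resolution latency into ``time_to_peak``
(ms before the spike of the maximal absolute deviation) and
``time_to_zero_cross`` (where the profile crosses zero on the spike-ward
side of the peak). ON/OFF identity is the sign of the profile at its peak;
finer functional grouping uses PCA followed by k-means on the standardized
profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .errors import ParameterError
from .popstats import round_half_away
from .sta import RFFit, STAVolume

__all__ = [
    "TemporalProfile",
    "ClusterResult",
    "extract_profile",
    "spline_refine",
    "classify",
    "population_counts",
    "best_permutation_accuracy",
]


@dataclass
class TemporalProfile:
    """STA center-pixel value per pre-spike lag, plus spline refinements.

    ``lag_times_ms`` ascends from one frame interval toward the window end;
    time zero is the spike occurrence, so larger lag = earlier stimulus.
    ``time_to_zero_cross_ms`` is NaN when the profile never crosses zero
    between its peak and the spike.
    """

    cell_id: str
    lag_times_ms: np.ndarray
    values: np.ndarray
    polarity: int
    degenerate: bool = False
    spline_times_ms: np.ndarray | None = None
    spline_values: np.ndarray | None = None
    time_to_peak_ms: float = np.nan
    time_to_zero_cross_ms: float = np.nan
    coarse_fallback: bool = False


def extract_profile(sta: STAVolume, fit: RFFit) -> TemporalProfile:
    """Lag series at the receptive-field center (the Gaussian-fit center
    rounded to the nearest pixel when available, else the raw peak pixel)."""
    if fit.gauss is not None and fit.gauss.converged:
        r = int(round(fit.gauss.center[0]))
        c = int(round(fit.gauss.center[1]))
    else:
        r, c = fit.peak_pixel
    rows, cols = sta.grid_shape
    if not (0 <= r < rows and 0 <= c < cols):
        raise ParameterError(f"{sta.cell_id}: RF center ({r}, {c}) outside grid")
    values = np.asarray(sta.values[:, r, c], dtype=float)
    degenerate = bool(np.all(values == 0.0))
    idx = int(np.argmax(np.abs(values)))
    polarity = int(np.sign(values[idx])) if not degenerate else 0
    return TemporalProfile(cell_id=sta.cell_id,
                           lag_times_ms=np.asarray(sta.lag_times_ms, dtype=float),
                           values=values, polarity=polarity, degenerate=degenerate,
                           time_to_peak_ms=float(sta.lag_times_ms[idx]))


def spline_refine(profile: TemporalProfile, grid_step_ms: float = 1.0) -> TemporalProfile:
    """Fill the spline fields of a profile (in place, also returned).

    A cubic interpolating spline through the lag samples is evaluated on a
    dense grid (step 1 ms, always including the knots so sample-aligned
    peaks are preserved exactly). ``time_to_peak_ms`` is the grid time of
    maximal |spline|; the zero crossing is searched from the peak toward
    the spike and refined by root bracketing. With fewer than 4 samples the
    spline is skipped and the frame-resolution peak is kept, flagged via
    ``coarse_fallback``.
    """
    t = profile.lag_times_ms
    v = profile.values
    if t.size < 4:
        warnings.warn(f"{profile.cell_id}: <4 lag samples, keeping "
                      "frame-resolution peak", stacklevel=2)
        profile.coarse_fallback = True
        if not profile.degenerate and v.size:
            idx = int(np.argmax(np.abs(v)))
            profile.time_to_peak_ms = float(t[idx])
            profile.polarity = int(np.sign(v[idx]))
        return profile

    cs = CubicSpline(t, v)
    grid = np.union1d(np.arange(t[0], t[-1] + 0.5 * grid_step_ms, grid_step_ms), t)
    sv = cs(grid)
    profile.spline_times_ms = grid
    profile.spline_values = sv
    if profile.degenerate:
        return profile

    i_peak = int(np.argmax(np.abs(sv)))
    profile.time_to_peak_ms = float(grid[i_peak])
    profile.polarity = int(np.sign(sv[i_peak]))

    # walk from the peak toward the spike (decreasing lag) for a sign change
    profile.time_to_zero_cross_ms = np.nan
    for j in range(i_peak, 0, -1):
        if np.sign(sv[j - 1]) != np.sign(sv[j]) and sv[j] != 0.0:
            if sv[j - 1] == 0.0:
                profile.time_to_zero_cross_ms = float(grid[j - 1])
            else:
                profile.time_to_zero_cross_ms = float(
                    brentq(cs, grid[j - 1], grid[j]))
            break
    return profile


@dataclass(frozen=True)
class ClusterResult:
    cell_id: str
    pca_coords: np.ndarray
    cluster_id: int
    cell_type: str


def classify(
    profiles: list[TemporalProfile],
    k: int = 5,
    variance_cutoff: float = 0.90,
    max_components: int = 5,
    seed: int = 0,
    n_init: int = 20,
) -> list[ClusterResult]:
    """PCA + k-means functional grouping of temporal profiles.

    Profiles are standardized to unit L2 norm — clustering then reflects
    waveform shape, polarity and latency rather than response strength —
    projected onto the leading principal components explaining >=
    ``variance_cutoff`` of the variance (capped at ``max_components``), and
    partitioned by k-means (``n_init`` restarts, best inertia, fixed seed).
    ON/OFF identity comes from each profile's own polarity, independent of
    cluster membership; clusters are labeled 1..k.
    """
    if not profiles:
        raise ParameterError("no profiles to classify")
    if len(profiles) < k:
        warnings.warn(f"only {len(profiles)} profiles; reducing k from {k}",
                      stacklevel=2)
        k = len(profiles)

    X = np.vstack([p.values for p in profiles])
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    Xs = X / np.where(norms > 0, norms, 1.0)
    n_comp = min(max_components, Xs.shape[0], Xs.shape[1])
    pca = PCA(n_components=n_comp, random_state=seed)
    coords_full = pca.fit_transform(Xs)
    cum = np.cumsum(pca.explained_variance_ratio_)
    m = int(np.searchsorted(cum, variance_cutoff) + 1)
    m = min(max(m, 1), n_comp)
    coords = coords_full[:, :m]

    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(coords)

    return [ClusterResult(cell_id=p.cell_id, pca_coords=coords[i],
                          cluster_id=int(labels[i]) + 1,
                          cell_type="ON" if p.polarity > 0 else "OFF")
            for i, p in enumerate(profiles)]


def population_counts(results: list[ClusterResult],
                      condition_by_cell: dict[str, str] | None = None):
    """Count table of ON/OFF cells (per condition when a mapping is given);
    percentages are within-condition, rounded to one decimal."""
    import pandas as pd

    if not results:
        raise ParameterError("no classification results")
    rows = [{"condition": (condition_by_cell or {}).get(r.cell_id, "all"),
             "cell_type": r.cell_type} for r in results]
    df = pd.DataFrame(rows)
    counts = (df.groupby(["condition", "cell_type"], sort=True)
              .size().rename("n").reset_index())
    totals = counts.groupby("condition")["n"].transform("sum")
    counts["percent"] = [round_half_away(100.0 * n / t)
                         for n, t in zip(counts["n"], totals)]
    return counts


def best_permutation_accuracy(true_labels, pred_labels) -> float:
    """Clustering accuracy maximized over label permutations (Hungarian
    assignment on the confusion matrix)."""
    from scipy.optimize import linear_sum_assignment

    true_labels = np.asarray(true_labels)
    pred_labels = np.asarray(pred_labels)
    t_vals = np.unique(true_labels)
    p_vals = np.unique(pred_labels)
    conf = np.zeros((t_vals.size, p_vals.size))
    for i, tv in enumerate(t_vals):
        for j, pv in enumerate(p_vals):
            conf[i, j] = np.sum((true_labels == tv) & (pred_labels == pv))
    ri, ci = linear_sum_assignment(-conf)
    return float(conf[ri, ci].sum() / true_labels.size)
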