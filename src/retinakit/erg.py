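"""ERG a-/b-wave quantification and intensity-response analysis.

An ERG flash response carries an early negative a-wave (photoreceptors)
followed by a positive b-wave (ON bipolar cells). Amplitudes are measured
against the averaged pre-stimulus baseline; each raw extremum is refined
by least-squares fitting a fifth-order polynomial over a +/-25 ms window
and taking the fitted extremum, which suppresses single-sample noise
error. Intensity-response curves aggregate b-amplitudes per stimulus
intensity and condition, and a paired t-test compares conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import signal, stats

from .errors import ParameterError
from .popstats import round_half_away
from .synth import ERGTrace

__all__ = [
    "ERGMeasurement",
    "measure_waves",
    "relative_change",
    "paired_t_test",
    "build_intensity_response",
]


@dataclass(frozen=True)
class ERGMeasurement:
    """Baseline-referenced a-/b-wave amplitudes of one ERG sweep.

    ``a_amp_uv`` is negative (trough below baseline), ``b_amp_uv``
    positive; times are ms from stimulus onset. Undetected waves carry
    NaN amplitudes and a False ``*_found`` flag.
    """

    intensity_log: float
    condition: str
    baseline_uv: float
    a_amp_uv: float = np.nan
    b_amp_uv: float = np.nan
    a_time_ms: float = np.nan
    b_time_ms: float = np.nan
    a_found: bool = False
    b_found: bool = False
    warnings: tuple[str, ...] = ()


def _poly_refine(t: np.ndarray, v: np.ndarray, t0: float, halfwidth_ms: float,
                 kind: str) -> tuple[float, float, list[str]]:
    """Refine a raw extremum by fitting a 5th-order polynomial around it.

    Returns (time, value) of the fitted extremum of the requested kind
    ("min"/"max") nearest the raw location; falls back to the raw sample
    (with a warning note) if the fit has no such interior extremum.
    """
    notes: list[str] = []
    m = (t >= t0 - halfwidth_ms) & (t <= t0 + halfwidth_ms)
    if t[m].size < 7:
        notes.append(f"{kind}: fit window clipped to {int(t[m].size)} samples")
    if t[m].size < 6:
        return t0, float(np.interp(t0, t, v)), notes
    if t[m][0] > t0 - halfwidth_ms + 1e-9 or t[m][-1] < t0 + halfwidth_ms - 1e-9:
        notes.append(f"{kind}: fit window clipped at trace edge")
    poly = np.polynomial.Polynomial.fit(t[m], v[m], 5)
    deriv = poly.deriv()
    second = deriv.deriv()
    roots = deriv.roots()
    want = 1.0 if kind == "min" else -1.0
    best = None
    for r in roots:
        if abs(r.imag) > 1e-8:
            continue
        x = float(r.real)
        if not (t[m][0] <= x <= t[m][-1]):
            continue
        if np.sign(second(x)) != want:
            continue
        if best is None or abs(x - t0) < abs(best - t0):
            best = x
    if best is None:
        notes.append(f"{kind}: no interior polynomial extremum, raw value kept")
        return t0, float(np.interp(t0, t, v)), notes
    return best, float(poly(best)), notes


def measure_waves(
    trace: ERGTrace,
    baseline_window_ms: float = 100.0,
    fit_halfwidth_ms: float = 25.0,
    a_search_ms: float = 120.0,
    b_search_ms: float = 300.0,
) -> ERGMeasurement:
    """Extract baseline-referenced a- and b-wave amplitudes from a sweep.

    Baseline is the mean voltage over the ``baseline_window_ms`` preceding
    stimulus onset. The a-wave is the earliest post-onset local minimum
    falling below the baseline by more than the baseline noise; the b-wave
    is the subsequent maximum rising above it. Extremum localization uses a
    lightly smoothed copy of the trace when it is noisy; amplitudes come
    from the fifth-order polynomial fit on the raw samples.
    """
    t = np.asarray(trace.time_ms, dtype=float) - trace.stimulus_onset_ms
    v = np.asarray(trace.voltage_uv, dtype=float)
    pre = (t >= -baseline_window_ms) & (t < 0)
    if not np.any(pre):
        raise ParameterError("trace must span the pre-onset baseline window")
    if t[-1] < 250.0:
        raise ParameterError("trace must extend >= 250 ms past onset")

    baseline = float(v[pre].mean())
    noise_sd = float(v[pre].std())
    margin = max(2.5 * noise_sd, 1e-9)

    if noise_sd > 0 and v.size >= 25:
        win = min(21, (v.size // 2) * 2 - 1)
        vs = signal.savgol_filter(v, win, 3)
    else:
        vs = v

    notes: list[str] = []

    # a-wave: earliest post-onset local minimum below baseline - margin
    a_mask = (t > 0) & (t <= a_search_ms)
    a_time = a_val = np.nan
    a_found = False
    idx = np.nonzero(a_mask)[0]
    if idx.size:
        mins, _ = signal.find_peaks(-vs[idx])
        cands = [i for i in mins if vs[idx[i]] < baseline - margin]
        if not cands:
            g = int(np.argmin(vs[idx]))
            if 0 < g < idx.size - 1 and vs[idx[g]] < baseline - margin:
                cands = [g]
        if cands:
            a_found = True
            raw_t = t[idx[cands[0]]]
            a_time, a_val, n = _poly_refine(t, v, raw_t, fit_halfwidth_ms, "min")
            notes += n

    # b-wave: maximum after the a-trough (or after onset when no a-wave)
    b_start = a_time if a_found else 0.0
    b_mask = (t > b_start) & (t <= b_search_ms)
    b_time = b_val = np.nan
    b_found = False
    idx = np.nonzero(b_mask)[0]
    if idx.size:
        g = int(np.argmax(vs[idx]))
        if vs[idx[g]] > baseline + margin:
            b_found = True
            raw_t = t[idx[g]]
            b_time, b_val, n = _poly_refine(t, v, raw_t, fit_halfwidth_ms, "max")
            notes += n

    return ERGMeasurement(
        intensity_log=trace.intensity_log, condition=trace.condition,
        baseline_uv=baseline,
        a_amp_uv=float(a_val - baseline) if a_found else np.nan,
        b_amp_uv=float(b_val - baseline) if b_found else np.nan,
        a_time_ms=float(a_time) if a_found else np.nan,
        b_time_ms=float(b_time) if b_found else np.nan,
        a_found=a_found, b_found=b_found, warnings=tuple(notes))


def relative_change(mean_treated: float, mean_control: float) -> float:
    """Percent change 100*(treated - control)/control, one decimal; NaN
    (undefined) when the control mean is zero."""
    if mean_control == 0:
        return float("nan")
    return round_half_away(100.0 * (mean_treated - mean_control) / mean_control)


class PairedTResult(NamedTuple):
    t: float
    df: int
    p: float
    degenerate: bool = False


def paired_t_test(control: Iterable[float], treated: Iterable[float]) -> PairedTResult:
    """Two-sided paired Student's t-test on treated - control differences.

    Zero-variance differences are degenerate: identical vectors give
    (t=0, p=1); a constant nonzero shift gives t = +/-inf with p
    reported as 0 by convention.
    """
    c = np.asarray(list(control), dtype=float)
    tr = np.asarray(list(treated), dtype=float)
    if c.size != tr.size:
        raise ParameterError("paired samples must have equal length")
    n = c.size
    if n < 2:
        raise ParameterError("paired t-test needs n >= 2")
    d = tr - c
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return PairedTResult(0.0, n - 1, 1.0, degenerate=True)
        return PairedTResult(float(np.inf * np.sign(d.mean())), n - 1, 0.0,
                             degenerate=True)
    res = stats.ttest_rel(tr, c)
    return PairedTResult(float(res.statistic), n - 1, float(res.pvalue))


def build_intensity_response(measurements: Iterable[ERGMeasurement]) -> pd.DataFrame:
    """Mean +/- s.e.m. b-wave amplitude per (condition, intensity).

    Rows are sorted by condition then increasing intensity; s.e.m. is NaN
    for single replicates. Monotonicity in intensity is reported, not
    enforced.
    """
    rows = [{"condition": m.condition, "intensity_log": m.intensity_log,
             "b_amp_uv": m.b_amp_uv}
            for m in measurements if np.isfinite(m.b_amp_uv)]
    if not rows:
        raise ParameterError("no measurements with a detected b-wave")
    df = pd.DataFrame(rows)
    out = (df.groupby(["condition", "intensity_log"])["b_amp_uv"]
           .agg(n="size", mean_b_uv="mean", sd_b_uv=lambda s: s.std(ddof=1))
           .reset_index()
           .sort_values(["condition", "intensity_log"], ignore_index=True))
    out["sem_b_uv"] = out["sd_b_uv"] / np.sqrt(out["n"])
    out["monotone_increasing"] = out.groupby("condition")["mean_b_uv"].transform(
        lambda s: bool(np.all(np.diff(s) > 0)))
    return out.drop(columns=["sd_b_uv"])
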