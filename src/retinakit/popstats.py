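"""Population-level summaries and condition contrasts.

Latency tables (n, percent, mean +/- SD/s.e.m. time-to-peak per cell type
and condition), Welch's t-test from summary statistics or raw samples,
latency increments between conditions, and firing-rate summaries. Rounding
follows the half-away-from-zero, one-decimal style of the tables this
module renders.
"""

from __future__ import annotations

import json
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .synth import SpikeTrain

__all__ = [
    "round_half_away",
    "WelchResult",
    "welch_t_test",
    "welch_t_test_raw",
    "latency_increment",
    "firing_rate_summary",
    "summarize_latencies",
    "latency_contrast",
    "render_report",
    "significance_stars",
]


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (2.25 -> 2.3, -2.25 -> -2.3)."""
    if not np.isfinite(x):
        return float(x)
    factor = 10.0 ** decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float
    degenerate: bool = False


def welch_t_test(mean1: float, sd1: float, n1: int,
                 mean2: float, sd2: float, n2: int) -> WelchResult:
    """Welch's unequal-variance t-test from summary statistics.

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2) with Welch-Satterthwaite
    degrees of freedom and a two-sided p-value.
    """
    if n1 < 2 or n2 < 2:
        raise ParameterError("both groups need n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ParameterError("standard deviations must be non-negative")
    v1 = sd1**2 / n1
    v2 = sd2**2 / n2
    if v1 + v2 == 0.0:
        t = 0.0 if mean1 == mean2 else np.inf * np.sign(mean1 - mean2)
        return WelchResult(float(t), float(n1 + n2 - 2),
                           1.0 if mean1 == mean2 else 0.0, degenerate=True)
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p))


def welch_t_test_raw(x: Iterable[float], y: Iterable[float]) -> WelchResult:
    """Welch's t-test from raw samples; exact agreement with the
    summary-statistic path by construction."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    return welch_t_test(x.mean(), x.std(ddof=1), x.size,
                        y.mean(), y.std(ddof=1), y.size)


def latency_increment(control_mean: float, treated_mean: float) -> tuple[float, float]:
    """Latency change (treated - control) in ms and as a percentage of the
    control mean, both rounded to one decimal. Non-positive control means
    make the percentage undefined; (nan, nan) is returned."""
    if control_mean <= 0:
        return (float("nan"), float("nan"))
    delta = treated_mean - control_mean
    return (round_half_away(delta), round_half_away(100.0 * delta / control_mean))


def firing_rate_summary(
    trains: Iterable[SpikeTrain],
    window: tuple[float, float],
    labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-group mean +/- SD firing rate (spikes/s) within a time window.

    ``labels`` maps cell_id -> group name (default: one group "all").
    Empty trains contribute a rate of 0.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ParameterError("window must have positive duration")
    rows = []
    for train in trains:
        if t0 < 0 or t1 > train.recording_duration_s:
            raise ParameterError(f"{train.cell_id}: window outside recording")
        n = int(np.count_nonzero((train.spike_times_s >= t0)
                                 & (train.spike_times_s < t1)))
        rows.append({"group": (labels or {}).get(train.cell_id, "all"),
                     "rate_hz": n / (t1 - t0)})
    df = pd.DataFrame(rows)
    out = (df.groupby("group")["rate_hz"]
           .agg(n="size", mean_rate_hz="mean", sd_rate_hz=lambda s: s.std(ddof=1))
           .reset_index())
    return out


def summarize_latencies(records: pd.DataFrame) -> pd.DataFrame:
    """Latency summary table from per-cell rows with columns
    ``condition``, ``cell_type``, ``time_to_peak_ms``.

    Returns n, within-condition percent, and the mean, SD and s.e.m. of
    time-to-peak per (condition, cell_type). SD and s.e.m. are both
    reported because published tables are often ambiguous about which one
    follows the +/- sign.
    """
    required = {"condition", "cell_type", "time_to_peak_ms"}
    if not required.issubset(records.columns):
        raise ParameterError(f"records must have columns {sorted(required)}")
    g = records.groupby(["condition", "cell_type"])["time_to_peak_ms"]
    out = g.agg(n="size", mean_ms="mean",
                sd_ms=lambda s: s.std(ddof=1)).reset_index()
    out["sem_ms"] = out["sd_ms"] / np.sqrt(out["n"])
    totals = out.groupby("condition")["n"].transform("sum")
    out["percent"] = [round_half_away(100.0 * n / t)
                      for n, t in zip(out["n"], totals)]
    return out


def latency_contrast(summary: pd.DataFrame, control: str, treated: str) -> pd.DataFrame:
    """Per-cell-type latency increments and Welch tests between two
    conditions of a ``summarize_latencies`` table."""
    rows = []
    for cell_type in sorted(summary["cell_type"].unique()):
        c = summary[(summary.condition == control) & (summary.cell_type == cell_type)]
        t = summary[(summary.condition == treated) & (summary.cell_type == cell_type)]
        if c.empty or t.empty:
            continue
        c, t = c.iloc[0], t.iloc[0]
        delta_ms, delta_pct = latency_increment(c.mean_ms, t.mean_ms)
        if c.n >= 2 and t.n >= 2:
            welch = WelchResult(*welch_t_test(t.mean_ms, t.sd_ms, int(t.n),
                                              c.mean_ms, c.sd_ms, int(c.n)))
        else:  # too few cells for a test; report the increment alone
            welch = WelchResult(np.nan, np.nan, np.nan, degenerate=True)
        rows.append({"cell_type": cell_type, "control": control, "treated": treated,
                     "increment_ms": delta_ms, "increment_percent": delta_pct,
                     "welch_t": welch.t, "welch_df": welch.df, "welch_p": welch.p})
    return pd.DataFrame(rows)


def significance_stars(p: float) -> str:
    """Conventional significance markers (0.05 / 0.01 / 0.001)."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def render_report(summaries: dict, path=None) -> str:
    """Deterministic plain-text report: each DataFrame entry becomes a TSV
    section, everything else is serialized into one sorted-key JSON block.
    Regenerating from the same inputs is byte-identical (no timestamps)."""
    lines = ["# retinakit report"]
    scalars = {}
    for name in sorted(summaries):
        value = summaries[name]
        if isinstance(value, pd.DataFrame):
            lines.append(f"\n## {name}")
            lines.append(value.to_csv(sep="\t", index=False,
                                      float_format="%.6g").rstrip("\n"))
        else:
            scalars[name] = value
    if scalars:
        lines.append("\n## parameters_and_statistics")
        lines.append(json.dumps(scalars, sort_keys=True, indent=2,
                                default=_json_default))
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
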