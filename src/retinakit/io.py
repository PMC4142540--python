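"""Plain-text readers/writers for the pipeline's domain types.

Spike trains travel as two-column delimited text (cell_id, time_s),
stimulus movies as (seed, dims) JSON descriptors regenerated on read,
ERG traces as (time_ms, voltage_uv) tables with a JSON metadata sidecar.
Malformed rows are reported with their line number and column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import (ERGGroundTruth, ERGTrace, SpikeTrain, StimulusMovie,
                    make_checkerboard)

__all__ = [
    "write_spike_table", "read_spike_table",
    "write_stimulus_descriptor", "read_stimulus_descriptor",
    "write_erg_trace", "read_erg_trace",
    "write_table",
]


def write_spike_table(path, trains: list[SpikeTrain]) -> None:
    """Write spike trains as tab-separated (cell_id, time_s), one spike per
    row, microsecond precision."""
    with open(path, "w") as fh:
        fh.write("cell_id\ttime_s\n")
        for train in trains:
            for t in train.spike_times_s:
                fh.write(f"{train.cell_id}\t{t:.6f}\n")


def read_spike_table(path, recording_duration_s: float | None = None) -> list[SpikeTrain]:
    """Read a spike table back into per-cell SpikeTrains (input order of
    first appearance preserved). Raises ValueError naming the offending
    line on malformed or non-monotone input."""
    times: dict[str, list[float]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["cell_id", "time_s"]:
            raise ValueError(f"{path}: expected columns cell_id, time_s, "
                             f"got {header[:2]}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            cell_id = parts[0]
            try:
                t = float(parts[1])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: column time_s is not a number "
                    f"({parts[1]!r})") from None
            bucket = times.setdefault(cell_id, [])
            if bucket and t <= bucket[-1]:
                raise ValueError(
                    f"{path}:{lineno}: spike times of {cell_id} must be "
                    "strictly increasing")
            bucket.append(t)
    out = []
    for cell_id, ts in times.items():
        duration = recording_duration_s
        if duration is None:
            duration = float(ts[-1]) if ts else 0.0
        out.append(SpikeTrain(cell_id, np.asarray(ts), duration))
    return out


def write_stimulus_descriptor(path, stim: StimulusMovie) -> None:
    """Persist a checkerboard as its (seed, dims, rate) descriptor; the
    movie regenerates bit-exactly on read."""
    if stim.seed is None:
        raise ValueError("stimulus has no seed; cannot write a descriptor")
    meta = {"seed": int(stim.seed), "frames": stim.n_frames,
            "grid_rows": stim.grid_rows, "grid_cols": stim.grid_cols,
            "frame_rate_hz": stim.frame_rate_hz,
            "checker_size_um": stim.checker_size_um}
    Path(path).write_text(json.dumps(meta, sort_keys=True, indent=2) + "\n")


def read_stimulus_descriptor(path) -> StimulusMovie:
    meta = json.loads(Path(path).read_text())
    for key in ("seed", "frames", "grid_rows", "grid_cols"):
        if key not in meta:
            raise ValueError(f"{path}: descriptor missing key {key!r}")
    return make_checkerboard(
        seed=meta["seed"], frames=meta["frames"], grid_rows=meta["grid_rows"],
        grid_cols=meta["grid_cols"],
        frame_rate_hz=meta.get("frame_rate_hz", 60.0),
        checker_size_um=meta.get("checker_size_um", 100.0))


def write_erg_trace(path, trace: ERGTrace) -> None:
    """Write an ERG trace as (time_ms, voltage_uv) TSV plus a .json sidecar
    holding onset, intensity, condition and any ground truth."""
    path = Path(path)
    df = pd.DataFrame({"time_ms": trace.time_ms, "voltage_uv": trace.voltage_uv})
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    meta = {"stimulus_onset_ms": trace.stimulus_onset_ms,
            "intensity_log": trace.intensity_log,
            "condition": trace.condition,
            "species_profile": trace.species_profile}
    if trace.ground_truth is not None:
        meta["ground_truth"] = vars(trace.ground_truth)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, sort_keys=True, indent=2) + "\n")


def read_erg_trace(path) -> ERGTrace:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["time_ms", "voltage_uv"]:
        raise ValueError(f"{path}: expected columns time_ms, voltage_uv")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    truth = meta.get("ground_truth")
    return ERGTrace(
        time_ms=df["time_ms"].to_numpy(), voltage_uv=df["voltage_uv"].to_numpy(),
        stimulus_onset_ms=meta["stimulus_onset_ms"],
        intensity_log=meta["intensity_log"], condition=meta["condition"],
        species_profile=meta.get("species_profile", "unknown"),
        ground_truth=ERGGroundTruth(**truth) if truth else None)


def write_table(df: pd.DataFrame, path) -> None:
    """Write any result table as TSV with stable float formatting."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
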