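"""End-to-end orchestration: simulate -> STA -> classify -> stats (+ ERG).

``run_pipeline`` executes every stage with per-stage logging, writes all
artifacts (spike tables, RF fits, profiles, clusters, ERG measurements,
intensity-response tables, a text report and a summary JSON embedding the
resolved configuration) into one directory, and is byte-identical across
reruns with the same configuration.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .config import PipelineConfig
from .erg import build_intensity_response, measure_waves, paired_t_test, relative_change
from .errors import NoSpikesError
from .popstats import (latency_contrast, render_report, significance_stars,
                       summarize_latencies)
from .profiles import classify, extract_profile, population_counts, spline_refine
from .sta import compute_sta, fit_rf
from .synth import make_checkerboard, make_population, simulate_erg

log = logging.getLogger("retinakit")

__all__ = ["run_pipeline", "analyze_population"]


def analyze_population(pairs, stim, config: PipelineConfig):
    """STA + RF fit + spline-refined profile for each (cell, train) pair.

    Returns (per-cell DataFrame, list of valid TemporalProfiles). Cells
    with no usable spikes are flagged, not fatal.
    """
    rows, valid_profiles = [], []
    for cell, train in pairs:
        row = {"cell_id": cell.cell_id, "condition": cell.condition,
               "true_polarity": cell.polarity,
               "true_latency_ms": cell.peak_latency_ms,
               "true_row": cell.spatial_center[0],
               "true_col": cell.spatial_center[1],
               "n_spikes": train.n_spikes}
        try:
            sta = compute_sta(stim, train, n_lags=config.n_lags,
                              window_ms=config.window_ms)
        except NoSpikesError:
            row.update(valid=False, flagged="no_usable_spikes")
            rows.append(row)
            continue
        fit = fit_rf(sta, z_min=config.z_min)
        profile = spline_refine(extract_profile(sta, fit))
        row.update(
            valid=bool(fit.valid), flagged="",
            peak_lag_index=fit.peak_lag_index,
            peak_row=fit.peak_pixel[0], peak_col=fit.peak_pixel[1],
            peak_value=fit.peak_value, peak_z=fit.peak_z,
            gauss_row=fit.gauss.center[0] if fit.gauss and fit.gauss.converged else np.nan,
            gauss_col=fit.gauss.center[1] if fit.gauss and fit.gauss.converged else np.nan,
            sigma_row=fit.gauss.sigmas[0] if fit.gauss and fit.gauss.converged else np.nan,
            sigma_col=fit.gauss.sigmas[1] if fit.gauss and fit.gauss.converged else np.nan,
            polarity=profile.polarity,
            cell_type="ON" if profile.polarity > 0 else "OFF",
            time_to_peak_ms=profile.time_to_peak_ms,
            time_to_zero_cross_ms=profile.time_to_zero_cross_ms)
        rows.append(row)
        if fit.valid:
            valid_profiles.append(profile)
    return pd.DataFrame(rows), valid_profiles


def _erg_branch(config: PipelineConfig, seed: int):
    """Simulate and measure the ERG grid for every configured profile."""
    measurements, change_rows = [], []
    for p_idx, profile in enumerate(config.erg_profiles):
        from .synth import ERG_CALIBRATION_POINTS
        intensities = ERG_CALIBRATION_POINTS[profile][0]
        per_condition = {}
        for c_idx, condition in enumerate(("control", "blocker")):
            for i_idx, intensity in enumerate(intensities):
                amps = []
                for rep in range(config.erg_replicates):
                    trace_seed = (seed + 7919 * p_idx + 104729 * c_idx
                                  + 1299709 * i_idx + rep) % (2**31 - 1)
                    trace = simulate_erg(intensity, condition=condition,
                                         species_profile=profile, seed=trace_seed,
                                         noise_sd_uv=config.erg_noise_sd_uv)
                    m = measure_waves(
                        trace, baseline_window_ms=config.erg_baseline_window_ms,
                        fit_halfwidth_ms=config.erg_fit_halfwidth_ms)
                    measurements.append({"species_profile": profile,
                                         **{k: getattr(m, k) for k in
                                            ("intensity_log", "condition",
                                             "a_amp_uv", "b_amp_uv",
                                             "a_time_ms", "b_time_ms",
                                             "baseline_uv")}})
                    if np.isfinite(m.b_amp_uv):
                        amps.append(m.b_amp_uv)
                per_condition[(condition, intensity)] = amps
        top = max(intensities)
        ctrl = per_condition[("control", top)]
        blk = per_condition[("blocker", top)]
        if ctrl and blk:
            change = relative_change(float(np.mean(blk)), float(np.mean(ctrl)))
            n_pair = min(len(ctrl), len(blk))
            t_res = paired_t_test(ctrl[:n_pair], blk[:n_pair])
            change_rows.append({"species_profile": profile, "intensity_log": top,
                                "b_change_percent": change,
                                "paired_t": t_res.t, "paired_p": t_res.p,
                                "stars": significance_stars(t_res.p)})
    return pd.DataFrame(measurements), pd.DataFrame(change_rows)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage and write the artifact directory. Returns the
    summary dictionary that is also serialized to ``summary.json``."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log.info("stage stimulate: %d frames at %g fps",
             int(config.duration_s * config.frame_rate_hz), config.frame_rate_hz)
    stim = make_checkerboard(config.seed,
                             frames=int(config.duration_s * config.frame_rate_hz),
                             grid_rows=config.grid_rows, grid_cols=config.grid_cols,
                             frame_rate_hz=config.frame_rate_hz,
                             checker_size_um=config.checker_size_um)
    rio.write_stimulus_descriptor(outdir / "stimulus.json", stim)

    all_rows, profiles_by_condition, trains = [], {}, []
    for c_idx, condition in enumerate(config.conditions):
        log.info("stage simulate: %s population (%d ON / %d OFF)",
                 condition, config.n_on, config.n_off)
        pairs = make_population(config.n_on, config.n_off, stim,
                                condition=condition,
                                seed=config.seed + 1000 * (c_idx + 1),
                                n_kernel_lags=config.n_lags)
        trains.extend(train for _, train in pairs)
        log.info("stage sta: fitting %d receptive fields", len(pairs))
        table, valid_profiles = analyze_population(pairs, stim, config)
        all_rows.append(table)
        profiles_by_condition[condition] = valid_profiles

    cells = pd.concat(all_rows, ignore_index=True)
    rio.write_spike_table(outdir / "spikes.tsv", trains)
    rio.write_table(cells, outdir / "rf_fits.tsv")

    log.info("stage classify: PCA + k-means")
    cluster_frames = []
    for condition, profs in profiles_by_condition.items():
        if not profs:
            continue
        results = classify(profs, k=config.k_clusters,
                           variance_cutoff=config.pca_variance_cutoff,
                           seed=config.seed)
        counts = population_counts(results,
                                   {r.cell_id: condition for r in results})
        cluster_frames.append(pd.DataFrame(
            [{"cell_id": r.cell_id, "condition": condition,
              "cluster_id": r.cluster_id, "cell_type": r.cell_type}
             for r in results]))
    clusters = (pd.concat(cluster_frames, ignore_index=True)
                if cluster_frames else pd.DataFrame())
    if not clusters.empty:
        rio.write_table(clusters, outdir / "clusters.tsv")

    log.info("stage stats: latency summaries and contrasts")
    valid_cells = cells[cells["valid"] == True]  # noqa: E712
    summary_table = summarize_latencies(valid_cells) if not valid_cells.empty else pd.DataFrame()
    contrast = (latency_contrast(summary_table, "control", "blocker")
                if {"control", "blocker"} <= set(config.conditions)
                and not summary_table.empty else pd.DataFrame())

    log.info("stage erg: %d profiles x %d replicates",
             len(config.erg_profiles), config.erg_replicates)
    erg_measurements, erg_changes = _erg_branch(config, config.seed)
    if not erg_measurements.empty:
        rio.write_table(erg_measurements, outdir / "erg_measurements.tsv")
        ir_frames = []
        for profile, grp in erg_measurements.groupby("species_profile"):
            from .erg import ERGMeasurement
            ms = [ERGMeasurement(intensity_log=r.intensity_log,
                                 condition=r.condition, baseline_uv=r.baseline_uv,
                                 b_amp_uv=r.b_amp_uv, b_found=np.isfinite(r.b_amp_uv))
                  for r in grp.itertuples()]
            ir = build_intensity_response(ms)
            ir.insert(0, "species_profile", profile)
            ir_frames.append(ir)
        rio.write_table(pd.concat(ir_frames, ignore_index=True),
                        outdir / "intensity_response.tsv")

    report_inputs = {"latency_summary": summary_table,
                     "latency_contrast": contrast,
                     "erg_b_change": erg_changes,
                     "config": config.to_dict()}
    render_report(report_inputs, outdir / "report.txt")

    summary = {
        "config": config.to_dict(),
        "n_cells": int(len(cells)),
        "n_valid": int(valid_cells.shape[0]),
        "latency_summary": summary_table.to_dict(orient="records"),
        "latency_contrast": contrast.to_dict(orient="records"),
        "erg_b_change": erg_changes.to_dict(orient="records"),
    }
    (outdir / "summary.json").write_text(
        json.dumps(summary, sort_keys=True, indent=2, default=_round_trip) + "\n")
    log.info("pipeline complete: %s", outdir)
    return summary


def _round_trip(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")
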