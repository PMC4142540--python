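"""Generator properties: determinism, distributions, and ground truth."""

import numpy as np
import pytest
from scipy import stats

from retinakit.errors import ParameterError
from retinakit.synth import (ERG_CALIBRATION_POINTS, GroundTruthCell,
                             biphasic_kernel, calibrate_intensity_response,
                             make_checkerboard, make_population, naka_rushton,
                             simulate_erg, simulate_ln_cell)


class TestCheckerboard:
    def test_deterministic_and_binary(self):
        a = make_checkerboard(1, frames=2, grid_rows=2, grid_cols=2)
        b = make_checkerboard(1, frames=2, grid_rows=2, grid_cols=2)
        assert np.array_equal(a.values, b.values)
        assert set(np.unique(a.values)) <= {-1, 1}

    def test_frame_interval_is_16_67_ms_at_60_fps(self):
        stim = make_checkerboard(0, frames=1)
        assert stim.frame_interval_ms == pytest.approx(16.67, abs=0.01)

    def test_checker_mean_is_zero_within_binomial_error(self):
        n = 100_000
        stim = make_checkerboard(5, frames=n, grid_rows=2, grid_cols=2)
        means = stim.values.astype(float).mean(axis=0)
        assert np.all(np.abs(means) < 3.0 / np.sqrt(n))

    @pytest.mark.parametrize("frames,rows,cols", [(0, 2, 2), (2, 0, 2), (2, 2, -1)])
    def test_non_positive_dims_rejected(self, frames, rows, cols):
        with pytest.raises(ParameterError):
            make_checkerboard(0, frames=frames, grid_rows=rows, grid_cols=cols)


class TestTemporalKernel:
    @pytest.mark.parametrize("latency", [35.0, 48.6, 67.36, 94.9, 120.0])
    @pytest.mark.parametrize("polarity", [1, -1])
    def test_dominant_extremum_sign_and_location(self, latency, polarity):
        cell = GroundTruthCell(cell_id="c", polarity=polarity,
                               spatial_center=(5, 5), peak_latency_ms=latency)
        t = np.linspace(0.5, 300.0, 3000)
        k = cell.temporal_kernel(t)
        i = np.argmax(np.abs(k))
        assert np.sign(k[i]) == polarity
        assert t[i] == pytest.approx(latency, abs=0.2)
        # biphasic: an opposite-sign lobe exists after the peak
        assert np.min(polarity * k) < -0.05


class TestLNSimulation:
    def test_zero_gain_is_homogeneous_poisson(self):
        """With no stimulus drive the spike count matches base_rate * T and
        the per-second counts pass a dispersion test against Poisson
        (<=1 failure at alpha=0.01 over 20 seeds)."""
        stim = make_checkerboard(3, frames=120 * 60, grid_rows=4, grid_cols=4)
        cell = GroundTruthCell(cell_id="c", polarity=1, spatial_center=(2, 2),
                               base_rate_hz=5.0, gain=0.0)
        failures = 0
        for seed in range(20):
            train = simulate_ln_cell(cell, stim, seed)
            expected = 5.0 * stim.duration_s
            assert abs(train.n_spikes - expected) < 3 * np.sqrt(expected)
            counts, _ = np.histogram(train.spike_times_s,
                                     bins=int(stim.duration_s))
            disp = (counts.size - 1) * counts.var(ddof=1) / counts.mean()
            p = stats.chi2.sf(disp, counts.size - 1)
            failures += int(min(p, 1 - p) < 0.005)
        assert failures <= 1

    def test_on_cell_spikes_follow_positive_contrast(self):
        """Brute-force conditional average: the stimulus at the RF center,
        one peak-latency before each spike, is positive for an ON cell."""
        stim = make_checkerboard(7, frames=120 * 60)
        cell = GroundTruthCell(cell_id="c", polarity=1, spatial_center=(9, 9),
                               peak_latency_ms=50.0, base_rate_hz=8.0, gain=2.0)
        train = simulate_ln_cell(cell, stim, 17)
        frames = np.floor(train.spike_times_s * 60).astype(int)
        lag = 3  # 50 ms / 16.67 ms
        frames = frames[frames >= lag]
        cond_mean = stim.values[frames - lag, 9, 9].astype(float).mean()
        assert cond_mean > 0.05

    def test_zero_duration_stimulus_rejected(self):
        cell = GroundTruthCell(cell_id="c", polarity=1, spatial_center=(1, 1))
        with pytest.raises(ParameterError):
            simulate_ln_cell(cell, make_checkerboard(0, frames=5, grid_rows=3,
                                                     grid_cols=3), 0)


class TestPopulation:
    def test_counts_types_and_determinism(self):
        stim = make_checkerboard(9, frames=120, grid_rows=9, grid_cols=9)
        pop = make_population(2, 8, stim, seed=4, center_margin=2.0)
        assert len(pop) == 10
        assert sum(c.polarity == -1 for c, _ in pop) == 8
        pop2 = make_population(2, 8, stim, seed=4, center_margin=2.0)
        for (c1, t1), (c2, t2) in zip(pop, pop2):
            assert c1 == c2
            assert np.array_equal(t1.spike_times_s, t2.spike_times_s)

    def test_latency_sample_means_match_configured_means(self):
        stim = make_checkerboard(9, frames=60, grid_rows=9, grid_cols=9)
        n = 150
        pop = make_population(n, n, stim, seed=8, center_margin=2.0)
        on = [c.peak_latency_ms for c, _ in pop if c.polarity == 1]
        off = [c.peak_latency_ms for c, _ in pop if c.polarity == -1]
        assert abs(np.mean(on) - 67.36) < 3 * 12.06 / np.sqrt(n)
        assert abs(np.mean(off) - 48.60) < 3 * 8.13 / np.sqrt(n)

    def test_negative_counts_rejected(self):
        stim = make_checkerboard(9, frames=60, grid_rows=9, grid_cols=9)
        with pytest.raises(ParameterError):
            make_population(-1, 5, stim)


class TestERGGenerator:
    @pytest.mark.parametrize("profile", sorted(ERG_CALIBRATION_POINTS))
    def test_calibration_hits_all_anchor_points(self, profile):
        params = calibrate_intensity_response(profile)
        log_i, amps = ERG_CALIBRATION_POINTS[profile]
        fitted = naka_rushton(10.0 ** np.asarray(log_i), *params)
        assert np.allclose(fitted, amps, rtol=1e-6)

    def test_degu_scotopic_top_intensity_b_amplitude(self):
        trace = simulate_erg(1.82, species_profile="degu_scotopic", seed=0,
                             noise_sd_uv=0.0)
        assert trace.ground_truth.b_amp_uv == pytest.approx(105.1, abs=0.2)

    def test_noiseless_trace_max_equals_ground_truth(self):
        trace = simulate_erg(0.52, species_profile="degu_scotopic", seed=0,
                             noise_sd_uv=0.0)
        post = trace.time_ms > 0
        assert trace.voltage_uv[post].max() == pytest.approx(
            trace.ground_truth.b_amp_uv, rel=1e-9)

    def test_blocker_scale_applied_to_ground_truth(self):
        trace = simulate_erg(1.82, condition="blocker",
                             species_profile="rat_scotopic", seed=0,
                             noise_sd_uv=0.0, b_scale=0.478)
        assert trace.ground_truth.b_amp_uv == pytest.approx(569.7 * 0.478,
                                                            rel=2e-3)

    def test_unknown_profile_and_out_of_range_intensity_rejected(self):
        with pytest.raises(ParameterError):
            simulate_erg(1.0, species_profile="hamster_scotopic")
        with pytest.raises(ParameterError):
            simulate_erg(3.5, species_profile="degu_scotopic")

    def test_noise_is_reproducible_under_seed(self):
        a = simulate_erg(1.82, seed=5)
        b = simulate_erg(1.82, seed=5)
        assert np.array_equal(a.voltage_uv, b.voltage_uv)
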