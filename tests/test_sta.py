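"""STA computation, peak finding, Gaussian fitting, and RF validity."""

import numpy as np
import pytest

from retinakit.errors import NoSpikesError, ParameterError
from retinakit.sta import (STAVolume, compute_sta, find_peak, fit_gaussian2d,
                           fit_rf, validate_rf, Gaussian2DFit)
from retinakit.synth import (GroundTruthCell, SpikeTrain, make_checkerboard,
                             simulate_ln_cell)


def _volume(values):
    values = np.asarray(values, dtype=float)
    return STAVolume(cell_id="v", values=values,
                     lag_times_ms=np.arange(1, values.shape[0] + 1) * 16.67,
                     n_spikes_used=1, n_spikes_excluded=0, frame_rate_hz=60.0)


class TestComputeSta:
    def test_default_window_has_18_laccording_frames(self):
        stim = make_checkerboard(1, frames=600, grid_rows=4, grid_cols=4)
        spikes = SpikeTrain("c", np.linspace(1.0, 9.0, 40), 10.0)
        sta = compute_sta(stim, spikes)
        assert sta.n_lags == 18
        assert sta.lag_times_ms[0] == pytest.approx(16.67, abs=0.01)
        assert sta.lag_times_ms[-1] == pytest.approx(300.0, abs=0.1)

    def test_single_spike_reproduces_preceding_frames(self):
        stim = make_checkerboard(2, frames=100, grid_rows=3, grid_cols=3)
        t_frame = 50
        spikes = SpikeTrain("c", np.array([(t_frame + 0.5) / 60.0]), 100 / 60.0)
        sta = compute_sta(stim, spikes, n_lags=4)
        for k in range(1, 5):
            assert np.array_equal(sta.values[k - 1], stim.values[t_frame - k])

    def test_early_spikes_excluded_from_average(self):
        stim = make_checkerboard(3, frames=100, grid_rows=3, grid_cols=3)
        spikes = SpikeTrain("c", np.array([0.01, 1.0]), 100 / 60.0)
        sta = compute_sta(stim, spikes, n_lags=18)
        assert sta.n_spikes_used == 1
        assert sta.n_spikes_excluded == 1

    def test_no_usable_spikes_raises_flaggable_error(self):
        stim = make_checkerboard(3, frames=100, grid_rows=3, grid_cols=3)
        spikes = SpikeTrain("c", np.array([0.01]), 100 / 60.0)
        with pytest.raises(NoSpikesError):
            compute_sta(stim, spikes, n_lags=18)

    def test_merged_train_sta_is_spike_weighted_mean(self):
        """Linearity: STA of a merged train equals the count-weighted mean
        of the component STAs, exactly."""
        stim = make_checkerboard(4, frames=2000, grid_rows=4, grid_cols=4)
        rng = np.random.default_rng(0)
        t_all = np.sort(rng.uniform(0.5, 30.0, 300))
        a, b = t_all[:100], t_all[100:]
        sta_a = compute_sta(stim, SpikeTrain("a", np.sort(a), 34.0))
        sta_b = compute_sta(stim, SpikeTrain("b", np.sort(b), 34.0))
        sta_m = compute_sta(stim, SpikeTrain("m", t_all, 34.0))
        na, nb = sta_a.n_spikes_used, sta_b.n_spikes_used
        merged = (na * sta_a.values + nb * sta_b.values) / (na + nb)
        assert np.allclose(sta_m.values, merged, atol=1e-12)

    def test_stimulus_independent_spikes_average_to_noise(self):
        """~5000 stimulus-independent spikes: every pixel of the volume
        stays within the binomial sampling bound for a +/-1 average."""
        stim = make_checkerboard(6, frames=6200 * 2)
        cell = GroundTruthCell(cell_id="null", polarity=1,
                               spatial_center=(9.0, 9.0),
                               base_rate_hz=5000 / stim.duration_s, gain=0.0)
        train = simulate_ln_cell(cell, stim, 42)
        sta = compute_sta(stim, train)
        assert sta.n_spikes_used > 4000
        assert np.max(np.abs(sta.values)) < 4.0 / np.sqrt(sta.n_spikes_used)


class TestFindPeak:
    def test_single_entry_located(self):
        v = np.zeros((6, 9, 9))
        v[3, 5, 5] = 0.9
        peak = find_peak(_volume(v))
        assert (peak.lag_index, peak.row, peak.col, peak.value) == (3, 5, 5, 0.9)

    def test_absolute_deviation_wins_regardless_of_sign(self):
        v = np.zeros((4, 5, 5))
        v[1, 2, 2] = 0.7
        v[2, 3, 3] = -0.8
        peak = find_peak(_volume(v))
        assert (peak.lag_index, peak.row, peak.col) == (2, 3, 3)
        assert peak.value == -0.8

    def test_ties_break_to_earliest_lag_then_row_major(self):
        v = np.zeros((3, 4, 4))
        v[0, 2, 1] = 0.5
        v[0, 1, 3] = -0.5
        v[2, 0, 0] = 0.5
        peak = find_peak(_volume(v))
        assert (peak.lag_index, peak.row, peak.col) == (0, 1, 3)

    def test_all_zero_volume_flagged_degenerate(self):
        peak = find_peak(_volume(np.zeros((3, 4, 4))))
        assert peak.degenerate


class TestGaussianFit:
    @staticmethod
    def _gaussian_frame(center, sigma=1.5, amp=1.0, shape=(15, 15)):
        rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
        return amp * np.exp(-(((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
                              / (2 * sigma**2)))

    def test_exact_gaussian_center_recovered(self):
        frame = self._gaussian_frame((7.25, 4.5))
        fit = fit_gaussian2d(frame, (7, 4))
        assert fit.converged
        assert fit.center[0] == pytest.approx(7.25, abs=1e-4)
        assert fit.center[1] == pytest.approx(4.5, abs=1e-4)

    def test_noisy_gaussian_center_error_below_fifth_checker(self):
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            frame = self._gaussian_frame((7.25, 4.5)) + rng.normal(0, 0.1, (15, 15))
            fit = fit_gaussian2d(frame, (7, 4))
            errs.append(np.hypot(fit.center[0] - 7.25, fit.center[1] - 4.5))
        assert np.median(errs) < 0.2

    def test_flat_frame_reports_non_convergence(self):
        fit = fit_gaussian2d(np.zeros((9, 9)), (4, 4))
        assert not fit.converged

    def test_small_frame_rejected(self):
        with pytest.raises(ParameterError):
            fit_gaussian2d(np.zeros((2, 5)), (0, 0))


class TestValidity:
    def _good_gauss(self, **kw):
        defaults = dict(center=(5.0, 5.0), sigmas=(1.2, 1.2), amplitude=0.2,
                        offset=0.0, rss=0.1, converged=True)
        defaults.update(kw)
        return Gaussian2DFit(**defaults)

    def test_threshold_is_inclusive(self):
        gauss = self._good_gauss()
        assert validate_rf(4.0, gauss, (19, 19), peak_pixel=(5, 5),
                           peak_value=0.2)
        assert not validate_rf(3.999, gauss, (19, 19), peak_pixel=(5, 5),
                               peak_value=0.2)

    def test_unresolvable_or_oversized_sigma_rejected(self):
        for sigmas in [(0.3, 1.2), (1.2, 12.0)]:
            gauss = self._good_gauss(sigmas=sigmas)
            assert not validate_rf(8.0, gauss, (19, 19), peak_pixel=(5, 5),
                                   peak_value=0.2)

    def test_fit_must_account_for_the_peak(self):
        gauss = self._good_gauss(amplitude=0.05)
        assert not validate_rf(8.0, gauss, (19, 19), peak_pixel=(5, 5),
                               peak_value=0.2)
        gauss = self._good_gauss(amplitude=-0.2)
        assert not validate_rf(8.0, gauss, (19, 19), peak_pixel=(5, 5),
                               peak_value=0.2)

    def test_strong_cells_are_valid(self, strong_on, strong_off):
        assert strong_on["fit"].valid
        assert strong_off["fit"].valid

    def test_shuffled_spikes_rarely_validate(self, stim300):
        """Time-shuffled (stimulus-independent) spikes should essentially
        never yield a valid RF."""
        n_valid = 0
        for seed in range(10):
            cell = GroundTruthCell(cell_id="n", polarity=1,
                                   spatial_center=(9.0, 9.0),
                                   base_rate_hz=8.0, gain=0.0)
            train = simulate_ln_cell(cell, stim300, 300 + seed)
            n_valid += int(fit_rf(compute_sta(stim300, train)).valid)
        assert n_valid <= 1


class TestRecovery:
    def test_ln_cell_center_within_one_checker(self, strong_on, strong_off):
        for fx in (strong_on, strong_off):
            true = fx["cell"].spatial_center
            got = fx["fit"].gauss.center
            assert np.hypot(got[0] - true[0], got[1] - true[1]) < 1.0

    def test_peak_sign_matches_polarity(self, strong_on, strong_off):
        assert strong_on["fit"].peak_value > 0
        assert strong_off["fit"].peak_value < 0
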