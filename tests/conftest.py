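import numpy as np
import pytest

from retinakit.profiles import extract_profile, spline_refine
from retinakit.sta import compute_sta, fit_rf
from retinakit.synth import GroundTruthCell, make_checkerboard, simulate_ln_cell


@pytest.fixture(scope="session")
def stim300():
    """Five-minute default checkerboard shared by the slower STA tests."""
    return make_checkerboard(11, frames=300 * 60)


def _analyzed_cell(stim, polarity, latency, base_rate, seed):
    cell = GroundTruthCell(
        cell_id=f"{'on' if polarity > 0 else 'off'}_fixture",
        polarity=polarity, spatial_center=(9.3, 7.7),
        peak_latency_ms=latency, base_rate_hz=base_rate)
    train = simulate_ln_cell(cell, stim, seed)
    sta = compute_sta(stim, train)
    fit = fit_rf(sta)
    profile = spline_refine(extract_profile(sta, fit))
    return {"cell": cell, "train": train, "sta": sta, "fit": fit,
            "profile": profile}


@pytest.fixture(scope="session")
def strong_on(stim300):
    return _analyzed_cell(stim300, +1, 67.0, 8.2, seed=21)


@pytest.fixture(scope="session")
def strong_off(stim300):
    return _analyzed_cell(stim300, -1, 48.6, 6.2, seed=22)
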