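import numpy as np
import pytest

import syndyn as sd
from syndyn.synthetic_data import design_preset, fixture


@pytest.fixture(scope="session")
def theta_ctrl():
    return fixture("theta_ctrl").params


@pytest.fixture(scope="session")
def theta_mut():
    return fixture("theta_mut").params


@pytest.fixture(scope="session")
def fate_schedule():
    return sd.ImagingSchedule((0.0, 6.0, 12.0, 24.0, 48.0, 72.0))


def make_counts(params, preset_name, seed):
    """Simulate a study and reduce it to lifetime-category counts."""
    preset = design_preset(preset_name)
    tracks = sd.simulate_study(params, preset.sim_design(seed))
    presence = sd.observe(tracks, preset.schedule)
    return sd.lifetime_categories(presence)


@pytest.fixture(scope="session")
def recovery_fits(theta_ctrl, theta_mut):
    """Paired two-state fits on large_recovery data, seeds 1-3.

    The expensive shared resource: six simulate+fit runs reused by the
    inference recovery tests and by acceptance criteria 4-7 and 9.
    Mutant datasets use seed offset 10000 so the pairs are independent.
    """
    out = {}
    for seed in (1, 2, 3):
        counts_ctrl = make_counts(theta_ctrl, "large_recovery", seed)
        counts_mut = make_counts(theta_mut, "large_recovery", seed + 10_000)
        out[seed] = {
            "counts_ctrl": counts_ctrl,
            "fit_ctrl": sd.fit("two_state", counts_ctrl),
            "fit_mut": sd.fit("two_state", counts_mut),
        }
    return out


@pytest.fixture(scope="session")
def small_recovery_fits(theta_ctrl):
    """Two-state fits at total length 2e4 µm (seeds 401-403), for bias checks."""
    out = {}
    for seed in (401, 402, 403):
        design = sd.SimDesign(2, 1, 1e4, 72.0, seed=seed)
        tracks = sd.simulate_study(theta_ctrl, design)
        schedule = sd.ImagingSchedule((0, 6, 12, 24, 48, 72))
        counts = sd.lifetime_categories(sd.observe(tracks, schedule))
        out[seed] = sd.fit("two_state", counts)
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260904)
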