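"""Shared fixtures: small synthetic acquisitions generated once per session."""

import numpy as np
import pytest

from conetrack import SimulationConfig, make_schedule, simulate_sequence

PX = 0.211


@pytest.fixture(scope="session")
def burst_schedule():
    """One canonical burst: 33 frames at 2-s intervals."""
    return make_schedule(33, 2.0, 600.0, 1, PX)


@pytest.fixture(scope="session")
def full_schedule():
    """The full protocol: 4 bursts every 10 min over 30 min."""
    return make_schedule(33, 2.0, 600.0, 4, PX)


@pytest.fixture(scope="session")
def default_sim(burst_schedule):
    """One burst at default (study-condition) settings, seed fixed."""
    config = SimulationConfig(seed=1)
    stack, truth = simulate_sequence(config, burst_schedule)
    return config, stack, truth


@pytest.fixture(scope="session")
def clean_sim(burst_schedule):
    """Noise-free burst (no shot noise, no read noise)."""
    config = SimulationConfig(seed=1, poisson_noise=False,
                              read_noise_sigma=0.0)
    stack, truth = simulate_sequence(config, burst_schedule)
    return config, stack, truth


@pytest.fixture(scope="session")
def migration_sim(full_schedule):
    """Four bursts with the cone extending at 0.25 μm/min."""
    config = SimulationConfig(seed=1, migration_velocity_um_min=0.25)
    stack, truth = simulate_sequence(config, full_schedule)
    return config, stack, truth


@pytest.fixture
def rectangle_mask():
    """Axis-aligned 40 × 10 px filled rectangle."""
    mask = np.zeros((30, 60), dtype=bool)
    mask[10:20, 5:45] = True
    return mask
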