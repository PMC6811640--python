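"""Shared fixtures: small simulated cohorts with known ground truth."""

import numpy as np
import pytest
from hypothesis import settings

from bleachnum.io import traces_from_frame
from bleachnum.simulate import (
    CellParams,
    NoiseParams,
    add_noise,
    default_times,
    simulate_cohort,
    simulate_pools,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """30 heterogeneous cells at x0 = 1e4 with realistic noise."""
    df, truth = simulate_cohort(30, 1e4, seed=101)
    return traces_from_frame(df), truth


@pytest.fixture()
def single_pool_trace():
    """One single-pool trace with known parameters and constant noise."""
    cell = CellParams(lambda1=4e-3, lambda2=0.0, x0=2000, alpha=0.0)
    noise = NoiseParams(nu=20.0, sigma_e0=136.6)
    times = default_times(45)
    rng = np.random.default_rng(11)
    latent = simulate_pools(cell, times, rng)
    y = add_noise(latent.total, cell, noise, rng)
    return times, y, cell, noise, latent
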