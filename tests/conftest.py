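"""Shared simulated acquisitions (session-scoped: the simulator is the
expensive part of the suite, and these fixtures are pure functions of their
seeds)."""

import numpy as np
import pytest

from respigate.phantom_sim import PhantomConfig, simulate_acquisition
from respigate.trajectory import TrajectoryConfig


@pytest.fixture(scope="session")
def small_acq():
    """One minute of free breathing: 24,000 spokes, 48^3 grid, 4 mm voxels."""
    traj = TrajectoryConfig(
        n_spokes_total=24_000, si_every=25, matrix=48, n_readout=48, voxel_mm=4.0
    )
    phantom = PhantomConfig(seed=1, duration=60.0)
    return simulate_acquisition(traj, phantom)


@pytest.fixture(scope="session")
def static_acq():
    """Motionless, noiseless phantom (no breathing, no contraction, no jitter)."""
    traj = TrajectoryConfig(
        n_spokes_total=500, si_every=25, matrix=32, n_readout=32, voxel_mm=6.0
    )
    phantom = PhantomConfig(
        seed=5,
        duration=2.0,
        resp_amp_mean=1e-9,
        resp_amp_sd=0.0,
        resp_period_sd=0.0,
        septal_shift_fraction=0.0,
        rr_sd=0.0,
        cardiac_contraction=0.0,
        noise_sd=0.0,
        bellows_lag=0.0,
        bellows_cutoff_hz=0.0,
    )
    return simulate_acquisition(traj, phantom)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
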