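"""Shared fixtures: small deterministic trajectories and TPMs."""

import math

import numpy as np
import pytest

from flockphi.trajectory import Trajectory


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def straight_pair():
    """Two individuals moving uniformly along +x, 50 mm apart in y."""
    steps = 12
    t = np.arange(steps, dtype=float)
    positions = np.empty((steps, 2, 2))
    positions[:, 0] = np.stack([100 + 10 * t, np.full(steps, 100.0)], axis=1)
    positions[:, 1] = np.stack([100 + 10 * t, np.full(steps, 150.0)], axis=1)
    return Trajectory(frames=np.arange(steps), positions=positions, frame_rate=20.0, ids=(1, 2))


@pytest.fixture()
def circular_motion():
    """One individual on a circle, one far away and static-ish."""
    steps = 40
    omega = 0.5  # rad per step
    t = np.arange(steps, dtype=float)
    positions = np.empty((steps, 2, 2))
    positions[:, 0, 0] = 500 + 200 * np.cos(omega * t)
    positions[:, 0, 1] = 500 + 200 * np.sin(omega * t)
    positions[:, 1, 0] = 2500 + 5 * t
    positions[:, 1, 1] = 2000.0
    return Trajectory(frames=np.arange(steps), positions=positions, frame_rate=20.0, ids=(1, 2))


@pytest.fixture(scope="session")
def random_tpm3(rng):
    return rng.random((8, 3))
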