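"""Shared fixtures: small trajectories, toy landscapes, simulated cohorts."""

import numpy as np
import pandas as pd
import pytest

from translocmove.raster import CLASS_CODES, LandscapeRaster
from translocmove.trajectory import AnimalMeta, PreprocessConfig, Trajectory

T0 = pd.Timestamp("2023-04-01 00:00:00", tz="UTC")


def make_traj(xy, start=T0, interval_h=2.0, meta=None, pdop=None):
    """Trajectory from an (n, 2) coordinate array at a fixed cadence."""
    xy = np.asarray(xy, float)
    n = len(xy)
    t = start + pd.to_timedelta(np.arange(n) * interval_h, unit="h")
    fixes = pd.DataFrame({
        "t": t, "x": xy[:, 0], "y": xy[:, 1],
        "pdop": pdop if pdop is not None else np.full(n, 2.0),
    })
    meta = meta or AnimalMeta("test", "resident")
    return Trajectory(meta, fixes)


def brownian_track(sigma_m2, n, dt_s=7200.0, seed=0, origin=(0.0, 0.0)):
    """Pure Brownian motion at fixed cadence (no telemetry noise added)."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, np.sqrt(sigma_m2 * dt_s), size=(n - 1, 2))
    xy = np.vstack([origin, origin + np.cumsum(steps, axis=0)])
    return xy


@pytest.fixture
def stationary_traj():
    """60 fixes all at the origin (movement indistinguishable from noise)."""
    return make_traj(np.zeros((60, 2)))


@pytest.fixture
def uniform_landscape():
    """Single-class (bottomland) 200x200 grid of 30-m cells."""
    grid = np.full((200, 200), CLASS_CODES["bottomland"], dtype=np.int16)
    return LandscapeRaster(origin=(0.0, 0.0), cell_size=30.0, grid=grid)


@pytest.fixture
def split_landscape():
    """Left half bottomland, right half upland pine; 200x200 30-m cells."""
    grid = np.full((200, 200), CLASS_CODES["bottomland"], dtype=np.int16)
    grid[:, 100:] = CLASS_CODES["upland_pine"]
    return LandscapeRaster(origin=(0.0, 0.0), cell_size=30.0, grid=grid)


@pytest.fixture(scope="session")
def small_cohort():
    """A small seeded cohort reused by several integration tests."""
    from translocmove.synthetic import SimConfig, simulate_cohort

    cfg = SimConfig(
        seed=11, n_resident=3, n_translocated=3, n_translocated_upland=2,
        horizon_days=35, switch_day=18, extent_m=15_000.0,
        homecoming_prob=0.0,
    )
    return simulate_cohort(cfg)
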