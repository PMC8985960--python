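"""Shared fixtures: default fixture geometry, acquisitions, simulated fields."""

from __future__ import annotations

import warnings

import hypothesis
import numpy as np
import pytest

from swetof import (
    AcquisitionConfig,
    FixtureGeometry,
    SimulationTruth,
    estimate_sws,
    simulate_velocity_field,
)

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("suite")


@pytest.fixture(scope="session")
def geometry() -> FixtureGeometry:
    return FixtureGeometry()


@pytest.fixture(scope="session")
def acquisition() -> AcquisitionConfig:
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def clean_field_1p0(geometry, acquisition):
    """Noise-free default-geometry field at 1.0 m/s."""
    return simulate_velocity_field(
        geometry, acquisition, SimulationTruth(true_sws=1.0, noise_sigma=0.0)
    )


@pytest.fixture(scope="session")
def noise_field(geometry, acquisition):
    """A field of pure measurement noise (no wave content at all)."""
    rng = np.random.default_rng(7)
    z = geometry.focal_length + np.arange(-5.0, 4.001, 0.05)
    t = np.arange(acquisition.n_frames) * acquisition.frame_interval_ms
    from swetof import VelocityField

    return VelocityField(
        values=rng.standard_normal((z.size, t.size)),
        depth_axis_mm=z,
        time_axis_ms=t,
        geometry=geometry,
        acquisition=acquisition,
    )


@pytest.fixture(scope="session")
def grid_estimates(geometry, acquisition):
    """Noise-free simulate -> estimate over the 0.4-1.8 m/s grid (shared by
    the recovery, separability and monotonicity checks)."""
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for c in np.round(np.arange(0.4, 1.801, 0.1), 10):
            field = simulate_velocity_field(
                geometry, acquisition, SimulationTruth(true_sws=float(c), noise_sigma=0.0)
            )
            out[float(c)] = estimate_sws(field)
    return out
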