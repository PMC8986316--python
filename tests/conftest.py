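"""Shared fixtures: steady-state particle simulations reused across the
suite.

The simulations use the standard physical conditions (D = 1 µm²/s,
v = 1 µm/s, Δt = 0.001 s, N = 1000) with recording windows long enough
that the half-window convergence diagnostic is satisfied; recording
lengths scale with the cell's diffusive relaxation time. They are
session-scoped because several tests interrogate the same steady
state.
"""

from __future__ import annotations

import pytest

from polargrad.brownian import SimConfig, SimResult, run
from polargrad.geometry import CellGeometry


def run_sphere(
    R: float,
    seed: int,
    T: float,
    burn: float,
    snapshot: float = 0.5,
    **kwargs,
) -> SimResult:
    g = CellGeometry.sphere(R)
    cfg = SimConfig(
        T_total=T,
        burn_in=burn,
        seed=seed,
        snapshot_interval=snapshot,
        **kwargs,
    )
    return run(cfg, g)


@pytest.fixture(scope="session")
def sphere_sim_R10() -> SimResult:
    """Reference run: sphere R = 10 µm, perfect absorption."""
    return run_sphere(10, seed=1, T=600.0, burn=150.0, snapshot=1.0)


@pytest.fixture(scope="session")
def sphere_sims_scaled(sphere_sim_R10) -> dict[float, SimResult]:
    """Perfect-absorption runs for R ∈ {5, 10, 20} µm."""
    return {
        5: run_sphere(5, seed=2, T=240.0, burn=80.0),
        10: sphere_sim_R10,
        20: run_sphere(20, seed=3, T=500.0, burn=150.0, snapshot=1.0),
    }


@pytest.fixture(scope="session")
def detachment_sims() -> dict[float, SimResult]:
    """Sphere R = 10 with detachment, t_bound ∈ {1, 0.3, 0.1} s."""
    return {
        tb: run_sphere(10, seed=4 + i, T=250.0, burn=70.0, t_bound=tb)
        for i, tb in enumerate((1.0, 0.3, 0.1))
    }


@pytest.fixture(scope="session")
def detachment_scaled(detachment_sims) -> dict[float, SimResult]:
    """t_bound = 1 s runs for R ∈ {5, 10, 20} µm."""
    return {
        5: run_sphere(5, seed=10, T=240.0, burn=80.0, t_bound=1.0),
        10: detachment_sims[1.0],
        20: run_sphere(20, seed=11, T=500.0, burn=150.0, snapshot=1.0, t_bound=1.0),
    }


@pytest.fixture(scope="session")
def detachment_limit_sim() -> SimResult:
    """t_bound = Δt: detachment within the capture step (the γ → ∞ limit)."""
    return run_sphere(10, seed=8, T=150.0, burn=50.0, t_bound=0.001)


@pytest.fixture(scope="session")
def reflecting_sim() -> SimResult:
    """kon = 0: fully reflecting surface, the no-gradient control."""
    return run_sphere(10, seed=9, T=150.0, burn=50.0, kon=0.0)
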