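"""Shared fixtures.

Expensive simulations (full-duration vertex-model runs, ring-collapse
equilibria) are session-scoped so that unit, property and acceptance tests
share a single computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from epitube import tube_collapse as tc
from epitube.synthetic import make_honeycomb
from epitube.vertex_model import VertexModelParams, run_simulation


def run_vertex(seed: int, boundary_force: float = 0.0, **overrides):
    params = VertexModelParams(seed=seed, boundary_force=boundary_force,
                               **overrides)
    mesh, states = make_honeycomb(100, 1.0, seed=seed, params=params)
    return run_simulation(mesh, states, params)


@pytest.fixture(scope="session")
def unforced_runs():
    """Five calibrated, unforced full-duration simulations (one per seed)."""
    return [run_vertex(seed) for seed in range(1, 6)]


@pytest.fixture(scope="session")
def forced_runs():
    """Five simulations with the 1 a.u. longitudinal boundary force."""
    return [run_vertex(seed, boundary_force=1.0) for seed in range(1, 6)]


@pytest.fixture(scope="session")
def clamp_result():
    mat = tc.MaterialParams()
    ring = tc.make_ring(1.0, 100, mat=mat)
    return tc.simulate_collapse(ring, mat, tc.LoadScenario(kind="clamps"),
                                max_time=4000, speed_tol=1e-6)


@pytest.fixture(scope="session")
def volume_result():
    mat = tc.MaterialParams()
    ring = tc.make_ring(1.0, 100, mat=mat)
    return tc.simulate_collapse(ring, mat, tc.LoadScenario(kind="volume"),
                                max_time=4000, speed_tol=1e-6)


@pytest.fixture(scope="session")
def pressure_result():
    mat = tc.MaterialParams()
    ring = tc.make_ring(1.0, 100, mat=mat)
    return tc.simulate_collapse(ring, mat, tc.LoadScenario(kind="pressure"),
                                max_time=4000, speed_tol=1e-6)


@pytest.fixture(scope="session")
def thin_ring_buckling():
    """Buckling of a thin ring (t/R = 0.1), the regime of the classical law."""
    mat = tc.MaterialParams(thickness_ratio=0.1)
    ring = tc.make_ring(1.0, 100, mat=mat)
    pcr = tc.critical_pressure(mat, 1.0)
    sc = tc.LoadScenario(kind="pressure", pressure_rate=pcr / 300.0,
                         max_pressure=3 * pcr)
    res = tc.simulate_collapse(ring, mat, sc, max_time=3000, speed_tol=1e-6)
    return res, pcr
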