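"""Shared fixtures.

The two expensive dynamics runs (a thermostatted pure-water box and the
scaled-down bilayer self-assembly) are session-scoped so that the unit and
integration tests share one trajectory each.
"""
from __future__ import annotations

import numpy as np
import pytest

from lipiddpd import (InitSpec, LipidTemplate, RunParams, SystemState,
                      TrajectoryRecorder, default_interactions, init_state,
                      run, water_topology)


@pytest.fixture(scope="session")
def interactions():
    return default_interactions()


@pytest.fixture
def template_pair():
    return LipidTemplate(1, 3, 4), LipidTemplate(2, 3, 9)


def make_water_state(L: float, rho: float = 3.0, seed: int = 0,
                     kBT: float = 1.0) -> SystemState:
    rng = np.random.default_rng(seed)
    n = int(round(rho * L ** 3))
    pos = rng.uniform(0.0, L, (n, 3))
    vel = rng.normal(0.0, np.sqrt(kBT), (n, 3))
    vel -= vel.mean(axis=0)
    return SystemState(L, pos, vel, water_topology(n))


@pytest.fixture(scope="session")
def water_run(interactions):
    """Pure-water box L = 8, rho = 3, a = 25, dt = 0.01: 5000 steps with the
    default thermostat, recording every 10th report (every 100 steps)."""
    state = make_water_state(8.0, seed=4)
    params = RunParams(n_steps=5000, seed=4, report_every=10)
    rec = TrajectoryRecorder(every=10)
    trace = run(state, params, interactions, observers=[rec])
    return state, trace, rec.frames


@pytest.fixture(scope="session")
def membrane_run(interactions):
    """Scaled-down self-assembly: lamellar start, L = 12, 60 + 60 lipids with
    tail lengths 4 and 9, 30 000 steps; keeps a frame every 1000 steps."""
    t1 = LipidTemplate(1, 3, 4)
    t2 = LipidTemplate(2, 3, 9)
    state = init_state(InitSpec("lamella", 60, 60, 12.0, seed=11), t1, t2)
    params = RunParams(n_steps=30000, seed=11, report_every=100)
    rec = TrajectoryRecorder(every=10)
    trace = run(state, params, interactions, observers=[rec])
    return state, trace, rec.frames
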