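"""Integrator and thermostat: fluctuation-dissipation, energy conservation
in the deterministic limit, momentum conservation, determinism."""
import numpy as np
import pytest

from lipiddpd import RunParams, SystemState, run, water_topology

from conftest import make_water_state


def test_fluctuation_dissipation_sigma_from_gamma():
    p = RunParams(n_steps=1, gamma=4.5, kBT=1.0)
    assert p.sigma == 3.0          # sqrt(2 * 4.5 * 1) exactly


def test_fluctuation_dissipation_gamma_from_sigma():
    p = RunParams(n_steps=1, gamma=None, sigma=2.0, kBT=1.0)
    assert p.gamma == pytest.approx(2.0, abs=1e-15)


def test_inconsistent_sigma_gamma_rejected():
    with pytest.raises(ValueError, match="fluctuation-dissipation"):
        RunParams(n_steps=1, gamma=4.5, sigma=2.0)


def _bonded_pair_state():
    top = water_topology(2)
    top.bond_idx = np.array([[0, 1]])
    top.bond_ks = np.array([100.0])
    top.bond_rs = np.array([0.7])
    pos = np.array([[2.0, 2.0, 2.0], [2.9, 2.0, 2.0]])  # stretched bond
    vel = np.array([[0.0, 0.1, 0.0], [0.0, -0.1, 0.0]])
    return SystemState(6.0, pos, vel, top)


def test_symplectic_limit_energy_conservation(interactions):
    """With the thermostat off the integrator is velocity Verlet: the
    total energy of a bonded pair oscillates with bounded amplitude but
    its windowed mean drifts < 1e-4 relative over 1e4 steps."""
    st = _bonded_pair_state()
    params = RunParams(n_steps=10_000, gamma=0.0, sigma=0.0, seed=0,
                       report_every=1)
    trace = run(st, params, interactions)
    # total energy per bead: potential + kinetic (K/N = 1.5 T_kin)
    e_tot = trace.e_per_bead + 1.5 * trace.t_kin
    first = e_tot[1:501].mean()
    last = e_tot[-500:].mean()
    assert abs(last - first) / abs(first) < 1e-4
    # and the instantaneous fluctuation stays bounded (no secular growth)
    assert np.ptp(e_tot[1:]) < 0.01 * abs(first)


def test_momentum_conservation(interactions):
    st = make_water_state(5.0, seed=2)
    params = RunParams(n_steps=2000, seed=2, report_every=500)
    run(st, params, interactions)
    assert np.abs(st.momentum()).max() < 1e-8


def test_same_seed_bit_identical_trajectories(interactions):
    a = make_water_state(5.0, seed=6)
    b = a.copy()
    params = RunParams(n_steps=300, seed=9, report_every=100)
    run(a, params, interactions)
    run(b, params, interactions)
    assert np.array_equal(a.positions, b.positions)
    assert np.array_equal(a.velocities, b.velocities)


def test_zero_steps_is_identity(interactions):
    st = make_water_state(4.0, seed=1)
    pos0, vel0 = st.positions.copy(), st.velocities.copy()
    trace = run(st, RunParams(n_steps=0, seed=1), interactions)
    assert len(trace) == 0
    assert np.array_equal(st.positions, pos0)
    assert np.array_equal(st.velocities, vel0)


def test_nonfinite_state_aborts_with_bead_diagnostic(interactions):
    st = make_water_state(4.0, seed=3)
    st.velocities[17, 0] = np.inf
    with pytest.raises(RuntimeError, match="bead 17"):
        run(st, RunParams(n_steps=5, seed=1, report_every=5), interactions)


def test_thermostat_temperature(water_run):
    """Kinetic temperature of the equilibrated water box is 1.00 +- 0.03."""
    _, trace, _ = water_run
    second_half = trace.t_kin[len(trace) // 2:]
    assert np.mean(second_half) == pytest.approx(1.0, abs=0.03)


def test_temperature_uniform_across_slabs(water_run):
    """Per-slab kinetic temperature is uniform within sampling error."""
    _, _, frames = water_run
    n_bins = 8
    L = frames[0].box
    per_frame = []
    for st in frames[len(frames) // 2:]:
        b = np.minimum((st.positions[:, 2] / (L / n_bins)).astype(int),
                       n_bins - 1)
        v2 = (st.velocities ** 2).sum(axis=1)
        t_slab = np.array([v2[b == k].mean() / 3.0 for k in range(n_bins)])
        per_frame.append(t_slab)
    per_frame = np.array(per_frame)
    mean = per_frame.mean(axis=0)
    se = per_frame.std(axis=0, ddof=1) / np.sqrt(per_frame.shape[0])
    # every slab within 5 standard errors of the global mean
    assert np.all(np.abs(mean - mean.mean()) < 5.0 * se + 1e-3)


def test_energy_trace_reports(interactions):
    st = make_water_state(4.0, seed=5)
    trace = run(st, RunParams(n_steps=250, seed=5, report_every=100),
                interactions)
    assert list(trace.step) == [0, 100, 200, 250]
    assert np.allclose(trace.time, np.array([0, 100, 200, 250]) * 0.01)
    assert np.all(np.isfinite(trace.e_per_bead))
    df = trace.to_dataframe()
    assert list(df.columns) == ["step", "time_tau", "E_pair", "E_bond",
                                "E_angle", "E_per_bead", "T_kin"]
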