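"""Force correctness: weight function, finite-difference gradients,
Newton's third law, and the cell-list vs all-pairs oracle."""
import math

import numpy as np
import pytest

from lipiddpd import (LipidTemplate, RunParams, SystemState,
                      build_system_topology, default_interactions,
                      bonded_forces, pair_forces, water_topology, weight)

NO_NOISE = dict(gamma=0.0, sigma=0.0)


@pytest.mark.parametrize("r, rc, w", [(0.0, 1.0, 1.0), (1.0, 1.0, 0.0),
                                      (0.25, 1.0, 0.75), (2.0, 1.0, 0.0),
                                      (0.5, 2.0, 0.75)])
def test_weight_function(r, rc, w):
    assert weight(r, rc) == pytest.approx(w, abs=1e-15)


def _two_bead_state(r):
    top = water_topology(2)
    pos = np.array([[1.0, 1.0, 1.0], [1.0 + r, 1.0, 1.0]])
    return SystemState(5.0, pos, np.zeros((2, 3)), top)


def test_conservative_force_two_beads(interactions):
    """a = 25 at half overlap gives |F| = a w = 12.5 on each bead."""
    st = _two_bead_state(0.5)
    p = RunParams(n_steps=0, **NO_NOISE)
    f = pair_forces(st, p, interactions).forces
    assert f[0] == pytest.approx([-12.5, 0.0, 0.0], abs=1e-12)
    assert f[1] == pytest.approx([12.5, 0.0, 0.0], abs=1e-12)


def test_newtons_third_law_with_noise(interactions):
    """Net force vanishes to round-off even with the random force on
    (shared zeta per pair)."""
    rng = np.random.default_rng(1)
    top = water_topology(200)
    st = SystemState(4.0, rng.uniform(0, 4, (200, 3)),
                     rng.normal(size=(200, 3)), top)
    p = RunParams(n_steps=0, seed=3)
    f = pair_forces(st, p, interactions, step_index=17).forces
    assert np.abs(f.sum(axis=0)).max() < 1e-10


def test_conservative_force_matches_energy_gradient(interactions):
    """-dU_C/dr at 20 random separations by central finite differences."""
    p = RunParams(n_steps=0, **NO_NOISE)
    rng = np.random.default_rng(2)
    h = 1e-6
    for r in rng.uniform(0.05, 0.99, 20):
        f = pair_forces(_two_bead_state(r), p, interactions).forces[1, 0]
        up = pair_forces(_two_bead_state(r + h), p, interactions).e_pair
        um = pair_forces(_two_bead_state(r - h), p, interactions).e_pair
        fd = -(up - um) / (2 * h)
        assert abs(fd - f) <= 1e-6 * max(1.0, abs(f))


def _lipid_state(rng, n_head=3, n_tail=4, L=12.0):
    """One lipid with a random-walk conformation kept inside the primary
    box (so torques about the centroid are meaningful)."""
    t1 = LipidTemplate(1, n_head, n_tail)
    top = build_system_topology(t1, LipidTemplate(2, n_head, n_tail), 1, 0, 0)
    pos = 6.0 + np.cumsum(rng.normal(0.0, 0.3, (top.n_beads, 3)), axis=0)
    assert pos.min() > 0.5 and pos.max() < L - 0.5
    return SystemState(L, pos, np.zeros((top.n_beads, 3)), top)


def test_bond_force_zero_at_rest_length():
    top = build_system_topology(LipidTemplate(1, 1, 1),
                                LipidTemplate(2, 1, 1), 0, 0, 2)
    # manually bond the two beads at the rest length
    st = _two_bead_state(0.7)
    st.topology.bond_idx = np.array([[0, 1]])
    st.topology.bond_ks = np.array([100.0])
    st.topology.bond_rs = np.array([0.7])
    f = bonded_forces(st)
    assert np.abs(f.forces).max() < 1e-12
    assert f.e_bond == pytest.approx(0.0, abs=1e-15)


def test_angle_force_zero_at_equilibrium():
    """Straight triple with theta0 = pi exerts no bending force."""
    top = build_system_topology(LipidTemplate(1, 3, 1),
                                LipidTemplate(2, 3, 1), 1, 0, 0)
    pos = np.zeros((5, 3))
    pos[:, 2] = [1.0, 1.7, 2.4, 3.1, 3.1]   # head chain straight along z
    pos[3] = [0.3, 0.0, 3.1]
    pos[4] = [-0.3, 0.0, 3.1]
    st = SystemState(8.0, pos + 4.0, np.zeros((5, 3)), top)
    # keep only the intra-chain (head) angle, which is exactly straight,
    # and drop the bonds (the tails sit off the rest length)
    keep = st.topology.angle_class == 0
    st.topology.angle_idx = st.topology.angle_idx[keep]
    st.topology.angle_k = st.topology.angle_k[keep]
    st.topology.angle_theta0 = st.topology.angle_theta0[keep]
    st.topology.bond_idx = st.topology.bond_idx[:0]
    st.topology.bond_ks = st.topology.bond_ks[:0]
    st.topology.bond_rs = st.topology.bond_rs[:0]
    f = bonded_forces(st)
    assert np.abs(f.forces).max() < 1e-10


def test_bonded_forces_match_finite_difference():
    """Bond + angle forces equal -grad of the bonded energy on 20 random
    lipid conformations to 1e-6 relative."""
    rng = np.random.default_rng(5)
    h = 1e-6
    for _ in range(20):
        st = _lipid_state(rng)
        f = bonded_forces(st).forces
        i = int(rng.integers(st.n_beads))
        a = int(rng.integers(3))

        def energy(delta):
            s2 = st.copy()
            s2.positions[i, a] += delta
            r = bonded_forces(s2)
            return r.e_bond + r.e_angle

        fd = -(energy(h) - energy(-h)) / (2 * h)
        scale = max(1.0, np.abs(f).max())
        assert abs(fd - f[i, a]) <= 1e-6 * scale
        # net force and torque of the bonded terms vanish
        assert np.abs(f.sum(axis=0)).max() < 1e-10
        torque = np.cross(st.positions - st.positions.mean(axis=0), f).sum(axis=0)
        assert np.abs(torque).max() < 1e-9


def test_cell_list_matches_all_pairs_oracle(interactions):
    """Cell-list pair forces equal the O(N^2) loop to round-off on a
    500-bead box, including the random-force contribution."""
    rng = np.random.default_rng(7)
    top = water_topology(500)
    st = SystemState(6.0, rng.uniform(0, 6, (500, 3)),
                     rng.normal(size=(500, 3)), top)
    p = RunParams(n_steps=0, seed=13)
    a = pair_forces(st, p, interactions, step_index=3)
    b = pair_forces(st, p, interactions, step_index=3, force_allpairs=True)
    assert np.abs(a.forces - b.forces).max() < 1e-10
    assert a.e_pair == pytest.approx(b.e_pair, rel=1e-12)


def test_overlapping_beads_get_finite_random_kick(interactions):
    top = water_topology(2)
    pos = np.array([[2.0, 2.0, 2.0], [2.0, 2.0, 2.0]])
    st = SystemState(5.0, pos, np.zeros((2, 3)), top)
    p = RunParams(n_steps=0, seed=1)
    res = pair_forces(st, p, interactions)
    assert res.n_overlap == 1
    assert np.all(np.isfinite(res.forces))
    assert np.abs(res.forces.sum(axis=0)).max() < 1e-12
    assert np.linalg.norm(res.forces[0]) > 0.0
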