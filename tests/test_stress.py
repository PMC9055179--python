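"""Irving-Kirkwood stress machinery: partition of unity, hand-placed pair
geometry, isotropy of a homogeneous fluid, tension and osmotic profiles."""
import numpy as np
import pytest

from lipiddpd import (InitSpec, LipidTemplate, RunParams, Species,
                      SystemState, TrajectoryRecorder, default_interactions,
                      init_state, interface_tension, local_pressure,
                      osmotic_pressure, run, water_topology)

from conftest import make_water_state


@pytest.fixture(scope="module")
def water_frames(interactions):
    """Short equilibrated pure-water run (L = 8) for stress statistics."""
    st = make_water_state(8.0, seed=21)
    rec = TrajectoryRecorder(every=2)
    run(st, RunParams(n_steps=2000, seed=21, report_every=50), interactions,
        observers=[rec])
    return rec.frames[5:]


def test_partition_of_unity(interactions, template_pair):
    """Slab-integrated IK virial equals the whole-box virial to 1e-10,
    including bonded (bond + angle-arm) contributions."""
    t1, t2 = template_pair
    state = init_state(InitSpec("random", 15, 15, 8.0, seed=2), t1, t2)
    for axis in ("x", "y", "z"):
        stress = local_pressure(state, axis, 16, interactions)
        for comp, glob in zip(("x", "y", "z"), stress.global_p):
            slab_mean = stress.component(comp).mean()  # equal slab volumes
            assert slab_mean == pytest.approx(glob, rel=1e-10, abs=1e-10)


def test_single_pair_virial_split_by_segment_length(interactions):
    """A pair spanning three slabs distributes its virial in proportion to
    the segment length inside each slab."""
    L, n_bins = 6.0, 6
    top = water_topology(2)
    # beads at z = 0.9 and z = 0.9 + 0.9*... within cutoff: r = 0.8 along z
    pos = np.array([[3.0, 3.0, 0.9], [3.0, 3.0, 1.7]])
    st = SystemState(L, pos, np.zeros((2, 3)), top)
    stress = local_pressure(st, "z", n_bins, interactions)
    v_bin = (L / n_bins) * L * L
    w = stress.p_zz * v_bin            # per-slab virial (kinetic part zero)
    # segment [0.9, 1.7] crosses slab edges at 1.0: fractions 1/8 and 7/8
    a = interactions[Species.W, Species.W]
    r = 0.8
    total = a * (1 - r) * r            # F * z_ij
    assert w[0] == pytest.approx(total * (0.1 / 0.8), rel=1e-12)
    assert w[1] == pytest.approx(total * (0.7 / 0.8), rel=1e-12)
    assert np.abs(w[2:]).max() < 1e-14


def test_homogeneous_fluid_isotropic_pressure(water_frames, interactions):
    """p_xx = p_yy = p_zz in every slab within sampling error, and the
    global pressure is the same along each axis."""
    stress = local_pressure(water_frames, "z", 8, interactions)
    assert np.ptp(stress.global_p) < 0.3          # ~1% of p ~ 23.6
    for comp in ("x", "y"):
        diff = stress.component(comp) - stress.p_zz
        assert np.abs(diff).max() < 1.5   # per-slab fluctuation band


def test_homogeneous_fluid_zero_tension(water_frames, interactions):
    """sigma = 0 within sampling error estimated from per-frame spread."""
    per_frame = [interface_tension(local_pressure([f], "z", 8, interactions),
                                   "z").sigma for f in water_frames]
    per_frame = np.array(per_frame)
    se = per_frame.std(ddof=1) / np.sqrt(len(per_frame))
    assert abs(per_frame.mean()) < 5.0 * se + 0.05


def test_homogeneous_fluid_zero_osmotic(water_frames, interactions):
    stress = local_pressure(water_frames, "z", 8, interactions)
    osm = osmotic_pressure(stress, "z", (0.0, 8.0))
    assert osm.pi.mean() == pytest.approx(0.0, abs=1e-10)  # by construction
    assert np.abs(osm.pi).max() < 1.0


def test_osmotic_bulk_window_required(water_frames, interactions):
    stress = local_pressure(water_frames, "z", 8, interactions)
    with pytest.raises(ValueError, match="bulk"):
        osmotic_pressure(stress, "z", (20.0, 30.0))


def test_too_thin_bins_refused(interactions):
    st = make_water_state(4.0, seed=1)
    with pytest.raises(ValueError, match="0.1"):
        local_pressure(st, "z", 100, interactions)


def test_per_species_decomposition_sums_to_total(interactions,
                                                 template_pair):
    t1, t2 = template_pair
    state = init_state(InitSpec("lamella", 30, 30, 10.0, seed=3), t1, t2)
    stress = local_pressure(state, "z", 20, interactions)
    total = stress.per_species.sum(axis=0)
    assert np.allclose(total[:, 0], stress.p_xx, atol=1e-12)
    assert np.allclose(total[:, 2], stress.p_zz, atol=1e-12)


def test_demixed_fluid_osmotic_peaks_at_interfaces(interactions):
    """Two immiscible soft fluids (a_AB = 100) develop osmotic-pressure
    extrema co-located with the composition-gradient maxima."""
    rng = np.random.default_rng(31)
    L = 8.0
    n = int(round(3 * L ** 3))
    top = water_topology(n)
    pos = rng.uniform(0, L, (n, 3))
    # A-rich lower half: reuse the HB1 species code for the A fluid
    top.species = np.where(pos[:, 2] < L / 2, np.int8(int(Species.HB1)),
                           np.int8(int(Species.W)))
    vel = rng.normal(size=(n, 3))
    vel -= vel.mean(axis=0)
    st = SystemState(L, pos, vel, top)
    rec = TrajectoryRecorder(every=2)
    run(st, RunParams(n_steps=2000, seed=31, report_every=50),
        default_interactions(), observers=[rec])
    frames = rec.frames[5:]
    stress = local_pressure(frames, "z", 16, default_interactions())
    osm = osmotic_pressure(stress, "z", (1.0, 3.0))
    from lipiddpd import density_profile

    prof = density_profile(frames, "z", 16)
    phi = prof.species("HB1")
    grad = np.abs(np.gradient(phi))
    n_bins = 16
    peak_pi = int(np.argmax(np.abs(osm.pi)))
    # co-location within 2 bins of one of the two interface gradient maxima
    top2 = np.argsort(grad)[-4:]
    dist = min(min(abs(peak_pi - b), n_bins - abs(peak_pi - b))
               for b in top2)
    assert dist <= 2
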