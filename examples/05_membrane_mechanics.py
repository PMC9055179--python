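"""Irving-Kirkwood mechanics across a fluid-fluid interface.

Runs a demixed two-fluid system (repulsion 100 between unlike beads,
chi ~ 21), computes the slab-resolved pressure tensor by distributing each
pair virial along its inter-bead segment, and prints the interface tension
and the osmotic-pressure profile.  The tension integrand
p_N - (p_T1 + p_T2)/2 peaks at the two interfaces and vanishes in the
bulk; the osmotic pressure Pi = p_N - <p_N>_bulk peaks where the
composition gradient is steepest.
"""
import numpy as np

from lipiddpd import (RunParams, SystemState, TrajectoryRecorder,
                      default_interactions, interface_tension,
                      local_pressure, osmotic_pressure, run, water_topology)
from lipiddpd.topology import Species, chi_from_a

L = 8.0
rng = np.random.default_rng(5)
n = int(round(3.0 * L ** 3))
top = water_topology(n)
pos = rng.uniform(0, L, (n, 3))
top.species = np.where(pos[:, 2] < L / 2, np.int8(int(Species.HB1)),
                       np.int8(int(Species.W)))
vel = rng.normal(size=(n, 3))
vel -= vel.mean(axis=0)
state = SystemState(L, pos, vel, top)

interactions = default_interactions()
print(f"Flory-Huggins chi of the pair: "
      f"{chi_from_a(interactions['HB1', 'W'], 25.0):.2f}")

recorder = TrajectoryRecorder(every=2)
run(state, RunParams(n_steps=3000, seed=5, report_every=50), interactions,
    observers=[recorder])
frames = recorder.frames[10:]

stress = local_pressure(frames, "z", 16, interactions)
tension = interface_tension(stress, "z")
print(f"total tension over the box: {tension.sigma:.2f} kT/r_c^2 "
      f"({tension.sigma / 2:.2f} per interface; two interfaces under "
      "periodic boundaries)")
print("tension integrand per slab:",
      " ".join(f"{v:5.2f}" for v in tension.integrand))

osm = osmotic_pressure(stress, "z", (1.5, 2.5))
print(f"total osmotic pressure: |Pi| <= {np.abs(osm.pi).max():.2f} "
      "kT/r_c^3 everywhere (planar mechanical equilibrium keeps p_N flat)")
pi_a = osm.species("HB1")
grad = np.abs(np.gradient(pi_a))
peak = int(np.argmax(grad))
print(f"species-A partial Pi varies only across the interfaces "
      f"(steepest at z = {osm.bin_centers[peak]:.2f} r_c)")
print("Nonzero anisotropy localises at the interfaces while the bulk "
      "stays tension-free, the structure the membrane analysis relies on.")
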