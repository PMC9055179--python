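"""Scaled-down asymmetric-membrane self-assembly.

Starts from a lamellar arrangement of two lipid species (tail lengths 4
and 9, three head beads each) in an L = 12 r_c box, runs 6000 DPD steps,
then classifies the final aggregate and prints the head/tail density-peak
positions along the membrane normal.  The hallmark of the asymmetric
membrane is that the two head-bead peaks are well separated (one leaflet
per species) while the tail distributions overlap (interdigitated core).

A production-quality version of this run uses more steps (the test suite
uses 30 000) and the 25-35 r_c box-size sweep.
"""
import numpy as np

from lipiddpd import (InitSpec, LipidTemplate, RunParams,
                      TrajectoryRecorder, classify, default_interactions,
                      density_profile, init_state, run)

t1 = LipidTemplate(1, n_head=3, n_tail=4)
t2 = LipidTemplate(2, n_head=3, n_tail=9)
state = init_state(InitSpec("lamella", 60, 60, 12.0, seed=11), t1, t2)

recorder = TrajectoryRecorder(every=10)
trace = run(state, RunParams(n_steps=6000, seed=11, report_every=100),
            default_interactions(), observers=[recorder])
print(f"final per-bead energy: {trace.e_per_bead[-1]:.3f} kT, "
      f"T_kin = {trace.t_kin[-1]:.3f}")

label = classify(state)
print(f"classified as: {label.label} (spans {label.spanning_dims} axes, "
      f"asymmetry index {label.asymmetry_index:.2f})")

profile = density_profile(recorder.frames[-4:], "z", 48)
for s in ("HB1", "TB1", "TB2", "HB2"):
    d = profile.species(s)
    print(f"  phi_{s}: peak at z = {profile.bin_centers[np.argmax(d)]:.1f} "
          f"r_c (max {d.max():.2f} beads/r_c^3)")
print("Separated HB1/HB2 peaks flanking overlapping TB1/TB2 peaks are the "
      "bimodal signature of the asymmetric bilayer.")
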