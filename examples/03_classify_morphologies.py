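"""Morphology classifier on hand-built aggregates.

Builds a flat bilayer slab, a bilayer tube and a bilayer shell with zero
dynamics and runs the classifier.  The labels follow from two topological
facts: along how many box axes the aggregate connects to its own periodic
image (2 = membrane, 1 = tube, 0 = vesicle) and whether it encloses a
water pocket disconnected from the bulk (hollow).
"""
from lipiddpd import InitSpec, LipidTemplate, classify, init_state

fixtures = [
    ("slab", InitSpec("lamella", 100, 100, 10.0, seed=1),
     LipidTemplate(1, 3, 4), LipidTemplate(2, 3, 4)),
    ("tube", InitSpec("cylinder", 220, 280, 10.0, seed=1),
     LipidTemplate(1, 1, 1), LipidTemplate(2, 1, 1)),
    ("shell", InitSpec("sphere", 100, 110, 14.0, seed=1),
     LipidTemplate(1, 3, 2), LipidTemplate(2, 3, 2)),
]

for name, spec, t1, t2 in fixtures:
    state = init_state(spec, t1, t2)
    label = classify(state)
    print(f"{name:6s} -> {label.label:8s} spanning_dims={label.spanning_dims} "
          f"hollow={bool(label.hollow)} asymmetry={label.asymmetry_index:.2f}")
print("Each constructed geometry maps to its intended label before any "
      "dynamics; the asymmetry index ~ 1 confirms type 1 occupies the "
      "lower/inner leaflet.")
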