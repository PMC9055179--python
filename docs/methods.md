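# Methods

## Model

Two phospholipid species self-assemble in explicit solvent, simulated with
dissipative particle dynamics (DPD).  Each lipid is a branched bead-spring
molecule: one linear hydrophilic head chain of `n_head` beads joined at its
last bead to two linear hydrophobic tail chains of `n_tail` beads each
(`n_head + 2 n_tail` beads per lipid).  Five bead species exist — heads and
tails of lipid types 1 and 2, plus water — all with unit mass.  Everything
is in reduced units: the pair cut-off `r_c` is the length scale, the bead
mass the mass scale, `k_B T` the energy scale, and `tau = r_c sqrt(m/kT)`
the time unit.

### Pair forces

Beads interact pairwise inside the cut-off through the standard DPD triple

* conservative: `F_C = a_ij (1 - r/r_c) r_hat`,
* dissipative: `F_D = -gamma w(r)^2 (r_hat . v_ij) r_hat`,
* random: `F_R = sigma w(r) zeta_ij dt^(-1/2) r_hat`,

with weight `w(r) = 1 - r/r_c` and `w_D = w_R^2`, which together with
`sigma^2 = 2 gamma k_B T` forms a pairwise momentum-conserving thermostat.
`zeta_ij = zeta_ji` is a zero-mean unit-variance Gaussian drawn once per
pair per step.  The conservative pair energy is
`U_C = (a_ij r_c / 2)(1 - r/r_c)^2`.

The repulsion table defaults to `a_ii = 25` between like beads and
`a_ij = 100` between unlike beads (`chi = 0.286 (a_ij - a_ii) ~ 21` for the
default contrast).  The five species are treated as pairwise distinct, so
the two head species also repel at 100; this is what segregates the two
lipid types into distinct leaflets.  Any entry can be overridden in the
configuration, including the head1–head2 coupling, for users who prefer to
group the two hydrophilic species.

### Bonded terms

Consecutive beads within each chain, and the last head bead with the first
bead of each tail, are bonded with harmonic springs
`U = (k_s/2)(r - r_s)^2`, `k_s = 100`, `r_s = 0.7 r_c`.  Bending terms
`U = k_theta (theta - theta_0)^2` (note: no 1/2 — the force is the exact
negative gradient of this expression) come in three classes:

| class | triple | `k_theta` | `theta_0` |
|---|---|---|---|
| intra-chain | any three consecutive beads of one chain | 6.0 | pi |
| head–tail junction | last two head beads + first tail bead (per tail) | 3.0 | pi |
| tail–tail split | the two first tail beads, apex at the last head bead | 4.5 | pi |

The junction and split equilibrium angles are genuinely open model choices;
both default to the straight angle (the only value the intra-chain class
fixes unambiguously) and are exposed as `theta0_junction` / `theta0_split`
config keys.  Lipids with a single head bead cannot define the junction
class; those terms are omitted with a logged warning.

### Integration

The equations of motion are integrated with the Groot–Warren modified
velocity-Verlet scheme at `lambda = 0.5`: half-kick, drift with periodic
wrap, force evaluation using the half-kicked velocities as the
dissipative-force predictor, closing half-kick.  Time step `dt = 0.01 tau`.
In the thermostat-off limit this reduces to plain velocity Verlet, and the
tests verify the symplectic signature (bounded energy oscillation, windowed
drift < 1e-4 over 1e4 steps), exact momentum conservation, and a kinetic
temperature within 3% of target for the standard water box.

Neighbour search is a linked-cell list (cell width >= `r_c`, half stencil);
boxes smaller than three cells per axis fall back to an all-pairs loop that
is also kept as the O(N^2) oracle in the tests.  Bead density is fixed at
`rho = 3`, so a box of side `L` holds `round(rho L^3)` beads, water filling
whatever the lipids do not use.

### Random numbers

The pair noise is counter-based: each `zeta_ij` is produced by a
splitmix64 hash of (seed, step, sorted pair indices) pushed through a
Box–Muller transform.  The draw is symmetric under i–j exchange (so the
random force is exactly pairwise antisymmetric) and independent of the
traversal order, which makes trajectories bitwise reproducible for a given
seed and identical between the cell-list and all-pairs paths.  Exactly
overlapping beads (r = 0) receive the contact-magnitude force along a
hash-derived random direction and are logged.

## Initial states and structure selection

Four builders produce starting configurations: `random` (straight rods at
random positions/orientations), `lamella` (flat bilayer slab, type 1 lower
leaflet), `cylinder` (bilayer tube along z, type 1 inner) and `sphere`
(bilayer shell, type 1 inner).  Leaflet bead spacing starts at the rest
bond length and is compressed (never below 0.35 `r_c`) when a leaflet's
extended contour would not fit its thickness budget; the soft springs relax
the compression within a few hundred steps.  Geometric impossibilities
(too many lipids for the available leaflet area, a bilayer thicker than
the box) raise errors naming the limiting dimension.  Velocities are
Maxwell–Boltzmann at the target temperature with the net momentum removed
exactly.

Because the assembled morphology can depend on the starting arrangement,
a parameter point is resolved by running the candidate arrangements
(lamellar, cylindrical, spherical by default) with identical physical
parameters and keeping the final state whose mean per-bead energy over the
final 10% of reports is lowest; ties within 1e-9 go to the lowest candidate
index.  The same rule drives the box-size sweep (default 25–35 `r_c` at
fixed lipid counts, water adjusting to keep `rho = 3`).  The 10% window is
a package choice: the comparison needs a plateau average, and the final
decade of a relaxed run is comfortably inside the plateau.

## Observables

* **Density profiles**: per-species bead counts in equal slabs along a box
  axis; slab sums recover bead counts exactly, frames average.
* **Orientational order**: per chain, `S = (3 cos^2 theta - 1)/2` of the
  head-chain first-to-last bead vector (minimum image) against a reference
  axis; 1 parallel, -0.5 perpendicular.  A whole-lipid end-to-end option
  exists.  Histograms get an unweighted least-squares Gaussian fit
  (mean, sd, amplitude); degenerate histograms return no fit.
* **Gyration tensor**: `R^2_g,ab = (1/N) sum_i (r_ia - rbar_a)(r_ib -
  rbar_b)` per chain with coordinates unwrapped along the chain
  connectivity; reported components are `sqrt` of the chain-averaged
  diagonal entries, and the scalar `<R_g>` is the square root of the mean
  trace.
* **Shape factor**: `delta = 1 - 3 (L1 L2 + L2 L3 + L3 L1)/(L1+L2+L3)^2`
  from the sorted gyration eigenvalues, averaged as the mean of per-chain
  values (not a ratio of means — the two conventions agree for the limits
  0 and 1 that the tests pin down).  Eigenvalues are normalised by the
  trace before combining so near-underflow tensors stay in [0, 1]; a
  zero-trace tensor defines `delta = 0`.
* **Stage segmentation**: the energy trace is split into three stages
  (random generation, mutual adaptation, formation) by exact least-squares
  change-point search — two change points minimising total within-stage
  variance, found by full enumeration over report indices with prefix
  sums.  A flat trace degenerates to boundaries at 1/3 and 2/3 with a
  flag; increasing stage means warn rather than fail.

## Local pressure, tension, osmotic pressure

The slab-resolved pressure tensor follows the Irving–Kirkwood-1 contour:
each pair virial `F_ij,a a_ij` is spread over the slabs crossed by the
minimum-image i–j segment in proportion to path length, plus the kinetic
term `m v_a^2` binned at each bead's position.  Angle (three-body) terms
are decomposed into the two arms i–apex and k–apex, which preserves the
total virial exactly because the apex force is minus the sum of the other
two.  Only conservative and bonded forces enter the recomputation from
frames: the thermostat's dissipative/random pair cancels in the mean by
construction.  The partition-of-unity identity — slab-integrated stress
equals the whole-box virial — holds to 1e-10 and is asserted in the tests.

A per-channel decomposition assigns half of every pair/bonded contribution
to each endpoint's species (kinetic terms wholly to their bead's species);
channel sums recover the totals exactly and provide the per-lipid-type
tension and osmotic decompositions.

Interface tension integrates `t = p_N - (p_T1 + p_T2)/2` over the profile;
the normal may be chosen independently of the profile axis, so the same
integrand can be resolved across the membrane (profile along the normal)
or laterally (profile along an in-plane axis, averaged over the other two
directions).  The osmotic profile is `Pi = p_N - <p_N>_bulk` referenced to
a caller-supplied bulk-water window; an empty window is an error.  Slabs
thinner than 0.1 `r_c` are refused (statistics unusable).

## Morphology classification

Visual phase assignment is replaced by an algorithmic criterion:

1. a periodic contact graph over all lipid beads (cut-off 1 `r_c`,
   `scipy.spatial.cKDTree` with box wrapping) is reduced to its largest
   connected aggregate (fewer than 10 lipids → `other`);
2. `spanning_dims` counts box axes along which the aggregate touches its
   own periodic image, detected as non-zero winding by a union-find that
   tracks integer image offsets along each edge;
3. `hollow` asks whether water is enclosed: cells of a 0.5 `r_c` occupancy
   grid within 0.5 `r_c` of an aggregate bead are blocked, free cells are
   flood-filled with periodic connectivity, and a second water-containing
   free region of at least 5 water beads marks an internal pocket.

Membrane = spans 2 axes; tube = spans 1 and hollow; vesicle = spans 0 and
hollow; everything else `other`.  The asymmetry index is the fraction of
type-1 head beads on the lower (membrane, along the non-spanning axis,
centre by circular mean) or inner (tube/vesicle, radius below the median
head radius) side.  All thresholds are keyword arguments.  The classifier
is deterministic and invariant under rigid translation and axis
permutation; the tests verify constructed slab/tube/shell states label
correctly with zero dynamics.

The tail-length drivers simulate only the half-grid `n_tb2 >= n_tb1` —
swapping the tail lengths merely relabels the species — and mirror the
other half with the asymmetry index complemented.  Individual point
failures are recorded as `other` with a diagnostic and the grid continues.

## What the generators emulate — and what they do not

The initial-state builders and the synthetic energy traces emulate the
*geometry* and *kinetic signature* of the study conditions: pre-assembled
leaflet-resolved aggregates, uniform solvent at liquid density, and
three-plateau relaxation curves.  They do not emulate finite-size
undulation spectra, protrusion modes, or solvent structuring, so tests
passing on them demonstrate the correctness of the machinery (forces,
thermostat, estimators, classifier), not quantitative agreement with any
particular lipid chemistry.

## Problem sizes used by the test suite

Full production conditions (600 + 600 chains, `L = 25–35 r_c`, 2x10^5
steps, lowest-energy selection over three arrangements and eleven box
sizes) are supported by the code but are cluster-scale work.  The test
suite exercises the same code paths at desk scale, a deliberate package
choice: a 1536-bead water box for thermostat and stress statistics
(5000 steps), a 5184-bead `L = 12` box with 60 + 60 lipids (tails 4
and 9, 30 000 steps) for self-assembly, classification, density structure
and tension, and 2–3-point tail-length grids with a few hundred steps for
the drivers.

One finding from the desk-scale bilayer deserves a note: at fixed
`L = 12` with 60 lipids per leaflet the membrane assembles and classifies
correctly, and its density profile shows the expected separated head peaks
with interdigitated tails, but it carries a finite in-plane tension of
about 5 `kT/r_c^2` — the fixed box pins the area per lipid at 2.4 `r_c^2`,
well above the tensionless area of these lipids.  A tension-free membrane
requires the box-size optimisation step, which is exactly why the
production protocol sweeps `L`.  The stress machinery itself is validated
independently: homogeneous water gives zero tension within one standard
error, and a demixed two-fluid interface (`delta a = 75`) gives
~4.6 `kT/r_c^2` per interface, in line with published DPD interfacial
tensions.

## Known limitations

* No barostat: all runs are NVT, so membrane tension is set by the box.
* No electrostatics, shear flow, or external fields.
* The classifier's hollowness test needs the aggregate shell to be closed
  at the 0.5 `r_c` grid resolution; very sparse hand-built shells can leak
  (the builders place lipids densely enough, but pathological inputs fall
  back to `other`).
* Angle potentials with `theta_0` away from 0 or pi have a genuinely
  singular gradient at collinear configurations; the implementation clamps
  the sine there (logged), which regularises the force at the cost of
  exactness in a measure-zero set.
* The stress recomputation ignores dissipative/random forces; their mean
  is zero but their fluctuation contribution to instantaneous profiles is
  not sampled.
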