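"""Initial configurations and lowest-energy structure selection.

Four initial lipid arrangements are supported: fully random rods, a flat
bilayer slab (lamella, normal along z, type 1 in the lower leaflet), a
bilayer tube (along z, type 1 inner) and a bilayer shell (sphere, type 1
inner).  Water fills the remaining volume to the target bead density rho,
and velocities are Maxwell-Boltzmann at the target temperature with the
net momentum removed exactly.

Because the self-assembled morphology can depend on the starting
arrangement, a parameter point is resolved by running several initial
arrangements with identical physical parameters and keeping the final
state whose late-window mean per-bead energy is lowest
(:func:`select_stable`); :func:`optimize_box` applies the same rule to a
sweep of box sizes.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import EnergyTrace, RunParams, SystemState, run
from .topology import (BEAD_MASS, BondedParams, InteractionMatrix,
                       LipidTemplate, build_system_topology)

log = logging.getLogger(__name__)

INIT_MODES = ("random", "lamella", "cylinder", "sphere")

#: minimum in-leaflet spacing between neighbouring lipids (r_c)
MIN_SPACING = 0.6
#: radial gap between the two leaflets' tail ends (r_c)
LEAFLET_GAP = 0.35
#: lateral offset between the two tail chains of one lipid (r_c)
TAIL_SEP = 0.35


@dataclass(frozen=True)
class InitSpec:
    """One initial-arrangement request."""

    mode: str
    n1: int
    n2: int
    L: float
    seed: int = 0

    def __post_init__(self):
        if self.mode not in INIT_MODES:
            raise ValueError(f"mode must be one of {INIT_MODES}, got {self.mode!r}")
        if self.n1 < 0 or self.n2 < 0:
            raise ValueError("lipid counts must be >= 0")
        if self.L <= 0:
            raise ValueError("box length must be positive")


def _place_lipid(origin, u, perp, n_head, n_tail, r_s):
    """Bead coordinates of one straight lipid: head chain along +u from
    ``origin``, two tail chains continuing along u, offset +-TAIL_SEP/2
    along ``perp``."""
    coords = np.empty((n_head + 2 * n_tail, 3))
    for k in range(n_head):
        coords[k] = origin + k * r_s * u
    last_head = coords[n_head - 1]
    for t, sign in enumerate((1.0, -1.0)):
        off = sign * 0.5 * TAIL_SEP * perp
        base = n_head + t * n_tail
        for m in range(n_tail):
            coords[base + m] = last_head + (m + 1) * r_s * u + off
    return coords


def _unit_perp(u, rng):
    """A unit vector perpendicular to u."""
    trial = np.array([1.0, 0.0, 0.0])
    if abs(u[0]) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    p = np.cross(u, trial)
    return p / np.linalg.norm(p)


def _fibonacci_sphere(n):
    """n near-uniform unit vectors on the sphere."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _leaflet_spacing(template, budget, r_s, what):
    """Bead spacing for a leaflet whose contour must fit inside ``budget``;
    beads start at the rest bond length and are compressed if needed (soft
    springs relax in a few hundred steps)."""
    n_links = template.n_head - 1 + template.n_tail
    spacing = min(r_s, budget / max(n_links, 1))
    if spacing < 0.35:
        raise ValueError(
            f"{what}: leaflet thickness budget {budget:.2f} r_c cannot hold "
            f"{n_links} bonds at >= 0.35 r_c spacing")
    return spacing


def _lamella_positions(spec, t1, t2, r_s):
    L = spec.L
    usable = L - 1.0 - LEAFLET_GAP   # leave >= 1 r_c of water
    c1, c2 = t1.contour_length, t2.contour_length
    sp1 = _leaflet_spacing(t1, usable * c1 / (c1 + c2), r_s, "lamella")
    sp2 = _leaflet_spacing(t2, usable * c2 / (c1 + c2), r_s, "lamella")
    span1 = sp1 * (t1.n_head - 1 + t1.n_tail)
    span2 = sp2 * (t2.n_head - 1 + t2.n_tail)
    z_lo = (L - (span1 + span2 + LEAFLET_GAP)) / 2.0  # centre the stack
    coords = []
    for template, count, lower, bead_sp in ((t1, spec.n1, True, sp1),
                                            (t2, spec.n2, False, sp2)):
        if count == 0:
            continue
        g = int(math.ceil(math.sqrt(count)))
        spacing = L / g
        if spacing < MIN_SPACING:
            raise ValueError(
                f"lamella leaflet area L^2 = {L * L:.1f} r_c^2 fits at most "
                f"{int((L / MIN_SPACING) ** 2)} lipids at spacing "
                f"{MIN_SPACING} r_c; requested {count}")
        if lower:
            origin_z = z_lo
            u = np.array([0.0, 0.0, 1.0])
        else:
            origin_z = z_lo + span1 + LEAFLET_GAP + span2
            u = np.array([0.0, 0.0, -1.0])
        perp = np.array([1.0, 0.0, 0.0])
        k = 0
        for iy in range(g):
            for ix in range(g):
                if k >= count:
                    break
                origin = np.array([(ix + 0.5) * spacing, (iy + 0.5) * spacing,
                                   origin_z])
                coords.append(_place_lipid(origin, u, perp, template.n_head,
                                           template.n_tail, bead_sp))
                k += 1
    return np.concatenate(coords, axis=0)


def _curved_positions(spec, t1, t2, r_s, shape):
    """Tube (along z) or spherical shell; type 1 forms the inner leaflet."""
    L = spec.L
    center = np.array([L / 2.0, L / 2.0, L / 2.0])
    R_mid = L / 4.0
    coords = []
    for template, count, inner in ((t1, spec.n1, True), (t2, spec.n2, False)):
        if count == 0:
            continue
        if inner:
            # smallest head radius at which `count` heads keep MIN_SPACING
            if shape == "cylinder":
                r_min = max(0.4, count * MIN_SPACING ** 2 / (2.0 * math.pi * L))
            else:
                r_min = max(0.4, math.sqrt(count * MIN_SPACING ** 2
                                           / (4.0 * math.pi)))
            budget = R_mid - LEAFLET_GAP / 2.0 - r_min
        else:
            budget = L / 2.0 - R_mid - LEAFLET_GAP / 2.0 - 0.6
        bead_sp = _leaflet_spacing(template, budget, r_s, shape)
        span = bead_sp * (template.n_head - 1 + template.n_tail)
        if inner:
            r0 = R_mid - LEAFLET_GAP / 2.0 - span
            direction = 1.0   # head chain points outward
        else:
            r0 = R_mid + LEAFLET_GAP / 2.0 + span
            direction = -1.0  # head chain points inward
        if shape == "cylinder":
            circ = 2.0 * math.pi * min(r0, R_mid)
            nphi = max(1, int(math.ceil(math.sqrt(count * circ / L))))
            nz = int(math.ceil(count / nphi))
            if L / nz < MIN_SPACING or circ / nphi < MIN_SPACING:
                raise ValueError(
                    f"cylinder leaflet area 2*pi*R*L = {circ * L:.1f} r_c^2 "
                    f"too small for {count} lipids at spacing "
                    f"{MIN_SPACING} r_c")
            base, extra = divmod(count, nz)
            for iz in range(nz):
                n_row = base + (1 if iz < extra else 0)
                for ip in range(n_row):
                    phi = 2.0 * math.pi * (ip + 0.5 * (iz % 2)) / n_row
                    rad = np.array([math.cos(phi), math.sin(phi), 0.0])
                    origin = center.copy()
                    origin[2] = (iz + 0.5) * L / nz
                    origin[:2] = center[:2] + r0 * rad[:2]
                    u = direction * rad
                    coords.append(_place_lipid(origin, u,
                                               np.array([0.0, 0.0, 1.0]),
                                               template.n_head,
                                               template.n_tail, bead_sp))
        else:  # sphere
            area = 4.0 * math.pi * min(r0, R_mid) ** 2
            if area / count < MIN_SPACING ** 2:
                raise ValueError(
                    f"spherical leaflet area 4*pi*R^2 = {area:.1f} r_c^2 too "
                    f"small for {count} lipids at spacing {MIN_SPACING} r_c")
            dirs = _fibonacci_sphere(count)
            for d in dirs:
                origin = center + r0 * d
                u = direction * d
                perp = _unit_perp(u, None)
                coords.append(_place_lipid(origin, u, perp, template.n_head,
                                           template.n_tail, bead_sp))
    return np.concatenate(coords, axis=0)


def _random_positions(spec, t1, t2, r_s, rng):
    coords = []
    for template, count in ((t1, spec.n1), (t2, spec.n2)):
        for _ in range(count):
            origin = rng.uniform(0.0, spec.L, 3)
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            perp = _unit_perp(u, rng)
            coords.append(_place_lipid(origin, u, perp, template.n_head,
                                       template.n_tail, r_s))
    if not coords:
        return np.empty((0, 3))
    return np.concatenate(coords, axis=0)


def init_state(spec: InitSpec, template1: LipidTemplate,
               template2: LipidTemplate, rho: float = 3.0, kBT: float = 1.0,
               bonded: BondedParams | None = None) -> SystemState:
    """Build a SystemState for the requested arrangement.

    The total bead count is round(rho * L^3); water fills the remainder
    after the lipids.  Velocities are Maxwell-Boltzmann at ``kBT`` shifted
    to exactly zero net momentum.
    """
    if bonded is None:
        bonded = BondedParams()
    rng = np.random.default_rng(spec.seed)
    r_s = bonded.r_s
    if spec.mode != "random":
        # both leaflets (compressible down to 0.35 r_c bond spacing) plus
        # the inter-leaflet gap must fit in the box with room for water
        links = (template1.n_head - 1 + template1.n_tail
                 + template2.n_head - 1 + template2.n_tail)
        thickness = 0.35 * links + LEAFLET_GAP
        if spec.L <= thickness + 1.0:
            raise ValueError(
                f"box L = {spec.L} r_c cannot hold a bilayer of minimum "
                f"thickness {thickness:.2f} r_c (plus water) for mode "
                f"{spec.mode!r}")
    n_total = int(round(rho * spec.L ** 3))
    n_lipid_beads = spec.n1 * template1.n_beads + spec.n2 * template2.n_beads
    n_water = n_total - n_lipid_beads
    if n_water < 0:
        raise ValueError(
            f"{n_lipid_beads} lipid beads exceed the rho*L^3 = {n_total} "
            "bead budget")

    if spec.mode == "random":
        lipid_xyz = _random_positions(spec, template1, template2, r_s, rng)
    elif spec.mode == "lamella":
        lipid_xyz = _lamella_positions(spec, template1, template2, r_s)
    else:
        lipid_xyz = _curved_positions(spec, template1, template2, r_s,
                                      spec.mode)

    water_xyz = rng.uniform(0.0, spec.L, (n_water, 3))
    positions = np.concatenate([lipid_xyz.reshape(-1, 3), water_xyz], axis=0)

    topology = build_system_topology(template1, template2, spec.n1, spec.n2,
                                     n_water, bonded)
    velocities = rng.normal(0.0, math.sqrt(kBT / BEAD_MASS),
                            (topology.n_beads, 3))
    velocities -= velocities.mean(axis=0)
    return SystemState(spec.L, positions, velocities, topology)


@dataclass
class SelectionResult:
    """Outcome of a lowest-energy selection over several candidate runs."""

    winner_index: int
    state: SystemState
    traces: list[EnergyTrace]
    energies: list[float]            # late-window mean per-bead energy
    labels: list[str]                # candidate descriptions
    failed: dict = field(default_factory=dict)  # label -> error message


def _pick_lowest(energies: list[float], tol: float = 1e-9) -> int:
    """Index of the lowest energy; ties within ``tol`` go to the lowest index."""
    e_min = min(energies)
    for i, e in enumerate(energies):
        if e <= e_min + tol:
            return i
    raise AssertionError("unreachable")


def select_stable(specs: list[InitSpec], template1: LipidTemplate,
                  template2: LipidTemplate, params: RunParams,
                  interactions: InteractionMatrix, rho: float = 3.0,
                  bonded: BondedParams | None = None,
                  window: float = 0.1) -> SelectionResult:
    """Run each initial arrangement and keep the lowest-energy final state.

    All candidates run with identical physical parameters; the comparison
    energy is the mean per-bead potential energy over the final ``window``
    fraction of reports.  Candidates whose run aborts are excluded (logged);
    if all abort, an error is raised.
    """
    if not specs:
        raise ValueError("need at least one initial arrangement")
    states, traces, energies, labels = [], [], [], []
    failed = {}
    for spec in specs:
        label = f"{spec.mode}(L={spec.L:g})"
        try:
            state = init_state(spec, template1, template2, rho=rho,
                               kBT=params.kBT, bonded=bonded)
            trace = run(state, params, interactions)
            e = (trace.final_window_mean(window) if len(trace) else
                 float("nan"))
        except (RuntimeError, ValueError) as err:
            log.warning("candidate %s aborted: %s", label, err)
            failed[label] = str(err)
            continue
        states.append(state)
        traces.append(trace)
        energies.append(e)
        labels.append(label)
    if not states:
        raise RuntimeError(f"all candidate runs aborted: {failed}")
    idx = _pick_lowest(energies)
    return SelectionResult(winner_index=idx, state=states[idx], traces=traces,
                           energies=energies, labels=labels, failed=failed)


DEFAULT_BOX_SWEEP = tuple(float(L) for L in range(25, 36))


@dataclass
class BoxScanResult:
    best_L: float
    table: pd.DataFrame
    state: SystemState


def optimize_box(spec: InitSpec, template1: LipidTemplate,
                 template2: LipidTemplate, params: RunParams,
                 interactions: InteractionMatrix,
                 L_values=None, rho: float = 3.0,
                 bonded: BondedParams | None = None,
                 window: float = 0.1) -> BoxScanResult:
    """Sweep the box size at fixed lipid counts; water adjusts to keep rho.

    Defaults to the 25..35 r_c sweep.  Returns the lowest-energy box and a
    (L, E_final) table; ties go to the smallest L.
    """
    if L_values is None:
        L_values = DEFAULT_BOX_SWEEP
    L_values = list(L_values)
    if not L_values:
        raise ValueError("need at least one box size")
    states, energies, kept = [], [], []
    failed = {}
    for L in L_values:
        sp = InitSpec(spec.mode, spec.n1, spec.n2, float(L), spec.seed)
        try:
            state = init_state(sp, template1, template2, rho=rho,
                               kBT=params.kBT, bonded=bonded)
            trace = run(state, params, interactions)
            e = trace.final_window_mean(window) if len(trace) else float("nan")
        except (RuntimeError, ValueError) as err:
            log.warning("box L=%s aborted: %s", L, err)
            failed[f"L={L}"] = str(err)
            continue
        states.append(state)
        energies.append(e)
        kept.append(float(L))
    if not states:
        raise RuntimeError(f"all box sizes aborted: {failed}")
    idx = _pick_lowest(energies)
    table = pd.DataFrame({"L": kept, "E_final": energies})
    return BoxScanResult(best_L=kept[idx], table=table, state=states[idx])
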