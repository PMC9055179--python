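"""DPD time evolution: system state, run parameters, forces and integrator.

The equations of motion are integrated with the Groot-Warren modified
velocity-Verlet scheme (lambda = 0.5): half-kick, drift, force evaluation
with the half-kicked velocities as the dissipative-force predictor, then
the closing half-kick.  The pairwise thermostat satisfies the
fluctuation-dissipation relation sigma^2 = 2 gamma k_B T, which
:class:`RunParams` enforces at construction.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import kernels
from .topology import BEAD_MASS, InteractionMatrix, SystemTopology

log = logging.getLogger(__name__)

_U64MASK = (1 << 64) - 1


def _noise_key(seed: int, step: int) -> np.uint64:
    """Per-step noise key: splitmix64 finalizer of (seed, step)."""
    x = ((seed & _U64MASK) * 0x9E3779B97F4A7C15 + step) & _U64MASK
    x = (x + 0x9E3779B97F4A7C15) & _U64MASK
    z = x
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _U64MASK
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _U64MASK
    return np.uint64(z ^ (z >> 31))


@dataclass
class RunParams:
    """Integration and thermostat parameters (reduced units).

    Exactly one of ``gamma`` / ``sigma`` may be left to be derived from the
    other through sigma^2 = 2 gamma k_B T; passing both requires them to be
    consistent.  Defaults are the standard DPD choice gamma = 4.5 (hence
    sigma = 3.0 at k_B T = 1) with a time step of 0.01 tau.
    """

    n_steps: int
    seed: int = 0
    gamma: float | None = 4.5
    sigma: float | None = None
    kBT: float = 1.0
    dt: float = 0.01
    r_cut: float = 1.0
    report_every: int = 100

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.report_every < 1:
            raise ValueError("report_every must be >= 1")
        if self.gamma is None and self.sigma is None:
            raise ValueError("provide gamma or sigma")
        if self.sigma is None:
            self.sigma = math.sqrt(2.0 * self.gamma * self.kBT)
        elif self.gamma is None:
            self.gamma = self.sigma ** 2 / (2.0 * self.kBT)
        else:
            if abs(self.sigma ** 2 - 2.0 * self.gamma * self.kBT) > 1e-10:
                raise ValueError(
                    "sigma and gamma violate the fluctuation-dissipation "
                    f"relation sigma^2 = 2 gamma kBT: sigma={self.sigma}, "
                    f"gamma={self.gamma}, kBT={self.kBT}")


@dataclass
class SystemState:
    """Positions, velocities and topology of all beads in a periodic cube."""

    box: float
    positions: np.ndarray
    velocities: np.ndarray
    topology: SystemTopology

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        n = self.topology.n_beads
        if self.positions.shape != (n, 3) or self.velocities.shape != (n, 3):
            raise ValueError(
                f"positions/velocities must have shape ({n}, 3) to match the "
                "topology")
        if self.box <= 0:
            raise ValueError("box length must be positive")
        self.wrap()

    @property
    def n_beads(self) -> int:
        return self.topology.n_beads

    @property
    def species(self) -> np.ndarray:
        return self.topology.species

    def wrap(self) -> None:
        np.mod(self.positions, self.box, out=self.positions)

    def copy(self) -> "SystemState":
        return SystemState(self.box, self.positions.copy(),
                           self.velocities.copy(), self.topology)

    def kinetic_temperature(self) -> float:
        """Instantaneous kinetic temperature <m v^2> / 3 per bead."""
        v2 = float(np.sum(self.velocities ** 2))
        return BEAD_MASS * v2 / (3.0 * self.n_beads)

    def momentum(self) -> np.ndarray:
        return BEAD_MASS * self.velocities.sum(axis=0)


@dataclass
class ForceResult:
    forces: np.ndarray
    e_pair: float
    e_bond: float
    e_angle: float
    n_overlap: int = 0
    n_clamped: int = 0

    @property
    def e_total(self) -> float:
        return self.e_pair + self.e_bond + self.e_angle


def weight(r: float | np.ndarray, r_cut: float = 1.0):
    """DPD weight function w(r) = 1 - r/r_cut for r < r_cut, else 0."""
    r = np.asarray(r, dtype=np.float64)
    out = np.where(r < r_cut, 1.0 - r / r_cut, 0.0)
    return float(out) if out.ndim == 0 else out


def _species64(state: SystemState) -> np.ndarray:
    return state.topology.species.astype(np.int64)


def pair_forces(state: SystemState, params: RunParams,
                interactions: InteractionMatrix, step_index: int = 0,
                velocities: np.ndarray | None = None,
                force_allpairs: bool = False) -> ForceResult:
    """Conservative + dissipative + random pair forces.

    Uses a linked-cell neighbour search when the box holds at least three
    cells per axis, otherwise the all-pairs loop (which is also exposed via
    ``force_allpairs`` as an O(N^2) oracle).  ``velocities`` overrides the
    velocities used for the dissipative force (the integrator's predictor).
    """
    pos = state.positions
    vel = state.velocities if velocities is None else velocities
    vel = np.ascontiguousarray(vel)
    f = np.zeros_like(pos)
    key = _noise_key(params.seed, step_index)
    inv_sqrt_dt = 1.0 / math.sqrt(params.dt)
    M = int(state.box / params.r_cut)
    if M >= 3 and not force_allpairs:
        cell_start, order = kernels.build_cells(pos, state.box, M)
        u, nov = kernels.pair_forces_cells(
            pos, vel, _species64(state), interactions.a, state.box,
            params.r_cut, params.gamma, params.sigma, inv_sqrt_dt, key, M,
            cell_start, order, kernels._OFFSETS, f)
    else:
        u, nov = kernels.pair_forces_allpairs(
            pos, vel, _species64(state), interactions.a, state.box,
            params.r_cut, params.gamma, params.sigma, inv_sqrt_dt, key, f)
    if nov:
        log.warning("%d exactly-overlapping bead pairs at step %d "
                    "(random contact direction used)", nov, step_index)
    return ForceResult(f, e_pair=u, e_bond=0.0, e_angle=0.0, n_overlap=nov)


def bonded_forces(state: SystemState) -> ForceResult:
    """Harmonic-bond and bending forces from the state's topology."""
    top = state.topology
    f = np.zeros_like(state.positions)
    eb, ea, ncl = kernels.bonded_forces_kernel(
        state.positions, state.box, top.bond_idx, top.bond_ks, top.bond_rs,
        top.angle_idx, top.angle_k, top.angle_theta0, f)
    if ncl:
        log.warning("%d angle gradients clamped at collinear configurations",
                    ncl)
    return ForceResult(f, e_pair=0.0, e_bond=eb, e_angle=ea, n_clamped=ncl)


def compute_forces(state: SystemState, params: RunParams,
                   interactions: InteractionMatrix, step_index: int = 0,
                   velocities: np.ndarray | None = None) -> ForceResult:
    """Total force (pair + bonded) and decomposed potential energies."""
    pr = pair_forces(state, params, interactions, step_index, velocities)
    br = bonded_forces(state)
    return ForceResult(pr.forces + br.forces, e_pair=pr.e_pair,
                       e_bond=br.e_bond, e_angle=br.e_angle,
                       n_overlap=pr.n_overlap, n_clamped=br.n_clamped)


@dataclass
class EnergyTrace:
    """Per-report energy decomposition and kinetic temperature.

    Energies are per bead in units of k_B T; time is in tau.
    """

    step: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    time: np.ndarray = field(default_factory=lambda: np.empty(0))
    e_pair: np.ndarray = field(default_factory=lambda: np.empty(0))
    e_bond: np.ndarray = field(default_factory=lambda: np.empty(0))
    e_angle: np.ndarray = field(default_factory=lambda: np.empty(0))
    e_per_bead: np.ndarray = field(default_factory=lambda: np.empty(0))
    t_kin: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __len__(self) -> int:
        return self.step.shape[0]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "step": self.step, "time_tau": self.time, "E_pair": self.e_pair,
            "E_bond": self.e_bond, "E_angle": self.e_angle,
            "E_per_bead": self.e_per_bead, "T_kin": self.t_kin,
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EnergyTrace":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(step=df["step"].to_numpy(np.int64),
                   time=df["time_tau"].to_numpy(float),
                   e_pair=df["E_pair"].to_numpy(float),
                   e_bond=df["E_bond"].to_numpy(float),
                   e_angle=df["E_angle"].to_numpy(float),
                   e_per_bead=df["E_per_bead"].to_numpy(float),
                   t_kin=df["T_kin"].to_numpy(float))

    def final_window_mean(self, fraction: float = 0.1) -> float:
        """Mean per-bead energy over the final `fraction` of reports."""
        n = max(1, int(math.ceil(fraction * len(self))))
        return float(np.mean(self.e_per_bead[-n:]))


class _TraceBuilder:
    def __init__(self):
        self.rows = []

    def add(self, step, time, fr: ForceResult, t_kin, n):
        self.rows.append((step, time, fr.e_pair / n, fr.e_bond / n,
                          fr.e_angle / n, fr.e_total / n, t_kin))

    def build(self) -> EnergyTrace:
        if not self.rows:
            return EnergyTrace()
        a = np.array(self.rows, dtype=np.float64)
        return EnergyTrace(step=a[:, 0].astype(np.int64), time=a[:, 1],
                           e_pair=a[:, 2], e_bond=a[:, 3], e_angle=a[:, 4],
                           e_per_bead=a[:, 5], t_kin=a[:, 6])


def _check_finite(state: SystemState, step: int) -> None:
    for name, arr in (("position", state.positions),
                      ("velocity", state.velocities)):
        bad = np.nonzero(~np.isfinite(arr).all(axis=1))[0]
        if bad.size:
            i = int(bad[0])
            raise RuntimeError(
                f"non-finite {name} at step {step}, bead {i} "
                f"(species {int(state.species[i])}): "
                f"pos={state.positions[i]}, vel={state.velocities[i]}")


def step(state: SystemState, params: RunParams,
         interactions: InteractionMatrix, step_index: int = 1,
         forces: ForceResult | None = None) -> ForceResult:
    """Advance the state by one time step in place; returns the new forces.

    ``forces`` is the force evaluation at the current state (recomputed if
    not supplied); the returned result can be threaded into the next call.
    """
    if forces is None:
        forces = compute_forces(state, params, interactions, step_index - 1)
    dt = params.dt
    v_half = state.velocities + (0.5 * dt / BEAD_MASS) * forces.forces
    state.positions += dt * v_half
    state.wrap()
    f_new = compute_forces(state, params, interactions, step_index,
                           velocities=v_half)
    state.velocities = v_half + (0.5 * dt / BEAD_MASS) * f_new.forces
    return f_new


class TrajectoryRecorder:
    """Observer that snapshots the state every ``every`` reports."""

    def __init__(self, every: int = 1):
        self.every = every
        self.frames: list[SystemState] = []
        self._count = 0

    def __call__(self, step_index: int, state: SystemState) -> None:
        if self._count % self.every == 0:
            self.frames.append(state.copy())
        self._count += 1


def run(state: SystemState, params: RunParams,
        interactions: InteractionMatrix, observers=()) -> EnergyTrace:
    """Advance ``n_steps`` steps in place, reporting every ``report_every``.

    Observers are callables ``(step_index, state)`` invoked at every report
    (including the initial state).  Returns the energy trace; a run with
    ``n_steps = 0`` leaves the state untouched.
    """
    builder = _TraceBuilder()
    n = state.n_beads
    if params.n_steps == 0:
        return builder.build()
    fr = compute_forces(state, params, interactions, 0)
    builder.add(0, 0.0, fr, state.kinetic_temperature(), n)
    for obs in observers:
        obs(0, state)
    for k in range(1, params.n_steps + 1):
        fr = step(state, params, interactions, step_index=k, forces=fr)
        if k % params.report_every == 0 or k == params.n_steps:
            t_kin = state.kinetic_temperature()
            builder.add(k, k * params.dt, fr, t_kin, n)
            _check_finite(state, k)
            for obs in observers:
                obs(k, state)
            log.info("step %d  E/bead=%.4f  T_kin=%.4f", k, fr.e_total / n,
                     t_kin)
    return builder.build()
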