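"""Observables: density profiles, orientational order, gyration tensor,
shape factor, kinetic-stage segmentation, and Irving-Kirkwood mechanics.

Conventions
-----------
* Profiles are binned along one box axis into equal slabs; per-species
  number densities are exact (slab sums recover bead counts).
* The orientational order parameter is the second Legendre polynomial
  S = <(3 cos^2 theta - 1)/2> of the chain direction against a reference
  axis: 1 when parallel, -0.5 when perpendicular.
* The gyration tensor of a chain is the second moment of its (periodically
  unwrapped) bead positions about the chain centre; the shape factor
  delta = 1 - 3 (L1 L2 + L2 L3 + L3 L1) / (L1 + L2 + L3)^2 of its sorted
  eigenvalues L1 <= L2 <= L3 is 0 for isotropic and 1 for rod-like chains.
* Local pressure uses the Irving-Kirkwood-1 contour: each pair (and each
  bonded-arm) virial F_ij,a * a_ij is spread over the slabs crossed by the
  i-j segment in proportion to path length, so slab-integrated stress
  equals the whole-box virial identically.  Only conservative and bonded
  forces enter: the dissipative and random pair of the thermostat cancels
  on average by construction.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import kernels
from .engine import EnergyTrace, SystemState
from .topology import BEAD_MASS, N_SPECIES, InteractionMatrix, Species

log = logging.getLogger(__name__)

_AXES = {"x": 0, "y": 1, "z": 2, 0: 0, 1: 1, 2: 2}


def _axis_index(axis) -> int:
    try:
        return _AXES[axis]
    except KeyError:
        raise ValueError(f"axis must be x, y, z or 0..2, got {axis!r}") from None


def _as_frames(states) -> list[SystemState]:
    if isinstance(states, SystemState):
        return [states]
    frames = list(states)
    if not frames:
        raise ValueError("need at least one frame")
    return frames


# ---------------------------------------------------------------------------
# density profiles
# ---------------------------------------------------------------------------

@dataclass
class Profile:
    """Per-species number density phi_s(bin) along one axis (beads / r_c^3)."""

    axis: str
    bin_edges: np.ndarray
    density: np.ndarray       # (N_SPECIES, n_bins)
    n_frames: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def species(self, s) -> np.ndarray:
        if isinstance(s, str):
            s = Species[s]
        return self.density[int(s)]

    def to_dataframe(self) -> pd.DataFrame:
        d = {"bin_center": self.bin_centers}
        for s in Species:
            d[f"phi_{s.name}"] = self.density[int(s)]
        return pd.DataFrame(d)


def density_profile(states, axis="z", n_bins: int = 60) -> Profile:
    """Per-species number density in equal slabs; frame lists are averaged."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    frames = _as_frames(states)
    L = frames[0].box
    h = L / n_bins
    ax = _axis_index(axis)
    counts = np.zeros((N_SPECIES, n_bins))
    for st in frames:
        b = np.minimum((st.positions[:, ax] / h).astype(np.int64), n_bins - 1)
        for s in range(N_SPECIES):
            sel = st.topology.species == s
            counts[s] += np.bincount(b[sel], minlength=n_bins)
    v_bin = h * L * L
    density = counts / (v_bin * len(frames))
    edges = np.linspace(0.0, L, n_bins + 1)
    return Profile(axis=str(axis), bin_edges=edges, density=density,
                   n_frames=len(frames))


# ---------------------------------------------------------------------------
# orientational order
# ---------------------------------------------------------------------------

@dataclass
class OrderResult:
    values: np.ndarray            # per-chain order parameter in [-0.5, 1]
    mean: float
    hist_centers: np.ndarray
    hist_counts: np.ndarray
    gauss_fit: tuple | None       # (mean, sd, amplitude) or None
    n_skipped: int


def _minimg_vec(d: np.ndarray, L: float) -> np.ndarray:
    return d - L * np.round(d / L)


def chain_direction_vectors(state: SystemState, lipid_type: int | None = None,
                            vector: str = "head") -> np.ndarray:
    """Per-chain direction vectors (minimum image).

    ``vector='head'`` uses the first-to-last bead of the head chain;
    ``'end_to_end'`` uses the first head bead to the last bead of the first
    tail chain (whole-lipid span).
    """
    top = state.topology
    chains = (np.arange(top.n_chains) if lipid_type is None
              else top.chains_of_type(lipid_type))
    first = top.chain_first[chains]
    nh = top.chain_nhead[chains]
    nt = top.chain_ntail[chains]
    if vector == "head":
        end = first + nh - 1
    elif vector == "end_to_end":
        end = first + nh + nt - 1
    else:
        raise ValueError("vector must be 'head' or 'end_to_end'")
    d = state.positions[end] - state.positions[first]
    return _minimg_vec(d, state.box)


def order_parameter(state: SystemState, lipid_type: int | None = None,
                    reference_axis="z", vector: str = "head",
                    n_hist_bins: int = 30) -> OrderResult:
    """Second-Legendre orientational order of chain directions.

    Chains with a zero-length direction vector (single-bead head chains, or
    a periodic coincidence) are skipped and counted in ``n_skipped``.
    """
    ax = _axis_index(reference_axis)
    d = chain_direction_vectors(state, lipid_type, vector)
    if d.shape[0] == 0:
        raise ValueError("no chains selected")
    norms = np.linalg.norm(d, axis=1)
    ok = norms > 1e-12
    n_skipped = int(np.count_nonzero(~ok))
    if n_skipped:
        log.warning("%d chains skipped (zero-length direction vector)",
                    n_skipped)
    cos = d[ok, ax] / norms[ok]
    values = 1.5 * cos ** 2 - 0.5
    hist, edges = np.histogram(values, bins=n_hist_bins, range=(-0.5, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    fit = _gaussian_fit(centers, hist.astype(float))
    return OrderResult(values=values, mean=float(values.mean()),
                       hist_centers=centers, hist_counts=hist.astype(float),
                       gauss_fit=fit, n_skipped=n_skipped)


def _gaussian_fit(x: np.ndarray, y: np.ndarray):
    """Unweighted least-squares Gaussian fit of a histogram; None on failure."""
    from scipy.optimize import curve_fit

    if np.count_nonzero(y) < 3:
        return None
    w = y / y.sum()
    mu0 = float((x * w).sum())
    sd0 = float(math.sqrt(max(((x - mu0) ** 2 * w).sum(), 1e-12)))
    a0 = float(y.max())

    def gauss(x, mu, sd, a):
        return a * np.exp(-0.5 * ((x - mu) / sd) ** 2)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(gauss, x, y, p0=(mu0, sd0, a0), maxfev=5000)
    except Exception:
        return None
    mu, sd, a = popt
    return (float(mu), abs(float(sd)), float(a))


# ---------------------------------------------------------------------------
# gyration tensor and shape factor
# ---------------------------------------------------------------------------

def unwrap_chain(state: SystemState, chain: int) -> np.ndarray:
    """Bead coordinates of one chain, unwrapped across periodic images by
    walking the chain connectivity with minimum-image steps."""
    top = state.topology
    first = int(top.chain_first[chain])
    nh = int(top.chain_nhead[chain])
    nt = int(top.chain_ntail[chain])
    n = nh + 2 * nt
    pos = state.positions
    L = state.box
    out = np.empty((n, 3))
    out[0] = pos[first]
    # head chain: sequential; tails: branch off the last head bead
    parents = np.empty(n, dtype=np.int64)
    parents[0] = -1
    for k in range(1, nh):
        parents[k] = k - 1
    for t in range(2):
        base = nh + t * nt
        parents[base] = nh - 1
        for m in range(1, nt):
            parents[base + m] = base + m - 1
    for k in range(1, n):
        p = parents[k]
        step = _minimg_vec(pos[first + k] - pos[first + p], L)
        out[k] = out[p] + step
    return out


def gyration_tensor_of(xyz: np.ndarray) -> np.ndarray:
    """Gyration tensor of one bead cloud (no unwrapping)."""
    d = np.asarray(xyz, float) - np.asarray(xyz, float).mean(axis=0)
    return d.T @ d / d.shape[0]


def gyration_tensors(state: SystemState,
                     lipid_type: int | None = None) -> np.ndarray:
    """Per-chain gyration tensors R^2_g,ab (shape (n_chains, 3, 3)).

    R^2_g,ab = (1/N) sum_i (r_ia - rbar_a)(r_ib - rbar_b) over the beads of
    one chain, with positions unwrapped along the chain connectivity.
    """
    top = state.topology
    chains = (np.arange(top.n_chains) if lipid_type is None
              else top.chains_of_type(lipid_type))
    tensors = np.empty((len(chains), 3, 3))
    for k, c in enumerate(chains):
        tensors[k] = gyration_tensor_of(unwrap_chain(state, int(c)))
    return tensors


@dataclass
class GyrationPoint:
    """Ensemble components <R_g,aa> = sqrt(mean over chains of R^2_g,aa)."""

    rg_xx: float
    rg_yy: float
    rg_zz: float

    @property
    def rg_mean(self) -> float:
        """Scalar <R_g> = sqrt(mean trace)."""
        return math.sqrt(self.rg_xx ** 2 + self.rg_yy ** 2 + self.rg_zz ** 2)


def gyration_point(tensors: np.ndarray) -> GyrationPoint:
    if tensors.shape[0] == 0:
        raise ValueError("no chains")
    m = tensors.mean(axis=0)
    return GyrationPoint(rg_xx=math.sqrt(max(m[0, 0], 0.0)),
                         rg_yy=math.sqrt(max(m[1, 1], 0.0)),
                         rg_zz=math.sqrt(max(m[2, 2], 0.0)))


def gyration_series(frames, times, lipid_type: int | None = None) -> pd.DataFrame:
    """<R_g,aa>(t) per frame; ``times`` in tau, one per frame."""
    rows = []
    for t, st in zip(times, _as_frames(frames)):
        g = gyration_point(gyration_tensors(st, lipid_type))
        rows.append((t, g.rg_xx, g.rg_yy, g.rg_zz, g.rg_mean))
    return pd.DataFrame(rows, columns=["time_tau", "rg_xx", "rg_yy", "rg_zz",
                                       "rg_mean"])


def shape_factor(tensors: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-chain shape factors and their ensemble mean.

    delta = 1 - 3 (L1 L2 + L2 L3 + L3 L1) / (L1 + L2 + L3)^2 with the
    sorted eigenvalues L1 <= L2 <= L3 of the gyration tensor; chains with a
    zero-trace tensor (single beads) get delta = 0.
    """
    if tensors.shape[0] == 0:
        raise ValueError("no chains")
    ev = np.linalg.eigvalsh(tensors)      # ascending
    ev = np.maximum(ev, 0.0)
    tr = ev.sum(axis=1)
    # normalise by the trace first so near-underflow eigenvalues stay stable
    safe_tr = np.where(tr > 0.0, tr, 1.0)
    evn = ev / safe_tr[:, None]
    pair = (evn[:, 0] * evn[:, 1] + evn[:, 1] * evn[:, 2]
            + evn[:, 2] * evn[:, 0])
    delta = np.where(tr > 0.0, 1.0 - 3.0 * pair, 0.0)
    delta = np.clip(delta, 0.0, 1.0)
    return delta, float(delta.mean())


def shape_series(frames, times, lipid_type: int | None = None) -> pd.DataFrame:
    rows = []
    for t, st in zip(times, _as_frames(frames)):
        _, mean = shape_factor(gyration_tensors(st, lipid_type))
        rows.append((t, mean))
    return pd.DataFrame(rows, columns=["time_tau", "delta"])


# ---------------------------------------------------------------------------
# kinetic-stage segmentation
# ---------------------------------------------------------------------------

STAGE_LABELS = ("random_generation", "mutual_adaptation", "formation")


@dataclass
class StageSegmentation:
    boundaries: np.ndarray        # (2,) change-point times, tau
    boundary_indices: np.ndarray  # (2,) report indices (start of stages 2, 3)
    stage_means: np.ndarray       # (3,) mean per-bead energy, k_B T
    durations: np.ndarray         # (3,) tau
    labels: tuple = STAGE_LABELS
    degenerate: bool = False


def segment_stages(trace: EnergyTrace, min_reports: int = 30) -> StageSegmentation:
    """Split an energy trace into three stages by exact least-squares
    change-point search (two change points minimising total within-stage
    variance, dynamic enumeration over report indices)."""
    y = np.asarray(trace.e_per_bead, dtype=float)
    t = np.asarray(trace.time, dtype=float)
    n = y.shape[0]
    if n < min_reports:
        raise ValueError(f"need at least {min_reports} reports, got {n}")
    if np.ptp(y) < 1e-12:
        b1, b2 = n // 3, (2 * n) // 3
        return _build_segmentation(y, t, b1, b2, degenerate=True)
    s1 = np.concatenate([[0.0], np.cumsum(y)])
    s2 = np.concatenate([[0.0], np.cumsum(y * y)])

    def seg_cost(i, j):
        # SSE of y[i:j] (vectorised over array arguments)
        m = j - i
        tot = s1[j] - s1[i]
        return (s2[j] - s2[i]) - tot * tot / m

    idx = np.arange(n + 1)
    c_head = seg_cost(0, idx[1:n - 1])          # [0, b1), b1 = 1..n-2
    c_tail = seg_cost(idx[2:n], n)              # [b2, n), b2 = 2..n-1
    best = (math.inf, 1, 2)
    for b1 in range(1, n - 1):
        b2s = np.arange(b1 + 1, n)
        mid = seg_cost(b1, b2s)
        tot = c_head[b1 - 1] + mid + c_tail[b2s - 2]
        k = int(np.argmin(tot))
        if tot[k] < best[0]:
            best = (float(tot[k]), b1, int(b2s[k]))
    _, b1, b2 = best
    return _build_segmentation(y, t, b1, b2, degenerate=False)


def _build_segmentation(y, t, b1, b2, degenerate):
    means = np.array([y[:b1].mean(), y[b1:b2].mean(), y[b2:].mean()])
    if not degenerate and (means[1] > means[0] + 1e-12
                           or means[2] > means[1] + 1e-12):
        warnings.warn("stage mean energies are not non-increasing",
                      RuntimeWarning, stacklevel=3)
    bounds = np.array([t[b1], t[b2]])
    durations = np.array([t[b1] - t[0], t[b2] - t[b1], t[-1] - t[b2]])
    return StageSegmentation(boundaries=bounds,
                             boundary_indices=np.array([b1, b2]),
                             stage_means=means, durations=durations,
                             degenerate=degenerate)


# ---------------------------------------------------------------------------
# Irving-Kirkwood local pressure, tension, osmotic pressure
# ---------------------------------------------------------------------------

@dataclass
class StressProfile:
    """Slab-resolved pressure-tensor diagonal along one axis.

    ``per_species`` holds the decomposition by contribution channel: each
    pair/bonded virial and each kinetic term is split half/half between the
    species of the two beads involved (kinetic terms go fully to their
    bead's species).  Summing channels recovers the totals exactly.
    """

    axis: str
    bin_edges: np.ndarray
    p_xx: np.ndarray
    p_yy: np.ndarray
    p_zz: np.ndarray
    per_species: np.ndarray       # (N_SPECIES, n_bins, 3)
    global_p: np.ndarray          # (3,) whole-box virial pressure components
    n_frames: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def component(self, axis) -> np.ndarray:
        return (self.p_xx, self.p_yy, self.p_zz)[_axis_index(axis)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_center": self.bin_centers,
                             "p_xx": self.p_xx, "p_yy": self.p_yy,
                             "p_zz": self.p_zz})


def local_pressure(frames, axis, n_bins: int,
                   interactions: InteractionMatrix,
                   r_cut: float = 1.0) -> StressProfile:
    """Irving-Kirkwood pressure profile from one or more frames.

    Recomputes conservative pair and bonded forces from positions (the
    thermostat's dissipative/random pair cancels in the mean) and spreads
    each virial along the minimum-image segment between its two beads.
    """
    frames = _as_frames(frames)
    st0 = frames[0]
    L = st0.box
    ax = _axis_index(axis)
    h = L / n_bins
    if h < 0.1:
        raise ValueError(
            f"bin width {h:.3f} r_c < 0.1 r_c: statistics unusable")
    top = st0.topology
    acc = np.zeros((n_bins, 3, N_SPECIES))
    glob = np.zeros(3)
    kin_glob = np.zeros(3)
    sp64 = top.species.astype(np.int64)
    M = int(L / r_cut)
    for st in frames:
        pos = st.positions
        if M >= 3:
            cell_start, order = kernels.build_cells(pos, L, M)
            kernels.ik_pair_stress_cells(pos, sp64, interactions.a, L, r_cut,
                                         ax, n_bins, M, cell_start, order,
                                         kernels._OFFSETS, acc, glob)
        else:
            kernels.ik_pair_stress_allpairs(pos, sp64, interactions.a, L,
                                            r_cut, ax, n_bins, acc, glob)
        kernels.ik_bonded_stress(pos, sp64, L, top.bond_idx, top.bond_ks,
                                 top.bond_rs, top.angle_idx, top.angle_k,
                                 top.angle_theta0, ax, n_bins, acc, glob)
        # kinetic part m v_a^2, binned by bead position
        b = np.minimum((pos[:, ax] / h).astype(np.int64), n_bins - 1)
        k = BEAD_MASS * st.velocities ** 2
        kin_glob += k.sum(axis=0)
        for s in range(N_SPECIES):
            sel = top.species == s
            if not np.any(sel):
                continue
            for comp in range(3):
                acc[:, comp, s] += np.bincount(b[sel], weights=k[sel, comp],
                                               minlength=n_bins)
    v_bin = h * L * L
    nf = len(frames)
    per_species = np.transpose(acc, (2, 0, 1)) / (v_bin * nf)
    total = per_species.sum(axis=0)
    global_p = (glob + kin_glob) / (L ** 3 * nf)
    edges = np.linspace(0.0, L, n_bins + 1)
    return StressProfile(axis=str(axis), bin_edges=edges,
                         p_xx=total[:, 0], p_yy=total[:, 1],
                         p_zz=total[:, 2], per_species=per_species,
                         global_p=global_p, n_frames=nf)


@dataclass
class TensionProfile:
    """Normal-minus-tangential anisotropy t = p_N - (p_T1 + p_T2)/2 per bin
    and its running integral; sigma is the total tension (k_B T / r_c^2)."""

    profile_axis: str
    normal_axis: str
    bin_centers: np.ndarray
    integrand: np.ndarray
    per_species: np.ndarray       # (N_SPECIES, n_bins)
    sigma: float
    bin_width: float

    def species(self, s) -> np.ndarray:
        if isinstance(s, str):
            s = Species[s]
        return self.per_species[int(s)]

    def species_sigma(self, species_list) -> float:
        tot = np.zeros_like(self.integrand)
        for s in species_list:
            tot = tot + self.species(s)
        return float(tot.sum() * self.bin_width)


def interface_tension(stress: StressProfile, normal_axis) -> TensionProfile:
    """Interface tension from a stress profile.

    ``normal_axis`` is the membrane normal whose pressure component plays
    p_N; the other two components are tangential.  When the profile axis
    coincides with the normal this is the classic tension integrand across
    the membrane; with a transverse profile axis it resolves the same
    integrand laterally (averaged over the remaining directions).
    """
    nrm = _axis_index(normal_axis)
    tang = [a for a in range(3) if a != nrm]
    comps = [stress.p_xx, stress.p_yy, stress.p_zz]
    integrand = comps[nrm] - 0.5 * (comps[tang[0]] + comps[tang[1]])
    ps = (stress.per_species[:, :, nrm]
          - 0.5 * (stress.per_species[:, :, tang[0]]
                   + stress.per_species[:, :, tang[1]]))
    width = float(stress.bin_edges[1] - stress.bin_edges[0])
    return TensionProfile(profile_axis=stress.axis,
                          normal_axis="xyz"[nrm],
                          bin_centers=stress.bin_centers,
                          integrand=integrand, per_species=ps,
                          sigma=float(integrand.sum() * width),
                          bin_width=width)


@dataclass
class OsmoticProfile:
    """Deviation of the normal pressure from its bulk-water value."""

    profile_axis: str
    normal_axis: str
    bin_centers: np.ndarray
    pi: np.ndarray
    per_species: np.ndarray       # (N_SPECIES, n_bins)
    bulk_window: tuple

    def species(self, s) -> np.ndarray:
        if isinstance(s, str):
            s = Species[s]
        return self.per_species[int(s)]


def osmotic_pressure(stress: StressProfile, normal_axis,
                     bulk_window: tuple[float, float]) -> OsmoticProfile:
    """Osmotic-pressure profile Pi(bin) = p_N(bin) - <p_N>_bulk.

    ``bulk_window`` is a coordinate interval along the profile axis that
    must contain at least one bin of bulk water; the same window zeroes the
    per-species partial contributions.
    """
    nrm = _axis_index(normal_axis)
    lo, hi = bulk_window
    centers = stress.bin_centers
    mask = (centers >= lo) & (centers <= hi)
    if not np.any(mask):
        raise ValueError(
            f"bulk window [{lo}, {hi}] contains no bins on the {stress.axis} "
            "axis; a bulk-water reference window on the profile axis is "
            "required")
    p_n = stress.component(nrm)
    pi = p_n - p_n[mask].mean()
    ps = stress.per_species[:, :, nrm]
    ps = ps - ps[:, mask].mean(axis=1, keepdims=True)
    return OsmoticProfile(profile_axis=stress.axis, normal_axis="xyz"[nrm],
                          bin_centers=centers, pi=pi, per_species=ps,
                          bulk_window=(float(lo), float(hi)))
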