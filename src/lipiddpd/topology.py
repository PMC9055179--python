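"""Bead species, lipid blueprints, and bonded topology.

A model phospholipid is a short branched bead-spring polymer: one linear
hydrophilic head chain of ``n_head`` beads joined at its last bead to two
linear hydrophobic tail chains of ``n_tail`` beads each.  Two lipid species
(type 1 and type 2) differ only in their bead species labels and chain
lengths; together with water they give five bead species.

All quantities are in reduced DPD units: the pair cut-off ``r_c`` is the
length scale, the bead mass is the mass scale, and ``k_B T`` the energy
scale.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np

log = logging.getLogger(__name__)

#: All beads share the same (unit) mass.
BEAD_MASS = 1.0


class Species(IntEnum):
    """The five bead species: heads/tails of lipid types 1 and 2, plus water."""

    HB1 = 0
    TB1 = 1
    HB2 = 2
    TB2 = 3
    W = 4


N_SPECIES = len(Species)
SPECIES_LABELS = [s.name for s in Species]
_LABEL_TO_SPECIES = {s.name: s for s in Species}


def species_from_label(label: str) -> Species:
    try:
        return _LABEL_TO_SPECIES[label]
    except KeyError:
        raise ValueError(f"unknown bead species label {label!r}; "
                         f"expected one of {SPECIES_LABELS}") from None


class AngleClass(IntEnum):
    """Three classes of bending terms inside one lipid."""

    intra_chain = 0        # three consecutive beads within one chain
    head_tail_junction = 1  # last two head beads + first tail bead
    tail_tail_split = 2     # first bead of each tail, apex at last head bead


@dataclass(frozen=True)
class BondedParams:
    """Bonded force-field constants (reduced units).

    Defaults are the standard coarse-grained phospholipid parameterisation:
    harmonic springs with ``k_s = 100``, ``r_s = 0.7 r_c`` and bending
    constants 6.0 / 3.0 / 4.5 for the intra-chain, head-tail-junction and
    tail-tail-split angle classes.  All equilibrium angles default to
    straight (pi).
    """

    k_s: float = 100.0
    r_s: float = 0.7
    k_theta_chain: float = 6.0
    k_theta_junction: float = 3.0
    k_theta_split: float = 4.5
    theta0_chain: float = math.pi
    theta0_junction: float = math.pi
    theta0_split: float = math.pi

    def __post_init__(self):
        if self.k_s <= 0 or self.r_s <= 0:
            raise ValueError("k_s and r_s must be positive")
        for k in (self.k_theta_chain, self.k_theta_junction, self.k_theta_split):
            if k < 0:
                raise ValueError("bending constants must be >= 0")
        for t0 in (self.theta0_chain, self.theta0_junction, self.theta0_split):
            if not 0.0 <= t0 <= math.pi:
                raise ValueError("equilibrium angles must lie in [0, pi]")


@dataclass(frozen=True)
class LipidTemplate:
    """Blueprint of one lipid species.

    ``n_head`` beads form the head chain, and two tail chains of ``n_tail``
    beads each branch off the last head bead, so a lipid has
    ``n_head + 2 * n_tail`` beads.
    """

    type_index: int            # 1 or 2
    n_head: int
    n_tail: int

    def __post_init__(self):
        if self.type_index not in (1, 2):
            raise ValueError("type_index must be 1 or 2")
        if self.n_head < 1 or self.n_tail < 1:
            raise ValueError("n_head and n_tail must be >= 1")

    @property
    def head_species(self) -> Species:
        return Species.HB1 if self.type_index == 1 else Species.HB2

    @property
    def tail_species(self) -> Species:
        return Species.TB1 if self.type_index == 1 else Species.TB2

    @property
    def n_beads(self) -> int:
        return self.n_head + 2 * self.n_tail

    @property
    def contour_length(self) -> float:
        """Head-to-tail-end contour length at the rest bond length 0.7 r_c."""
        return 0.7 * (self.n_head - 1 + self.n_tail)


@dataclass(frozen=True)
class BondTerm:
    i: int
    j: int
    k_s: float
    r_s: float

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("bond endpoints must differ")


@dataclass(frozen=True)
class AngleTerm:
    i: int
    j: int  # apex
    k: int
    k_theta: float
    theta0: float
    angle_class: AngleClass

    def __post_init__(self):
        if len({self.i, self.j, self.k}) != 3:
            raise ValueError("angle indices must be distinct")


def chi_from_a(a_ij: float, a_ii: float) -> float:
    """Flory–Huggins parameter from DPD repulsion amplitudes, chi = 0.286 (a_ij - a_ii)."""
    return 0.286 * (a_ij - a_ii)


@dataclass
class InteractionMatrix:
    """Symmetric 5x5 table of maximum soft-repulsion amplitudes a_ij."""

    a: np.ndarray

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=np.float64)
        if self.a.shape != (N_SPECIES, N_SPECIES):
            raise ValueError(f"interaction matrix must be {N_SPECIES}x{N_SPECIES}")
        if not np.allclose(self.a, self.a.T):
            raise ValueError("interaction matrix must be symmetric")
        if np.any(self.a < 0):
            raise ValueError("repulsion amplitudes must be >= 0")

    def __getitem__(self, key):
        s1, s2 = key
        if isinstance(s1, str):
            s1 = species_from_label(s1)
        if isinstance(s2, str):
            s2 = species_from_label(s2)
        return float(self.a[int(s1), int(s2)])

    def set(self, s1, s2, value: float) -> None:
        if isinstance(s1, str):
            s1 = species_from_label(s1)
        if isinstance(s2, str):
            s2 = species_from_label(s2)
        self.a[int(s1), int(s2)] = value
        self.a[int(s2), int(s1)] = value


def default_interactions(a_like: float = 25.0, a_unlike: float = 100.0) -> InteractionMatrix:
    """Default repulsion table: a_ii = 25 between like beads, a_ij = 100 otherwise.

    The five bead species are treated as pairwise distinct, so heads of
    lipid types 1 and 2 also repel with ``a_unlike``; this is what drives
    the two species into distinct leaflets.  Any entry can be overridden
    afterwards with :meth:`InteractionMatrix.set`.
    """
    a = np.full((N_SPECIES, N_SPECIES), a_unlike, dtype=np.float64)
    np.fill_diagonal(a, a_like)
    return InteractionMatrix(a)


def build_lipid(template: LipidTemplate, first_index: int = 0,
                bonded: BondedParams | None = None, _warn: bool = True
                ) -> tuple[list[Species], list[BondTerm], list[AngleTerm]]:
    """Build the bead species list and bonded terms for one lipid.

    Beads are numbered contiguously from ``first_index`` in the order
    head chain, tail chain A, tail chain B.  Bonds connect consecutive
    beads within each chain and the last head bead to the first bead of
    each tail.  Angle terms come in three classes:

    * intra-chain: every three consecutive beads within one chain;
    * head-tail junction: the last two head beads plus the first bead of
      each tail chain (one term per tail, apex at the last head bead's
      predecessor-neighbour, i.e. the middle bead of the triple);
    * tail-tail split: the two first tail beads with the last head bead as
      apex (one term per lipid).

    Lipids with a single head bead cannot define the junction class; those
    terms are omitted with a logged warning.
    """
    if bonded is None:
        bonded = BondedParams()
    nh, nt = template.n_head, template.n_tail
    head = [first_index + i for i in range(nh)]
    tail_a = [first_index + nh + i for i in range(nt)]
    tail_b = [first_index + nh + nt + i for i in range(nt)]

    species = ([template.head_species] * nh + [template.tail_species] * (2 * nt))

    bonds: list[BondTerm] = []
    for chain in (head, tail_a, tail_b):
        for i, j in zip(chain[:-1], chain[1:]):
            bonds.append(BondTerm(i, j, bonded.k_s, bonded.r_s))
    for tail in (tail_a, tail_b):
        bonds.append(BondTerm(head[-1], tail[0], bonded.k_s, bonded.r_s))

    angles: list[AngleTerm] = []
    for chain in (head, tail_a, tail_b):
        for i, j, k in zip(chain[:-2], chain[1:-1], chain[2:]):
            angles.append(AngleTerm(i, j, k, bonded.k_theta_chain,
                                    bonded.theta0_chain, AngleClass.intra_chain))
    if nh >= 2:
        for tail in (tail_a, tail_b):
            angles.append(AngleTerm(head[-2], head[-1], tail[0],
                                    bonded.k_theta_junction,
                                    bonded.theta0_junction,
                                    AngleClass.head_tail_junction))
    elif _warn:
        log.warning("lipid with n_head=%d < 2: head-tail junction angle terms "
                    "omitted (triple undefined)", nh)
    angles.append(AngleTerm(tail_a[0], head[-1], tail_b[0],
                            bonded.k_theta_split, bonded.theta0_split,
                            AngleClass.tail_tail_split))
    return species, bonds, angles


@dataclass
class SystemTopology:
    """Whole-system bonded topology and bead metadata as flat arrays.

    ``chain_id`` is -1 for water beads; lipid beads carry the index of
    their chain.  ``chain_first`` / ``chain_template`` describe the bead
    layout of each chain (head beads first, then the two tails).
    """

    species: np.ndarray          # (N,) int8
    bond_idx: np.ndarray         # (nb, 2) int64
    bond_ks: np.ndarray          # (nb,) float64
    bond_rs: np.ndarray          # (nb,) float64
    angle_idx: np.ndarray        # (na, 3) int64, middle column is the apex
    angle_k: np.ndarray          # (na,) float64
    angle_theta0: np.ndarray     # (na,) float64
    angle_class: np.ndarray      # (na,) int8
    chain_id: np.ndarray         # (N,) int64, -1 for water
    chain_type: np.ndarray       # (N,) int8, 0 water / 1 / 2
    chain_first: np.ndarray      # (n_chains,) int64
    chain_nhead: np.ndarray      # (n_chains,) int64
    chain_ntail: np.ndarray      # (n_chains,) int64

    @property
    def n_beads(self) -> int:
        return self.species.shape[0]

    @property
    def n_chains(self) -> int:
        return self.chain_first.shape[0]

    @property
    def n_water(self) -> int:
        return int(np.count_nonzero(self.species == int(Species.W)))

    def chains_of_type(self, type_index: int) -> np.ndarray:
        """Indices of chains belonging to lipid type 1 or 2."""
        kinds = self.chain_type[self.chain_first]
        return np.nonzero(kinds == type_index)[0]


def build_system_topology(template1: LipidTemplate, template2: LipidTemplate,
                          n1: int, n2: int, n_water: int,
                          bonded: BondedParams | None = None) -> SystemTopology:
    """Assemble the topology of n1 type-1 lipids, n2 type-2 lipids and water.

    Beads are laid out lipid by lipid (all type-1 chains, then all type-2
    chains), with water beads last.  Two calls with equal inputs yield
    identical term lists.
    """
    if n1 < 0 or n2 < 0 or n_water < 0:
        raise ValueError("counts must be non-negative")
    if bonded is None:
        bonded = BondedParams()
    species: list[int] = []
    bonds: list[BondTerm] = []
    angles: list[AngleTerm] = []
    chain_id: list[int] = []
    chain_type: list[int] = []
    chain_first: list[int] = []
    chain_nhead: list[int] = []
    chain_ntail: list[int] = []

    cursor = 0
    cid = 0
    for template, count in ((template1, n1), (template2, n2)):
        for k in range(count):
            sp, bd, an = build_lipid(template, cursor, bonded, _warn=(k == 0))
            species.extend(int(s) for s in sp)
            bonds.extend(bd)
            angles.extend(an)
            chain_id.extend([cid] * template.n_beads)
            chain_type.extend([template.type_index] * template.n_beads)
            chain_first.append(cursor)
            chain_nhead.append(template.n_head)
            chain_ntail.append(template.n_tail)
            cursor += template.n_beads
            cid += 1
    species.extend([int(Species.W)] * n_water)
    chain_id.extend([-1] * n_water)
    chain_type.extend([0] * n_water)

    bond_idx = np.array([(b.i, b.j) for b in bonds], dtype=np.int64).reshape(-1, 2)
    angle_idx = np.array([(a.i, a.j, a.k) for a in angles], dtype=np.int64).reshape(-1, 3)
    return SystemTopology(
        species=np.array(species, dtype=np.int8),
        bond_idx=bond_idx,
        bond_ks=np.array([b.k_s for b in bonds], dtype=np.float64),
        bond_rs=np.array([b.r_s for b in bonds], dtype=np.float64),
        angle_idx=angle_idx,
        angle_k=np.array([a.k_theta for a in angles], dtype=np.float64),
        angle_theta0=np.array([a.theta0 for a in angles], dtype=np.float64),
        angle_class=np.array([int(a.angle_class) for a in angles], dtype=np.int8),
        chain_id=np.array(chain_id, dtype=np.int64),
        chain_type=np.array(chain_type, dtype=np.int8),
        chain_first=np.array(chain_first, dtype=np.int64),
        chain_nhead=np.array(chain_nhead, dtype=np.int64),
        chain_ntail=np.array(chain_ntail, dtype=np.int64),
    )


def water_topology(n_water: int) -> SystemTopology:
    """Topology of a pure-water box (no bonded terms)."""
    t1 = LipidTemplate(1, 1, 1)
    t2 = LipidTemplate(2, 1, 1)
    return build_system_topology(t1, t2, 0, 0, n_water)
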