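"""Configuration loading with full defaults and strict key validation.

All defaults are the standard parameterisation of the model: bead density
rho = 3, repulsion 25 (like) / 100 (unlike), thermostat gamma = 4.5 (hence
sigma = 3.0 at k_B T = 1), time step 0.01 tau, springs k_s = 100 /
r_s = 0.7 r_c, bending constants 6.0 / 3.0 / 4.5 with straight equilibrium
angles, three head beads per lipid, 600 + 600 chains and 200 000 steps.
TOML and JSON inputs are accepted; dumps are JSON.  Unknown keys are
rejected with a message naming the key.
"""
from __future__ import annotations

import dataclasses
import json
import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .engine import RunParams
from .topology import (BondedParams, InteractionMatrix, LipidTemplate,
                       default_interactions, species_from_label)


@dataclass
class LipidConfig:
    n_hb: int = 3
    n_tb: int = 4


@dataclass
class InteractionConfig:
    a_like: float = 25.0
    a_unlike: float = 100.0
    #: entries like {"HB1-HB2": 25.0} override single pairs
    overrides: dict = field(default_factory=dict)


@dataclass
class BondedConfig:
    k_s: float = 100.0
    r_s: float = 0.7
    k_theta_chain: float = 6.0
    k_theta_junction: float = 3.0
    k_theta_split: float = 4.5
    theta0_chain: float = math.pi
    theta0_junction: float = math.pi
    theta0_split: float = math.pi


@dataclass
class RunConfig:
    gamma: float | None = 4.5
    sigma: float | None = None
    kbt: float = 1.0
    dt: float = 0.01
    steps: int = 200_000
    seed: int = 0
    r_cut: float = 1.0
    report_every: int = 100


@dataclass
class SystemConfig:
    n1: int = 600
    n2: int = 600
    L: float = 30.0
    rho: float = 3.0
    mode: str = "lamella"


_SECTIONS = {
    "lipid1": LipidConfig,
    "lipid2": LipidConfig,
    "interactions": InteractionConfig,
    "bonded": BondedConfig,
    "run": RunConfig,
    "system": SystemConfig,
}


@dataclass
class FullConfig:
    lipid1: LipidConfig = field(default_factory=LipidConfig)
    lipid2: LipidConfig = field(default_factory=lambda: LipidConfig(n_tb=9))
    interactions: InteractionConfig = field(default_factory=InteractionConfig)
    bonded: BondedConfig = field(default_factory=BondedConfig)
    run: RunConfig = field(default_factory=RunConfig)
    system: SystemConfig = field(default_factory=SystemConfig)

    def __post_init__(self):
        # normalise sigma/gamma through the fluctuation-dissipation relation
        rc = self.run
        if rc.gamma is None and rc.sigma is None:
            raise ValueError("[run] needs gamma or sigma")
        if rc.sigma is None:
            rc.sigma = math.sqrt(2.0 * rc.gamma * rc.kbt)
        elif rc.gamma is None:
            rc.gamma = rc.sigma ** 2 / (2.0 * rc.kbt)
        elif abs(rc.sigma ** 2 - 2.0 * rc.gamma * rc.kbt) > 1e-10:
            raise ValueError(
                "[run] sigma and gamma violate sigma^2 = 2 gamma kbt")

    # -- materialisation -------------------------------------------------
    def templates(self) -> tuple[LipidTemplate, LipidTemplate]:
        return (LipidTemplate(1, self.lipid1.n_hb, self.lipid1.n_tb),
                LipidTemplate(2, self.lipid2.n_hb, self.lipid2.n_tb))

    def interaction_matrix(self) -> InteractionMatrix:
        m = default_interactions(self.interactions.a_like,
                                 self.interactions.a_unlike)
        for key, value in self.interactions.overrides.items():
            s1, s2 = key.split("-")
            m.set(species_from_label(s1), species_from_label(s2),
                  float(value))
        return m

    def bonded_params(self) -> BondedParams:
        b = self.bonded
        return BondedParams(k_s=b.k_s, r_s=b.r_s,
                            k_theta_chain=b.k_theta_chain,
                            k_theta_junction=b.k_theta_junction,
                            k_theta_split=b.k_theta_split,
                            theta0_chain=b.theta0_chain,
                            theta0_junction=b.theta0_junction,
                            theta0_split=b.theta0_split)

    def run_params(self, n_steps: int | None = None,
                   seed: int | None = None) -> RunParams:
        rc = self.run
        return RunParams(n_steps=rc.steps if n_steps is None else n_steps,
                         seed=rc.seed if seed is None else seed,
                         gamma=rc.gamma, sigma=rc.sigma, kBT=rc.kbt,
                         dt=rc.dt, r_cut=rc.r_cut,
                         report_every=rc.report_every)

    # -- (de)serialisation -----------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "FullConfig":
        sections = {}
        for key, value in data.items():
            if key not in _SECTIONS:
                raise ValueError(
                    f"unknown config section {key!r}; expected one of "
                    f"{sorted(_SECTIONS)}")
            klass = _SECTIONS[key]
            names = {f.name for f in dataclasses.fields(klass)}
            for sub in value:
                if sub not in names:
                    raise ValueError(
                        f"[{key}] unknown key {sub!r}; expected one of "
                        f"{sorted(names)}")
            sections[key] = klass(**value)
        return cls(**sections)


def load_config(path: str | Path | None = None) -> FullConfig:
    """Load a TOML or JSON configuration; None or a missing-keys file gives
    the full default parameter set."""
    if path is None:
        return FullConfig()
    path = Path(path)
    text = path.read_bytes()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = tomllib.loads(text.decode())
    return FullConfig.from_dict(data)


def dump_config(config: FullConfig, path: str | Path) -> None:
    """Dump a configuration as JSON; load(dump(load(x))) is lossless."""
    Path(path).write_text(json.dumps(config.to_dict(), indent=2))
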