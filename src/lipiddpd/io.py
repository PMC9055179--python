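"""Trajectory serialisation (extended XYZ, HDF5) and run manifests.

Extended-XYZ frames carry the species label, position and velocity of each
bead plus the cubic box in the comment line, written at full double
precision so that write-read round-trips are bit-identical.  The HDF5
container stores the same data in growable datasets for long runs.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .engine import SystemState
from .topology import SPECIES_LABELS, SystemTopology, species_from_label

_FMT = "%.17g"


@dataclass
class RawFrame:
    """One trajectory frame without topology."""

    species: list[str]
    positions: np.ndarray
    velocities: np.ndarray
    box: float
    step: int | None = None


def state_to_frame(state: SystemState, step: int | None = None) -> RawFrame:
    labels = [SPECIES_LABELS[s] for s in state.topology.species]
    return RawFrame(labels, state.positions.copy(), state.velocities.copy(),
                    state.box, step)


def frame_to_state(frame: RawFrame, topology: SystemTopology) -> SystemState:
    """Attach a frame to an existing topology (labels must agree)."""
    got = [species_from_label(s) for s in frame.species]
    if not np.array_equal(np.array(got, dtype=np.int8), topology.species):
        raise ValueError("frame species labels do not match the topology")
    return SystemState(frame.box, frame.positions.copy(),
                       frame.velocities.copy(), topology)


def write_xyz_frame(fh, frame: RawFrame) -> None:
    n = len(frame.species)
    L = frame.box
    lattice = " ".join(_FMT % v for v in
                       (L, 0, 0, 0, L, 0, 0, 0, L))
    comment = (f'Lattice="{lattice}" '
               'Properties=species:S:1:pos:R:3:vel:R:3')
    if frame.step is not None:
        comment += f" Step={frame.step}"
    fh.write(f"{n}\n{comment}\n")
    for s, p, v in zip(frame.species, frame.positions, frame.velocities):
        fh.write(s + " " + " ".join(_FMT % x for x in (*p, *v)) + "\n")


def write_xyz(path, frames) -> None:
    if isinstance(frames, (RawFrame, SystemState)):
        frames = [frames]
    with open(path, "w") as fh:
        for fr in frames:
            if isinstance(fr, SystemState):
                fr = state_to_frame(fr)
            write_xyz_frame(fh, fr)


class XYZParseError(ValueError):
    pass


def read_xyz(path) -> list[RawFrame]:
    """Read all frames of an extended-XYZ file."""
    frames = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise XYZParseError(
                f"{path}:{i + 1}: expected atom count, got {lines[i]!r}")
        if i + 1 + n >= len(lines) + 1:
            raise XYZParseError(f"{path}:{i + 1}: truncated frame")
        comment = lines[i + 1]
        box = _parse_lattice(comment, path, i + 2)
        step = None
        for tok in comment.split():
            if tok.startswith("Step="):
                step = int(tok[5:])
        species = []
        pos = np.empty((n, 3))
        vel = np.empty((n, 3))
        for k in range(n):
            ln = i + 2 + k
            parts = lines[ln].split()
            if len(parts) != 7:
                raise XYZParseError(
                    f"{path}:{ln + 1}: expected 'species x y z vx vy vz', "
                    f"got {lines[ln]!r}")
            species.append(parts[0])
            pos[k] = [float(x) for x in parts[1:4]]
            vel[k] = [float(x) for x in parts[4:7]]
        frames.append(RawFrame(species, pos, vel, box, step))
        i += 2 + n
    return frames


def _parse_lattice(comment: str, path, lineno) -> float:
    start = comment.find('Lattice="')
    if start < 0:
        raise XYZParseError(f"{path}:{lineno}: missing Lattice")
    end = comment.find('"', start + 9)
    vals = [float(x) for x in comment[start + 9:end].split()]
    if len(vals) != 9:
        raise XYZParseError(f"{path}:{lineno}: lattice needs 9 numbers")
    L = vals[0]
    expected = [L, 0, 0, 0, L, 0, 0, 0, L]
    if vals != expected:
        raise XYZParseError(f"{path}:{lineno}: only cubic boxes supported")
    return L


class H5TrajectoryWriter:
    """Append frames to an HDF5 container (species stored once)."""

    def __init__(self, path, state: SystemState):
        import h5py

        self._fh = h5py.File(path, "w")
        n = state.n_beads
        self._fh.create_dataset("species", data=state.topology.species)
        self._fh.attrs["box"] = state.box
        self._fh.attrs["species_labels"] = SPECIES_LABELS
        self._pos = self._fh.create_dataset(
            "positions", shape=(0, n, 3), maxshape=(None, n, 3),
            dtype="f8", chunks=(1, n, 3))
        self._vel = self._fh.create_dataset(
            "velocities", shape=(0, n, 3), maxshape=(None, n, 3),
            dtype="f8", chunks=(1, n, 3))
        self._steps = self._fh.create_dataset(
            "steps", shape=(0,), maxshape=(None,), dtype="i8")

    def append(self, state: SystemState, step: int = 0) -> None:
        k = self._pos.shape[0]
        for ds in (self._pos, self._vel):
            ds.resize(k + 1, axis=0)
        self._steps.resize(k + 1, axis=0)
        self._pos[k] = state.positions
        self._vel[k] = state.velocities
        self._steps[k] = step
        self._fh.flush()

    def close(self) -> None:
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def read_h5(path) -> list[RawFrame]:
    import h5py

    frames = []
    with h5py.File(path, "r") as fh:
        labels = [SPECIES_LABELS[s] for s in fh["species"][...]]
        box = float(fh.attrs["box"])
        steps = fh["steps"][...]
        for k in range(fh["positions"].shape[0]):
            frames.append(RawFrame(labels, fh["positions"][k],
                                   fh["velocities"][k], box, int(steps[k])))
    return frames


@dataclass
class RunManifest:
    """Provenance record of one run: config snapshot, seed, outputs."""

    config: dict
    seed: int
    version: str
    outputs: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps({
            "config": self.config, "seed": self.seed,
            "version": self.version, "outputs": self.outputs,
            "metadata": self.metadata}, indent=2))

    @classmethod
    def load(cls, path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        return cls(config=d["config"], seed=d["seed"], version=d["version"],
                   outputs=d["outputs"], metadata=d.get("metadata", {}))

    def validate(self, root=".") -> None:
        """Every listed output file must exist."""
        missing = [p for p in self.outputs
                   if not (Path(root) / p).exists()]
        if missing:
            raise FileNotFoundError(f"manifest outputs missing: {missing}")
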