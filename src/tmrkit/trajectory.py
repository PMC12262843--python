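"""Trajectory container and multi-model PDB round trip.

A trajectory holds a fixed particle set (residue id + atom/bead name per
particle) and an ordered stack of coordinate frames.  The representation
tag distinguishes coarse-grained bead trajectories ("CG", one "BB" bead
per residue, unit masses) from atomistic ones ("AA").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

from .structure_io import StructureModel, _to_atom_array

__all__ = ["Trajectory", "read_trajectory", "write_trajectory", "particle_masses"]

_ELEMENT_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "P": 30.974, "S": 32.06,
}


def particle_masses(atom_names: np.ndarray, representation: str = "CG") -> np.ndarray:
    """Per-particle masses; unit masses for coarse-grained beads."""
    if representation == "CG":
        return np.ones(len(atom_names))
    masses = np.empty(len(atom_names))
    for i, name in enumerate(np.asarray(atom_names, str)):
        element = name.lstrip("0123456789")[:1].upper()
        masses[i] = _ELEMENT_MASS.get(element, 12.011)
    return masses


@dataclass
class Trajectory:
    """Ordered coordinate frames over a fixed particle set."""

    res_id: np.ndarray  # (n,) int
    atom_name: np.ndarray  # (n,) str
    frames: np.ndarray  # (n_frames, n, 3) float, Angstrom
    dt: float = 1.0
    representation: str = "CG"
    chain_id: np.ndarray | None = None  # defaults to chain A
    replica_id: str = "r0"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_particles, 3)")
        n = self.frames.shape[1]
        self.res_id = np.asarray(self.res_id, int)
        self.atom_name = np.asarray(self.atom_name, str)
        if len(self.res_id) != n or len(self.atom_name) != n:
            raise ValueError("particle annotation length mismatch")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.chain_id is None:
            self.chain_id = np.full(n, "A")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_particles(self) -> int:
        return self.frames.shape[1]

    @property
    def masses(self) -> np.ndarray:
        return particle_masses(self.atom_name, self.representation)

    def residue_mask(self, residues: np.ndarray) -> np.ndarray:
        return np.isin(self.res_id, np.asarray(residues, int))

    def frame_model(self, index: int, model_id: str | None = None) -> StructureModel:
        """A single frame viewed as a structure model."""
        return StructureModel(
            model_id=model_id or f"{self.replica_id}_frame{index}",
            predictor="trajectory",
            chain_id=np.asarray(self.chain_id),
            res_id=self.res_id,
            res_name=np.full(self.n_particles, "ALA"),
            atom_name=self.atom_name,
            coord=self.frames[index],
        )

    def with_frames(self, frames: np.ndarray) -> "Trajectory":
        return Trajectory(
            res_id=self.res_id,
            atom_name=self.atom_name,
            frames=frames,
            dt=self.dt,
            representation=self.representation,
            chain_id=self.chain_id,
            replica_id=self.replica_id,
        )


def write_trajectory(traj: Trajectory, path: str | Path) -> Path:
    """Write as multi-model PDB (one MODEL block per frame)."""
    path = Path(path)
    arrays = struc.stack(
        [_to_atom_array(traj.frame_model(i)) for i in range(traj.n_frames)]
    )
    pfile = pdbio.PDBFile()
    pfile.set_structure(arrays)
    pfile.write(str(path))
    return path


def read_trajectory(
    path: str | Path,
    dt: float = 1.0,
    representation: str = "CG",
    replica_id: str | None = None,
) -> Trajectory:
    """Read a multi-model PDB as a trajectory."""
    path = Path(path)
    pfile = pdbio.PDBFile.read(str(path))
    stack = pfile.get_structure(model=None)
    if isinstance(stack, struc.AtomArray):  # single model
        stack = struc.stack([stack])
    return Trajectory(
        res_id=stack.res_id.astype(int),
        atom_name=stack.atom_name.astype(str),
        frames=stack.coord.astype(float),
        dt=dt,
        representation=representation,
        chain_id=stack.chain_id.astype(str),
        replica_id=replica_id or path.stem,
    )
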