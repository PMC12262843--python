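"""Structural model I/O, confidence channels and subdomain definitions.

Models are read from and written to PDB; the per-residue confidence score
(pLDDT, 0-100) travels in the B-factor column as emitted by current
structure predictors.  Predicted-aligned-error (PAE) matrices are read
from JSON in both the nested-list and flat-list dialects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

__all__ = [
    "StructureModel",
    "SubdomainMap",
    "ConfidenceProfile",
    "PAEMatrix",
    "StructureParseError",
    "SubdomainError",
    "read_structure",
    "write_structure",
    "make_subdomain_map",
    "default_subdomain_map",
    "extract_confidence",
    "read_pae",
    "pae_block_stats",
]

#: Residue interval (1-based, half-open) of the full membrane-associated region.
TMR_INTERVAL = (550, 777)

_SUBDOMAIN_ORDER = ("APH1", "TM0", "TM1", "TM2", "APH2", "TM3", "TM4")
_TM_ORDER = ("TM1", "TM2", "TM3", "TM4")

#: Default helix boundaries, half-open; a boundary residue belongs to the
#: later helix (615 starts TM2, 736 starts TM4).
DEFAULT_TM_BOUNDARIES: dict[str, tuple[int, int]] = {
    "TM1": (600, 615),
    "TM2": (615, 636),
    "TM3": (715, 736),
    "TM4": (736, 751),
}


class StructureParseError(ValueError):
    """Raised when a structure file cannot be parsed."""


class SubdomainError(ValueError):
    """Raised for invalid subdomain interval definitions."""


@dataclass
class StructureModel:
    """An atomic (or coarse-grained bead) model with optional confidence.

    Atom attributes are stored as parallel arrays of equal length.
    ``confidence`` is per-atom pLDDT in [0, 100], or ``None`` when the
    source carried no confidence channel.
    """

    model_id: str
    predictor: str
    chain_id: np.ndarray  # (n,) str
    res_id: np.ndarray  # (n,) int
    res_name: np.ndarray  # (n,) str
    atom_name: np.ndarray  # (n,) str
    coord: np.ndarray  # (n, 3) float, Angstrom
    confidence: np.ndarray | None = None  # (n,) float in [0, 100]

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.ndim != 2 or self.coord.shape[1] != 3:
            raise ValueError("coord must have shape (n, 3)")
        n = len(self.coord)
        for name in ("chain_id", "res_id", "res_name", "atom_name"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != {n} atoms")
            setattr(self, name, arr)
        if not np.all(np.isfinite(self.coord)):
            raise ValueError("non-finite coordinates")
        if self.confidence is not None:
            self.confidence = np.asarray(self.confidence, dtype=float)
            if len(self.confidence) != n:
                raise ValueError("confidence length mismatch")
            if np.any((self.confidence < 0) | (self.confidence > 100)):
                raise ValueError("confidence outside [0, 100]")

    @property
    def n_atoms(self) -> int:
        return len(self.coord)

    @property
    def chains(self) -> list[str]:
        """Chain identifiers in order of first appearance."""
        _, idx = np.unique(self.chain_id, return_index=True)
        return [str(c) for c in self.chain_id[np.sort(idx)]]

    def select(self, mask: np.ndarray, model_id: str | None = None) -> "StructureModel":
        return StructureModel(
            model_id=model_id or self.model_id,
            predictor=self.predictor,
            chain_id=self.chain_id[mask],
            res_id=self.res_id[mask],
            res_name=self.res_name[mask],
            atom_name=self.atom_name[mask],
            coord=self.coord[mask],
            confidence=None if self.confidence is None else self.confidence[mask],
        )

    def chain(self, chain_id: str) -> "StructureModel":
        mask = self.chain_id == chain_id
        if not mask.any():
            raise KeyError(f"no chain {chain_id!r} in model {self.model_id!r}")
        return self.select(mask)

    def ca_mask(self) -> np.ndarray:
        """Alpha-carbon (or single-bead 'BB') atoms."""
        return (self.atom_name == "CA") | (self.atom_name == "BB")

    def residue_ids(self, chain: str | None = None) -> np.ndarray:
        """Sorted unique residue numbers, optionally restricted to a chain."""
        mask = np.ones(self.n_atoms, bool) if chain is None else self.chain_id == chain
        return np.unique(self.res_id[mask])


@dataclass(frozen=True)
class SubdomainMap:
    """Named residue intervals of the transmembrane region.

    All intervals are 1-based and half-open ``[start, end)``, so each
    boundary residue belongs to exactly one subdomain.  ``HP1``/``HP2``
    are the derived hairpin unions TM1+TM2 and TM3+TM4.
    """

    intervals: Mapping[str, tuple[int, int]]
    tmr_interval: tuple[int, int] = TMR_INTERVAL

    def __post_init__(self) -> None:
        for name, (start, end) in self.intervals.items():
            if end <= start:
                raise SubdomainError(f"{name}: empty interval [{start}, {end})")
        tms = [n for n in _TM_ORDER if n in self.intervals]
        if set(tms) != set(_TM_ORDER):
            missing = set(_TM_ORDER) - set(tms)
            raise SubdomainError(f"missing TM intervals: {sorted(missing)}")
        prev_end = None
        for name in _TM_ORDER:
            start, end = self.intervals[name]
            if prev_end is not None and start < prev_end:
                raise SubdomainError(
                    f"{name} starts at {start}, before previous helix end {prev_end}"
                )
            prev_end = end
        lo, hi = self.tmr_interval
        for name in _TM_ORDER:
            start, end = self.intervals[name]
            if start < lo or end > hi:
                raise SubdomainError(
                    f"{name} [{start}, {end}) outside TMR [{lo}, {hi})"
                )

    def __getitem__(self, name: str) -> tuple[int, int]:
        if name == "HP1":
            return (self.intervals["TM1"][0], self.intervals["TM2"][1])
        if name == "HP2":
            return (self.intervals["TM3"][0], self.intervals["TM4"][1])
        return tuple(self.intervals[name])

    def residues(self, name: str) -> np.ndarray:
        """Residue numbers of a subdomain (or HP1/HP2 union)."""
        if name == "HP1":
            return np.concatenate([self.residues("TM1"), self.residues("TM2")])
        if name == "HP2":
            return np.concatenate([self.residues("TM3"), self.residues("TM4")])
        start, end = self.intervals[name]
        return np.arange(start, end)

    @property
    def tm_names(self) -> tuple[str, ...]:
        return _TM_ORDER

    def to_dict(self) -> dict:
        return {name: list(iv) for name, iv in self.intervals.items()}


@dataclass(frozen=True)
class ConfidenceProfile:
    """Per-residue pLDDT, one value per residue present in the region."""

    res_id: np.ndarray
    plddt: np.ndarray
    chain_id: str = "A"

    def mean(self) -> float:
        return float(np.mean(self.plddt))

    def subset(self, interval: tuple[int, int]) -> "ConfidenceProfile":
        start, end = interval
        mask = (self.res_id >= start) & (self.res_id < end)
        return ConfidenceProfile(self.res_id[mask], self.plddt[mask], self.chain_id)


@dataclass(frozen=True)
class PAEMatrix:
    """Predicted aligned error over all residues of all chains, in Angstrom."""

    matrix: np.ndarray
    chain_lengths: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"PAE matrix must be square, got shape {m.shape}")
        if np.any(m < 0):
            raise ValueError("PAE entries must be non-negative")
        object.__setattr__(self, "matrix", m)
        if self.chain_lengths and sum(self.chain_lengths) != m.shape[0]:
            raise ValueError(
                f"chain lengths {self.chain_lengths} do not sum to matrix "
                f"dimension {m.shape[0]}"
            )

    @property
    def n_res(self) -> int:
        return self.matrix.shape[0]


# ---------------------------------------------------------------------------
# PDB I/O


def read_structure(
    path: str | Path,
    dialect: str = "pdb",
    model_id: str | None = None,
    predictor: str = "unknown",
) -> StructureModel:
    """Read ATOM records from a PDB file into a :class:`StructureModel`.

    The B-factor column is mapped to the confidence channel; if every
    B-factor is zero the model is treated as carrying no confidence.
    """
    if dialect != "pdb":
        raise ValueError(f"unsupported dialect {dialect!r} (only 'pdb')")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prescan_pdb(path)
    try:
        pfile = pdbio.PDBFile.read(str(path))
        atoms = pfile.get_structure(model=1, extra_fields=["b_factor"])
    except Exception as exc:  # pragma: no cover - biotite error text varies
        raise StructureParseError(f"{path}: {exc}") from exc
    atoms = atoms[struc.filter_amino_acids(atoms) | (atoms.atom_name == "BB")]
    if atoms.array_length() == 0:
        raise StructureParseError(f"{path}: no amino-acid ATOM records")
    b = atoms.b_factor
    confidence = None if np.allclose(b, 0.0) else np.clip(b, 0.0, 100.0)
    return StructureModel(
        model_id=model_id or path.stem,
        predictor=predictor,
        chain_id=atoms.chain_id.astype(str),
        res_id=atoms.res_id.astype(int),
        res_name=atoms.res_name.astype(str),
        atom_name=atoms.atom_name.astype(str),
        coord=atoms.coord.astype(float),
        confidence=confidence,
    )


def _prescan_pdb(path: Path) -> None:
    """Cheap line-level validation so parse errors can name the line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise StructureParseError(
                        f"{path}:{lineno}: truncated ATOM record"
                    )
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                except ValueError as exc:
                    raise StructureParseError(
                        f"{path}:{lineno}: unparseable coordinates"
                    ) from exc


def _to_atom_array(model: StructureModel) -> struc.AtomArray:
    n = model.n_atoms
    atoms = struc.AtomArray(n)
    atoms.chain_id = model.chain_id.astype("U4")
    atoms.res_id = model.res_id.astype(int)
    atoms.res_name = model.res_name.astype("U5")
    atoms.atom_name = model.atom_name.astype("U6")
    atoms.coord = model.coord.astype(np.float32)
    atoms.hetero = np.zeros(n, bool)
    names = atoms.atom_name.astype(str)
    atoms.element = np.array(
        [("C" if nm in ("BB", "CA") else nm.lstrip("0123456789")[:1]) for nm in names],
        dtype="U2",
    )
    atoms.set_annotation(
        "b_factor",
        np.zeros(n) if model.confidence is None else model.confidence.astype(float),
    )
    return atoms


def write_structure(model: StructureModel, path: str | Path) -> Path:
    """Write a model as PDB (B-factor column = confidence, 0 if absent)."""
    path = Path(path)
    pfile = pdbio.PDBFile()
    pfile.set_structure(_to_atom_array(model))
    pfile.write(str(path))
    return path


# ---------------------------------------------------------------------------
# Subdomain maps


def make_subdomain_map(
    boundaries: Mapping[str, tuple[int, int]] | None = None,
    policy: str = "half_open",
    tmr_interval: tuple[int, int] = TMR_INTERVAL,
) -> SubdomainMap:
    """Validate helix boundary intervals and build a :class:`SubdomainMap`.

    ``boundaries`` must at least define TM1..TM4; missing helices default
    to :data:`DEFAULT_TM_BOUNDARIES`.  Only the half-open policy is
    implemented: residue 615 ends TM1's interval and starts TM2's.
    """
    if policy != "half_open":
        raise ValueError(f"unsupported interval policy {policy!r}")
    merged: dict[str, tuple[int, int]] = dict(DEFAULT_TM_BOUNDARIES)
    if boundaries:
        for name, iv in boundaries.items():
            if name not in _SUBDOMAIN_ORDER:
                raise SubdomainError(f"unknown subdomain name {name!r}")
            merged[name] = (int(iv[0]), int(iv[1]))
    return SubdomainMap(intervals=merged, tmr_interval=tmr_interval)


def default_subdomain_map() -> SubdomainMap:
    return make_subdomain_map()


# ---------------------------------------------------------------------------
# Confidence


def extract_confidence(
    model: StructureModel,
    region: tuple[int, int] | None = None,
    chain: str | None = None,
) -> ConfidenceProfile:
    """Per-residue pLDDT taken from the C-alpha atom of each residue.

    Raises if the model has no confidence channel or the region selects
    no residues.
    """
    if model.confidence is None:
        raise ValueError(
            f"model {model.model_id!r} carries no confidence channel; refusing "
            "to impute"
        )
    if chain is None:
        chain = model.chains[0]
    mask = model.ca_mask() & (model.chain_id == chain)
    if region is not None:
        start, end = region
        mask &= (model.res_id >= start) & (model.res_id < end)
    if not mask.any():
        raise ValueError(f"region {region} selects no residues in {model.model_id!r}")
    res = model.res_id[mask]
    plddt = model.confidence[mask]
    order = np.argsort(res, kind="stable")
    return ConfidenceProfile(res[order], plddt[order], chain_id=chain)


# ---------------------------------------------------------------------------
# PAE


def read_pae(path: str | Path, chain_lengths: Sequence[int] = ()) -> PAEMatrix:
    """Read a PAE matrix from JSON.

    Accepts the nested-list dialect (``predicted_aligned_error`` as a list
    of rows) and the flat-list dialect (``pae`` or ``predicted_aligned_error``
    as a flat list of n*n values).  A top-level list wrapping one object is
    unwrapped, as emitted by AF2 pipelines.
    """
    with open(path) as fh:
        payload = json.load(fh)
    if isinstance(payload, list):
        if len(payload) == 0:
            raise ValueError(f"{path}: empty JSON payload")
        if isinstance(payload[0], dict):
            payload = payload[0]
        else:
            payload = {"predicted_aligned_error": payload}
    raw = None
    for key in ("predicted_aligned_error", "pae"):
        if key in payload:
            raw = payload[key]
            break
    if raw is None:
        raise ValueError(f"{path}: no PAE key found")
    arr = np.asarray(raw, dtype=float)
    if arr.ndim == 1:
        n = int(round(np.sqrt(arr.size)))
        if n * n != arr.size:
            raise ValueError(
                f"{path}: flat PAE list of length {arr.size} is not a square"
            )
        arr = arr.reshape(n, n)
    elif arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"{path}: PAE payload of shape {arr.shape} is not square")
    return PAEMatrix(matrix=arr, chain_lengths=tuple(int(c) for c in chain_lengths))


def pae_block_stats(pae: PAEMatrix) -> dict[tuple[int, int], dict[str, float]]:
    """Mean/min PAE per chain-pair block given the recorded chain lengths.

    Returns ``{(i, j): {"mean": ..., "min": ...}}`` over chain indices.
    """
    if not pae.chain_lengths:
        raise ValueError("PAEMatrix carries no chain lengths")
    offsets = np.concatenate([[0], np.cumsum(pae.chain_lengths)])
    stats: dict[tuple[int, int], dict[str, float]] = {}
    for i in range(len(pae.chain_lengths)):
        for j in range(len(pae.chain_lengths)):
            block = pae.matrix[offsets[i]:offsets[i + 1], offsets[j]:offsets[j + 1]]
            stats[(i, j)] = {"mean": float(block.mean()), "min": float(block.min())}
    return stats
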