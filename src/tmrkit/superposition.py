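"""Rigid-body least-squares superposition and pairwise RMSD matrices."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import StructureModel

__all__ = [
    "RMSDMatrix",
    "extract_region",
    "kabsch_superpose",
    "superpose_coords",
    "rmsd",
    "pairwise_rmsd_matrix",
]


@dataclass(frozen=True)
class RMSDMatrix:
    """Symmetric matrix of pairwise minimal RMSD values (Angstrom)."""

    model_ids: tuple[str, ...]
    values: np.ndarray
    region: str = "whole"
    selection: str = "CA"
    n_residues: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.shape != (len(self.model_ids), len(self.model_ids)):
            raise ValueError("matrix shape does not match model ids")
        if np.any(v < 0) or not np.allclose(np.diag(v), 0.0):
            raise ValueError("RMSD matrix must be non-negative with zero diagonal")
        if not np.allclose(v, v.T):
            raise ValueError("RMSD matrix must be symmetric")
        object.__setattr__(self, "values", v)

    def to_tsv(self) -> str:
        lines = ["\t".join(("model",) + self.model_ids)]
        for mid, row in zip(self.model_ids, self.values):
            lines.append("\t".join([mid] + [f"{x:.3f}" for x in row]))
        return "\n".join(lines) + "\n"


def extract_region(model: StructureModel, interval: tuple[int, int]) -> StructureModel:
    """Sub-model with exactly the residues in the half-open interval."""
    start, end = interval
    mask = (model.res_id >= start) & (model.res_id < end)
    if not mask.any():
        raise ValueError(
            f"interval [{start}, {end}) selects no residues in {model.model_id!r}"
        )
    return model.select(mask)


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` with
    ``mobile @ rotation.T + translation`` the fitted coordinates.  The
    rotation is always proper (det = +1); in reflection-favouring
    degenerate cases the smallest singular direction has its sign flipped.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape:
        raise ValueError(f"point counts differ: {mobile.shape} vs {reference.shape}")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("need at least 3 points of dimension 3")
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    x = mobile - mob_c
    y = reference - ref_c
    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    fitted = x @ rot.T
    value = float(np.sqrt(np.mean(np.sum((fitted - y) ** 2, axis=1))))
    trans = ref_c - mob_c @ rot.T
    return rot, trans, value


def superpose_coords(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Mobile coordinates after the optimal fit onto reference."""
    rot, trans, _ = kabsch_superpose(mobile, reference)
    return np.asarray(mobile, float) @ rot.T + trans


def rmsd(a: np.ndarray, b: np.ndarray, superpose: bool = True) -> float:
    """RMSD between two equal-size coordinate sets, optionally after fitting."""
    if superpose:
        return kabsch_superpose(a, b)[2]
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _selection_coords(
    model: StructureModel,
    residues: np.ndarray,
    selection: str,
    chain: str,
) -> np.ndarray:
    if selection == "CA":
        sel = model.ca_mask()
    elif selection == "backbone":
        sel = np.isin(model.atom_name, ("N", "CA", "C", "O", "BB"))
    else:
        raise ValueError(f"unsupported selection {selection!r}")
    sel &= model.chain_id == chain
    coords = []
    for res in residues:
        mask = sel & (model.res_id == res)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ValueError(f"residue {res} missing in {model.model_id!r}")
        coords.append(model.coord[idx[0]] if selection == "CA" else model.coord[idx].mean(0))
    return np.asarray(coords)


def pairwise_rmsd_matrix(
    models: list[StructureModel],
    region: tuple[int, int] | None = None,
    selection: str = "CA",
    min_shared: int = 10,
) -> RMSDMatrix:
    """Pairwise minimal C-alpha RMSD over a common residue set.

    Each pair is superposed independently over the shared residues of the
    requested region (intersection across all models; multimers contribute
    their first chain).  Fails if fewer than ``min_shared`` residues are
    shared by all models.
    """
    if len(models) < 2:
        raise ValueError("need at least two models")
    chains = [m.chains[0] for m in models]
    shared: np.ndarray | None = None
    for m, ch in zip(models, chains):
        res = np.unique(m.res_id[m.ca_mask() & (m.chain_id == ch)])
        shared = res if shared is None else np.intersect1d(shared, res)
    assert shared is not None
    if region is not None:
        start, end = region
        shared = shared[(shared >= start) & (shared < end)]
    if shared.size < min_shared:
        raise ValueError(
            f"only {shared.size} residues shared by all models "
            f"(need >= {min_shared}): {shared.tolist()}"
        )
    coords = [
        _selection_coords(m, shared, selection, ch) for m, ch in zip(models, chains)
    ]
    n = len(models)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = rmsd(coords[i], coords[j])
    region_tag = "whole" if region is None else f"tmr_{region[0]}_{region[1] - 1}"
    return RMSDMatrix(
        model_ids=tuple(m.model_id for m in models),
        values=values,
        region=region_tag,
        selection=selection,
        n_residues=int(shared.size),
    )
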