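"""Conformational-landscape embedding: alignment, PCA, TICA, density, DCC.

The feature space is the flattened 3N coordinates of the backbone
particles of the membrane-embedded hairpins (CG "BB" beads, or C-alpha
for atomistic/static models — a 1:1 residue mapping, so static predictor
models can be projected into a trajectory-trained space).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .structure_io import StructureModel, SubdomainMap
from .superposition import kabsch_superpose, superpose_coords
from .trajectory import Trajectory

__all__ = [
    "PCAModel",
    "TICAModel",
    "DensityGrid",
    "feature_residues",
    "trajectory_features",
    "model_features",
    "align_trajectory",
    "fit_pca",
    "project",
    "fit_tica",
    "dcc",
    "density2d",
]

DEFAULT_TICA_LAG = 100


def feature_residues(submap: SubdomainMap) -> np.ndarray:
    """Feature selection: residues of both membrane-embedded hairpins."""
    return np.concatenate([submap.residues("HP1"), submap.residues("HP2")])


def _backbone_indices(res_id, atom_name, chain_id, residues) -> np.ndarray:
    """Index of the single backbone particle (BB or CA) per feature residue."""
    name = np.asarray(atom_name, str)
    backbone = (name == "BB") | (name == "CA")
    first_chain = np.asarray(chain_id)[0]
    backbone &= np.asarray(chain_id) == first_chain
    indices = []
    missing = []
    for res in np.asarray(residues, int):
        idx = np.flatnonzero(backbone & (np.asarray(res_id, int) == res))
        if idx.size == 0:
            missing.append(int(res))
        else:
            indices.append(idx[0])
    if missing:
        raise ValueError(f"feature residues unmappable: {missing}")
    return np.asarray(indices, int)


def trajectory_features(traj: Trajectory, residues: np.ndarray) -> np.ndarray:
    """(n_frames, 3N) flattened backbone coordinates over the selection."""
    idx = _backbone_indices(traj.res_id, traj.atom_name, traj.chain_id, residues)
    return traj.frames[:, idx, :].reshape(traj.n_frames, -1)


def model_features(model: StructureModel, residues: np.ndarray) -> np.ndarray:
    """(3N,) feature vector of a static model (C-alpha as bead equivalent)."""
    idx = _backbone_indices(model.res_id, model.atom_name, model.chain_id, residues)
    return model.coord[idx, :].reshape(-1)


@dataclass
class PCAModel:
    """Mean + orthonormal eigenvectors + explained-variance fractions."""

    mean: np.ndarray  # (d,)
    components: np.ndarray  # (d, d) orthonormal columns, sorted
    eigenvalues: np.ndarray  # (d,) non-increasing, >= 0
    feature_residues: np.ndarray | None = None

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total == 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / total

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "components": self.components.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "feature_residues": (
                None if self.feature_residues is None
                else self.feature_residues.tolist()
            ),
        }


@dataclass
class TICAModel:
    """Time-lagged independent components (symmetrized estimator)."""

    lag: int
    mean: np.ndarray
    components: np.ndarray  # (d, k) generalized eigenvectors
    eigenvalues: np.ndarray  # (k,) sorted by decreasing value

    @property
    def timescales(self) -> np.ndarray:
        """Implied timescales -lag / ln|lambda| (inf for |lambda| >= 1)."""
        lam = np.abs(self.eigenvalues)
        with np.errstate(divide="ignore"):
            out = np.where(lam >= 1.0, np.inf, -self.lag / np.log(np.clip(lam, 1e-300, None)))
        return out

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, float) - self.mean) @ self.components


@dataclass(frozen=True)
class DensityGrid:
    """Normalized 2-D histogram over (PC1, PC2); masses sum to 1."""

    mass: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray

    @property
    def modes(self) -> list[tuple[float, float]]:
        return self.find_modes()

    def find_modes(
        self, smooth_sigma: float = 2.5, min_mass_ratio: float = 0.2
    ) -> list[tuple[float, float]]:
        """Bin-center locations of significant local density maxima.

        The histogram is Gaussian-smoothed (``smooth_sigma`` bins) before
        searching for strict 8-neighbourhood maxima; maxima below
        ``min_mass_ratio`` of the global maximum are discarded.
        """
        import scipy.ndimage

        m = scipy.ndimage.gaussian_filter(self.mass, smooth_sigma)
        padded = np.pad(m, 1, constant_values=-1.0)
        centers_x = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        centers_y = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        floor = min_mass_ratio * m.max()
        out = []
        for i in range(m.shape[0]):
            for j in range(m.shape[1]):
                if m[i, j] <= floor:
                    continue
                window = padded[i:i + 3, j:j + 3].copy()
                window[1, 1] = -np.inf
                if m[i, j] > window.max():
                    out.append((float(centers_x[i]), float(centers_y[j])))
        return out


def align_trajectory(
    traj: Trajectory,
    reference: np.ndarray,
    fit_residues: np.ndarray,
) -> Trajectory:
    """Superpose every frame onto reference coordinates by a Kabsch fit.

    ``reference`` holds the fit-selection coordinates (n_fit, 3) in the
    target frame; the fitted rigid transform is applied to all particles.
    """
    idx = _backbone_indices(traj.res_id, traj.atom_name, traj.chain_id, fit_residues)
    reference = np.asarray(reference, float)
    if reference.shape != (len(idx), 3):
        raise ValueError(
            f"reference shape {reference.shape} != fit selection ({len(idx)}, 3)"
        )
    if len(idx) < 3:
        raise ValueError("degenerate fit selection (< 3 particles)")
    out = np.empty_like(traj.frames)
    for f in range(traj.n_frames):
        rot, trans, _ = kabsch_superpose(traj.frames[f, idx], reference)
        out[f] = traj.frames[f] @ rot.T + trans
    return traj.with_frames(out)


def fit_pca(
    frames: np.ndarray, feature_residues: np.ndarray | None = None
) -> PCAModel:
    """Eigen-decomposition of the feature covariance.

    Components are ordered by decreasing eigenvalue with a deterministic
    sign convention: the largest-magnitude loading of each component is
    positive.
    """
    x = np.asarray(frames, float)
    if x.ndim != 2:
        raise ValueError("frames must be a 2-D array (n_frames, n_features)")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 frames for PCA")
    if x.shape[1] < 2:
        raise ValueError("need feature dimension >= 2")
    mean = x.mean(axis=0)
    centered = x - mean
    cov = centered.T @ centered / (x.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    for k in range(eigvecs.shape[1]):
        j = int(np.argmax(np.abs(eigvecs[:, k])))
        if eigvecs[j, k] < 0:
            eigvecs[:, k] = -eigvecs[:, k]
    return PCAModel(
        mean=mean,
        components=eigvecs,
        eigenvalues=eigvals,
        feature_residues=None if feature_residues is None else np.asarray(feature_residues),
    )


def project(
    model: PCAModel,
    coords: np.ndarray | StructureModel,
    n_components: int | None = None,
) -> np.ndarray:
    """Project frames or a static model into the PCA space.

    A :class:`StructureModel` is mapped through the model's recorded
    feature residues (C-alpha per residue); arrays are taken as already
    featurized.
    """
    if isinstance(coords, StructureModel):
        if model.feature_residues is None:
            raise ValueError("PCAModel has no feature residue record")
        x = model_features(coords, model.feature_residues)
    else:
        x = np.asarray(coords, float)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"feature dimension {x.shape[1]} != model dimension {model.mean.shape[0]}"
        )
    comps = model.components if n_components is None else model.components[:, :n_components]
    y = (x - model.mean) @ comps
    return y[0] if single else y


def fit_tica(
    segments: list[np.ndarray] | np.ndarray,
    lag: int = DEFAULT_TICA_LAG,
    n_components: int | None = None,
    epsilon: float = 1e-10,
) -> TICAModel:
    """Symmetrized TICA over one or more trajectory segments.

    Lagged pairs are drawn within segments only (never across replica
    boundaries).  Solves the symmetrized generalized eigenproblem
    ``C_tau v = lambda C_0 v``; under this estimator ``|lambda| <= 1``
    up to numerical tolerance.
    """
    if isinstance(segments, np.ndarray) and segments.ndim == 2:
        segments = [segments]
    segments = [np.asarray(s, float) for s in segments]
    if lag < 1:
        raise ValueError("lag must be >= 1")
    shortest = min(len(s) for s in segments)
    if lag >= shortest:
        raise ValueError(f"lag {lag} >= shortest segment length {shortest}")
    heads = np.concatenate([s[:-lag] for s in segments])
    tails = np.concatenate([s[lag:] for s in segments])
    mean = 0.5 * (heads.mean(axis=0) + tails.mean(axis=0))
    h = heads - mean
    t = tails - mean
    n = len(h)
    c0 = (h.T @ h + t.T @ t) / (2.0 * n)
    ctau = (h.T @ t + t.T @ h) / (2.0 * n)
    # whiten in the well-conditioned principal subspace of C0; the raw
    # generalized problem is ill-posed when features are near rank-deficient
    s0, u0 = np.linalg.eigh(c0)
    keep = s0 > max(epsilon, 1e-12 * s0.max())
    whiten = u0[:, keep] / np.sqrt(s0[keep])
    k_sym = whiten.T @ ctau @ whiten
    eigvals, w = np.linalg.eigh(0.5 * (k_sym + k_sym.T))
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = whiten @ w[:, order]
    if n_components is not None:
        eigvals = eigvals[:n_components]
        eigvecs = eigvecs[:, :n_components]
    for k in range(eigvecs.shape[1]):
        j = int(np.argmax(np.abs(eigvecs[:, k])))
        if eigvecs[j, k] < 0:
            eigvecs[:, k] = -eigvecs[:, k]
    return TICAModel(lag=lag, mean=mean, components=eigvecs, eigenvalues=eigvals)


def dcc(traj: Trajectory, residues: np.ndarray | None = None) -> np.ndarray:
    """Dynamical cross-correlation of per-particle displacement vectors.

    Entry (i, j) is ``<dr_i . dr_j> / sqrt(<|dr_i|^2><|dr_j|^2>)`` over
    frames, in [-1, 1].  Zero-variance particles get correlation 0 with a
    warning.
    """
    if traj.n_frames < 10:
        raise ValueError("need at least 10 frames for DCC")
    if residues is not None:
        idx = _backbone_indices(traj.res_id, traj.atom_name, traj.chain_id, residues)
        coords = traj.frames[:, idx, :]
    else:
        coords = traj.frames
    disp = coords - coords.mean(axis=0, keepdims=True)
    inner = np.einsum("fik,fjk->ij", disp, disp) / disp.shape[0]
    var = np.diag(inner).copy()
    zero = var <= 1e-300
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance particles in DCC; set to 0")
        var[zero] = 1.0
    corr = inner / np.sqrt(var[:, None] * var[None, :])
    corr[zero, :] = 0.0
    corr[:, zero] = 0.0
    np.fill_diagonal(corr, np.where(zero, 0.0, 1.0))
    return np.clip(corr, -1.0, 1.0)


def density2d(points: np.ndarray, bins: int = 60) -> DensityGrid:
    """Normalized 2-D histogram of PC coordinates (total mass 1)."""
    pts = np.atleast_2d(np.asarray(points, float))
    if pts.shape[0] < 1 or pts.shape[1] < 2:
        raise ValueError("need at least one 2-D point")
    hist, xe, ye = np.histogram2d(pts[:, 0], pts[:, 1], bins=bins)
    return DensityGrid(mass=hist / hist.sum(), x_edges=xe, y_edges=ye)
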