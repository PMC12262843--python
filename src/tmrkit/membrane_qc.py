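"""Membrane-ejection detection and replica exclusion.

A hairpin counts as ejected when its center of mass leaves the membrane
slab (phosphate planes widened by a margin) and stays outside for a
sustained run of frames.  Detection is sticky: once ejected, a replica
stays ejected, matching the observed irreversibility of exits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .structure_io import SubdomainMap
from .trajectory import Trajectory

__all__ = [
    "MembraneSlabSeries",
    "HairpinEjection",
    "EjectionReport",
    "hairpin_z_series",
    "detect_ejection",
    "filter_replicas",
    "qc_trajectories",
]

logger = logging.getLogger(__name__)

DEFAULT_MARGIN = 5.0
DEFAULT_PERSISTENCE = 50


@dataclass(frozen=True)
class MembraneSlabSeries:
    """Per-frame mean phosphate-plane z of the two leaflets (Angstrom)."""

    upper: np.ndarray
    lower: np.ndarray

    def __post_init__(self) -> None:
        upper = np.asarray(self.upper, float)
        lower = np.asarray(self.lower, float)
        if upper.shape != lower.shape:
            raise ValueError("leaflet series length mismatch")
        if np.any(upper <= lower):
            raise ValueError("upper leaflet must lie above lower leaflet")
        object.__setattr__(self, "upper", upper)
        object.__setattr__(self, "lower", lower)

    def __len__(self) -> int:
        return len(self.upper)

    @staticmethod
    def constant(upper: float, lower: float, n_frames: int) -> "MembraneSlabSeries":
        return MembraneSlabSeries(
            upper=np.full(n_frames, float(upper)),
            lower=np.full(n_frames, float(lower)),
        )

    @staticmethod
    def from_phosphate_z(phosphate_z: np.ndarray) -> "MembraneSlabSeries":
        """Leaflet planes from per-frame phosphate z-coordinates.

        Leaflets are assigned by the sign of z relative to the frame-0
        slab midplane.
        """
        z = np.asarray(phosphate_z, float)
        if z.ndim != 2:
            raise ValueError("phosphate_z must be (n_frames, n_phosphates)")
        mid0 = float(np.mean(z[0]))
        upper_mask = z[0] >= mid0
        if not upper_mask.any() or upper_mask.all():
            raise ValueError("could not split phosphates into two leaflets")
        return MembraneSlabSeries(
            upper=z[:, upper_mask].mean(axis=1),
            lower=z[:, ~upper_mask].mean(axis=1),
        )


@dataclass(frozen=True)
class HairpinEjection:
    ejected: bool
    first_frame: int | None


@dataclass(frozen=True)
class EjectionReport:
    """Per-replica ejection status; excluded iff any hairpin ejected."""

    replica_id: str
    hairpins: dict[str, HairpinEjection]

    @property
    def excluded(self) -> bool:
        return any(h.ejected for h in self.hairpins.values())

    def to_dict(self) -> dict:
        return {
            "replica_id": self.replica_id,
            "excluded": self.excluded,
            "hairpins": {
                name: {"ejected": h.ejected, "first_frame": h.first_frame}
                for name, h in self.hairpins.items()
            },
        }


def hairpin_z_series(
    traj: Trajectory, submap: SubdomainMap, hairpin: str
) -> np.ndarray:
    """Per-frame z of the hairpin's (mass-weighted) center of mass."""
    if hairpin not in ("HP1", "HP2"):
        raise ValueError(f"hairpin must be HP1 or HP2, got {hairpin!r}")
    residues = submap.residues(hairpin)
    mask = traj.residue_mask(residues)
    present = np.unique(traj.res_id[mask])
    missing = np.setdiff1d(residues, present)
    if missing.size:
        raise ValueError(f"{hairpin} residues missing from trajectory: {missing.tolist()}")
    w = traj.masses[mask]
    z = traj.frames[:, mask, 2]
    return (z * w).sum(axis=1) / w.sum()


def detect_ejection(
    z_series: np.ndarray,
    slab: MembraneSlabSeries,
    margin: float = DEFAULT_MARGIN,
    persistence: int = DEFAULT_PERSISTENCE,
) -> HairpinEjection:
    """Sticky ejection detection on a center-of-mass z series.

    Ejected iff z leaves ``[lower - margin, upper + margin]`` and stays
    outside for at least ``persistence`` consecutive frames; the reported
    frame is the start of the first such run.
    """
    z = np.asarray(z_series, float)
    if len(z) != len(slab):
        raise ValueError(f"series length {len(z)} != slab length {len(slab)}")
    if persistence < 1:
        raise ValueError("persistence must be >= 1")
    outside = (z > slab.upper + margin) | (z < slab.lower - margin)
    run = 0
    for i, out in enumerate(outside):
        run = run + 1 if out else 0
        if run >= persistence:
            return HairpinEjection(ejected=True, first_frame=i - persistence + 1)
    return HairpinEjection(ejected=False, first_frame=None)


def filter_replicas(reports: list[EjectionReport]) -> list[str]:
    """Replica ids with no ejected hairpin; logs one line per exclusion."""
    retained = []
    for report in reports:
        if report.excluded:
            for name, h in report.hairpins.items():
                if h.ejected:
                    logger.info(
                        "excluding replica %s: %s ejected at frame %s",
                        report.replica_id, name, h.first_frame,
                    )
        else:
            retained.append(report.replica_id)
    if not retained:
        logger.warning("all %d replicas excluded by membrane QC", len(reports))
    return retained


def qc_trajectories(
    trajectories: list[Trajectory],
    slabs: list[MembraneSlabSeries],
    submap: SubdomainMap,
    margin: float = DEFAULT_MARGIN,
    persistence: int = DEFAULT_PERSISTENCE,
) -> tuple[list[Trajectory], list[EjectionReport]]:
    """Run ejection QC on an ensemble; returns (retained, all reports)."""
    reports = []
    for traj, slab in zip(trajectories, slabs):
        hairpins = {}
        for hp in ("HP1", "HP2"):
            z = hairpin_z_series(traj, submap, hp)
            hairpins[hp] = detect_ejection(z, slab, margin, persistence)
        reports.append(EjectionReport(replica_id=traj.replica_id, hairpins=hairpins))
    retained_ids = set(filter_replicas(reports))
    retained = [t for t in trajectories if t.replica_id in retained_ids]
    return retained, reports
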