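"""End-to-end orchestration: consensus model comparison and landscape runs.

A run is driven by a :class:`RunConfig` (YAML on disk), writes TSV/JSON
artifacts into an output directory and records every file in a manifest
with a content hash, so identically-seeded runs can be verified
bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import clustering, contact_analysis, landscape, membrane_qc
from .membrane_qc import MembraneSlabSeries
from .structure_io import (
    StructureModel,
    SubdomainMap,
    extract_confidence,
    make_subdomain_map,
    read_structure,
    write_structure,
)
from .superposition import pairwise_rmsd_matrix
from .trajectory import Trajectory, read_trajectory

__all__ = ["RunConfig", "ConsensusReport", "run_consensus", "run_landscape"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated parameters of a pipeline run."""

    models: list[dict] = field(default_factory=list)  # {path, predictor}
    trajectories: list[dict] = field(default_factory=list)  # {path, replica_id, dt}
    boundaries: dict = field(default_factory=dict)  # TM name -> [start, end)
    tmr_interval: tuple[int, int] = (550, 777)
    contact_metric: str = "CA"
    trajectory_metric: str = "residue_COM"
    cutoff: float = contact_analysis.DEFAULT_CUTOFF
    min_fraction: float = contact_analysis.DEFAULT_MIN_FRACTION
    qc_margin: float = membrane_qc.DEFAULT_MARGIN
    qc_persistence: int = membrane_qc.DEFAULT_PERSISTENCE
    slab_upper: float = 20.0
    slab_lower: float = -20.0
    stride: int = 1
    tica_lag: int = landscape.DEFAULT_TICA_LAG
    k_range: tuple[int, int] = (2, 10)
    cluster_seeds: int = 5
    seed: int = 0
    output_dir: str = "tmrkit_out"

    def __post_init__(self) -> None:
        if self.cutoff <= 0 or not 0 <= self.min_fraction <= 1:
            raise ValueError("contact parameters out of range")
        if self.qc_persistence < 1 or self.stride < 1 or self.tica_lag < 1:
            raise ValueError("qc/stride/lag parameters out of range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("tmr_interval", "k_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        for entry in cfg.models + cfg.trajectories:
            if not Path(entry["path"]).exists():
                raise FileNotFoundError(entry["path"])
        return cfg

    def subdomain_map(self) -> SubdomainMap:
        boundaries = {
            name: (int(iv[0]), int(iv[1])) for name, iv in self.boundaries.items()
        }
        return make_subdomain_map(boundaries or None, tmr_interval=self.tmr_interval)

    def load_models(self) -> list[StructureModel]:
        return [
            read_structure(
                m["path"],
                model_id=m.get("model_id"),
                predictor=m.get("predictor", "unknown"),
            )
            for m in self.models
        ]

    def load_trajectories(self) -> list[Trajectory]:
        return [
            read_trajectory(
                t["path"],
                dt=float(t.get("dt", 1.0)),
                representation=t.get("representation", "CG"),
                replica_id=t.get("replica_id"),
            )
            for t in self.trajectories
        ]


@dataclass
class ConsensusReport:
    """Cross-predictor comparison of static models."""

    rmsd_whole: object
    rmsd_tmr: object
    interfaces: dict[str, dict]
    consensus_label: str
    votes: dict[str, int]
    confidence: dict[str, dict[str, float]]
    dimer: dict | None = None

    def to_dict(self) -> dict:
        return {
            "rmsd_whole": {
                "model_ids": list(self.rmsd_whole.model_ids),
                "values": self.rmsd_whole.values.tolist(),
                "n_residues": self.rmsd_whole.n_residues,
            },
            "rmsd_tmr": {
                "model_ids": list(self.rmsd_tmr.model_ids),
                "values": self.rmsd_tmr.values.tolist(),
                "region": self.rmsd_tmr.region,
                "n_residues": self.rmsd_tmr.n_residues,
            },
            "interfaces": self.interfaces,
            "consensus_label": self.consensus_label,
            "votes": self.votes,
            "confidence": self.confidence,
            "dimer": self.dimer,
        }


def _write_manifest(outdir: Path, files: list[Path]) -> Path:
    manifest = {}
    for f in sorted(files):
        manifest[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def run_consensus(config: RunConfig) -> ConsensusReport:
    """RMSD matrices, per-model interface calls and majority consensus."""
    models = config.load_models()
    if len(models) < 2:
        raise ValueError("consensus run needs at least 2 models")
    submap = config.subdomain_map()
    try:
        rmsd_whole = pairwise_rmsd_matrix(models, region=None)
        rmsd_tmr = pairwise_rmsd_matrix(models, region=config.tmr_interval)
    except ValueError as exc:
        raise RuntimeError(f"stage=rmsd: {exc}") from exc
    interfaces = {}
    votes: Counter = Counter()
    for model in models:
        try:
            call = contact_analysis.classify_interface(
                model, submap, metric=config.contact_metric,
                cutoff=config.cutoff, min_fraction=config.min_fraction,
            )
        except ValueError as exc:
            raise RuntimeError(
                f"stage=interface model={model.model_id}: {exc}"
            ) from exc
        interfaces[model.model_id] = call.to_dict()
        votes[call.label] += 1
    consensus_label = votes.most_common(1)[0][0]
    confidence = {}
    for model in models:
        if model.confidence is None:
            continue
        per_region = {}
        for region in ("HP1", "HP2"):
            start, end = submap[region]
            try:
                prof = extract_confidence(model, (start, end))
                per_region[region] = prof.mean()
            except ValueError:
                continue
        if per_region:
            confidence[model.model_id] = per_region
    dimer_summary = None
    for model in models:
        if len(model.chains) == 2:
            decomp = contact_analysis.chain_contact_decomposition(
                model, submap, metric=config.contact_metric,
                cutoff=config.cutoff, min_fraction=config.min_fraction,
            )
            dimer_summary = {"model_id": model.model_id, **decomp["summary"]}
            break
    report = ConsensusReport(
        rmsd_whole=rmsd_whole,
        rmsd_tmr=rmsd_tmr,
        interfaces=interfaces,
        consensus_label=consensus_label,
        votes=dict(votes),
        confidence=confidence,
        dimer=dimer_summary,
    )
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    for tag, matrix in (("whole", rmsd_whole), ("tmr", rmsd_tmr)):
        p = outdir / f"rmsd_{tag}.tsv"
        p.write_text(matrix.to_tsv())
        files.append(p)
    p = outdir / "consensus.json"
    p.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
    files.append(p)
    _write_manifest(outdir, files)
    return report


def run_landscape(config: RunConfig) -> dict:
    """QC -> align -> PCA -> project -> TICA -> cluster -> representatives."""
    trajectories = config.load_trajectories()
    if not trajectories:
        raise ValueError("landscape run requires at least one trajectory")
    submap = config.subdomain_map()
    slabs = [
        MembraneSlabSeries.constant(config.slab_upper, config.slab_lower, t.n_frames)
        for t in trajectories
    ]
    retained, qc_reports = membrane_qc.qc_trajectories(
        trajectories, slabs, submap,
        margin=config.qc_margin, persistence=config.qc_persistence,
    )
    if not retained:
        raise RuntimeError(
            "all replicas excluded by membrane QC: "
            + json.dumps([r.to_dict() for r in qc_reports])
        )
    feat_res = landscape.feature_residues(submap)
    reference = landscape.trajectory_features(retained[0], feat_res)[0].reshape(-1, 3)
    aligned = [
        landscape.align_trajectory(t, reference, feat_res) for t in retained
    ]
    segments = [
        landscape.trajectory_features(t, feat_res)[:: config.stride] for t in aligned
    ]
    pooled = np.concatenate(segments)
    pca = landscape.fit_pca(pooled, feat_res)
    projections = landscape.project(pca, pooled, n_components=2)
    static_proj = {}
    for model in config.load_models():
        static_proj[model.model_id] = landscape.project(
            pca, model, n_components=2
        ).tolist()
    tica = None
    if all(len(s) > config.tica_lag for s in segments):
        tica = landscape.fit_tica(segments, lag=config.tica_lag, n_components=2)
    else:
        logger.warning("TICA skipped: lag >= shortest segment")
    density = landscape.density2d(projections)
    k, cluster_model = clustering.elbow_select(
        projections, config.k_range, seeds=config.cluster_seeds,
        base_seed=config.seed,
    )
    pooled_traj = Trajectory(
        res_id=aligned[0].res_id,
        atom_name=aligned[0].atom_name,
        frames=np.concatenate([t.frames[:: config.stride] for t in aligned]),
        dt=aligned[0].dt * config.stride,
        representation=aligned[0].representation,
        replica_id="pooled",
    )
    reps = clustering.representatives(
        cluster_model, pooled_traj, submap,
        metric=config.trajectory_metric, cutoff=config.cutoff,
        min_fraction=config.min_fraction, seed=config.seed,
    )
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    proj_path = outdir / "projections.tsv"
    with open(proj_path, "w") as fh:
        fh.write("frame\tPC1\tPC2\n")
        for i, row in enumerate(projections):
            fh.write(f"{i}\t{row[0]:.6f}\t{row[1]:.6f}\n")
    files.append(proj_path)
    result = {
        "qc": [r.to_dict() for r in qc_reports],
        "retained_replicas": [t.replica_id for t in retained],
        "explained_variance_ratio": pca.explained_variance_ratio[:10].tolist(),
        "pc12_variance_percent": float(
            100 * pca.explained_variance_ratio[:2].sum()
        ),
        "static_projections": static_proj,
        "tica_eigenvalues": None if tica is None else tica.eigenvalues.tolist(),
        "tica_timescales": None if tica is None else tica.timescales.tolist(),
        "n_density_modes": len(density.modes),
        "elbow_k": k,
        "cost_curve": {int(kk): v for kk, v in cluster_model.cost_curve.items()},
        "clusters": [
            {
                "cluster": r["cluster"],
                "medoid_frame": r["medoid_frame"],
                "n_members": r["n_members"],
                "interface": r["interface"].to_dict(),
            }
            for r in reps
        ],
    }
    for r in reps:
        p = outdir / f"cluster{r['cluster']}_medoid.pdb"
        write_structure(r["medoid_model"], p)
        files.append(p)
        fp = outdir / f"cluster{r['cluster']}_fingerprint.tsv"
        np.savetxt(fp, r["fingerprint"], delimiter="\t", fmt="%.4f")
        files.append(fp)
    report_path = outdir / "landscape.json"
    report_path.write_text(json.dumps(result, indent=2, sort_keys=True) + "\n")
    files.append(report_path)
    _write_manifest(outdir, files)
    result["pca"] = pca
    result["cluster_model"] = cluster_model
    result["projections"] = projections
    return result
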