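"""Inter-residue distance/contact maps and contact-interface classification.

Distances are computed either between C-alpha (or CG "BB" bead) positions
or between residue centers of mass.  A contact is a residue pair at or
below the cutoff (default 12 A, sized for coarse-grained resolution).
The interface of a four-helix bundle is classified from the contact
fractions of the four cross-hairpin helix pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import StructureModel, SubdomainMap
from .trajectory import Trajectory, particle_masses

__all__ = [
    "DistanceMap",
    "ContactMap",
    "InterfaceCall",
    "CROSS_HAIRPIN_PAIRS",
    "distance_map",
    "contact_map",
    "classify_interface",
    "chain_contact_decomposition",
    "mean_contact_map",
]

DEFAULT_CUTOFF = 12.0
DEFAULT_MIN_FRACTION = 0.05
DOMINANCE_FACTOR = 1.5

#: Cross-hairpin helix pairs considered for interface classification.
CROSS_HAIRPIN_PAIRS = (
    ("TM1", "TM3"),
    ("TM1", "TM4"),
    ("TM2", "TM3"),
    ("TM2", "TM4"),
)


@dataclass(frozen=True)
class DistanceMap:
    """|A| x |B| matrix of Euclidean residue-residue distances (Angstrom)."""

    res_a: np.ndarray
    res_b: np.ndarray
    values: np.ndarray
    metric: str = "CA"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.shape != (len(self.res_a), len(self.res_b)):
            raise ValueError("distance matrix shape mismatch")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "values", v)

    def min(self) -> float:
        return float(self.values.min())


@dataclass(frozen=True)
class ContactMap:
    """Boolean thresholding of a distance map (contact iff distance <= cutoff)."""

    res_a: np.ndarray
    res_b: np.ndarray
    values: np.ndarray  # bool
    cutoff: float = DEFAULT_CUTOFF
    metric: str = "CA"

    @property
    def fraction(self) -> float:
        return float(np.mean(self.values))

    @property
    def n_contacts(self) -> int:
        return int(np.sum(self.values))


@dataclass(frozen=True)
class InterfaceCall:
    """Result of cross-hairpin interface classification."""

    label: str  # "TM2-TM3" | "TM1-TM4" | "none" | "other"
    fractions: dict[str, float]
    min_distances: dict[str, float]
    cutoff: float = DEFAULT_CUTOFF
    min_fraction: float = DEFAULT_MIN_FRACTION

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "fractions": self.fractions,
            "min_distances": self.min_distances,
            "cutoff": self.cutoff,
            "min_fraction": self.min_fraction,
        }


def _residue_positions(
    model: StructureModel,
    residues: np.ndarray,
    metric: str,
    chain: str | None = None,
) -> np.ndarray:
    """One representative position per residue under the chosen metric."""
    if chain is None:
        chain = model.chains[0]
    chain_mask = model.chain_id == chain
    positions = np.empty((len(residues), 3))
    if metric == "CA":
        sel = model.ca_mask() & chain_mask
    elif metric == "residue_COM":
        sel = chain_mask
        masses = particle_masses(
            model.atom_name, "CG" if np.all(model.ca_mask()) else "AA"
        )
    else:
        raise ValueError(f"unsupported metric {metric!r}")
    missing = []
    for i, res in enumerate(np.asarray(residues, int)):
        mask = sel & (model.res_id == res)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            missing.append(int(res))
            continue
        if metric == "CA":
            positions[i] = model.coord[idx[0]]
        else:
            w = masses[idx]
            positions[i] = (model.coord[idx] * w[:, None]).sum(0) / w.sum()
    if missing:
        raise ValueError(
            f"residues not resolved in {model.model_id!r} chain {chain}: {missing}"
        )
    return positions


def _as_residue_array(interval_or_residues) -> np.ndarray:
    if isinstance(interval_or_residues, tuple) and len(interval_or_residues) == 2:
        start, end = interval_or_residues
        return np.arange(int(start), int(end))
    return np.asarray(interval_or_residues, int)


def distance_map(
    model: StructureModel,
    set_a,
    set_b,
    metric: str = "CA",
    chain_a: str | None = None,
    chain_b: str | None = None,
) -> DistanceMap:
    """Euclidean distance matrix between two residue sets.

    Sets are given as half-open intervals ``(start, end)`` or explicit
    residue-id arrays.
    """
    res_a = _as_residue_array(set_a)
    res_b = _as_residue_array(set_b)
    pos_a = _residue_positions(model, res_a, metric, chain_a)
    pos_b = _residue_positions(model, res_b, metric, chain_b)
    diff = pos_a[:, None, :] - pos_b[None, :, :]
    values = np.sqrt(np.sum(diff * diff, axis=2))
    return DistanceMap(res_a=res_a, res_b=res_b, values=values, metric=metric)


def contact_map(dmap: DistanceMap, cutoff: float = DEFAULT_CUTOFF) -> ContactMap:
    """Boolean contact map at the given cutoff (inclusive boundary)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return ContactMap(
        res_a=dmap.res_a,
        res_b=dmap.res_b,
        values=dmap.values <= cutoff,
        cutoff=cutoff,
        metric=dmap.metric,
    )


def classify_interface(
    model: StructureModel,
    submap: SubdomainMap,
    metric: str = "CA",
    cutoff: float = DEFAULT_CUTOFF,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    dominance: float = DOMINANCE_FACTOR,
    chain: str | None = None,
) -> InterfaceCall:
    """Classify the cross-hairpin contact interface of a four-helix bundle.

    Decision rule: for each cross-hairpin helix pair, the fraction of
    residue pairs in contact is computed; pairs with fraction at or above
    ``min_fraction`` are "in contact".  The label is the dominant
    in-contact pair (its fraction at least ``dominance`` times the
    runner-up); "none" if no pair passes; "other" if several pass without
    a dominant one or the dominant pair is not TM2-TM3/TM1-TM4.
    """
    fractions: dict[str, float] = {}
    min_dists: dict[str, float] = {}
    for ha, hb in CROSS_HAIRPIN_PAIRS:
        dmap = distance_map(
            model, submap[ha], submap[hb], metric=metric, chain_a=chain, chain_b=chain
        )
        cmap = contact_map(dmap, cutoff)
        key = f"{ha}-{hb}"
        fractions[key] = cmap.fraction
        min_dists[key] = dmap.min()
    call_kwargs = dict(cutoff=cutoff, min_fraction=min_fraction)
    passing = {k: f for k, f in fractions.items() if f >= min_fraction}
    if not passing:
        return InterfaceCall("none", fractions, min_dists, **call_kwargs)
    ranked = sorted(passing.items(), key=lambda kv: (-kv[1], kv[0]))
    best_key, best_f = ranked[0]
    if len(ranked) > 1 and best_f < dominance * ranked[1][1]:
        return InterfaceCall("other", fractions, min_dists, **call_kwargs)
    if best_key in ("TM2-TM3", "TM1-TM4"):
        return InterfaceCall(best_key, fractions, min_dists, **call_kwargs)
    return InterfaceCall("other", fractions, min_dists, **call_kwargs)


def chain_contact_decomposition(
    dimer: StructureModel,
    submap: SubdomainMap,
    metric: str = "CA",
    cutoff: float = DEFAULT_CUTOFF,
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> dict:
    """Intra- vs inter-chain contact decomposition of a two-chain model.

    Intra-chain maps cover HP1 x HP2 within each chain; the inter-chain
    map covers TMR(A) x TMR(B).  The summary lists helix pairs whose
    contact fraction reaches ``min_fraction`` in each category.
    """
    chains = dimer.chains
    if len(chains) != 2:
        raise ValueError(f"expected exactly 2 chains, found {chains}")
    ch_a, ch_b = chains
    tm_names = submap.tm_names
    result: dict = {"intra": {}, "inter": None, "summary": {"intra": {}, "inter": []}}
    for ch in (ch_a, ch_b):
        dmap = distance_map(
            dimer, submap["HP1"], submap["HP2"], metric=metric,
            chain_a=ch, chain_b=ch,
        )
        result["intra"][ch] = contact_map(dmap, cutoff)
        pairs = []
        for ha, hb in CROSS_HAIRPIN_PAIRS:
            sub = distance_map(
                dimer, submap[ha], submap[hb], metric=metric, chain_a=ch, chain_b=ch
            )
            if contact_map(sub, cutoff).fraction >= min_fraction:
                pairs.append(f"{ha}-{hb}")
        result["summary"]["intra"][ch] = pairs
    lo, hi = submap.tmr_interval
    shared = np.intersect1d(
        dimer.residue_ids(ch_a), dimer.residue_ids(ch_b)
    )
    tmr_res = shared[(shared >= lo) & (shared < hi)]
    inter_dmap = distance_map(
        dimer, tmr_res, tmr_res, metric=metric, chain_a=ch_a, chain_b=ch_b
    )
    result["inter"] = contact_map(inter_dmap, cutoff)
    for ha in tm_names:
        for hb in tm_names:
            sub = distance_map(
                dimer, submap[ha], submap[hb], metric=metric,
                chain_a=ch_a, chain_b=ch_b,
            )
            if contact_map(sub, cutoff).fraction >= min_fraction:
                result["summary"]["inter"].append(f"{ha}({ch_a})-{hb}({ch_b})")
    return result


def mean_contact_map(
    traj: Trajectory,
    frames,
    set_a,
    set_b,
    metric: str = "residue_COM",
    cutoff: float = DEFAULT_CUTOFF,
) -> np.ndarray:
    """Per-pair contact frequency over a set of frames (values in [0, 1])."""
    frames = np.asarray(frames, int)
    if frames.size == 0:
        raise ValueError("empty frame set")
    acc = None
    for idx in frames:
        cmap = contact_map(
            distance_map(traj.frame_model(int(idx)), set_a, set_b, metric=metric),
            cutoff,
        )
        acc = cmap.values.astype(float) if acc is None else acc + cmap.values
    return acc / frames.size
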