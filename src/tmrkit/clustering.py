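"""K-medoids (PAM-style) clustering of the PC projection with elbow k-selection."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .contact_analysis import (
    DEFAULT_CUTOFF,
    DEFAULT_MIN_FRACTION,
    InterfaceCall,
    classify_interface,
    mean_contact_map,
)
from .structure_io import SubdomainMap
from .trajectory import Trajectory

__all__ = ["ClusterModel", "kmedoids", "elbow_select", "representatives"]


@dataclass
class ClusterModel:
    """Converged K-medoids assignment plus the scanned cost curve."""

    k: int
    medoid_indices: np.ndarray  # (k,) indices into the dataset
    labels: np.ndarray  # (n,) cluster index per point
    cost: float  # summed point-to-medoid distance
    cost_curve: dict[int, float] = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "medoid_indices": self.medoid_indices.tolist(),
            "labels": self.labels.tolist(),
            "cost": self.cost,
            "cost_curve": {int(k): v for k, v in self.cost_curve.items()},
            "seed": self.seed,
        }


def _pairwise_distances(points: np.ndarray) -> np.ndarray:
    diff = points[:, None, :] - points[None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=2))


def _maxmin_init(dist: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Greedy farthest-point initial medoids from a seeded random start."""
    n = dist.shape[0]
    medoids = [int(rng.integers(n))]
    while len(medoids) < k:
        d_to_nearest = dist[:, medoids].min(axis=1)
        d_to_nearest[medoids] = -1.0
        medoids.append(int(np.argmax(d_to_nearest)))
    return np.asarray(sorted(medoids), int)


def _pam(dist: np.ndarray, medoids: np.ndarray, max_iter: int = 300):
    """Alternating assignment/update until labels stabilize.

    Ties broken by lowest index.  Cost is asserted non-increasing across
    iterations.
    """
    medoids = np.array(medoids, int)
    prev_labels = None
    prev_cost = np.inf
    for _ in range(max_iter):
        labels = np.argmin(dist[:, medoids], axis=1)  # argmin takes lowest index on ties
        cost = float(dist[np.arange(len(labels)), medoids[labels]].sum())
        assert cost <= prev_cost + 1e-9, "PAM cost increased"
        prev_cost = cost
        if prev_labels is not None and np.array_equal(labels, prev_labels):
            break
        prev_labels = labels
        new_medoids = medoids.copy()
        for c in range(len(medoids)):
            members = np.flatnonzero(labels == c)
            if members.size == 0:
                continue
            in_cost = dist[np.ix_(members, members)].sum(axis=0)
            new_medoids[c] = int(members[np.argmin(in_cost)])
        medoids = new_medoids
    # greedy swap phase: try replacing each medoid by each non-medoid and
    # accept the best improving swap until none improves (escapes the
    # local optima the plain alternation can converge to)
    n = dist.shape[0]
    labels = np.argmin(dist[:, medoids], axis=1)
    cost = float(dist[np.arange(n), medoids[labels]].sum())
    improved = True
    while improved:
        improved = False
        d_med = dist[:, medoids]  # (n, k)
        order = np.argsort(d_med, axis=1)
        d1 = d_med[np.arange(n), order[:, 0]]
        nearest = order[:, 0]
        d2 = d_med[np.arange(n), order[:, 1]] if len(medoids) > 1 else np.full(n, np.inf)
        best_cost = cost
        best_swap = None
        for c in range(len(medoids)):
            base = np.where(nearest == c, d2, d1)  # cost without medoid c
            swap_costs = np.minimum(base[:, None], dist).sum(axis=0)  # per candidate
            swap_costs[medoids] = np.inf
            j = int(np.argmin(swap_costs))
            if swap_costs[j] < best_cost - 1e-12:
                best_cost = float(swap_costs[j])
                best_swap = (c, j)
        if best_swap is not None:
            assert best_cost <= cost, "PAM cost increased"
            medoids = medoids.copy()
            medoids[best_swap[0]] = best_swap[1]
            cost = best_cost
            improved = True
    labels = np.argmin(dist[:, medoids], axis=1)
    cost = float(dist[np.arange(n), medoids[labels]].sum())
    return medoids, labels, cost


def kmedoids(points: np.ndarray, k: int, seed: int = 0) -> ClusterModel:
    """PAM-style K-medoids on Euclidean distances, deterministic given seed."""
    points = np.atleast_2d(np.asarray(points, float))
    n = points.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of points n={n}")
    dist = _pairwise_distances(points)
    rng = np.random.default_rng(seed)
    medoids, labels, cost = _pam(dist, _maxmin_init(dist, k, rng))
    return ClusterModel(
        k=k, medoid_indices=medoids, labels=labels, cost=cost, seed=seed
    )


def elbow_select(
    points: np.ndarray,
    k_range: range | tuple[int, int] = (2, 10),
    seeds: int = 5,
    base_seed: int = 0,
) -> tuple[int, ClusterModel]:
    """Choose k at the knee (maximum second difference) of the cost curve.

    The cost per k is the best over ``seeds`` seeded initializations plus
    a warm start from the previous k's medoids, which guarantees a
    non-increasing curve.  Returns (k, fitted model at that k) with the
    full curve attached.
    """
    points = np.atleast_2d(np.asarray(points, float))
    n = points.shape[0]
    if isinstance(k_range, range):
        k_lo, k_hi = k_range.start, k_range.stop - 1
    else:
        k_lo, k_hi = k_range
    if not (1 <= k_lo <= k_hi <= n):
        raise ValueError(f"k range [{k_lo}, {k_hi}] not within [1, {n}]")
    dist = _pairwise_distances(points)
    scan_lo = max(1, k_lo - 1)
    curve: dict[int, float] = {}
    best: dict[int, tuple[np.ndarray, np.ndarray, float]] = {}
    prev_medoids: np.ndarray | None = None
    for k in range(scan_lo, k_hi + 1):
        candidates = []
        for s in range(seeds):
            rng = np.random.default_rng(base_seed + 1000 * k + s)
            candidates.append(_maxmin_init(dist, k, rng))
        if prev_medoids is not None and len(prev_medoids) == k - 1:
            d_to_nearest = dist[:, prev_medoids].min(axis=1)
            d_to_nearest[prev_medoids] = -1.0
            extra = int(np.argmax(d_to_nearest))
            candidates.append(np.asarray(sorted([*prev_medoids, extra]), int))
        best_run = None
        for init in candidates:
            run = _pam(dist, init)
            if best_run is None or run[2] < best_run[2]:
                best_run = run
        assert best_run is not None
        curve[k] = best_run[2]
        best[k] = best_run
        prev_medoids = best_run[0]
    ks = sorted(curve)
    costs = np.array([curve[k] for k in ks])
    if np.allclose(costs, costs[0]):
        warnings.warn("flat cost curve; returning smallest k")
        chosen = k_lo
    else:
        # knee = max second difference of log-cost: robust to unequal
        # basin separations (a plain-cost knee under-counts clusters when
        # the per-split cost drops differ by orders of magnitude)
        log_costs = np.log(np.maximum(costs, 1e-12))
        second_diff = {}
        for i, k in enumerate(ks):
            if k < k_lo or i == 0 or i == len(ks) - 1:
                continue
            second_diff[k] = log_costs[i - 1] - 2 * log_costs[i] + log_costs[i + 1]
        if not second_diff:
            chosen = k_lo
        else:
            chosen = max(sorted(second_diff), key=lambda k: second_diff[k])
    medoids, labels, cost = best[chosen]
    model = ClusterModel(
        k=chosen,
        medoid_indices=medoids,
        labels=labels,
        cost=cost,
        cost_curve=curve,
        seed=base_seed,
    )
    return chosen, model


def representatives(
    model: ClusterModel,
    traj: Trajectory,
    submap: SubdomainMap,
    metric: str = "residue_COM",
    cutoff: float = DEFAULT_CUTOFF,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    max_frames_per_cluster: int = 500,
    seed: int = 0,
) -> list[dict]:
    """Medoid structure, mean contact fingerprint and interface per cluster.

    Points are assumed to index trajectory frames (in order).  The mean
    cross-hairpin contact map is accumulated over up to
    ``max_frames_per_cluster`` member frames (deterministic subsample).
    """
    rng = np.random.default_rng(seed)
    out = []
    for c in range(model.k):
        members = np.flatnonzero(model.labels == c)
        medoid_idx = int(model.medoid_indices[c])
        if medoid_idx >= traj.n_frames:
            raise ValueError(
                f"medoid index {medoid_idx} not resolvable to a frame "
                f"(trajectory has {traj.n_frames})"
            )
        frame_members = members[members < traj.n_frames]
        if frame_members.size > max_frames_per_cluster:
            frame_members = np.sort(
                rng.choice(frame_members, size=max_frames_per_cluster, replace=False)
            )
        fingerprint = mean_contact_map(
            traj, frame_members, submap["HP1"], submap["HP2"],
            metric=metric, cutoff=cutoff,
        )
        medoid_model = traj.frame_model(medoid_idx, model_id=f"cluster{c}_medoid")
        call = classify_interface(
            medoid_model, submap, metric=metric, cutoff=cutoff,
            min_fraction=min_fraction,
        )
        out.append(
            {
                "cluster": c,
                "medoid_frame": medoid_idx,
                "n_members": int(members.size),
                "medoid_model": medoid_model,
                "fingerprint": fingerprint,
                "interface": call,
            }
        )
    return out
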