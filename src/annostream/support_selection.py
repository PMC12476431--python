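"""Support-set construction policies.

The clustering policy clusters the flattened binary label windows of all
positive patches with k-means (k = 100 by default), discards the single
largest cluster (which tends to hold the most frequent, least informative
pattern), and fills the patch budget proportionally from the remaining
clusters by largest-remainder apportionment. The random policy is a plain
uniform sample and serves as the baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .preprocessing import SlicePatch


@dataclass
class ClusterAssignment:
    n_clusters: int
    labels: np.ndarray  # per-patch cluster id
    sizes: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not self.sizes:
            ids, counts = np.unique(self.labels, return_counts=True)
            self.sizes = {int(i): int(c) for i, c in zip(ids, counts)}


@dataclass
class SupportSet:
    patches: list[SlicePatch]
    policy: str  # "clustering" | "random"
    provenance: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.patches)


def binarize_and_flatten(patch: SlicePatch) -> np.ndarray:
    """Row-major flattening of the patch's binary label window."""
    if patch.label_pixels is None:
        raise ValueError("patch has no label window")
    return (patch.label_pixels > 0).astype(np.uint8).ravel(order="C")


def cluster_patches(vectors: np.ndarray, k: int, seed: int, n_init: int = 10) -> ClusterAssignment:
    """Seeded k-means over binary label vectors.

    If fewer distinct vectors than k exist, k is lowered to that number with
    a warning (k-means cannot produce more non-empty clusters than distinct
    points).
    """
    vectors = np.asarray(vectors, dtype=np.float64)
    if vectors.ndim != 2 or len(vectors) == 0:
        raise ValueError("need a non-empty 2D array of flattened label vectors")
    n_distinct = len(np.unique(vectors, axis=0))
    if n_distinct < k:
        warnings.warn(
            f"only {n_distinct} distinct label vectors; lowering k from {k}",
            stacklevel=2,
        )
        k = max(1, n_distinct)
    km = KMeans(n_clusters=k, random_state=seed, n_init=n_init)
    labels = km.fit_predict(vectors)
    return ClusterAssignment(n_clusters=k, labels=labels)


def largest_remainder_allocation(sizes: dict[int, int], budget: int) -> dict[int, int]:
    """Apportion ``budget`` draws to clusters proportionally to size.

    Uses the largest-remainder (Hamilton) rule; remainder ties break toward
    the lower cluster id. Allocations are capped at cluster size, with any
    freed budget re-apportioned greedily by remaining capacity.
    """
    total = sum(sizes.values())
    if total == 0 or budget <= 0:
        return {cid: 0 for cid in sizes}
    quotas = {cid: budget * n / total for cid, n in sizes.items()}
    alloc = {cid: int(np.floor(q)) for cid, q in quotas.items()}
    leftover = budget - sum(alloc.values())
    order = sorted(sizes, key=lambda cid: (-(quotas[cid] - alloc[cid]), cid))
    for cid in order[:leftover]:
        alloc[cid] += 1
    # cap at availability and redistribute any excess
    excess = 0
    for cid in sorted(alloc):
        if alloc[cid] > sizes[cid]:
            excess += alloc[cid] - sizes[cid]
            alloc[cid] = sizes[cid]
    while excess > 0:
        candidates = [cid for cid in sorted(alloc) if alloc[cid] < sizes[cid]]
        if not candidates:
            break
        for cid in candidates:
            if excess == 0:
                break
            alloc[cid] += 1
            excess -= 1
    return alloc


def select_support_clustering(
    assignment: ClusterAssignment,
    patches: list[SlicePatch],
    budget: int,
    seed: int,
) -> SupportSet:
    """Drop the largest cluster, then sample the budget proportionally from
    the rest (uniform without replacement within each cluster)."""
    if len(assignment.labels) != len(patches):
        raise ValueError("assignment does not cover the patch list")
    sizes = dict(assignment.sizes)
    largest = min(
        (cid for cid in sizes), key=lambda cid: (-sizes[cid], cid)
    )
    remaining = {cid: n for cid, n in sizes.items() if cid != largest}
    if not remaining:
        warnings.warn(
            "all patches fall in a single cluster; sampling from it instead",
            stacklevel=2,
        )
        remaining = {largest: sizes[largest]}
        largest = None
    n_candidates = sum(remaining.values())
    if n_candidates < budget:
        warnings.warn(
            f"only {n_candidates} candidate patches for a budget of {budget}; "
            "returning all of them",
            stacklevel=2,
        )
    alloc = largest_remainder_allocation(remaining, min(budget, n_candidates))
    rng = np.random.default_rng(seed)
    by_cluster: dict[int, list[int]] = {}
    for idx, cid in enumerate(assignment.labels):
        by_cluster.setdefault(int(cid), []).append(idx)
    chosen: list[int] = []
    provenance: list[dict] = []
    for cid in sorted(alloc):
        take = alloc[cid]
        if take == 0:
            continue
        members = by_cluster[cid]
        picked = rng.choice(len(members), size=take, replace=False)
        for i in sorted(int(p) for p in picked):
            idx = members[i]
            chosen.append(idx)
            provenance.append(
                {
                    "scan_id": patches[idx].scan_id,
                    "origin": patches[idx].origin,
                    "cluster_id": cid,
                }
            )
    return SupportSet(
        patches=[patches[i] for i in chosen], policy="clustering", provenance=provenance
    )


def select_support_random(patches: list[SlicePatch], budget: int, seed: int) -> SupportSet:
    """Uniform sample without replacement of size ``min(budget, n)``."""
    if not patches:
        raise ValueError("no candidate patches")
    rng = np.random.default_rng(seed)
    n = len(patches)
    take = min(budget, n)
    picked = sorted(int(i) for i in rng.choice(n, size=take, replace=False))
    return SupportSet(
        patches=[patches[i] for i in picked],
        policy="random",
        provenance=[
            {"scan_id": patches[i].scan_id, "origin": patches[i].origin} for i in picked
        ],
    )
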