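"""Variability-based CpG selection and k-means feature compression.

The pipeline's first reduction keeps the K most variable CpGs by sample
standard deviation (default K = 10,000), then clusters their beta profiles
into C k-means clusters (default 1,000) and keeps R cluster-representative
CpGs (default 1,938): each cluster contributes its medoid, and the remaining
R - C slots are filled with the members next-closest to their centroid,
allocated to clusters proportionally to cluster size by largest remainder.
This preserves one-per-cluster coverage while hitting an arbitrary target
count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .io import BetaMatrix

logger = logging.getLogger(__name__)

DEFAULT_TOP_K = 10_000
DEFAULT_N_CLUSTERS = 1_000
DEFAULT_TARGET_REPS = 1_938


@dataclass
class ReducedSet:
    """Outcome of the selection/compression stage."""

    selected_cpgs: list[str]
    sd_of_cpg: dict[str, float]
    cluster_of_cpg: dict[str, int] = field(default_factory=dict)
    representatives: list[str] = field(default_factory=list)
    inertia: float | None = None
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        reps = set(self.representatives)
        return pd.DataFrame(
            {
                "cpg_id": self.selected_cpgs,
                "sd": [self.sd_of_cpg[c] for c in self.selected_cpgs],
                "cluster": [self.cluster_of_cpg.get(c, -1) for c in self.selected_cpgs],
                "is_representative": [c in reps for c in self.selected_cpgs],
            }
        )


def select_top_variable(matrix: BetaMatrix, k: int = DEFAULT_TOP_K) -> ReducedSet:
    """Keep the k CpGs with the largest sample standard deviation.

    SD uses the n-1 denominator; ties break toward the earlier input row.  If
    k exceeds the number of CpGs all are kept with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if matrix.shape[1] < 2:
        raise ValueError("standard deviation needs at least 2 samples")
    sd = matrix.values.std(axis=1, ddof=1)
    if k > len(sd):
        logger.warning("k=%d exceeds %d CpGs; keeping all", k, len(sd))
        k = len(sd)
    # Stable sort on -sd: among ties the earlier row wins.
    order = np.argsort(-sd.to_numpy(), kind="stable")[:k]
    order.sort()  # preserve original row order among the selected
    selected = [matrix.cpg_ids[i] for i in order]
    return ReducedSet(selected_cpgs=selected, sd_of_cpg=sd.to_dict())


def _largest_remainder(extra: int, sizes: np.ndarray, capacity: np.ndarray) -> np.ndarray:
    """Apportion ``extra`` slots to clusters ∝ size, capped by capacity."""
    alloc = np.zeros(len(sizes), dtype=int)
    if extra <= 0 or sizes.sum() == 0:
        return alloc
    quota = extra * sizes / sizes.sum()
    alloc = np.minimum(np.floor(quota).astype(int), capacity)
    remaining = extra - alloc.sum()
    # Priority: largest fractional remainder, then larger cluster, then index.
    frac = quota - np.floor(quota)
    prio = sorted(range(len(sizes)), key=lambda i: (-frac[i], -sizes[i], i))
    while remaining > 0:
        progressed = False
        for i in prio:
            if remaining == 0:
                break
            if alloc[i] < capacity[i]:
                alloc[i] += 1
                remaining -= 1
                progressed = True
        if not progressed:
            break  # every cluster exhausted
    return alloc


def reduce_by_kmeans(
    matrix: BetaMatrix,
    reduced: ReducedSet,
    n_clusters: int = DEFAULT_N_CLUSTERS,
    target_reps: int = DEFAULT_TARGET_REPS,
    seed: int = 0,
    n_init: int = 10,
) -> ReducedSet:
    """Cluster selected CpG profiles and pick representative CpGs.

    k-means (k-means++ init, ``n_init`` restarts, best inertia kept) on raw
    beta profiles with samples as dimensions.  Each cluster's medoid (member
    closest to the centroid) is a representative; remaining slots go to the
    next-closest members, proportionally to cluster size.
    """
    if not reduced.selected_cpgs:
        raise ValueError("empty selected CpG set")
    if target_reps < n_clusters:
        raise ValueError(f"target_reps={target_reps} < n_clusters={n_clusters}")
    if n_clusters > len(reduced.selected_cpgs):
        raise ValueError(
            f"n_clusters={n_clusters} exceeds {len(reduced.selected_cpgs)} selected CpGs"
        )
    sub = matrix.subset_cpgs(reduced.selected_cpgs)
    X = sub.values.to_numpy()
    km = KMeans(
        n_clusters=n_clusters,
        init="k-means++",
        n_init=n_init,
        max_iter=300,
        tol=1e-4,
        random_state=seed,
    ).fit(X)
    labels = km.labels_
    dists = np.linalg.norm(X - km.cluster_centers_[labels], axis=1)

    cpgs = np.asarray(reduced.selected_cpgs)
    members: list[np.ndarray] = []
    for c in range(n_clusters):
        idx = np.flatnonzero(labels == c)
        # order by distance to centroid; ties to earlier row via stable sort
        members.append(idx[np.argsort(dists[idx], kind="stable")])

    sizes = np.array([len(m) for m in members])
    reps_idx: list[int] = [int(m[0]) for m in members if len(m)]
    capacity = np.maximum(sizes - 1, 0)
    alloc = _largest_remainder(target_reps - len(reps_idx), sizes, capacity)
    for c, k_extra in enumerate(alloc):
        reps_idx.extend(int(i) for i in members[c][1 : 1 + k_extra])
    reps_idx.sort()

    return ReducedSet(
        selected_cpgs=reduced.selected_cpgs,
        sd_of_cpg=reduced.sd_of_cpg,
        cluster_of_cpg=dict(zip(cpgs.tolist(), (labels + 1).tolist())),
        representatives=cpgs[reps_idx].tolist(),
        inertia=float(km.inertia_),
        seed=seed,
    )
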