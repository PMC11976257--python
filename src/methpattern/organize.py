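"""Deriving CpG modules and sample methylation patterns by k-means.

Significant CpGs are clustered into ``k_mod`` modules (labels M1..Mk) on
their beta profiles across samples; all cohort samples are clustered into
``k_pat`` methylation patterns (MP1..MPk) on their profiles over the
significant CpGs.  Labels follow a deterministic convention: modules ordered
by ascending median beta (M1 lowest), patterns likewise over the significant
CpGs, so the same partition always receives the same names regardless of
input order or k-means internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .io import BetaMatrix, SampleAnnotation

DEFAULT_K_MOD = 4
DEFAULT_K_PAT = 7


@dataclass
class ModulePatternAssignment:
    module_of_cpg: dict[str, str] = field(default_factory=dict)
    pattern_of_sample: dict[str, str] = field(default_factory=dict)
    module_median: dict[str, float] = field(default_factory=dict)
    pattern_median: dict[str, float] = field(default_factory=dict)
    k_mod: int | None = None
    k_pat: int | None = None
    module_seed: int | None = None
    pattern_seed: int | None = None
    module_inertia: float | None = None
    pattern_inertia: float | None = None
    module_silhouette: float | None = None
    pattern_silhouette: float | None = None


def _ordered_labels(
    raw_labels: np.ndarray, medians_by_cluster: np.ndarray, prefix: str
) -> tuple[np.ndarray, dict[str, float]]:
    """Relabel clusters by ascending median beta; ties by cluster index."""
    order = np.argsort(medians_by_cluster, kind="stable")
    rename = {int(c): f"{prefix}{pos + 1}" for pos, c in enumerate(order)}
    labels = np.array([rename[int(c)] for c in raw_labels])
    medians = {rename[int(c)]: float(medians_by_cluster[c]) for c in order}
    return labels, medians


def assign_modules(
    matrix: BetaMatrix,
    k_mod: int = DEFAULT_K_MOD,
    seed: int = 0,
    n_init: int = 10,
    assignment: ModulePatternAssignment | None = None,
) -> ModulePatternAssignment:
    """k-means CpGs (rows) into modules M1..Mk ordered by median beta."""
    if k_mod < 1:
        raise ValueError("k_mod must be >= 1")
    n_cpgs = matrix.shape[0]
    if k_mod > n_cpgs:
        raise ValueError(f"k_mod={k_mod} exceeds {n_cpgs} CpGs")
    X = matrix.values.to_numpy()
    km = KMeans(n_clusters=k_mod, n_init=n_init, random_state=seed).fit(X)
    med = np.array([np.median(X[km.labels_ == c]) for c in range(k_mod)])
    labels, medians = _ordered_labels(km.labels_, med, "M")
    out = assignment or ModulePatternAssignment()
    out.module_of_cpg = dict(zip(matrix.cpg_ids, labels.tolist()))
    out.module_median = medians
    out.k_mod = k_mod
    out.module_seed = seed
    out.module_inertia = float(km.inertia_)
    if 1 < k_mod < n_cpgs:
        out.module_silhouette = float(silhouette_score(X, km.labels_))
    return out


def assign_patterns(
    matrix: BetaMatrix,
    k_pat: int = DEFAULT_K_PAT,
    seed: int = 0,
    n_init: int = 10,
    assignment: ModulePatternAssignment | None = None,
) -> ModulePatternAssignment:
    """k-means samples (columns) into patterns MP1..MPk ordered by median beta.

    All cohort samples present in the matrix are assigned, whether or not
    they belonged to a significant bicluster.
    """
    if k_pat < 1:
        raise ValueError("k_pat must be >= 1")
    n_samples = matrix.shape[1]
    if k_pat > n_samples:
        raise ValueError(f"k_pat={k_pat} exceeds {n_samples} samples")
    X = matrix.values.to_numpy().T  # samples x CpGs
    km = KMeans(n_clusters=k_pat, n_init=n_init, random_state=seed).fit(X)
    med = np.array([np.median(X[km.labels_ == c]) for c in range(k_pat)])
    labels, medians = _ordered_labels(km.labels_, med, "MP")
    out = assignment or ModulePatternAssignment()
    out.pattern_of_sample = dict(zip(matrix.sample_ids, labels.tolist()))
    out.pattern_median = medians
    out.k_pat = k_pat
    out.pattern_seed = seed
    out.pattern_inertia = float(km.inertia_)
    if 1 < k_pat < n_samples:
        out.pattern_silhouette = float(silhouette_score(X, km.labels_))
    return out


def pattern_composition(
    assignment: ModulePatternAssignment,
    annotation: SampleAnnotation,
    field_name: str,
) -> pd.DataFrame:
    """Pattern x level contingency table for one annotation column.

    Unknown/missing values form their own column; row sums equal pattern
    sizes.
    """
    if field_name not in annotation.table.columns:
        raise KeyError(f"annotation has no column {field_name!r}")
    pat = pd.Series(assignment.pattern_of_sample, name="pattern")
    lev = annotation.table[field_name].reindex(pat.index).astype("string")
    lev = lev.fillna("unknown")
    tab = pd.crosstab(pat, lev)
    tab = tab.sort_index(key=lambda ix: [(len(s), s) for s in ix])
    return tab
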