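"""UMAP embedding of samples on the significant CpGs, with projection.

The cohort is embedded in two dimensions from its beta profiles over the
significant CpG basis (Manhattan distance, 15 neighbors by default).
External cohorts measured on the same CpGs are projected into the fitted
space with the model's transform — the training coordinates are never
refitted — so validation samples can be placed relative to the discovered
methylation patterns reproducibly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import umap

from .io import BetaMatrix, read_beta_matrix

DEFAULT_N_NEIGHBORS = 15
DEFAULT_METRIC = "manhattan"
DEFAULT_MIN_DIST = 0.1


@dataclass
class EmbeddingModel:
    """A fitted 2-D UMAP over a fixed CpG basis.

    ``cpg_basis`` is stored sorted so embedding is invariant to the CpG row
    order of the input; projection requires every basis CpG in the new data.
    """

    n_neighbors: int
    metric: str
    min_dist: float
    seed: int
    cpg_basis: list[str]
    train_sample_ids: list[str]
    train_coords: np.ndarray
    _reducer: umap.UMAP
    _train_matrix: BetaMatrix

    @property
    def params(self) -> dict:
        return {
            "n_neighbors": self.n_neighbors,
            "metric": self.metric,
            "min_dist": self.min_dist,
            "seed": self.seed,
        }

    def coords_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.train_coords,
            index=pd.Index(self.train_sample_ids, name="sample_id"),
            columns=["umap1", "umap2"],
        )

    def save(self, directory) -> None:
        """Persist as a plain-text archive: params + training matrix + coords.

        The model is reconstructed by refitting, which is deterministic given
        the stored seed.
        """
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        with open(d / "params.json", "w") as fh:
            json.dump({"format_version": 1, **self.params}, fh, indent=1, sort_keys=True)
        # full precision so the reloading refit sees bit-identical input
        self._train_matrix.values.to_csv(
            d / "train_matrix.tsv", sep="\t", float_format="%.17g",
            na_rep="NA", index_label="cpg_id",
        )
        self.coords_frame().to_csv(d / "train_coords.tsv", sep="\t", float_format="%.6f")

    @classmethod
    def load(cls, directory) -> "EmbeddingModel":
        d = Path(directory)
        with open(d / "params.json") as fh:
            p = json.load(fh)
        matrix = read_beta_matrix(d / "train_matrix.tsv")
        return fit_embedding(
            matrix,
            n_neighbors=p["n_neighbors"],
            metric=p["metric"],
            min_dist=p["min_dist"],
            seed=p["seed"],
        )


def fit_embedding(
    matrix: BetaMatrix,
    n_neighbors: int = DEFAULT_N_NEIGHBORS,
    metric: str = DEFAULT_METRIC,
    min_dist: float = DEFAULT_MIN_DIST,
    seed: int = 0,
) -> EmbeddingModel:
    """Fit a 2-D UMAP of samples from their beta profiles.

    Deterministic given ``seed``; requires at least ``n_neighbors + 1``
    samples.
    """
    n_samples = matrix.shape[1]
    if n_samples < n_neighbors + 1:
        raise ValueError(
            f"need >= {n_neighbors + 1} samples for n_neighbors={n_neighbors}, "
            f"got {n_samples}"
        )
    if metric not in ("manhattan", "euclidean"):
        raise ValueError(f"unsupported metric {metric!r}")
    basis = sorted(matrix.cpg_ids)
    ordered = matrix.subset_cpgs(basis)
    X = ordered.values.to_numpy().T  # samples x CpGs
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=n_neighbors,
        metric=metric,
        min_dist=min_dist,
        random_state=seed,
    )
    coords = reducer.fit_transform(X)
    return EmbeddingModel(
        n_neighbors=n_neighbors,
        metric=metric,
        min_dist=min_dist,
        seed=seed,
        cpg_basis=basis,
        train_sample_ids=matrix.sample_ids,
        train_coords=np.asarray(coords, dtype=float),
        _reducer=reducer,
        _train_matrix=ordered,
    )


def project_samples(model: EmbeddingModel, new_matrix: BetaMatrix) -> pd.DataFrame:
    """Project new samples into a fitted embedding without refitting.

    The new matrix must contain every CpG of the model's basis (extra CpGs
    are ignored); returns a (sample x [umap1, umap2]) frame.
    """
    if new_matrix.shape[1] == 0:
        raise ValueError("no samples to project")
    missing = sorted(set(model.cpg_basis) - set(new_matrix.cpg_ids))
    if missing:
        shown = ", ".join(missing[:5])
        raise ValueError(
            f"{len(missing)} basis CpG(s) missing from new data: {shown}"
            + ("..." if len(missing) > 5 else "")
        )
    X = new_matrix.subset_cpgs(model.cpg_basis).values.to_numpy().T
    coords = model._reducer.transform(X)
    return pd.DataFrame(
        np.asarray(coords, dtype=float),
        index=pd.Index(new_matrix.sample_ids, name="sample_id"),
        columns=["umap1", "umap2"],
    )
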