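"""End-to-end orchestration: one config, one seed, one result bundle.

Stages run in order — I/O, feature reduction, consensus biclustering,
module/pattern derivation, embedding, statistics — each seeded from a single
master seed via stage-keyed seed sequences, so any stage can be re-run in
isolation and reproduce the end-to-end result.  All artifacts are plain TSV
plus JSON sidecars; wall-clock timings go to a separate file so the rest of
the bundle is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biclust, embed, organize, reduce, stats
from .io import (
    BetaMatrix,
    SampleAnnotation,
    align,
    read_annotation,
    read_beta_matrix,
)

logger = logging.getLogger(__name__)

_STAGES = ("reduce", "biclust", "organize", "embed", "stats")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, with the published defaults.

    ``top_k`` / ``n_clusters`` / ``target_reps`` reproduce the
    10,000 -> 1,000 clusters -> 1,938 representatives reduction; ``k_mod=4``
    and ``k_pat=7`` the module/pattern counts; the embedding uses Manhattan
    distance with 15 neighbors.
    """

    matrix_path: str | None = None
    annotation_path: str | None = None
    out_dir: str = "methpattern_out"
    dialect: str = "tsv"
    top_k: int = reduce.DEFAULT_TOP_K
    n_clusters: int = reduce.DEFAULT_N_CLUSTERS
    target_reps: int = reduce.DEFAULT_TARGET_REPS
    kmeans_n_init: int = 10
    ranks: tuple[int, ...] = biclust.DEFAULT_RANKS
    n_seeds: int = biclust.DEFAULT_SEEDS
    row_thresh: float = biclust.DEFAULT_ROW_THRESH
    col_thresh: float = biclust.DEFAULT_COL_THRESH
    alpha: float = biclust.DEFAULT_ALPHA
    support_min: float = biclust.DEFAULT_SUPPORT_MIN
    n_perm: int = biclust.DEFAULT_N_PERM
    nmf_max_iter: int = 200
    nmf_tol: float = 1e-5
    k_mod: int = organize.DEFAULT_K_MOD
    k_pat: int = organize.DEFAULT_K_PAT
    n_neighbors: int = embed.DEFAULT_N_NEIGHBORS
    metric: str = embed.DEFAULT_METRIC
    min_dist: float = embed.DEFAULT_MIN_DIST
    continuous_fields: tuple[str, ...] = ("age", "tcc")
    categorical_fields: tuple[str, ...] = (
        "diagnosis",
        "coo",
        "bcl2_rearranged",
        "bcl6_rearranged",
        "mutational_cluster",
    )
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.target_reps < self.n_clusters:
            raise ValueError("target_reps must be >= n_clusters")
        if self.top_k < self.target_reps:
            raise ValueError("top_k must be >= target_reps")
        for name in ("top_k", "n_clusters", "target_reps", "k_mod", "k_pat"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        self.ranks = tuple(int(r) for r in self.ranks)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ranks"] = list(self.ranks)
        d["continuous_fields"] = list(self.continuous_fields)
        d["categorical_fields"] = list(self.categorical_fields)
        return d

    _PATH_FIELDS = ("matrix_path", "annotation_path", "out_dir")

    def analysis_params(self) -> dict:
        """Config without filesystem paths: what determines the results."""
        return {k: v for k, v in self.to_dict().items() if k not in self._PATH_FIELDS}

    def param_hash(self) -> str:
        blob = json.dumps(self.analysis_params(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic stage seed below 2**31, keyed by stage name."""
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineResult:
    config: PipelineConfig
    reduced: reduce.ReducedSet
    biclusters: list[biclust.Bicluster]
    significant: biclust.SignificantSet
    assignment: organize.ModulePatternAssignment
    embedding: embed.EmbeddingModel | None
    wilcoxon: dict[str, list[stats.AssociationResult]]
    enrichment: dict[str, list[stats.AssociationResult]]
    stage_seconds: dict[str, float] = field(default_factory=dict)


def run_pipeline(
    config: PipelineConfig,
    matrix: BetaMatrix | None = None,
    annotation: SampleAnnotation | None = None,
    write: bool = True,
) -> PipelineResult:
    """Execute the full analysis and (optionally) write the result bundle.

    Inputs may be passed in memory or read from the configured paths.  Any
    stage failure aborts with the stage name; partially written outputs are
    removed.
    """
    timings: dict[str, float] = {}

    def timed(stage, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:  # noqa: BLE001 - rewrapped with stage context
            raise PipelineStageError(stage, exc) from exc
        timings[stage] = time.perf_counter() - t0
        return out

    if matrix is None:
        if config.matrix_path is None:
            raise ValueError("no matrix given and no matrix_path configured")
        matrix = timed("io", lambda: read_beta_matrix(config.matrix_path, config.dialect))
    if annotation is None and config.annotation_path:
        annotation = read_annotation(config.annotation_path, config.dialect)
    if annotation is not None:
        matrix, annotation = align(matrix, annotation)
    matrix = matrix.impute_missing()

    top_k = config.top_k
    if top_k > matrix.shape[0]:
        logger.warning("top_k=%d exceeds %d CpGs; using all", top_k, matrix.shape[0])
        top_k = matrix.shape[0]

    def _reduce():
        sel = reduce.select_top_variable(matrix, top_k)
        return reduce.reduce_by_kmeans(
            matrix,
            sel,
            n_clusters=config.n_clusters,
            target_reps=min(config.target_reps, len(sel.selected_cpgs)),
            seed=stage_seed(config.master_seed, "reduce"),
            n_init=config.kmeans_n_init,
        )

    reduced = timed("reduce", _reduce)

    rep_matrix = matrix.subset_cpgs(reduced.representatives)

    def _biclust():
        return biclust.consensus_biclustering(
            rep_matrix.values.to_numpy(),
            rep_matrix.cpg_ids,
            rep_matrix.sample_ids,
            ranks=config.ranks,
            seeds=config.n_seeds,
            row_thresh=config.row_thresh,
            col_thresh=config.col_thresh,
            alpha=config.alpha,
            support_min=config.support_min,
            n_perm=config.n_perm,
            master_seed=stage_seed(config.master_seed, "biclust"),
            max_iter=config.nmf_max_iter,
            tol=config.nmf_tol,
        )

    biclusters, significant = timed("biclust", _biclust)

    assignment = organize.ModulePatternAssignment()
    model = None
    wilcoxon: dict[str, list[stats.AssociationResult]] = {}
    enrichment: dict[str, list[stats.AssociationResult]] = {}
    if significant.cpgs:
        sig_matrix = matrix.subset_cpgs(significant.cpgs)

        def _organize():
            seed = stage_seed(config.master_seed, "organize")
            a = organize.assign_modules(sig_matrix, config.k_mod, seed=seed)
            return organize.assign_patterns(
                sig_matrix, config.k_pat, seed=seed, assignment=a
            )

        assignment = timed("organize", _organize)

        if sig_matrix.shape[1] >= config.n_neighbors + 1:
            model = timed(
                "embed",
                lambda: embed.fit_embedding(
                    sig_matrix,
                    n_neighbors=config.n_neighbors,
                    metric=config.metric,
                    min_dist=config.min_dist,
                    seed=stage_seed(config.master_seed, "embed"),
                ),
            )
        else:
            logger.warning("too few samples for embedding; stage skipped")

        if annotation is not None:

            def _stats():
                pat = assignment.pattern_of_sample
                pat_series = pd.Series(pat)
                for col in config.continuous_fields:
                    if col not in annotation.table.columns:
                        continue
                    vals = annotation.table[col].reindex(pat_series.index)
                    keep = vals.notna()
                    if keep.sum() < 4 or pat_series[keep].nunique() < 2:
                        continue
                    wilcoxon[col] = stats.pairwise_wilcoxon(
                        vals[keep].to_numpy(), pat_series[keep].to_numpy()
                    )
                for col in config.categorical_fields:
                    if col not in annotation.table.columns:
                        continue
                    enrichment[col] = stats.pattern_enrichment(
                        pat, annotation.table[col]
                    )
                return None

            timed("stats", _stats)
    else:
        logger.warning("empty significant set; downstream stages skipped")

    result = PipelineResult(
        config=config,
        reduced=reduced,
        biclusters=biclusters,
        significant=significant,
        assignment=assignment,
        embedding=model,
        wilcoxon=wilcoxon,
        enrichment=enrichment,
        stage_seconds=timings,
    )
    if write:
        write_bundle(result, Path(config.out_dir))
    return result


def _bicluster_frame(biclusters: list[biclust.Bicluster]) -> pd.DataFrame:
    rows = []
    for i, b in enumerate(biclusters):
        rows.append(
            {
                "bicluster_id": i,
                "rank": b.rank,
                "factor": b.factor,
                "n_cpgs": len(b.cpg_ids),
                "n_samples": len(b.sample_ids),
                "coherence": b.coherence,
                "consensus_support": b.consensus_support,
                "p_consensus": b.p_consensus,
                "p_coherence": b.p_coherence,
                "significant": b.significant,
            }
        )
    return pd.DataFrame(rows)


def _members_frame(biclusters: list[biclust.Bicluster]) -> pd.DataFrame:
    rows = []
    for i, b in enumerate(biclusters):
        for c in b.cpg_ids:
            rows.append((i, "cpg", c, b.row_membership[c]))
        for s in b.sample_ids:
            rows.append((i, "sample", s, b.col_membership[s]))
    return pd.DataFrame(rows, columns=["bicluster_id", "kind", "id", "membership"])


def _assoc_frame(results: dict[str, list[stats.AssociationResult]]) -> pd.DataFrame:
    rows = []
    for col, lst in sorted(results.items()):
        for r in lst:
            rows.append(
                {
                    "field": col,
                    "group_a": r.comparison[0],
                    "group_b": r.comparison[1],
                    "statistic": r.statistic,
                    "p_raw": r.p_raw,
                    "p_adjusted": r.p_adjusted,
                    "m": r.m,
                    "method": r.method,
                    "odds_ratio": r.odds_ratio,
                    "ci95_low": r.ci95[0] if r.ci95 else None,
                    "ci95_high": r.ci95[1] if r.ci95 else None,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "field", "group_a", "group_b", "statistic", "p_raw", "p_adjusted",
            "m", "method", "odds_ratio", "ci95_low", "ci95_high",
        ],
    )


def write_bundle(result: PipelineResult, out_dir: Path) -> None:
    """Write all artifacts; on failure remove everything written so far."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def tsv(name: str, df: pd.DataFrame, index: bool = False) -> None:
        path = out_dir / name
        df.to_csv(path, sep="\t", float_format="%.6g", index=index)
        written.append(path)

    try:
        tsv("reduced_set.tsv", result.reduced.to_frame())
        tsv("biclusters.tsv", _bicluster_frame(result.biclusters))
        tsv("bicluster_members.tsv", _members_frame(result.biclusters))
        tsv(
            "significant_set.tsv",
            pd.DataFrame(
                [("cpg", c) for c in result.significant.cpgs]
                + [("sample", s) for s in result.significant.samples],
                columns=["kind", "id"],
            ),
        )
        a = result.assignment
        tsv(
            "modules.tsv",
            pd.DataFrame(sorted(a.module_of_cpg.items()), columns=["cpg_id", "module"]),
        )
        tsv(
            "patterns.tsv",
            pd.DataFrame(
                sorted(a.pattern_of_sample.items()), columns=["sample_id", "pattern"]
            ),
        )
        if result.embedding is not None:
            coords = result.embedding.coords_frame()
            coords["source_cohort"] = "train"
            tsv("embedding.tsv", coords, index=True)
            result.embedding.save(out_dir / "embedding_model")
            written.append(out_dir / "embedding_model")
        tsv("stats_wilcoxon.tsv", _assoc_frame(result.wilcoxon))
        tsv("stats_enrichment.tsv", _assoc_frame(result.enrichment))

        summary = {
            "n_selected_cpgs": len(result.reduced.selected_cpgs),
            "n_representatives": len(result.reduced.representatives),
            "n_biclusters": len(result.biclusters),
            "n_significant_biclusters": sum(b.significant for b in result.biclusters),
            "n_significant_cpgs": len(result.significant.cpgs),
            "n_significant_samples": len(result.significant.samples),
            "module_sizes": _label_sizes(a.module_of_cpg),
            "pattern_sizes": _label_sizes(a.pattern_of_sample),
            "module_silhouette": a.module_silhouette,
            "pattern_silhouette": a.pattern_silhouette,
        }
        _json(out_dir / "summary.json", summary, written)
        _json(
            out_dir / "run_metadata.json",
            {
                "config": result.config.analysis_params(),
                "param_hash": result.config.param_hash(),
                "stage_seeds": {
                    s: stage_seed(result.config.master_seed, s) for s in _STAGES
                },
            },
            written,
        )
        # timings.json also carries the filesystem paths: everything here is
        # run-environment specific, all other artifacts are byte-reproducible
        _json(
            out_dir / "timings.json",
            {
                "stage_seconds": result.stage_seconds,
                "paths": {
                    k: getattr(result.config, k) for k in PipelineConfig._PATH_FIELDS
                },
            },
            written,
        )
    except Exception:
        for p in written:
            if p.is_dir():
                for f in sorted(p.rglob("*"), reverse=True):
                    f.unlink()
                p.rmdir()
            elif p.exists():
                p.unlink()
        raise


def _label_sizes(mapping: dict[str, str]) -> dict[str, int]:
    out: dict[str, int] = {}
    for v in mapping.values():
        out[v] = out.get(v, 0) + 1
    return dict(sorted(out.items()))


def _json(path: Path, payload, written: list[Path]) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    written.append(path)
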