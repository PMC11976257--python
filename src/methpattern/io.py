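"""Reading, writing and aligning beta-value matrices and sample annotations.

All pipeline stages exchange a :class:`BetaMatrix` — a CpG x sample matrix of
methylation fractions (beta values) in [0, 1] — and a :class:`SampleAnnotation`
table carrying per-sample clinical and molecular covariates.  Files are plain
TSV (CSV selectable): the matrix has a sample-ID header row and probe IDs in
the first column; the annotation has a header row with a mandatory
``sample_id`` column.  Probe identifiers are opaque strings; no array-manifest
lookup is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Recognised categorical annotation columns and their declared levels.
#: Values outside the declared set are mapped to ``UNKNOWN_LEVEL``.
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "diagnosis": ("FL", "DLBCL", "FL-DLBCL", "other"),
    "coo": ("GCB", "ABC", "unclassified", "n.a."),
    "bcl2_rearranged": ("yes", "no"),
    "bcl6_rearranged": ("yes", "no"),
}

UNKNOWN_LEVEL = "unknown"

_NA_STRINGS = {"", "NA", "NaN", "nan", "na"}


class BetaMatrixError(ValueError):
    """Raised on malformed beta matrices or annotation tables."""


@dataclass
class BetaMatrix:
    """CpG x sample matrix of methylation beta values.

    Parameters
    ----------
    values
        DataFrame with probe IDs as index, sample IDs as columns; entries are
        floats in [0, 1], ``NaN`` marking missing measurements.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise BetaMatrixError(f"duplicate probe IDs: {dups[:5]}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise BetaMatrixError(f"duplicate sample IDs: {dups[:5]}")
        arr = df.to_numpy(dtype=float)
        bad = np.where((arr < 0) | (arr > 1))
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise BetaMatrixError(
                f"beta value out of [0,1] at (probe {df.index[i]!r}, "
                f"sample {df.columns[j]!r}): {arr[i, j]}"
            )
        self.values = df.astype(float)

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_cpgs(self, cpg_ids) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[list(cpg_ids)])

    def subset_samples(self, sample_ids) -> "BetaMatrix":
        return BetaMatrix(self.values[list(sample_ids)])

    def impute_missing(self, max_missing_frac: float = 0.2) -> "BetaMatrix":
        """Mean-impute missing betas per CpG; drop CpGs missing too often.

        CpGs with more than ``max_missing_frac`` missing entries are dropped
        (count logged); remaining missing cells are filled with the CpG's mean
        across samples, which leaves per-CpG location statistics unchanged.
        """
        df = self.values
        frac = df.isna().mean(axis=1)
        keep = frac <= max_missing_frac
        if (~keep).any():
            logger.warning(
                "dropping %d CpGs with >%d%% missing values",
                int((~keep).sum()),
                int(max_missing_frac * 100),
            )
        df = df.loc[keep]
        if df.isna().any().any():
            df = df.apply(lambda row: row.fillna(row.mean()), axis=1)
        return BetaMatrix(df)


@dataclass
class SampleAnnotation:
    """Per-sample covariate table indexed by sample ID.

    Recognised columns: ``diagnosis``, ``coo``, ``age``, ``bcl2_rearranged``,
    ``bcl6_rearranged``, ``tcc`` (tumor cell content, fraction in [0, 1]) and
    ``mutational_cluster``; arbitrary extra columns are carried through.
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        df = self.table
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise BetaMatrixError(f"duplicate sample IDs in annotation: {dups[:5]}")
        if "tcc" in df.columns:
            tcc = pd.to_numeric(df["tcc"], errors="coerce")
            bad = tcc.dropna()
            bad = bad[(bad < 0) | (bad > 1)]
            if len(bad):
                raise BetaMatrixError(
                    f"tcc outside [0,1] for samples {bad.index.tolist()[:5]}"
                )
            df["tcc"] = tcc
        if "age" in df.columns:
            df["age"] = pd.to_numeric(df["age"], errors="coerce")
        for col, levels in CATEGORICAL_LEVELS.items():
            if col in df.columns:
                raw = df[col].astype("string")
                known = raw.isin(levels) | raw.isna()
                if (~known).any():
                    logger.warning(
                        "column %r: %d value(s) outside declared levels mapped to %r",
                        col,
                        int((~known).sum()),
                        UNKNOWN_LEVEL,
                    )
                df[col] = raw.where(known, UNKNOWN_LEVEL).fillna(UNKNOWN_LEVEL)
        self.table = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def subset(self, sample_ids) -> "SampleAnnotation":
        return SampleAnnotation(self.table.loc[list(sample_ids)].copy())


def _sep(dialect: str) -> str:
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")
    return "\t" if dialect == "tsv" else ","


def read_beta_matrix(path, dialect: str = "tsv") -> BetaMatrix:
    """Read a beta matrix from a delimited text file.

    First row is the sample header, first column the probe IDs.  Empty cells
    and ``NA`` are treated as missing.  Raises :class:`BetaMatrixError` for
    out-of-range values, duplicate IDs or an empty file.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    if not header:
        raise BetaMatrixError(f"no data rows/columns parsed from {path}")
    sample_header = header.split(_sep(dialect))[1:]
    if len(set(sample_header)) < len(sample_header):
        dups = sorted({s for s in sample_header if sample_header.count(s) > 1})
        raise BetaMatrixError(f"duplicate sample IDs in header: {dups[:5]}")
    try:
        df = pd.read_csv(
            path,
            sep=_sep(dialect),
            index_col=0,
            na_values=list(_NA_STRINGS),
            keep_default_na=False,
        )
    except pd.errors.EmptyDataError as exc:
        raise BetaMatrixError(f"no data rows/columns parsed from {path}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise BetaMatrixError(f"no data rows/columns parsed from {path}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise BetaMatrixError(f"non-numeric beta value in {path}: {exc}") from exc
    return BetaMatrix(df)


def write_beta_matrix(matrix: BetaMatrix, path, dialect: str = "tsv") -> None:
    """Write a beta matrix; floats at 6 decimals, missing cells as ``NA``."""
    matrix.values.to_csv(
        path, sep=_sep(dialect), float_format="%.6f", na_rep="NA", index_label="cpg_id"
    )


def read_annotation(path, dialect: str = "tsv") -> SampleAnnotation:
    """Read a sample annotation table (requires a ``sample_id`` column)."""
    df = pd.read_csv(
        path,
        sep=_sep(dialect),
        na_values=list(_NA_STRINGS),
        keep_default_na=False,
        dtype=str,
    )
    if "sample_id" not in df.columns:
        raise BetaMatrixError(f"annotation {path} lacks a 'sample_id' column")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    return SampleAnnotation(df)


def write_annotation(annotation: SampleAnnotation, path, dialect: str = "tsv") -> None:
    annotation.table.to_csv(path, sep=_sep(dialect), na_rep="NA", index_label="sample_id")


def align(
    matrix: BetaMatrix, annotation: SampleAnnotation
) -> tuple[BetaMatrix, SampleAnnotation]:
    """Restrict matrix and annotation to their common samples, in matrix order.

    Raises if the intersection is empty; logs the number of samples dropped
    from each side.
    """
    ann_ids = set(annotation.sample_ids)
    common = [s for s in matrix.sample_ids if s in ann_ids]
    if not common:
        raise BetaMatrixError("matrix and annotation share no sample IDs")
    n_drop_mat = len(matrix.sample_ids) - len(common)
    n_drop_ann = len(annotation.sample_ids) - len(common)
    if n_drop_mat or n_drop_ann:
        logger.info(
            "align: dropped %d matrix sample(s), %d annotation sample(s)",
            n_drop_mat,
            n_drop_ann,
        )
    return matrix.subset_samples(common), annotation.subset(common)
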