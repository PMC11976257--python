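"""Fuzzy non-negative matrix factorization biclustering with significance.

The analysis core.  A beta matrix V (CpGs x samples) is factorized at several
ranks with multiplicative updates minimizing squared Frobenius error.  Each
factor defines a fuzzy bicluster: a CpG's membership in factor f is its
normalized loading W[i, f] / sum_g W[i, g] (and analogously for samples via
H), and members are the rows/columns whose membership passes a threshold.

Significance of a bicluster rests on three conditions, all of which must
hold:

* consensus — across repeated factorizations (all ranks x seeds), other runs
  must contain a bicluster whose CpG set overlaps the reference bicluster
  more than chance (upper-tail hypergeometric p <= alpha) in at least a
  ``support_min`` fraction of runs, with median match p <= alpha;
* coherence — the member rows must be tighter on the member samples than on
  the cohort at large (coherence gain), exceeding random same-shaped
  submatrices (permutation p <= alpha).

The union of CpGs and samples over significant biclusters is the significant
set handed to module/pattern derivation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

_EPS = 1e-12

DEFAULT_RANKS = tuple(range(3, 11))
DEFAULT_SEEDS = 5
DEFAULT_ROW_THRESH = 0.5
DEFAULT_COL_THRESH = 0.5
DEFAULT_ALPHA = 0.01
DEFAULT_SUPPORT_MIN = 0.5
DEFAULT_N_PERM = 999


@dataclass
class FactorizationResult:
    rank: int
    W: np.ndarray
    H: np.ndarray
    error_trace: list[float]
    seed: int
    n_iter: int


@dataclass
class Bicluster:
    """A (CpG set, sample set) pair with fuzzy memberships and a verdict."""

    cpg_ids: list[str]
    sample_ids: list[str]
    row_membership: dict[str, float]
    col_membership: dict[str, float]
    factor: int
    rank: int
    coherence: float | None = None
    coherence_gain: float | None = None
    consensus_support: float | None = None
    p_consensus: float | None = None
    p_coherence: float | None = None
    p_submatrix: float | None = None
    significant: bool = False
    row_idx: np.ndarray | None = None
    col_idx: np.ndarray | None = None


@dataclass
class SignificantSet:
    cpgs: list[str] = field(default_factory=list)
    samples: list[str] = field(default_factory=list)


def nmf_factorize(
    V: np.ndarray,
    rank: int,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-5,
) -> FactorizationResult:
    """Multiplicative-update NMF of a nonnegative matrix.

    W and H are initialized uniform on (0, 1] scaled by the mean of V, then
    updated with the standard Frobenius multiplicative rules, which never
    increase the reconstruction error.  Iteration stops at ``max_iter`` or
    when the relative error changes by less than ``tol``.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError("V must be a matrix")
    if np.any(V < 0):
        raise ValueError("V has negative entries")
    n, m = V.shape
    if not 1 <= rank <= min(n, m):
        raise ValueError(f"rank {rank} outside [1, {min(n, m)}]")

    rng = np.random.default_rng(seed)
    scale = max(V.mean(), _EPS)
    # uniform on (0, 1]: 1 - U with U uniform on [0, 1)
    W = scale * (1.0 - rng.random((n, rank)))
    H = scale * (1.0 - rng.random((rank, m)))

    norm_V = np.linalg.norm(V)
    if norm_V == 0:
        norm_V = 1.0
    trace: list[float] = []
    prev = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        # H update
        WtV = W.T @ V
        WtWH = (W.T @ W) @ H
        H *= WtV / np.maximum(WtWH, _EPS)
        # W update
        VHt = V @ H.T
        WHHt = W @ (H @ H.T)
        W *= VHt / np.maximum(WHHt, _EPS)
        err = float(np.linalg.norm(V - W @ H) / norm_V)
        trace.append(err)
        if prev - err < tol * max(prev, _EPS) and np.isfinite(prev):
            break
        prev = err
    return FactorizationResult(rank=rank, W=W, H=H, error_trace=trace, seed=seed, n_iter=it)


def fuzzy_memberships(loadings: np.ndarray, axis: int) -> np.ndarray:
    """Normalize factor loadings to fuzzy memberships along ``axis``.

    Rows (or columns) that are entirely zero get membership 0 everywhere, so
    uninformative probes never enter a bicluster.
    """
    s = loadings.sum(axis=axis, keepdims=True)
    out = np.divide(loadings, s, out=np.zeros_like(loadings, dtype=float), where=s > 0)
    return out


def bicluster_coherence(sub: np.ndarray) -> float:
    """Mean absolute deviation of a submatrix from its row-mean profile."""
    if sub.size == 0:
        return float("nan")
    return float(np.mean(np.abs(sub - sub.mean(axis=1, keepdims=True))))


def coherence_gain(V: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> float:
    """How much tighter the member rows are on the member columns.

    Gain = coherence of the member rows over *all* samples minus their
    coherence over the member samples.  A bicluster whose rows are flat
    everywhere (background probes) gains nothing however coherent its
    submatrix looks, whereas a genuine bicluster — rows heterogeneous across
    the cohort but homogeneous within the member samples — gains a lot.
    """
    return bicluster_coherence(V[rows, :]) - bicluster_coherence(V[np.ix_(rows, cols)])


def extract_biclusters(
    fr: FactorizationResult,
    cpg_ids: list[str],
    sample_ids: list[str],
    V: np.ndarray | None = None,
    row_thresh: float = DEFAULT_ROW_THRESH,
    col_thresh: float = DEFAULT_COL_THRESH,
) -> list[Bicluster]:
    """Threshold fuzzy memberships into per-factor biclusters.

    Factor f's bicluster comprises the CpGs with row membership >= row_thresh
    and the samples with column membership >= 2 * col_thresh / rank;
    biclusters empty on either side are dropped.  When V is given, member
    coherence is recorded.

    The two thresholds deliberately live on different scales.  CpG loadings
    are sparse across factors — a structured probe is dominated by one or two
    factors at any rank — so an absolute membership cut is meaningful.  A
    sample's profile, in contrast, mixes contributions from every CpG-module
    factor, so its memberships concentrate near the uniform share 1/rank and
    an absolute cut empties biclusters at higher ranks; the column cut is
    therefore expressed relative to rank (at the default 0.5 it equals the
    uniform share, and at rank 2 it coincides with the absolute value).
    """
    if not (0 <= row_thresh < 1 and 0 <= col_thresh < 1):
        raise ValueError("thresholds must lie in [0, 1)")
    rowm = fuzzy_memberships(fr.W, axis=1)  # CpG memberships across factors
    colm = fuzzy_memberships(fr.H, axis=0)  # sample memberships across factors
    col_cut = 2.0 * col_thresh / fr.rank
    out: list[Bicluster] = []
    for f in range(fr.rank):
        if row_thresh == 0:
            rows = np.flatnonzero(fr.W[:, f] > 0)
        else:
            rows = np.flatnonzero(rowm[:, f] >= row_thresh)
        if col_thresh == 0:
            cols = np.flatnonzero(fr.H[f, :] > 0)
        else:
            cols = np.flatnonzero(colm[f, :] >= col_cut)
        if rows.size == 0 or cols.size == 0:
            continue
        bic = Bicluster(
            cpg_ids=[cpg_ids[i] for i in rows],
            sample_ids=[sample_ids[j] for j in cols],
            row_membership={cpg_ids[i]: float(rowm[i, f]) for i in rows},
            col_membership={sample_ids[j]: float(colm[f, j]) for j in cols},
            factor=f,
            rank=fr.rank,
            row_idx=rows,
            col_idx=cols,
        )
        if V is not None:
            bic.coherence = bicluster_coherence(V[np.ix_(rows, cols)])
            bic.coherence_gain = coherence_gain(V, rows, cols)
        out.append(bic)
    return out


def hypergeometric_overlap_p(set_a, set_b, universe) -> float:
    """Upper-tail hypergeometric p of the overlap between two ID sets.

    P(X >= |A & B|) drawing |B| items from a universe of |U| containing |A|
    successes.
    """
    A, B, U = set(set_a), set(set_b), set(universe)
    if not A <= U or not B <= U:
        raise ValueError("sets must be subsets of the universe")
    k = len(A & B)
    return float(hypergeom.sf(k - 1, len(U), len(A), len(B)))


def coherence_permutation_p(
    bic: Bicluster,
    V: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> float:
    """Permutation p-value for bicluster coherence gain.

    The null draws ``n_perm`` random (row set, column set) pairs of the same
    shape uniformly from V and computes their coherence gain; p =
    (1 + #{null gain >= observed}) / (n_perm + 1).  A random submatrix gains
    essentially nothing (a random column subset is representative of the
    cohort), so only biclusters whose member samples genuinely tighten the
    member rows score small p.  On a constant matrix every gain is 0 and
    p = 1.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n, m = V.shape
    nr, nc = len(bic.cpg_ids), len(bic.sample_ids)
    if nr > n or nc > m:
        raise ValueError("bicluster dimensions exceed matrix dimensions")
    if bic.row_idx is None or bic.col_idx is None:
        raise ValueError("bicluster lacks member indices into V")
    observed = coherence_gain(V, np.asarray(bic.row_idx), np.asarray(bic.col_idx))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        rows = rng.choice(n, size=nr, replace=False)
        cols = rng.choice(m, size=nc, replace=False)
        if coherence_gain(V, rows, cols) >= observed:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def selection_null_gains(
    V: np.ndarray,
    ranks,
    n_shuffles: int = 10,
    row_thresh: float = DEFAULT_ROW_THRESH,
    col_thresh: float = DEFAULT_COL_THRESH,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-5,
    min_gains: int = 99,
    max_shuffles: int = 100,
) -> np.ndarray:
    """Coherence gains of biclusters extracted from association-free data.

    Each row of V is permuted independently (preserving every CpG's marginal
    distribution while destroying all row-column association), the full
    extraction — NMF at every rank plus membership thresholding — is re-run,
    and the coherence gains of the resulting biclusters are pooled.  This is
    the proper reference for an observed gain: it carries the same selection
    effect (rows and columns co-chosen to fit the same fluctuations) that a
    random-submatrix null ignores.

    At least ``n_shuffles`` shuffled copies are analysed; if they yield fewer
    than ``min_gains`` biclusters (the add-one permutation p cannot resolve
    small significance levels on a thin null), more shuffles are drawn up to
    ``max_shuffles``.
    """
    rng = np.random.default_rng(seed)
    n, m = V.shape
    dummy_rows = [str(i) for i in range(n)]
    dummy_cols = [str(j) for j in range(m)]
    gains: list[float] = []
    done = 0
    while done < n_shuffles or (len(gains) < min_gains and done < max_shuffles):
        Vs = V.copy()
        for i in range(n):
            Vs[i] = Vs[i, rng.permutation(m)]
        for rank in ranks:
            fr = nmf_factorize(
                Vs, rank, seed=int(rng.integers(2**31)), max_iter=max_iter, tol=tol
            )
            for b in extract_biclusters(
                fr, dummy_rows, dummy_cols, V=Vs,
                row_thresh=row_thresh, col_thresh=col_thresh,
            ):
                gains.append(b.coherence_gain)
        done += 1
    if len(gains) < min_gains:
        logger.warning(
            "selection null yielded only %d gains after %d shuffles; "
            "small p-values may be unattainable", len(gains), done,
        )
    return np.asarray(gains, dtype=float)


def _best_match_p(ref: Bicluster, others: list[Bicluster], universe: list[str]) -> float:
    """Best (smallest) CpG-set hypergeometric match p against a run's biclusters.

    Ties break toward the larger overlap, then lexicographically smallest
    CpG set.
    """
    best: tuple[float, int, tuple[str, ...]] | None = None
    ref_set = set(ref.cpg_ids)
    for b in others:
        p = hypergeometric_overlap_p(ref_set, b.cpg_ids, universe)
        key = (p, -len(ref_set & set(b.cpg_ids)), tuple(sorted(b.cpg_ids)))
        if best is None or key < best:
            best = key
    return best[0] if best is not None else 1.0


def derive_run_seeds(master_seed: int, ranks, n_seeds: int) -> dict[tuple[int, int], int]:
    """Deterministic per-(rank, replicate) NMF seeds below 2**31."""
    seeds: dict[tuple[int, int], int] = {}
    for rank in sorted(ranks):
        for s in range(n_seeds):
            ss = np.random.SeedSequence([int(master_seed), int(rank), int(s)])
            seeds[(rank, s)] = int(ss.generate_state(1)[0] % (2**31))
    return seeds


def consensus_biclustering(
    V: np.ndarray,
    cpg_ids: list[str],
    sample_ids: list[str],
    ranks=DEFAULT_RANKS,
    seeds: int = DEFAULT_SEEDS,
    row_thresh: float = DEFAULT_ROW_THRESH,
    col_thresh: float = DEFAULT_COL_THRESH,
    alpha: float = DEFAULT_ALPHA,
    support_min: float = DEFAULT_SUPPORT_MIN,
    n_perm: int = DEFAULT_N_PERM,
    master_seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-5,
    n_null_shuffles: int = 10,
) -> tuple[list[Bicluster], SignificantSet]:
    """Multi-rank consensus biclustering with significance filtering.

    Runs the factorization for every (rank, seed) pair; the biclusters from
    each rank's first run serve as reference biclusters, scored for consensus
    support against all other runs and for coherence gain against biclusters
    extracted from ``n_null_shuffles`` row-shuffled copies of V (the
    selection-aware null; this p is the verdict's ``p_coherence``).  The
    simpler random-submatrix permutation p with ``n_perm`` draws is recorded
    per bicluster as ``p_submatrix`` for reference but does not enter the
    verdict, because it ignores the selection effect of the extraction and
    is anti-conservative on association-free data.  Returns the scored
    reference biclusters and the union significant set.  Fully deterministic
    given ``master_seed``.
    """
    ranks = sorted(set(int(r) for r in ranks))
    if not ranks:
        raise ValueError("ranks must be non-empty")
    if seeds < 2:
        raise ValueError("need at least 2 seeds for consensus")
    V = np.asarray(V, dtype=float)
    run_seeds = derive_run_seeds(master_seed, ranks, seeds)

    runs: dict[tuple[int, int], list[Bicluster]] = {}
    for (rank, s), seed in run_seeds.items():
        fr = nmf_factorize(V, rank, seed=seed, max_iter=max_iter, tol=tol)
        runs[(rank, s)] = extract_biclusters(
            fr, cpg_ids, sample_ids, V=V, row_thresh=row_thresh, col_thresh=col_thresh
        )

    perm_rng = np.random.SeedSequence([int(master_seed), 0xC0FFEE])
    perm_seeds = iter(int(x % (2**31)) for x in perm_rng.generate_state(4096))

    null_gains = selection_null_gains(
        V,
        ranks,
        n_shuffles=n_null_shuffles,
        row_thresh=row_thresh,
        col_thresh=col_thresh,
        seed=next(perm_seeds),
        max_iter=max_iter,
        tol=tol,
    )

    references: list[Bicluster] = []
    for rank in ranks:
        references.extend(runs[(rank, 0)])

    for ref in references:
        match_ps: list[float] = []
        n_support = 0
        for key, bics in runs.items():
            if key == (ref.rank, 0):
                continue
            p = _best_match_p(ref, bics, cpg_ids)
            match_ps.append(p)
            if p <= alpha:
                n_support += 1
        n_other = max(len(runs) - 1, 1)
        ref.consensus_support = n_support / n_other
        ref.p_consensus = float(np.median(match_ps)) if match_ps else 1.0
        ref.p_coherence = float(
            (1 + np.sum(null_gains >= ref.coherence_gain)) / (null_gains.size + 1)
        )
        ref.p_submatrix = coherence_permutation_p(
            ref, V, n_perm=n_perm, seed=next(perm_seeds)
        )
        ref.significant = (
            ref.p_consensus <= alpha
            and ref.p_coherence <= alpha
            and ref.consensus_support >= support_min
        )

    sig = [b for b in references if b.significant]
    if not references:
        logger.warning("no non-empty biclusters extracted; significant set is empty")
    cpg_order = {c: i for i, c in enumerate(cpg_ids)}
    samp_order = {s: i for i, s in enumerate(sample_ids)}
    sig_cpgs = sorted({c for b in sig for c in b.cpg_ids}, key=cpg_order.__getitem__)
    sig_samples = sorted(
        {s for b in sig for s in b.sample_ids}, key=samp_order.__getitem__
    )
    return references, SignificantSet(cpgs=sig_cpgs, samples=sig_samples)
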