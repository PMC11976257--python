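"""Downstream cohort statistics: rank tests, enrichment, mitotic clock.

Continuous covariates are compared across methylation patterns with pairwise
two-sided Wilcoxon rank-sum tests under Bonferroni correction (family = all
pairs actually tested).  Categorical enrichment uses Fisher's exact test
with a Haldane–Anscombe corrected odds ratio when a cell is zero.  The
epiCMIT-style mitotic-clock score is the maximum of a hypermethylation
component (mean beta over a hyper CpG list) and a hypomethylation component
(mean 1 - beta over a hypo list).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import BetaMatrix

logger = logging.getLogger(__name__)

_EXACT_MAX_N = 10  # exact rank-sum enumeration when both groups at most this


@dataclass
class AssociationResult:
    comparison: tuple[str, str]
    statistic: float
    p_raw: float
    p_adjusted: float
    m: int
    method: str
    odds_ratio: float | None = None
    ci95: tuple[float, float] | None = None


@dataclass
class EpiCMITScore:
    hyper_component: float | None
    hypo_component: float | None

    @property
    def score(self) -> float:
        parts = [c for c in (self.hyper_component, self.hypo_component) if c is not None]
        return max(parts)


def bonferroni_adjust(p_list) -> list[float]:
    """min(1, m * p) for each p, with m the family size (list length)."""
    p = np.asarray(list(p_list), dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, len(p) * p).tolist()


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return len(np.unique(pooled)) < len(pooled)


def pairwise_wilcoxon(values, groups, adjust: bool = True) -> list[AssociationResult]:
    """Two-sided Wilcoxon rank-sum test for every unordered group pair.

    Exact null enumeration when both groups have <= 10 observations and no
    ties; otherwise the normal approximation with tie and continuity
    correction.  Groups with fewer than 2 observations are skipped with a
    warning.  Bonferroni family size is the number of pairs actually tested.
    """
    s = pd.Series(np.asarray(values, dtype=float), index=None)
    g = pd.Series(groups).astype(str).reset_index(drop=True)
    s = s.reset_index(drop=True)
    ok = s.notna() & g.notna()
    s, g = s[ok], g[ok]
    by_group = {lvl: s[g == lvl].to_numpy() for lvl in sorted(g.unique())}
    if len(by_group) < 2:
        raise ValueError("need at least 2 groups")
    usable = {}
    for lvl, arr in by_group.items():
        if len(arr) < 2:
            logger.warning("group %r has <2 observations; skipped", lvl)
        else:
            usable[lvl] = arr
    pairs = list(combinations(sorted(usable), 2))
    results: list[AssociationResult] = []
    for a, b in pairs:
        x, y = usable[a], usable[b]
        exact = len(x) <= _EXACT_MAX_N and len(y) <= _EXACT_MAX_N and not _has_ties(x, y)
        if exact:
            res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            method = "wilcoxon_exact"
        else:
            res = sps.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=True
            )
            method = "wilcoxon_normal"
        results.append(
            AssociationResult(
                comparison=(a, b),
                statistic=float(res.statistic),
                p_raw=float(res.pvalue),
                p_adjusted=float("nan"),
                m=len(pairs),
                method=method,
            )
        )
    adj = bonferroni_adjust([r.p_raw for r in results]) if adjust else [r.p_raw for r in results]
    for r, p in zip(results, adj):
        r.p_adjusted = p
    return results


def fisher_enrichment(table, haldane: bool = True) -> AssociationResult:
    """Two-sided Fisher exact test with (optionally) Haldane-corrected OR.

    ``table`` is a 2x2 of nonnegative integer counts [[a, b], [c, d]].  The
    odds ratio is a*d / (b*c); when ``haldane`` and any cell is zero, 0.5 is
    added to every cell first (Haldane–Anscombe).  The 95% CI uses the
    log-OR normal approximation on the (corrected) cells.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("counts must be nonnegative integers")
    _, p = sps.fisher_exact(t.astype(int), alternative="two-sided")
    a, b, c, d = t.ravel()
    corrected = t.ravel()
    if np.any(t == 0):
        if haldane:
            corrected = t.ravel() + 0.5
            a, b, c, d = corrected
            odds = (a * d) / (b * c)
        else:
            odds = math.inf if a * d > 0 else (0.0 if b * c > 0 else math.nan)
            corrected = t.ravel() + 0.5  # CI always needs positive cells
    else:
        odds = (a * d) / (b * c)
    ca, cb, cc, cd = corrected
    se = math.sqrt(1 / ca + 1 / cb + 1 / cc + 1 / cd)
    log_or = math.log((ca * cd) / (cb * cc))
    ci = (math.exp(log_or - 1.96 * se), math.exp(log_or + 1.96 * se))
    return AssociationResult(
        comparison=("exposed", "reference"),
        statistic=float(odds) if np.isfinite(odds) else odds,
        p_raw=float(p),
        p_adjusted=float(p),
        m=1,
        method="fisher_exact",
        odds_ratio=odds,
        ci95=ci,
    )


def pattern_enrichment(
    pattern_of_sample: dict[str, str],
    annotation_column: pd.Series,
    haldane: bool = True,
) -> list[AssociationResult]:
    """One-vs-rest Fisher enrichment of each annotation level in each pattern.

    Samples with the unknown level are excluded row-wise.  Bonferroni family
    is all (pattern, level) tables tested.
    """
    pat = pd.Series(pattern_of_sample)
    lev = annotation_column.reindex(pat.index).astype("string")
    keep = lev.notna() & (lev != "unknown")
    pat, lev = pat[keep], lev[keep]
    results: list[AssociationResult] = []
    for p in sorted(pat.unique()):
        for l in sorted(lev.unique()):
            in_p = pat == p
            has_l = lev == l
            tab = [
                [int((in_p & has_l).sum()), int((in_p & ~has_l).sum())],
                [int((~in_p & has_l).sum()), int((~in_p & ~has_l).sum())],
            ]
            r = fisher_enrichment(tab, haldane=haldane)
            r.comparison = (p, str(l))
            results.append(r)
    m = len(results)
    adj = bonferroni_adjust([r.p_raw for r in results])
    for r, padj in zip(results, adj):
        r.p_adjusted = padj
        r.m = m
    return results


def epicmit_score(sample_betas: pd.Series, hyper_list, hypo_list) -> EpiCMITScore:
    """Mitotic-clock score: max of hyper- and hypomethylation components.

    ``hyper_component`` is the mean beta over the hypermethylation CpG list,
    ``hypo_component`` the mean of 1 - beta over the hypomethylation list.
    CpGs absent from ``sample_betas`` are dropped with a warning; a list that
    is entirely absent leaves its component undefined.
    """
    betas = pd.Series(sample_betas, dtype=float)

    def component(ids, transform):
        ids = list(ids)
        present = [c for c in ids if c in betas.index]
        if len(present) < len(ids):
            logger.warning("%d clock CpG(s) missing from sample", len(ids) - len(present))
        if not present:
            return None
        vals = betas.loc[present].dropna()
        if vals.empty:
            return None
        return float(transform(vals).mean())

    hyper = component(hyper_list, lambda v: v)
    hypo = component(hypo_list, lambda v: 1.0 - v)
    if hyper is None and hypo is None:
        raise ValueError("no clock CpGs present in the sample")
    return EpiCMITScore(hyper_component=hyper, hypo_component=hypo)


def epicmit_table(matrix: BetaMatrix, hyper_list, hypo_list) -> pd.DataFrame:
    """Per-sample mitotic-clock components and score."""
    rows = []
    for s in matrix.sample_ids:
        sc = epicmit_score(matrix.values[s], hyper_list, hypo_list)
        rows.append((s, sc.hyper_component, sc.hypo_component, sc.score))
    return pd.DataFrame(
        rows, columns=["sample_id", "hyper", "hypo", "score"]
    ).set_index("sample_id")


def group_beta_summary(matrix: BetaMatrix, cpg_subset, groups) -> pd.DataFrame:
    """Per-group median and range of per-sample median beta over a CpG subset.

    Mirrors cohort summaries of the form "median [range] beta-value" for a
    module within a pattern.
    """
    cpg_subset = list(cpg_subset)
    if not cpg_subset:
        raise ValueError("empty CpG subset")
    sub = matrix.subset_cpgs(cpg_subset)
    per_sample = sub.values.median(axis=0)
    if isinstance(groups, (dict, pd.Series)):
        g = pd.Series(groups).reindex(per_sample.index)
    else:
        g = pd.Series(list(groups), index=per_sample.index)
    out = per_sample.groupby(g).agg(["median", "min", "max"])
    out.columns = ["median", "low", "high"]
    out.index.name = "group"
    return out
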