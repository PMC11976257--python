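"""Synthetic methylation cohorts with planted module x pattern structure.

The generator emulates the geometry of a germinal-center B-cell lymphoma
methylation cohort: a minority of CpGs carry subgroup structure, organised
into latent CpG modules whose tumor-intrinsic mean beta depends on the
sample's latent methylation pattern.  Each specimen is a mixture of tumor and
non-tumor bystander cells, so the observed expectation is the tumor mean
diluted toward a common bystander profile in proportion to one minus the
tumor cell content (TCC).  Measurement noise is beta-distributed, which
respects the [0, 1] support and the mean-variance behaviour of array betas.

Defaults plant 4 modules x 7 patterns in 180 samples x 5,000 CpGs with 10%
structured CpGs, mirroring the discovered cohort geometry at desk scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BetaMatrix, SampleAnnotation

__all__ = [
    "SyntheticTruth",
    "simulate_cohort",
    "mix_tumor_bystander",
    "epicmit_reference_lists",
]

# Default cohort geometry.
DEFAULT_N_CPGS = 5000
DEFAULT_N_SAMPLES = 180
DEFAULT_N_MODULES = 4
DEFAULT_N_PATTERNS = 7
DEFAULT_FRAC_STRUCTURED = 0.10
DEFAULT_TCC_RANGE = (0.6, 1.0)
DEFAULT_PRECISION = 50.0
DEFAULT_MIN_SEPARATION = 0.25

_EPS = 1e-6


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort, for recovery testing.

    ``module_of_cpg`` maps each CpG to a module index 1..M, 0 for nuisance
    CpGs without pattern structure.  ``mu`` is the M x P tumor-intrinsic mean
    beta per (module, pattern).
    """

    module_of_cpg: dict[str, int]
    pattern_of_sample: dict[str, int]
    mu: np.ndarray
    bystander_profile: dict[str, float]
    tcc_of_sample: dict[str, float]
    precision: float
    seed: int
    min_separation: float = DEFAULT_MIN_SEPARATION

    def structured_cpgs(self) -> list[str]:
        return [c for c, m in self.module_of_cpg.items() if m > 0]

    def to_json(self, path) -> None:
        payload = {
            "module_of_cpg": self.module_of_cpg,
            "pattern_of_sample": self.pattern_of_sample,
            "mu": self.mu.tolist(),
            "bystander_profile": self.bystander_profile,
            "tcc_of_sample": self.tcc_of_sample,
            "precision": self.precision,
            "seed": self.seed,
            "min_separation": self.min_separation,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            module_of_cpg={k: int(v) for k, v in d["module_of_cpg"].items()},
            pattern_of_sample={k: int(v) for k, v in d["pattern_of_sample"].items()},
            mu=np.asarray(d["mu"], dtype=float),
            bystander_profile=d["bystander_profile"],
            tcc_of_sample=d["tcc_of_sample"],
            precision=float(d["precision"]),
            seed=int(d["seed"]),
            min_separation=float(d.get("min_separation", DEFAULT_MIN_SEPARATION)),
        )


def mix_tumor_bystander(beta_tumor: float, beta_bystander: float, tcc: float) -> float:
    """Expected observed beta of a tumor/bystander cell mixture.

    ``tcc * beta_tumor + (1 - tcc) * beta_bystander``; all arguments must lie
    in [0, 1].
    """
    for name, v in (
        ("beta_tumor", beta_tumor),
        ("beta_bystander", beta_bystander),
        ("tcc", tcc),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0,1]")
    return tcc * beta_tumor + (1.0 - tcc) * beta_bystander


def _draw_mu(
    rng: np.random.Generator,
    n_modules: int,
    n_patterns: int,
    min_separation: float,
    max_tries: int = 10_000,
) -> np.ndarray:
    """Draw a module x pattern mean matrix with guaranteed pattern contrast.

    Rejection-samples until every pattern pair differs by at least
    ``min_separation`` in at least one module, so no two planted patterns are
    indistinguishable in expectation.
    """
    for _ in range(max_tries):
        mu = rng.uniform(0.05, 0.95, size=(n_modules, n_patterns))
        diffs = np.abs(mu[:, :, None] - mu[:, None, :]).max(axis=0)
        iu = np.triu_indices(n_patterns, k=1)
        if diffs[iu].min() >= min_separation:
            return mu
    raise RuntimeError(
        f"could not draw mu with separation {min_separation} in {max_tries} tries"
    )


def _beta_noise(rng: np.random.Generator, mean: np.ndarray, s: float) -> np.ndarray:
    m = np.clip(mean, _EPS, 1.0 - _EPS)
    return rng.beta(m * s, (1.0 - m) * s)


def simulate_cohort(
    n_cpgs: int = DEFAULT_N_CPGS,
    n_samples: int = DEFAULT_N_SAMPLES,
    n_modules: int = DEFAULT_N_MODULES,
    n_patterns: int = DEFAULT_N_PATTERNS,
    frac_structured: float = DEFAULT_FRAC_STRUCTURED,
    tcc_range: tuple[float, float] = DEFAULT_TCC_RANGE,
    precision: float = DEFAULT_PRECISION,
    seed: int = 0,
    min_separation: float = DEFAULT_MIN_SEPARATION,
) -> tuple[BetaMatrix, SampleAnnotation, SyntheticTruth]:
    """Simulate a beta-value cohort with planted biclusters.

    For a structured CpG i in module m and a sample j in pattern p with tumor
    fraction t_j, the expected beta is ``t_j * mu[m, p] + (1 - t_j) *
    bystander[i]`` and the observation is Beta-distributed around it with
    concentration ``precision``.  Nuisance CpGs use a pattern-independent
    tumor mean.  Fully reproducible given ``seed``.
    """
    if n_modules < 1 or n_patterns < 1:
        raise ValueError("n_modules and n_patterns must be >= 1")
    if not 0.0 < frac_structured <= 1.0:
        raise ValueError("frac_structured must be in (0, 1]")
    if n_patterns > n_samples:
        raise ValueError(f"n_patterns={n_patterns} exceeds n_samples={n_samples}")
    lo, hi = tcc_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError(f"degenerate tcc_range {tcc_range}")
    if precision <= 0:
        raise ValueError("precision must be > 0")

    rng = np.random.default_rng(seed)
    cpg_ids = [f"cg{i:06d}" for i in range(n_cpgs)]
    sample_ids = [f"S{j:04d}" for j in range(n_samples)]

    # Module assignment: first n_structured CpGs split evenly across modules,
    # then shuffled so structure is not positional.
    n_structured = max(n_modules, int(round(frac_structured * n_cpgs)))
    modules = np.zeros(n_cpgs, dtype=int)
    modules[:n_structured] = (np.arange(n_structured) % n_modules) + 1
    rng.shuffle(modules)

    # Pattern assignment: balanced then shuffled, so every pattern is occupied.
    patterns = (np.arange(n_samples) % n_patterns) + 1
    rng.shuffle(patterns)

    mu = _draw_mu(rng, n_modules, n_patterns, min_separation)

    # Bystander profile: modules emulating the low-methylated normal-B-cell
    # modules get a low target; the last module a high one (the M4 analog);
    # nuisance CpGs span the full range.
    bystander = np.empty(n_cpgs)
    is_nuisance = modules == 0
    bystander[is_nuisance] = rng.uniform(0.05, 0.95, size=int(is_nuisance.sum()))
    for m in range(1, n_modules + 1):
        idx = modules == m
        target = 0.85 if m == n_modules else 0.07
        bystander[idx] = np.clip(
            rng.normal(target, 0.03, size=int(idx.sum())), 0.01, 0.99
        )

    tcc = rng.uniform(lo, hi, size=n_samples) if hi > lo else np.full(n_samples, lo)

    # Tumor-intrinsic mean per (CpG, sample).  Nuisance CpGs are methylated
    # identically in tumor and bystander cells (their mean equals the
    # bystander value), so they carry neither pattern nor tumor-content
    # signal — only measurement noise.
    tumor_mean = np.empty((n_cpgs, n_samples))
    tumor_mean[is_nuisance, :] = bystander[is_nuisance, None]
    for m in range(1, n_modules + 1):
        idx = modules == m
        tumor_mean[idx, :] = mu[m - 1, patterns - 1][None, :]

    mean = tcc[None, :] * tumor_mean + (1.0 - tcc)[None, :] * bystander[:, None]
    betas = _beta_noise(rng, mean, precision)

    matrix = BetaMatrix(pd.DataFrame(betas, index=cpg_ids, columns=sample_ids))
    truth = SyntheticTruth(
        module_of_cpg=dict(zip(cpg_ids, modules.tolist())),
        pattern_of_sample=dict(zip(sample_ids, patterns.tolist())),
        mu=mu,
        bystander_profile=dict(zip(cpg_ids, bystander.tolist())),
        tcc_of_sample=dict(zip(sample_ids, tcc.tolist())),
        precision=precision,
        seed=seed,
        min_separation=min_separation,
    )
    annotation = _simulate_annotation(rng, sample_ids, patterns, tcc, n_patterns)
    return matrix, annotation, truth


def _simulate_annotation(
    rng: np.random.Generator,
    sample_ids: list[str],
    patterns: np.ndarray,
    tcc: np.ndarray,
    n_patterns: int,
) -> SampleAnnotation:
    """Clinical covariates correlated with the planted patterns.

    Low-numbered patterns lean FL / GCB / BCL2-rearranged and younger, high
    ones DLBCL / ABC and older — a caricature of the real cohort sufficient
    to exercise the downstream association statistics.
    """
    n = len(sample_ids)
    frac = (patterns - 1) / max(n_patterns - 1, 1)  # 0 = FL-like, 1 = ABC-like
    p_dlbcl = 0.15 + 0.7 * frac
    u = rng.uniform(size=n)
    diagnosis = np.where(u < p_dlbcl, "DLBCL", "FL").astype(object)
    diagnosis[(u >= p_dlbcl) & (u < p_dlbcl + 0.08)] = "FL-DLBCL"
    coo = np.where(rng.uniform(size=n) < 0.2 + 0.6 * frac, "ABC", "GCB")
    bcl2 = np.where(rng.uniform(size=n) < 0.9 - 0.7 * frac, "yes", "no")
    bcl6 = np.where(rng.uniform(size=n) < 0.3, "yes", "no")
    age = np.clip(rng.normal(55 + 15 * frac, 8), 20, 95).round(1)
    mut_cluster = np.where(frac > 0.7, "MYD88-like", np.where(frac < 0.3, "BCL2-like", "mixed"))
    df = pd.DataFrame(
        {
            "diagnosis": diagnosis,
            "coo": coo,
            "age": age,
            "bcl2_rearranged": bcl2,
            "bcl6_rearranged": bcl6,
            "tcc": np.round(tcc, 4),
            "mutational_cluster": mut_cluster,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return SampleAnnotation(df)


def epicmit_reference_lists(truth: SyntheticTruth) -> tuple[list[str], list[str]]:
    """Synthetic hyper-/hypomethylation CpG lists keyed to planted truth.

    Stands in for the published mitotic-clock CpG lists (external data, not
    shipped): the hypermethylation list is the low-bystander structured
    modules, the hypomethylation list the high-bystander module, so the score
    responds to planted methylation gain and loss respectively.
    """
    n_modules = int(max(truth.module_of_cpg.values()))
    hyper = [c for c, m in truth.module_of_cpg.items() if 0 < m < n_modules]
    hypo = [c for c, m in truth.module_of_cpg.items() if m == n_modules]
    return hyper, hypo
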