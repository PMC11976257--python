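# Methods

`methpattern` subtypes DNA methylation array cohorts by fuzzy non-negative
matrix factorization (NMF) biclustering. This note records the model, the
defaults and why they are what they are, what the synthetic cohorts do and do
not emulate, and the numerical choices a maintainer would want to know.

## The analysis, stage by stage

**Input.** A CpG × sample matrix of beta values (methylation fractions in
[0, 1]) and a per-sample annotation table. Beta values — not M-values — are
the working scale throughout, matching how cohort summaries are reported
("median [range] beta-value"). Missing betas are mean-imputed per CpG, which
leaves per-CpG location statistics unchanged; CpGs with more than 20% missing
entries are dropped with a logged count.

**Feature reduction.** The `top_k` (default 10,000) most variable CpGs by
sample standard deviation (denominator n−1, ties to the earlier row) are
clustered by k-means into `n_clusters` (default 1,000) clusters of beta
profiles, and `target_reps` (default 1,938) representative CpGs are kept:
each cluster's medoid, plus the members next-closest to their centroid,
allocated proportionally to cluster size by largest remainder. One medoid per
cluster guarantees coverage; the proportional extras let the stage hit an
arbitrary representative count. Profiles are clustered raw (no row
standardization): the methylation level itself is the signal.

**Fuzzy NMF biclustering.** The representative matrix V is factorized as
V ≈ WH at every rank in `ranks` (default 3–10) for `n_seeds` (default 5)
random restarts each, with multiplicative updates minimizing squared
Frobenius error. A CpG's fuzzy membership in factor f is its normalized
loading W[i,f]/Σ_g W[i,g] (zero rows get membership 0, so uninformative
probes never enter a bicluster); sample memberships are defined analogously
on H columns. Factor f's bicluster is the set of CpGs with membership ≥
`row_thresh` (default 0.5, absolute) and samples with membership ≥
2·`col_thresh`/rank (default: the uniform share 1/rank).

The two member rules deliberately live on different scales. A structured
CpG's loading concentrates on one or two factors at any rank (its profile
*is* a module pattern), so an absolute cut is meaningful and separates
structured from background probes. A sample's profile is a mixture of every
module's factor, so its memberships concentrate near 1/rank and an absolute
cut empties all biclusters from rank ≈ 5 on; the rank-relative cut keeps the
sample rule meaningful across the sweep and coincides with the absolute
value at rank 2.

**Significance.** A reference bicluster (from each rank's first restart) is
significant iff all three hold:

1. *Consensus*: in at least `support_min` (default 0.5) of all other
   (rank, restart) runs there is a bicluster whose CpG set matches the
   reference's at upper-tail hypergeometric p ≤ `alpha` (default 0.01), and
   the median match p is ≤ alpha. Matching uses CpG sets only — CpG modules
   are the durable output; sample sets are re-derived downstream.
2. *Coherence gain*: the member CpGs must be tighter (lower mean absolute
   deviation from their row-mean profile) on the member samples than on the
   cohort at large. The gain is calibrated against a **selection-aware
   null**: the same NMF + thresholding pipeline is re-run on copies of V
   whose rows are each permuted independently (all row-column association
   destroyed, all marginals kept), and the observed gain must exceed the
   pooled null gains at p ≤ alpha (add-one permutation rule). At least 10
   shuffled copies are analysed, more (up to 100) if they yield fewer than
   99 null biclusters, so the add-one p can resolve alpha.

Two simpler alternatives were evaluated and rejected on synthetic cohorts
with known truth. Scoring raw submatrix coherence selects exactly the wrong
biclusters: factors collecting flat background CpGs look maximally "tight",
while genuine module biclusters, whose members span several patterns, look
loose. And comparing against *random* same-shaped submatrices is
anti-conservative (measured 14% of null biclusters flagged at alpha = 0.01)
because NMF co-selects rows and columns that fit the same noise
fluctuations — an effect only a null that re-runs the selection can carry.
The random-submatrix permutation p is still computed and reported per
bicluster (`p_submatrix`) for reference.

The significant set is the union of CpGs and samples over significant
biclusters.

**Modules and patterns.** Significant CpGs are k-means clustered into
`k_mod` modules (default 4) on their beta profiles; all cohort samples into
`k_pat` patterns (default 7) on their profiles over the significant CpGs.
The defaults transcribe the discovered geometry of the motivating cohort; no
automatic k selection is performed, but silhouette scores are reported as
advisory output. Labels follow a deterministic convention: modules M1..Mk by
ascending module median beta, patterns MP1..MPk likewise, so identical
partitions always receive identical names regardless of input order.

**Embedding.** A 2-D UMAP of samples over the significant CpGs (Manhattan
distance, 15 neighbors, `min_dist` 0.1, fixed seed). External cohorts
measured on the same CpG basis are projected with the fitted model's
transform — the training coordinates are never refitted — which keeps
validation-cohort placement reproducible. The CpG basis is stored sorted, so
the embedding is invariant to input row order. The persisted model archive
is plain text (parameters, the training matrix at full float precision, and
the coordinates); loading refits deterministically from the stored seed.

**Statistics.** Continuous covariates are compared across patterns with
two-sided Wilcoxon rank-sum tests for every unordered pair (exact
enumeration when both groups ≤ 10 without ties, otherwise the normal
approximation with tie and continuity correction), Bonferroni-corrected with
the family = pairs actually tested. Categorical enrichment uses Fisher's
exact test per (pattern, level) one-vs-rest table with a Haldane–Anscombe
(+0.5) corrected odds ratio whenever a cell is zero — zero cells are routine
in small patterns — and a log-OR normal 95% CI; samples at the unknown level
are excluded row-wise. The mitotic-clock score is
max(mean beta over a hypermethylation CpG list, mean (1−beta) over a
hypomethylation list); the published clock lists are external configuration,
and a synthetic list generator keyed to planted truth supports testing.

## The synthetic cohort generator

The generator is the ground-truth instrument for every downstream stage. It
plants `n_modules` × `n_patterns` structure (default 4 × 7) in
`frac_structured` (default 10%) of `n_cpgs` (default 5,000) CpGs across
`n_samples` (default 180) samples:

- the module × pattern mean matrix `mu` is drawn uniform on [0.05, 0.95],
  rejection-sampled until every pattern pair differs by ≥ 0.25 in at least
  one module, so no two planted patterns coincide in expectation;
- each sample is a tumor/bystander mixture: expected beta =
  tcc·mu[m,p] + (1−tcc)·bystander, with per-sample tumor cell content
  uniform on [0.6, 1.0] and a per-CpG bystander profile that is low (≈0.07)
  for all structured modules except the last, which is high (≈0.85) — the
  analog of normal-B-cell methylation being low in the variable modules and
  high in the last;
- observations are Beta-distributed around their expectation with
  concentration s = 50 (α = μs, β = (1−μ)s), respecting the [0, 1] support
  and array-like mean-variance behaviour;
- nuisance CpGs are methylated identically in tumor and bystander cells, so
  they carry measurement noise only. This matters: had nuisance CpGs a
  tumor-intrinsic level different from their bystander level, tumor-content
  dilution would correlate *all* of them with TCC, creating a genuine
  background bicluster that no honest significance test rejects — a
  tumor-informative but pattern-uninformative class the generator
  deliberately omits.

The generator does **not** emulate copy-number effects on beta, probe
cross-hybridization, batch effects, within-pattern biological heterogeneity
beyond TCC dilution, or correlated noise between neighbouring probes.
Passing recovery tests therefore show the machinery works when subgroups are
real, separated by ≥ 0.25 somewhere, and noise is independent per probe —
not that real lymphoma cohorts satisfy those conditions. Dispersion and
separation defaults are calibration choices of this package.

The simulated annotation correlates diagnosis, cell of origin, BCL2/BCL6
rearrangement, age and a mutational-cluster label with the planted pattern
index (low-numbered patterns lean FL/GCB/BCL2-rearranged, high ones
DLBCL/ABC), so the association statistics have signal to find.

## Numerical choices

- NMF: uniform (0, 1] initialization scaled by mean(V); multiplicative
  updates with denominator floor 1e-12; stop at `max_iter` (default 200) or
  relative error change < `tol` (1e-5). The error trace is monotonically
  non-increasing (guaranteed by the update rule; asserted in tests to
  1e-10).
- k-means everywhere: k-means++ init, `n_init` restarts (10 by default, best
  inertia kept), max_iter 300, tol 1e-4, seeded.
- Seeds: one master seed per pipeline run; per-stage seeds derive from it by
  stage-name-keyed seed sequences (all below 2³¹), so any stage re-runs in
  isolation with identical results. Rerunning with the same config and
  master seed reproduces every artifact byte-for-byte; wall-clock timings
  and filesystem paths live in a separate `timings.json`.
- Tie-breaks: top-variable selection and medoid choice prefer the earlier
  input row; consensus matching prefers smaller p, then larger overlap, then
  lexicographic CpG set.
- Degenerate inputs: constant matrices produce no biclusters (memberships
  are uniform, below any positive threshold) and permutation p = 1;
  an empty significant set skips the downstream stages with a warning
  rather than failing.

## Problem sizes in the shipped tests

The recovery tests run the default cohort (5,000 × 180) end-to-end — about a
minute on one CPU — and assert pattern ARI ≥ 0.8 and structured-CpG F1 ≥ 0.9.
F1 is measured on the representative-CpG universe: the 1,000-cluster /
1,938-representative compression by design retains only part of each
structured module (a module's CpGs are mutually similar and collapse into
few clusters, which cap their representative count), so recovery against
*all* planted CpGs is bounded near 0.5 for any downstream method; what the
biclustering stage can and should be scored on is the CpGs it was shown.
Size control runs 20 structure-free cohorts of 600 × 80 (each row of a
simulated cohort permuted independently) and requires the significant
fraction ≤ 2·alpha. Oracle-equivalence tests (exact Wilcoxon, hypergeometric
overlap, Fisher, k-means) enumerate instances small enough for brute force.

## Known limitations

- The rank sweep, membership thresholds, alpha, support threshold and
  permutation depth are reproducible defaults realizing "fuzzy NMF
  biclustering with significance"; the significant-set size on any real
  cohort is sensitive to them.
- Consensus support measures optimizer stability across restarts and ranks;
  on its own it is not a significance statement (restarts on the *same*
  matrix converge to similar optima even on noise), which is why the
  selection-aware coherence test carries the size control.
- UMAP axis orientation and geometry are seed-dependent; only
  neighborhood-level statements (within- vs between-pattern distances,
  projection into the right pattern's region) are stable and only those are
  tested.
- With fewer samples than `n_neighbors` + 1 the embedding stage is skipped;
  with an empty significant set all downstream stages are skipped with a
  warning.
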