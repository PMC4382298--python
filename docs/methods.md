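# Methods

## Problem and model

`crsig` implements a meta-analysis procedure for detecting a
tissue-independent transcriptional response to a treatment (the motivating
case is caloric restriction, CR) across several independent two-group
microarray studies, and for quantifying how well that response is
conserved in a second group of studies (other species, other longevity
models).

The pipeline has four statistical layers.

**1. Per-study differential statistics.** Each study is a linear-scale
signal matrix (MAS5-style summarised intensities) with `control` and
`treated` samples. Per gene we compute the log2 fold change
`mean(log2 treated) − mean(log2 control)` and a two-sided Welch two-sample
t-test on log2 signals. Welch (unequal variances) is the conservative
default when the variance structure of the two diet groups is unknown.
Probe-level matrices are first collapsed to one row per gene: probes
without a gene annotation or annotated to several genes are discarded,
and among a gene's remaining probes the one with the largest mean
intensity across all arrays in the study is kept (ties broken by the
lexicographically smallest probe id, for determinism).

**2. PAGE gene-set Z-scores.** For a gene set with `m` members measured
in a study,

    Z = (Sm − μ) · √m / δ

where `Sm` is the member-mean log2 fold change and `μ`, `δ` the mean and
sample standard deviation (n−1 denominator; the n−1 choice is immaterial
at transcriptome scale but is fixed so exact oracle tests are possible)
of fold changes over all measured genes. Terms are filtered by ontology
depth (default levels 3–5; depth is consumed as supplied metadata — no
DAG traversal) and by *effective* set size, the number of members actually
measured in the study (default 10–1000), because different platforms
measure different gene subsets. Cells that fail the size filter are
explicit missing values, never 0 — 0 is a valid Z.

**3. Consensus signature.** For each term with Z-scores in at least
`min_studies` studies (default 2), a two-sided one-sample t-test of its
Z-scores against 0; Benjamini–Hochberg correction over exactly the tested
terms; a term passes when the adjusted p < 0.00285 **and** |median Z over
studies| ≥ 2.58. The median filter guarantees at least half of the
studies individually clear the per-study |Z| threshold. Both thresholds
are the screening convention of the procedure and are config-exposed.
A zero-variance Z row with non-zero mean is the strongest possible
cross-study pattern, so it receives p = 0 and a `degenerate` flag rather
than being dropped; a zero-variance zero-mean row carries no evidence and
is excluded. A parallel gene-level consensus reports genes significant
(p < 0.05) in a majority of studies (default ceil(5/8·n)) with a
consistent direction among the significant studies — consistency is not
required of non-significant studies, which may drift either way.

**4. Concordance.** Agreement between two study groups is the Spearman
correlation (Pearson on midranks) of their per-term median-Z vectors,
with four resampling schemes:

1. *permutation* — shuffle the term pairing; one-sided add-one Monte
   Carlo p = (1 + #{r* ≥ r_obs})/(n+1). The add-one estimator never
   returns 0 and has floor 1/(n+1) (0.001 at 999 resamples).
2. *pair bootstrap* — resample terms with replacement; percentile CI.
3. *model-based permutation* — terms in a GO-style collection share
   genes, which correlates their Z-scores even under the null and widens
   the null spread of r. The predicted null correlation is
   `overlap(i,j)/√(size_i·size_j)` — exactly the Gram matrix of the
   normalised set-indicator vectors, hence positive semidefinite for any
   genuine set system; the eigenvalue-clipping repair (clip at 1e-8,
   rescale to unit diagonal) only guards against floating-point rounding
   or externally supplied matrices. Each iteration draws two independent
   zero-mean Gaussian vectors with this covariance via its Cholesky
   factor and records their Spearman r; add-one one-sided p. Sizes are
   nominal annotation sizes within the analysed universe, since one
   matrix must serve both study groups.
4. *model-based bootstrap* — as 3, centred on the componentwise average
   of the two observed vectors; percentile CI. If both observed vectors
   are constant the observed r is undefined (recorded as NaN) and the
   scheme degenerates to the scheme-3 null.

One-sided alternatives (positive concordance) are the default because the
scientific hypothesis is conservation of the signature; a two-sided flag
is exposed. Terms missing in either vector are dropped pairwise,
identically in all four schemes, with the dropped count recorded.

## Synthetic compendium

Real CR compendia are not bundled, so the `simulate` module generates
multi-study data with known truth: per gene and study, log2 signal =
baseline (Normal(8, 1.5²) per gene/study — log-normal-like intensities on
the linear scale) + treatment shift + Normal(0, noise_sd²) noise,
anti-logged to linear scale. Default noise_sd = 0.25 log2 units and
effect_size = 0.5 log2 units (a 1.4-fold shift against ±19 % sample
noise) are calibration choices of what a well-powered tissue study looks
like, not estimates of any real dataset, which report no effect-size or
noise figures usable here. Default group sizes are 5 + 5, matching the
unpublished mouse datasets of the motivating study.

Gene sets are built from a shared pool: consecutive terms form designated
pairs sharing `round(overlap_fraction · min(size_i, size_j))` genes; all
other pairs are disjoint. This pairwise-only overlap structure is the
simplest one that exercises the overlap-correlation formula; real GO
hierarchies have richer (nested, transitive) overlap that the generator
does not emulate. Ontology depths are drawn uniformly from {3,4,5}
because depth is only a filter key downstream.

Signal terms are chosen as whole overlap components (pairs), each with
one shared direction. This is forced by the truth contract: a term with
direction 0 must contain no shifted gene in any study, so an overlapping
partner of a signal term cannot itself be null. Each signal component is
realised in `round(study_penetrance · n_studies)` randomly chosen studies
(pair partners together). All randomness flows from one generator per
top-level call, derived from the config seed and a stable stage label
(CRC-32 of the label mixed into a SeedSequence), so stages are
reproducible independently of execution order.

What passing tests on this generator do **not** show: robustness to
probe-level artifacts, platform batch effects, non-Gaussian noise,
correlated genes outside the set structure, or unequal group sizes —
real-data behaviour on those axes is out of the generator's reach.

## Numerical and design choices

- Fold changes, μ and δ are computed on the log2 scale throughout.
- BH runs over exactly the terms surviving the `min_studies` filter.
- Even-count medians use the mean-of-middle-two convention.
- Degenerate differential genes (zero variance in both groups): t = 0,
  p = 1 for equal means; p = 0 with a flag for unequal means.
- `spearman` raises on constant rank vectors rather than returning NaN;
  bootstrap resamples that hit this are redrawn and counted.
- The Cholesky factorisation adds a 1e-8 diagonal jitter so that exactly
  singular repaired matrices (e.g., duplicated terms) still factor.
- All file writes are atomic (temp file + rename); a crashed run never
  leaves a truncated primary output. Run manifests carry parameters,
  seed, and SHA-256 checksums of all inputs/outputs, and contain no
  timestamps, so reruns are byte-identical.

## Problem sizes used in the checks

The calibration and recovery checks run at 1,000 terms × 8 studies ×
20,000 genes (20 replicates for the null calibration), 5,000 null
simulations for the overlap-correlation validation at overlap ratios
{0, 0.25, 0.5, 1}, and 500 replicates × 199 simulations for the
scheme-3 calibration; these sizes give Monte Carlo error comfortably
inside the asserted bands while keeping a full run in minutes on one
core.

## Known limitations

- The Spearman comparison between a recovered median-Z vector and a
  two-valued (±1) truth-direction vector has an attainable ceiling of
  √(3·p·q) ≤ √3/2 ≈ 0.866 (p, q the direction proportions): against a
  binary vector, midrank Spearman is a point-biserial correlation on
  ranks. Values near 0.86 therefore indicate *perfect* direction
  separation; no threshold above the ceiling can be met by any method.
- The overlap model treats median-of-medians vectors as Gaussian with the
  single-study correlation structure; medians across n studies slightly
  dampen between-term correlation relative to the formula, making the
  model-based permutation marginally conservative (measured rejection
  ≈ 0.036 at nominal 0.05 in the shipped calibration check).
- The gene-level consensus assumes shared gene identifiers across
  studies; cross-species orthology mapping is upstream of this package.
- Per-study Z-scores are treated as exchangeable across tissues in the
  one-sample t-test; tissue-specific variance structure is ignored.
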