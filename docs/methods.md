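# Methods

This note records the statistical model behind `npcomb`, the numerical
choices made where the design was genuinely open, what the simulators do
and do not emulate, and the known limitations.

## The NPC model and its assumptions

The global null hypothesis — no modality is associated with the outcome —
is the conjunction of per-modality partial nulls.  The method assumes:

* samples are exchangeable under the null (the usual permutation-test
  requirement), so permuting the outcome vector generates the joint null
  distribution of all statistics at once;
* each partial statistic is oriented so larger values mean stronger
  evidence (the engines guarantee this: magnitudes for two-sided tests,
  signed statistics for one-sided);
* the combining function is convex and monotone in each partial p-value
  (Fisher, Liptak and Tippett all are).

Nothing is assumed about the dependence *between* modalities: because the
outcome is permuted identically across all datasets, whatever dependence
exists among measurements on shared samples is preserved in every
permuted replicate, and the pooled null distribution of the combined
statistic inherits it.  This is the entire mechanism by which NPC stays
calibrated on correlated datasets while classical meta-analysis
(independence-based chi-square reference for Fisher's combination,
independently permuted rank baselines) does not.

Datasets may cover only part of the sample universe: each modality reads
the permuted label of exactly its own samples from the shared assignment
table, so overlapping samples stay synchronized and disjoint remainders
contribute independent information.

## Pooling and the zero-avoidance correction

Permutation p-values are pooled over all B+1 statistics (observed row
included) self-inclusively:

    lambda_b = #{b' in 0..B : T_b' >= T_b} / (B + 1).

For b = 0 this is the +1/+1-corrected permutation p-value, bounded below
by 1/(B+1); a permutation p-value of exactly zero would otherwise wreck
FDR control after multiple-testing adjustment.  The same rule, applied to
all rows, produces the pseudo p-values fed to the combining function; the
symmetric, self-inclusive treatment makes pseudo and observed p-values
identically distributed under the null, which the combination step
requires.  The uncorrected variant (`zero_correction=False`) divides
exceedance counts over the B permutation rows only and is retained purely
as a comparison mode: its global p-values can reach zero and its small-p
mass is visibly inflated in the calibration harness.

Ties count as exceedances (conservative).  Tie detection uses a
floating-point tolerance (relative 1e-9, absolute 1e-12): mirrored label
assignments yield mathematically identical two-sided statistics that
differ in the last bits depending on the arithmetic path, and treating
them as distinct would make pooled counts platform-dependent.

Permutations are drawn uniformly with replacement from the permutation
group; when the group has at most B+1 distinct label assignments the full
set is enumerated instead (`exhaustive="auto"`), making the p-values
exact.  One seeded generator materializes the whole plan before any
statistic is computed, so modality processing order cannot affect results.

Liptak's probit transform is clamped at the ±Φ⁻¹(1 − 1/(2(B+1)))
quantiles so a partial p-value of exactly 1 stays finite without
materially changing pooled ranks.

## Per-modality statistics

* **Continuous data** (microarray-like, proteomics): per-feature OLS of
  the measurement on intercept + outcome + covariates; t = β̂/(s·c).  With
  moderation on (default), s² is replaced by the empirical-Bayes posterior
  (d₀s₀² + d_g s²_g)/(d₀ + d_g), with (d₀, s₀²) obtained by matching the
  first two moments of log s²_g against a scaled-F model (trigamma
  inversion by Newton iteration); residual degrees of freedom grow to
  d₀ + d_g.
* **Counts** (RNA-seq-like): log-cpm transform
  log₂((count + 0.5)/(libsize + 1) · 10⁶), then a lowess curve of the
  quarter-root residual variance against mean log₂-count, evaluated at
  fitted values and inverted to fourth-power precision weights; the
  statistic is the weighted-least-squares moderated t.
* **Genotypes** {0,1,2}: Cochran–Armitage trend z with scores (0,1,2) and
  the conditional (hypergeometric) variance given the genotype margins —
  exactly the permutation variance, so the statistic is
  permutation-compatible by construction.
* **Uniform-like data**: Wilcoxon rank-sum z with midranks and
  tie-corrected variance, one-sided toward an upward shift in group 2 by
  default (matching the simulator's shift direction; configurable).  Its
  parametric p-value applies the usual 0.5 continuity correction, without
  which the normal approximation misses the stated accuracy against exact
  enumeration at n = 3 per group.
* **Multi-class outcomes** use the partial F over the outcome's indicator
  columns (moderated denominator when moderation is on); continuous
  outcomes enter as a single numeric regressor.

Hyperparameters that depend on the data but not on a specific labeling —
the moderation prior (d₀, s₀²) and the voom precision weights — are
estimated once under the observed labels and reused for all permutations.
Re-estimating them per permutation changes B lowess fits' worth of work
for no detectable change in the pooled ranks on null data; both choices
are exposed (`moderation_per_perm`, `weights_per_perm`).  Only the
outcome column is permuted; covariates stay attached to their samples.
Features with zero variance under a labeling get statistic 0 (flagged, so
their partial p-value is 1); perfect separation (zero residual variance,
non-zero effect) gets a large finite sentinel so ordering is preserved
without NaN propagation.

## Comparison methods

* **CP**: Fisher's classical combination −2 Σ log pᵢ of the *parametric*
  per-modality p-values against χ²(2k) — the textbook meta-analysis,
  valid only under independence and demonstrably anti-conservative when
  modalities are positively correlated.
* **RankSum / RankProd baselines**: features ranked within modality
  (rank 1 = strongest evidence, midranks for ties), combined by sum or
  product, with the null distribution generated by *independently* drawn
  permutation plans per modality — deliberately reproducing the
  independent-studies assumption whose violation makes these baselines
  miscalibrated on correlated data.
* **NPC-synchronized rank variants** reuse the shared plan, restoring
  calibration.
* **Rank-product tail approximation**: with q = ρ/nᵏ,
  p = q Σⱼ₌₀^{k−1}(−log q)ʲ/j! — the Erlang(k) tail of −log Π Uᵢ for iid
  Uniform(0,1) ranks.  This continuous approximation is accurate for
  large feature counts but substantially overstates the extreme discrete
  tail at small n (at n = 10, k = 2 it gives 0.056 where the exact
  probability of the minimal rank product is 0.01); see Limitations.
* **Benjamini–Heller partial conjunction**: with sorted partial p-values,
  min over j of ((n−u+1)/j)·p₍u−1+j₎, testing that at least u partial
  nulls are false; at u = 1 it coincides with the minimum
  Benjamini–Hochberg-adjusted value (asserted exactly in the tests).

## Evaluation metrics

The partial AUC integrates the tie-grouped ROC polyline (trapezoid rule,
linear interpolation at the region boundary — the integrator choice only
moves third-decimal values) over FPR ∈ [1−spec_hi, 1−spec_lo], default
specificity [0.9, 1].  McClish standardization maps it through
0.5·(1 + (pAUC − min)/(max − min)), min = diagonal area, max = full
rectangle, so chance ordering scores exactly 0.5 and a perfect ranking 1
for any specificity range (an algebraic identity, property-tested over
random ranges).  A perfectly inverted ranking scores 0.5·(1 − min/(max −
min)) ≈ 0.474 over [0.9, 1] — the zero of the *full-range* AUC does not
carry over to the standardized partial scale.

Benchmark experiments simulate one study per repetition, score it with
every method (paired design), take per-method medians over repetitions,
and compare the best method to each other with the paired two-sided
Wilcoxon signed-rank test (paired, because all methods see identical
data; the harness default is 20 repetitions).

The joint null criterion is checked by the double Kolmogorov–Smirnov
procedure: per repetition, two all-null microarray-like datasets
(uncorrelated or perfectly correlated) are simulated, the samples split
randomly into two equal groups, the method applied, and its gene p-values
KS-tested against Uniform(0,1); the repetition-level KS p-values are then
themselves KS-tested against Uniform(0,1) (both levels use the asymptotic
two-sided distribution).  Permutation-p granularity (multiples of
1/(B+1)) makes the first-level test slightly conservative, so harness
runs keep B ≥ 200.

## Problem sizes used by the shipped harnesses

The calibration and benchmark demonstrations in the acceptance tests run
at reduced scale, chosen so the full suite is a coffee-break job on one
core: the double-KS harness uses 200 repetitions × 200 genes × 20 samples
with B = 200; the correlation-robustness comparison uses 500 genes (250
deregulated in both datasets), 10 samples per group, B = 300, 5
repetitions over ρ ∈ {0, 0.6, 0.9}; the integration-benefit comparison
uses 4 modalities × 500 genes (deregulation counts 400/300/200/100,
common block 100), B = 300, 5 repetitions.  At these sizes the observed
behavior is unambiguous: corrected NPC passes the double-KS check in both
scenarios with all three combiners while parametric CP collapses on
correlated data (dks p ≈ 0), NPC's median pAUC moves by less than 0.05
across correlation levels while CP and the rank-product baseline degrade,
and the Fisher-combined analysis beats the best single-modality analysis
on common-behavior genes.

## What the simulators emulate — and what they do not

`sim_microarray` draws iid N(0,1) noise with per-gene mean shifts
δ ~ U(0.5, 2) (random sign) in group 2; `sim_rnaseq` draws negative
binomial counts with log-normal baselines (meanlog 5, sdlog 1.5), gene
dispersions U(0.05, 0.5) and log-uniform fold changes in
{1/3..1/1.5} ∪ {1.5..3}; `sim_snp` samples genotypes uniformly from
{0,1,2}, shifting group-2 frequencies to (1/3−ε, 1/3, 1/3+ε) with
ε = 0.25; `sim_uniform` adds a δ = 0.3 location shift.  The SNP and
uniform effect sizes are package choices (no external reference states
them) set so single-modality power at 10 samples per group is moderate
(0.5–0.9) — the regime where integration visibly helps; both are
config-exposed.  Correlated pairs use the Gaussian convolution
(X, ρX + √(1−ρ²)Z) per null gene, giving population Pearson correlation
exactly ρ; deregulated genes share the same shift across the pair but
carry independent noise, since no construction can fix both a correlation
level and a deregulation level at once.

Real omics data differ in ways the simulators deliberately omit:
within-dataset gene–gene correlation (irrelevant to NPC, which analyses
each gene across datasets independently), library-size variation (off by
default; `libsize_cv` exercises the voom weights), batch effects,
missing values and annotation ambiguity.  Passing tests therefore
demonstrate the statistical machinery — calibration, synchronization,
power ordering — not robustness to real-data preprocessing artifacts.

## Design choices on open points

* **Pseudo p-value pooling** is symmetric and self-inclusive over all B+1
  rows (see above); the asymmetric alternative (observed row corrected,
  pseudo rows not) breaks the identical-distribution property.
* **Covariates under permutation** stay with their samples while only the
  outcome is permuted — simple label permutation.  Under strong
  covariate–outcome confounding this is only approximately exact; a
  Freedman–Lane-style residual scheme is a known stricter alternative and
  a possible extension, so the simple scheme is documented here as a
  divergence point.
* **Feature mapping** operates on raw data before any statistic:
  `aggregate` collapses a group's features by mean or median per
  modality, `expand` forms one group per cross-modality feature tuple.
  Features with no mapping partner are dropped by default
  (`keep_unmapped` promotes each to a singleton group); a gene with zero
  partners in some modality is simply combined over the modalities that
  measure it.
* **Genotype statistic**: the Cochran–Armitage trend test, the standard
  permutation-compatible choice for 0/1/2 data in case-control designs.
* **Combiner weights** may be zero for some modalities (annihilating
  their contribution); they are normalized to sum to 1 on input.

## Known limitations

* The rank-product gamma-tail approximation is unreliable in the extreme
  discrete tail for small feature counts (error up to ~0.1 at n = 10,
  k = 2); exact enumeration or bound-based algorithms are preferable
  there.  The NPC-synchronized rank-product variant does not suffer from
  this, since its p-values come from permutation.
* Moderation hyperparameters and voom weights estimated once (not per
  permutation) are an approximation; the per-permutation options exist
  but cost a lowess fit per permutation.
* Monte-Carlo permutation p-values have granularity 1/(B+1); analyses at
  real-data scale should use B ≥ 10000 (the library default is 1000).
* Missing values, batch correction and genome-coordinate annotation are
  out of scope; inputs must be complete numeric matrices.
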