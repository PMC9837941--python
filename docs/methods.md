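# Methods

This note records the statistical models behind each module, the
defaults and why they were chosen, what the synthetic cohort does and
does not emulate, and the numerical conventions that make results
reproducible bit for bit.

## Normalization

Counts are converted to log₂ RPKM:
`log2(count · 1e9 / (libsize · length_bp) + pseudocount)`, with library
size defined as the within-matrix column sum (the pipeline starts at
count matrices, so aligner-reported totals are out of reach; the two
differ only by reads lost to annotation filtering). The pseudocount
defaults to 1, which maps zero counts to exactly 0 and keeps all values
finite and non-negative — a sensible floor for degraded (FFPE) input
where zeros are common. Deconvolution runs on linear CPM because the
mixture model is linear in expression.

## Pair-variance statistic

The per-patient progression statistic is the Euclidean distance between
a patient's two samples in the joint space of the top `n_pcs` principal
components (default 3) of the top `n_hvg` highly variable genes
(default 500, largest cross-sample variance of log₂ RPKM, ties broken
lexicographically). Conventions:

* Genes are centered but not unit-scaled by default: HVG selection
  deliberately retains high-variance genes and unit scaling would undo
  that emphasis. `scale_genes` exposes the alternative.
* Raw PC scores (U·S) are used for distances; `weight_by_variance`
  divides by singular values for the whitened alternative. Raw scores
  weight components by the variance they explain, which matches how a
  PC plot is read.
* PC signs are fixed by forcing the largest-magnitude loading of each
  component positive, so scores are stable across SVD implementations.
* Subset analyses (one molecular group) re-select HVGs and refit the
  PCA inside the subset; excluded samples cannot influence the result.

Group comparisons use Welch's unequal-variance t-test (group sizes here
are very unequal, e.g. 12 vs 4 vs 8); covariate association uses
Pearson correlation with the t-based two-sided p (Spearman available).
Centering-only PCA makes distances scale linearly when all profiles are
scaled — a useful invariance check.

## Pair-blocked moderated differential expression

Balanced pairs make the two-level model with a patient blocking factor
equivalent to a one-sample analysis of within-pair differences
d_g(p) = x_relapse − x_primary; the implementation uses the latter.
Gene variances s²_g (df d_g = n_pairs − 1) are assumed drawn from a
scaled-inverse-χ²(d₀, s₀²) prior whose hyperparameters are estimated by
moment matching on log s²_g: with
e_g = log s²_g − ψ(d_g/2) + log(d_g/2), the model implies
E[e] = log s₀² + ψ(d₀/2) − log(d₀/2) and
Var[e] = ψ′(d_g/2) + ψ′(d₀/2), so d₀ follows from inverting the
trigamma function on the excess variance (Newton iteration) and s₀²
from the mean. Non-positive excess variance means the spread of the
observed variances is explained by sampling noise alone: d₀ = ∞ and
the moderated t degenerates to a z-test at the pooled variance. The
moderated statistic is t_g = mean(d_g)/√(s̃²_g/n) with
s̃²_g = (d₀s₀² + d_g s²_g)/(d₀+d_g) on d₀ + d_g df. The test suite
cross-checks t, p and (d₀, s₀²) against the Bioconductor limma
implementation on a shared fixture.

DEG calls use Benjamini–Hochberg adjusted p < 0.05 with no fold-change
filter; top-k lists are ordered by (p_adj, |log2fc| descending,
gene id) so output is deterministic. Group 3 and Group 4 are merged by
default for DGE (the non-SHH/non-WNT cohort), with per-group reruns
available. Over-representation of DEG lists is the upper-tail
hypergeometric p with BH across a GMT collection.

## Composition

`build_signature` collapses a labeled single-cell count matrix to
per-type mean CPM profiles and picks, per type, the `markers_per_type`
(default 50) genes with the largest log₂ CPM margin over the best other
type; the marker union forms the signature rows. A type with no
positive-margin gene is degenerate and rejected.

`deconvolve_nnls` solves, per bulk sample, weighted non-negative least
squares min ‖W(S·f − b)‖₂, f ≥ 0, then renormalizes f to sum to one
(relative fractions). W is diagonal with 1/mean_g (mean over signature
columns): overdispersed counts have an approximately constant
coefficient of variation, so relative-error weighting is the matched
objective and prevents a few high-abundance genes from dominating;
`row_weight_power=0` recovers plain NNLS. On the default synthetic
cohort the weighting cuts fraction RMSE from ~0.04 to ~0.015. Each
sample also gets a permutation p: the fraction of `n_perm` (default
100) random gene-relabelings of the bulk vector whose reconstruction
correlation (Pearson on log₂) reaches the observed one.

Paired primary→relapse fraction shifts are tested per cell type with a
paired t-test, stratified by the *primary* sample's molecular group
(so a rare pair whose group label switches at relapse stays with its
diagnosis group); strata under 3 pairs are reported with NaN and a
warning rather than pooled.

The enrichment cross-check (`gsva_like_scores`) is a single-sample
weighted Kolmogorov–Smirnov running sum on a profile's gene ranking:
inside-set steps proportional to |value − median(profile)|^exponent
(default exponent 1), outside-set steps uniform, score = extreme
positive + extreme negative deviation. Two choices matter and both were
made for null symmetry: median-centering the weights (raw log-scale
expression is all-positive, which otherwise drags every random set's
score up by ~+0.2) and the two-extreme score form. Empirically the
null mean over random sets is ~0.02. The direction of marker-set score
shifts between group-mean primary and relapse profiles must agree with
the deconvolution shifts — the package's built-in cross-validation of
any composition finding.

## Survival

Kaplan–Meier, log-rank and Cox (Efron tie handling, Newton–Raphson)
are delegated to lifelines; Greenwood standard errors are accumulated
from the event table. The cutoff scan is implemented directly: every
distinct expression value inside the 10th–90th percentile window whose
split leaves ≥ 5 samples per arm is tried as a high/low cutoff, the
split minimizing the raw log-rank p wins, and the Bonferroni factor is
the number of cutoffs actually tested. The scan's inner log-rank is a
direct risk-table computation (thousands of splits per gene; verified
against lifelines in the tests); the scan depends on expression only
through ranks, hence is invariant to monotone transforms. The window
and minimum arm size are exposed — the cutoff-scan idea has no single
canonical parameterization, so parameters are configuration, not truth.
Risk direction is the sign of the high arm's observed-minus-expected
event count.

Metagenes pool candidate genes whose corrected scan p < α and whose
risk direction is concordant with their differential-expression
direction: relapse-up + high-expression-risk → *unfavorable*;
relapse-down + high-expression-protective → *favorable*. The per-sample
score is the mean of z-scored (across samples) member expression —
scale-free and insensitive to set size. For relapsed cohorts the
survival clock starts at re-operation; the generator emits both clocks
(`os_months` from relapse, `pfs_months` from diagnosis).

Separation (monotone partial likelihood) in the Cox fit is promoted
from a convergence warning to an explicit error, as are absurd
coefficient/SE magnitudes. Categorical association uses Fisher's exact
test for 2×2 tables with any expected cell < 5, otherwise chi-squared;
sparse tables larger than 2×2 fall back to chi-squared with a warning
(no exact RxC test is attempted).

## Fingerprint

VAF < 0.1 → 0, VAF > 0.9 → 2, else 1 (strict inequalities; boundary
values are called heterozygous). A pair is verified when ≥ 80% of
≥ 20 jointly called sites match. Concordance on genotype codes rather
than raw VAF correlation is robust to the heavy allele-fraction noise
of degraded material; both thresholds are configurable because no
published criterion exists for this check.

## Synthetic cohort generator

The generator emulates the data structure the analyses assume, not any
particular dataset:

* **Cohort**: 24 SHH + 5 Group 3 + 14 Group 4 patient pairs; ages
  bimodal for SHH (infant ~N(2.5,1) with prob. 0.4, child/adult
  ~N(22,8)) and unimodal child for Group 3/4; relapse patterns drawn
  per group (SHH: ½ local, ⅙ distant, ⅓ combined; Group 3/4: no local,
  distant/combined split); ~4.7% of Group 4 pairs switch label to
  Group 3 at relapse, so molecular groups are conserved in ~95% of
  pairs.
* **Expression**: six cell-type signature profiles (lognormal baseline,
  disjoint marker blocks of 60 genes upregulated 8-fold); per sample a
  Dirichlet-drawn fraction vector mixes the profiles, the mixture is
  scaled to a library size uniform in 0.5–2 × 10⁶, and counts are
  negative-binomial with size 10 (CV ≈ 32% above Poisson). Dirichlet
  totals are 56 per group, giving per-type fraction SDs of ~0.04–0.06 —
  the between-tumor composition variability under which the paired
  tests operate; this concentration makes the programmed 1.5× shift
  detectable at the cohort's 14 Group 4 pairs with ~90% power even for
  an oracle reading true fractions, which is the regime the detection
  analyses presuppose.
* **Programmed effects**: relapse Dirichlet parameters move the A1
  (cell-cycle) mean up exactly 1.5× and C1 down 0.7× in Group 3/4, and
  B1 up 1.4× / C1 down 0.7× in SHH. The multi-component shift is solved
  jointly so every stated fold is exact (composing single-component
  rescales would perturb earlier targets). 50 DE genes (half up, half
  down, default |log2FC| 1) multiply relapse expression; ~45% of pairs
  (weighted toward young SHH patients, which creates the age–variance
  association) get a ×1.5 CNV block over a contiguous 5%-of-genes run
  on one of 22 synthetic chromosomes, relapse only. Gene lengths are
  log-uniform 300 bp–30 kb so RPKM normalization is non-trivial.
* **Survival**: exponential baseline (mean 36 months from re-operation);
  the linear predictor is log HR 0.8 per SD of the unfavorable-metagene
  mean expression (half of the DE-up genes); censoring is independent
  uniform with the horizon solved analytically to hit the 30% target
  censor rate. Only the unfavorable metagene enters the hazard; the
  favorable side has no programmed survival effect, so favorable-set
  recovery is a precision/direction check, not a recall check.
* **Fingerprints**: per-patient genotypes Binomial(2, MAF~U(0.1,0.5))
  at 200 sites, shared exactly by both samples; VAF = genotype/2 +
  N(0, 0.05) noise, 5% missing.
* **Single-cell reference**: ≥ 100 cells per type (default 120), NB
  counts around the same signature profiles at library size 5000 —
  bulk and reference share a generative platform, which is why no
  cross-platform batch correction is modeled.

What the generator does **not** emulate: FFPE degradation artifacts,
platform/batch effects, ambient RNA or doublets in the reference,
linkage between SNP sites, non-proportional hazards, and competing
risks. Passing tests therefore demonstrate internal statistical
correctness and calibration of the chain, not robustness to those
real-data pathologies.

A subtlety worth knowing: because all genes share each sample's
realized fraction vector, gene-level tests are correlated within a
cohort even under the null. Average type-I error stays nominal, but a
single cohort's p-value histogram is noisier than an independence
assumption predicts; the strict uniformity property is tested with the
composition variation frozen (concentrated Dirichlet), and calibration
under loose mixtures is tested as an average across cohorts. Similarly,
group comparisons of pair distances are only exchangeable when groups
share a composition prior, which the calibration harness enforces.

## Numerical conventions

Ties everywhere break deterministically (lexicographic gene ids after
the primary key); every stochastic routine takes an explicit seed and
reruns are bit-identical; TSV is tab-separated UTF-8 without quoting,
with missing clinical fields as literal `NA`; writers prepend a
`#relapse-delta v<version>` comment. BH adjustment enforces
monotonicity and caps at 1. The trigamma inversion uses Newton steps
with asymptotic initializations at both extremes. The pipeline hashes
every artifact (SHA-256) into a manifest; deterministic stages
reproduce hashes under a fixed seed.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run the chain at reduced but
representative sizes chosen once: cohorts of 800–2000 genes,
calibration sweeps of 150–400 null tests or 5–30 cohorts, 20–30 seeds
for power/recovery estimates, and 3-cohort aggregates wherever a
single 43-pair realization's sampling noise would dominate the
quantity being reported (direction concordance, fold-increase). These
sizes keep Monte-Carlo error a factor of a few below each check's
margin.

## Known limitations

* The NNLS deconvolution is a deliberate, documented stand-in for
  hosted mixture-estimation tools: same estimand (relative fractions
  over a signature), different solver; no attempt is made to reproduce
  any specific tool numerically.
* The enrichment score is a single-profile statistic without a
  variance model; it is used only for direction cross-checks, never
  for inference on its own.
* The cutoff scan's Bonferroni correction counts tested cutoffs within
  one gene only; scanning many genes requires a further multiplicity
  layer (the metagene builder applies its α to already-corrected
  per-gene p-values across a small fixed candidate list).
* `fit_variance_prior` assumes a common d₀ across genes; variance
  outliers (e.g. a CNV block) pull the prior slightly.
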