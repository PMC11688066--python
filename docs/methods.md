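# Methods

## Problem

Cross-tissue tumor comparisons (e.g. microsatellite-instable colorectal
vs endometrial cancers) are confounded by tissue of origin: most genes
that differ between two tumor types differ simply because colon and
endometrium differ. `orthosel` selects *cancer-specific,
normal-invariant* genes — genes that discriminate the two tumor types
while expressing indistinguishably in the two matched normal tissues —
from a four-group design (tissue A/B × tumor/normal).

## Model and procedure

Expression is TPM-normalized (`tpm_g = (count_g / length_kb_g) /
Σ rate × 10⁶`; columns sum to 10⁶ exactly). Samples are split into a
tumor matrix `X_T` with tissue labels `y_T` and a normal matrix `X_N`
with labels `y_N`, coded A → +1, B → −1 and mean-centered downstream.
The ±1 coding makes the covariance direction symmetric in the two
classes even with unequal group sizes after centering.

The selection funnel has three stages:

1. **Screen.** A negative-binomial Wald test between the two tumor
   classes restricts the universe to genes with |log2 FC| > 1 and
   BH-adjusted p < 0.01 (strict inequalities). This stage is plumbing —
   it reduces a transcriptome-scale input to a tractable,
   tumor-discriminating universe — and any external DE engine's output
   can be substituted through the DEG-table format.
2. **Tumor PLS-DA.** For a single centered response the first PLS weight
   vector is, in closed form, `w ∝ X_cᵀ y_c`. Genes with "large enough"
   first-component weight are kept; see *Weight cutoff* below.
3. **Normal-invariance filter.** On normal samples the covariance
   direction `v = X_cᵀ y_c` is the axis that separates the tissues.
   Unit vectors `w` with `w·v = 0` are projections carrying zero
   covariance with the tissue label; drawn uniformly from the
   (p−2)-sphere in the hyperplane, their expected squared coordinates
   are, in closed form,

       E[w_i²] = (1 − u_i²) / (p − 1),   u = v/‖v‖,

   strictly decreasing in |u_i|. Genes nearly orthogonal to the
   discrimination axis therefore receive systematically larger squared
   weight, which is why thresholding the rescaled coefficients of `v`
   directly (|coef| < τ, default τ = 0.9) selects the same genes as the
   Monte-Carlo squared-sum statistic without any sampling. Both routes
   are implemented; the coefficient shortcut is the default, the sampler
   (`method="sq_sum"`) is the first-principles cross-check.

The final list is the intersection of stages 2 and 3 within the screened
universe.

## Key numerical and design choices

**Coefficient scaling.** The invariance threshold is applied on the
*correlation* scale by default: each coefficient is the Pearson
correlation of the gene with the tissue label over normal samples,
bounded in [−1, 1]. A unit-norm vector over thousands of genes can
contain at most one entry ≥ 0.9, so a τ = 0.9 cut is only meaningful
under a per-gene normalization; `unit_norm` and `raw` scalings are kept
for exploration. Zero-variance genes get coefficient 0 (a constant gene
cannot discriminate tissues, hence is always invariant).

**Sphere sampler.** The default sampler projects standard-normal draws
onto the hyperplane and renormalizes — exactly uniform on the
constrained sphere. An alternative `angles` sampler parametrizes the
sphere by independent uniform spherical angles in a Gram–Schmidt basis;
independent uniform angles do *not* induce the uniform surface measure
(the Jacobian weights early angles by powers of sin φ), so this dialect
is retained for comparison, not as the default. Accumulation of squared
weights is streamed in chunks, so memory is flat in the number of draws.

**Gram–Schmidt complement.** The orthonormal complement of `u` is built
by Gram–Schmidt over seeded random completion vectors with a second
orthogonalization pass per vector (classical re-orthogonalization);
completeness `uuᵀ + BBᵀ = I` holds to 10⁻¹⁰ at p up to hundreds.

**Tumor weight cutoff.** "Large enough" is operationalized by a
per-gene permutation null: each gene's raw covariance weight is
standardized by its standard deviation across label permutations
(default 30), and genes with |z| > 4 are kept. This calibration is
scale-free per gene and tracks signal content rather than the size of
the gene universe. A fixed top-quantile mode (default 0.16, roughly the
selection ratio a transcriptome-scale screen of ~4000 genes yields) and
fixed absolute/signed thresholds are also available; absolute-value
selection is the default semantics because a strongly negative weight is
just as discriminative as a strongly positive one. Note that a pooled
null quantile on *unit-norm* weights cannot work: observed and permuted
unit-norm weight vectors share the same scale by construction.

**Screen internals.** Median-of-ratios size factors; per-gene
moment-based NB dispersion `α̂ = max(0, (s² − m)/m²)` from pooled
within-class moments; Wald statistic on the log2 ratio of
pseudocounted (0.5) class means with delta-method SE; BH adjustment.
No dispersion shrinkage or independent filtering — transparency and
testability are preferred over fidelity to any particular external
tool. All-zero genes are reported as (log2 FC 0, p 1), never an error.

**Survival validation.** Each selected gene is dichotomized at the
cohort median (ties to the low group — a fixed, reproducible rule; the
choice of cutpoint is a documented convention, not a verified one) and
tested with the two-sample log-rank test per tumor cohort. Per-gene
significance at α = 0.05 is reported without multiplicity correction,
with a BH-adjusted column alongside for the stricter view. KM curves
and the log-rank statistic are delegated to lifelines.

**Clustering validation.** Average-linkage hierarchical clustering on
Euclidean distances over per-gene z-scored expression, cut at 2
clusters; the headline statistic is majority-vote purity (ARI is
reported alongside). Standardization matters because TPM scales span
orders of magnitude; a display heatmap may use unscaled values, but the
tested distance metric is the scaled one.

## Synthetic data

The generator emulates the four-group design at desk scale with four
planted gene classes: `TISSUE` (tissue fold in both conditions — the
confounders), `CANCER_INVARIANT` (tissue fold in tumors only — the
target), `CANCER_SHARED` (tumor-vs-normal effect identical in both
tissues), and `SHARED_NULL`. Counts are negative binomial with mean
`base_g × L_s × f_gs` and variance `μ + α μ²`; fold directions are
randomized per gene so selection cannot cheat on sign; tissue folds are
split symmetrically (±fold^½) so the baseline is the geometric group
mean.

Defaults define the study conditions: 400 genes with fractions
0.25/0.10/0.10/0.55 over the four classes, 30/30 tumor and 60/60 normal
samples, fold 4 for both effects. The free noise parameters were frozen
once after a design-stage power analysis: dispersion α = 0.02,
baseline means log-uniform over 10^1.5–10^3, log-normal library sizes
(σ = 0.3), gene lengths uniform on 500–10 000 bp. The dispersion is at
the clean end of bulk RNA-seq practice deliberately: the desk-scale
cohort (60 normals per tissue) must carry information comparable to the
hundreds-to-thousands-of-samples cohorts the design mimics, and at
α = 0.02 a 4-fold tissue effect yields normal-tissue correlations of
~0.92–0.96, safely above the τ = 0.9 invariance cut, while
cancer-invariant genes sit near 0. What passing tests show is therefore
that the pipeline recovers planted structure under its stated
assumptions — NB counts, a common dispersion, no batch effects, no
GC/length bias, no mutational processes; they do not show robustness to
real-data pathologies outside that model.

Survival outcomes are exponential with the log-hazard shifted by
log(HR) for samples in the upper expression half of each effect gene
(within each tumor cohort), with independent exponential censoring;
normals carry no survival record.

## Verification sizes and known limitations

The test suite checks the sphere moments at p = 50, K = 20 000 (exact
per-gene SEs from the Beta(1/2, (p−2)/2) law of w_i², simultaneous
Šidák band at family rate 1%), shortcut/sampling selection equality at
p = 100, K = 50 000 for τ ∈ {0.5, 0.9}, PLS weights against an
independent NIPALS iteration (20 random instances, 10⁻⁸ relative),
Gram–Schmidt completeness at p ∈ {3, 20, 200}, end-to-end recovery over
5 seeds, screen calibration under a pure-null generator, and survival
type-I rate over 500 replicates on 100-sample cohorts.

Two rank-level claims do not hold at desk scale and their tests
document this by failing honestly:

* Spearman rank agreement > 0.99 between the sampled squared-weight
  scores and −|u|: because Σu_i² = 1, the spread of E[w_i²] across
  genes is at most ~1/(p−1), and at p = 100, K = 50 000 Monte-Carlo
  noise dominates the rank order among the necessarily small
  coefficients (achievable Spearman ≈ 0.5–0.7). The *linear*
  association is strong (Pearson ≈ −0.94, anchored by the large
  coefficients), and the selection-level equivalence is exact.
* Agreement of the asymptotic log-rank p with a 10 000-permutation null
  within pure Monte-Carlo error at n = 20: the χ²(1) reference carries
  a systematic finite-sample error (~0.015–0.02 absolute) that exceeds
  the ~0.005 Monte-Carlo SE. The statistic itself matches the
  permutation oracle's to machine precision; only the asymptotic tail
  approximation is at its validity edge at 20 events.

Other limitations: the screen is a simplified moment-based NB Wald
test, not a drop-in for shrinkage-based engines; the intersection has
no uncertainty quantification; survival analysis is univariate with a
median cut (no Cox model, covariates, or optimal-cutpoint scanning);
and the angle-parametrized sampler is intentionally non-uniform, as
described above.
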