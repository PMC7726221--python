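# Methods

## Model and estimation

`haplopred` fits the multi-component linear mixed model
y = Xb + u_A + u_D + u_H + e with u_A ~ N(0, σ²_α A_g),
u_D ~ N(0, σ²_δ D_g), u_H ~ N(0, σ²_αh A_gh), e ~ N(0, σ²_e I), one record
per individual. The relationship matrices are cross-products of the coding
matrices scaled by the trace normalizer k = tr(WW′)/n, which forces a mean
diagonal of exactly 1 and makes each matrix invariant to rescaling of its
coding (any centering-equivalent coding yields the same matrix).

Codings follow the genetic partition of genotypic values:

* SNP additive: x − 2p for x copies of the counted allele, p the sample
  frequency; columns are mean-zero by construction.
* SNP dominance: {2,1,0} copies → {−2q², 2pq, −2p²}; expectation zero and
  orthogonal to the additive column under exact Hardy–Weinberg proportions
  (both identities are asserted in tests).
* Haplotype additive: every distinct phased allele string of a block is an
  allele; the column for allele l codes c_l − 2p_l. Row sums within a block
  vanish identically, so each block contributes at most (alleles − 1) to
  the rank of W_αh. Rare haplotype alleles are retained: frequency
  filtering is applied at the SNP level only (MAF threshold, inclusive at
  the boundary), before any fold masking, and allele/coding frequencies
  are full-sample frequencies.

### REML

Variance components maximize the restricted likelihood. The fitter takes
three EM steps (guaranteed ascent, robust at boundaries), then switches to
average-information (AI) Newton steps with step-halving back to the EM
update whenever a proposed step would decrease the restricted
log-likelihood. Negative proposals are truncated at a floor of
1e−8 × var(y); convergence requires relative log-likelihood change < 1e−8
and relative parameter change < 1e−6. Non-convergence is flagged on the
result object, never raised. Heritability of component i is
σ̂²_i / Σ σ̂² (phenotypic variance under the model), so reported component
heritabilities plus the residual fraction sum to 1 exactly.

All solves are dense Cholesky factorizations. At the problem sizes this
package targets (n up to a few thousand) a fit takes seconds, so variance
components are re-estimated per cross-validation fold by default; a config
switch reuses full-data components across folds instead. Per-fold and
reused-component accuracies agree closely on simulated traits (tested).

### GBLUP

Fixed effects are estimated by GLS on training records,
b̂ = (X′V⁻¹X)⁻¹X′V⁻¹y; component predictions for *all* individuals are
û_i = σ̂²_i G_i[:, train] V_train⁻¹ (y − Xb̂). Masked individuals'
phenotypes never enter the equations — a poisoning test asserts that
replacing validation phenotypes with arbitrary values changes no
prediction by more than 1e−10. If V_train is numerically singular a ridge
of 1e−8 × mean(diag) is added with a warning.

The relationship-matrix form is algebraically identical to a marker-effect
ridge solution of the equivalent model (α̂ from normal equations in marker
space, genetic value Wα̂); the test suite verifies agreement to 1e−8 via
the m-dimensional normal equations, a computation path independent of the
n-dimensional V-based solver. Because the trace normalizer absorbs any
duplication of coding columns, GREML heritabilities and GBLUP predictions
are invariant to repeated SNPs; this invariance is what licenses reading
the haplotype-minus-SNP heritability difference as epistasis rather than
double counting.

### Per-locus heritability profiles

Effects are back-solved from a converged fit as
effect = (σ̂²/k) W′V⁻¹(y − Xb̂). The heritability of SNP j is
var(W[:, j]) × effect_j² / σ̂²_P; the heritability of a haplotype block is
the sample variance of the block's fitted genetic-value vector over σ̂²_P.
The exact per-locus formula is a package design choice — the tested
contract is ranking behavior (a single simulated causal SNP attains the
maximum profile value), not absolute values, and the profile sum is only
bounded by, not equal to, the component heritability because of shrinkage.

## Haplotype blocks

* **Fixed distance**: windows of the given width laid on absolute
  coordinates (window index = position // width). Absolute anchoring keeps
  the hand-checkable property that window membership depends only on
  position, and the recorded span of every emitted block is the window
  width. Windows with fewer than two SNPs emit no block.
* **Fixed count**: consecutive groups of exactly s SNPs; when a
  chromosome's count is not divisible by s, the last block is the
  chromosome's final s SNPs and may overlap its predecessor, so min = max
  = s SNPs per block and the count is Σ ceil(m_c/s).
* **Annotation intervals**: BED intervals (converted to 1-based inclusive
  at the reader boundary) are extended by a 2-kb flank on both ends,
  merged per class (coding / noncoding / chipseq analyzed separately; a
  SNP may appear in blocks of different classes), and split into chunks of
  at most 150 kb; chunks with fewer than two SNPs are dropped. Block span
  is the first-to-last SNP distance, hence never exceeds the chunk width.

Block statistics (totals, averages, min/max SNPs and spans, coverage as
union-of-spans over the genome length, flank-extended coverage) are
internally consistent by construction and cross-checked against an
independent interval-union routine.

## Synthetic data

The generator emulates the minimal structure the analysis needs, not a
demographic model.

* **Genotypes**: founder haplotypes follow a first-order Markov chain
  along each chromosome — a latent uniform is copied from the previous SNP
  with probability `ld_decay` (default 0.7) or drawn fresh, then
  thresholded at that SNP's target frequency. Marginal allele frequencies
  are exact (default spectrum: uniform MAF on [0.05, 0.5]); the adjacent
  allelic correlation equals `ld_decay` when neighboring frequencies are
  equal and is attenuated toward the Fréchet bound otherwise. Diploids
  pair independent founder haplotypes; an optional generation of random
  mating (whole-chromosome transmission, no recombination) adds GRM
  off-diagonal structure. No recombination maps, genotyping error or
  imputation error are modeled.
* **Annotations**: intervals with configurable size distribution placed
  uniformly on length-weighted chromosomes, classed coding / noncoding /
  chipseq with configurable fractions.
* **Phenotypes**: y = Xb + additive + dominance + epistasis + residual.
  Fixed effects are a sex-like binary factor (default effect 0.5) and an
  age-like uniform covariate on [30, 80] (default slope 0.02/year),
  mimicking the covariate structure of human cohort traits. Additive and
  dominance components use the package's own codings with standard-normal
  effects. The epistasis component is **cis-phase** within-block
  additive-by-additive interaction: for each sampled SNP pair in a block
  (default 2 pairs per block), each of an individual's two haplotypes
  contributes the product of the pair's centered allele indicators times a
  standard-normal effect. Cis products are additive functions of the
  haplotype allele, so a haplotype additive model can absorb them while a
  SNP additive model cannot — exactly the contrast the epistasis
  heritability estimator differences out. Genotype-level products would
  put half the interaction variance in trans phase, which no model in the
  comparison can capture, and the dose-response of the estimator would be
  flat.
* **Variance control**: components are orthogonalized sequentially
  (dominance against additive, epistasis against both) and rescaled so
  each realized sample variance equals its requested fraction of the unit
  phenotypic variance exactly; the residual absorbs the remainder.
  Orthogonalization makes the requested fractions genuinely disjoint
  contributions — without it, third-moment coupling under LD leaks
  additive-direction signal into the dominance and interaction products.
* **Skew and missingness**: an optional inverse Box-Cox transform with
  parameter λ (λ = 1 is an affine shift, λ = 0 exponentiates) produces
  skewed traits for exercising the normality transform; missing phenotypes
  are masked completely at random at a configurable rate.

What passing tests on these data do *not* show: robustness to phasing or
imputation error, population structure or admixture, ascertainment of the
SNP panel, or linked selection — none of which the generator produces.

## Phenotype preparation

Box-Cox λ is the profile-likelihood maximizer (scipy's Brent optimization
of the profile log-likelihood; a brute-force λ-grid oracle test confirms
agreement to 1e−3). Values must be positive; an optional shift maps the
minimum to 1. Outlier removal is a single pass: mean and SD computed once
on all non-missing values, records beyond the SD threshold (default 10,
chosen to remove only the 13–17 SD scale of genuinely impossible values
while never touching plausible tails) are dropped and reported with their
SD distances on the raw scale — outliers are removed before any
transformation, since the documented distances of real outliers refer to
the raw scale. Fixed-effect designs expand classification variables to
reference-coded indicators plus an intercept and pass covariates through
as numeric columns; missing covariates on phenotyped rows are an error,
not imputed.

## Cross-validation

Ten-fold: the first nine folds have size ceil(n/10) and the tenth takes
the remainder (equal folds when 10 | n; most-even fallback with a warning
when the ceil rule is infeasible). Observed accuracy is the Pearson
correlation between raw phenotypic values and predicted total genetic
values in validation individuals, averaged over folds with the SD across
folds (n−1 denominator); a config flag offers fixed-effect-adjusted
phenotypes for sensitivity analysis. Fixed effects and (by default)
variance components are estimated within each training fold. The percent
gain of a haplotype model is 100 × (acc_hap − acc_snp_best)/acc_snp_best
against the better of the two SNP models.

## Epistasis heritability

h²_E = h²_g − h²_s with the model pairing fixed by which components the
haplotype model contains: haplotype-only and additive+haplotype models
(4, 2) difference against the SNP additive model (6); models containing
dominance (1, 3) difference against the additive+dominance model (5).
Mismatched pairings raise. Negative estimates are reported with a
haplotype-loss flag rather than clamped — loss (the haplotype model
estimating SNP additive signal less accurately than the SNP model) is
real model behavior, diagnosable in the heritability profiles. The
differencing estimator is upward-biased when the haplotype model absorbs
non-epistatic variance; the simulation suite quantifies this only
indirectly (null mean ≈ 0.02 at n = 500 under a purely additive trait
with tight LD). A variance-based alternative is deliberately not
implemented; the API leaves the estimator pluggable.

## Problem sizes and numerical choices

Simulation-based checks run at sizes where the statistical property being
asserted genuinely holds with margin: parameter recovery at n = 1000,
m = 2000 (20 replicates, Model 5, truth h²_add = 0.4, h²_dom = 0.1);
epistasis dose response at n = 500 with 4-SNP blocks, ld_decay 0.9, 10
replicates per level v ∈ {0, 0.05, 0.10, 0.15}; null-heritability
concentration at n = 800, where SE(ĥ²) ≈ 0.02 puts ≥95% of boundary-noise
replicates below 0.05 (at n = 500 the SE is ~0.03–0.04 and the rate is
only ~90%). GRMs are built dense; cross-products use einsum traces;
symmetry is enforced exactly after each product. Degenerate inputs —
monomorphic SNPs, zero-trace codings, zero-variance phenotypes, singular
designs — raise immediately with specific messages.

## Known limitations

* The REML fitter is dense-matrix; it is not intended for biobank-scale n.
* Haplotype dominance is not modeled (no model variant includes it).
* The per-SNP heritability definition is a back-solve convention; absolute
  values are not comparable across models with different column counts.
* The epistasis estimator inherits haplotype loss as negative bias and
  model absorption as positive bias; it is a diagnostic, not an unbiased
  variance component.
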