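# haplopred

Haplotype-block genomic prediction for quantitative traits: multi-allelic
GBLUP/GREML mixed models, cross-validated prediction accuracy, and
haplotype-epistasis heritability.

## The problem

Standard genomic prediction fits every SNP as an independent biallelic locus
and ignores where SNPs sit on the genome and what they do. Haplotype models
instead group consecutive phased SNPs into blocks — by fixed chromosome
distance, fixed SNP count, or functional annotation intervals (genes, coding
genes, noncoding genes, ChIP-seq binding sites) — and treat each block as a
single multi-allelic locus whose distinct phased allele strings are the
alleles. When interactions between SNPs on the same haplotype contribute to
the trait, the haplotype additive model absorbs that within-block
additive-by-additive epistasis and predicts better than a SNP model.
`haplopred` is a tested implementation of this analysis for people studying
haplotype effects on complex traits in human cohorts or breeding populations;
a synthetic-data module with a fully known variance architecture stands in
for access-restricted cohort data.

## The model

The mixed model for phenotypes **y** on n individuals is

    y = Xb + W_α α + W_δ δ + W_αh α_h + e

with fixed effects **b**, SNP additive effects α (coding x − 2p for x copies
of the counted allele at sample frequency p), SNP dominance effects δ
(genotypes {2,1,0} coded {−2q², 2pq, −2p²}), and haplotype additive effects
α_h (one column per block allele l, coding c_l − 2p_l for c_l carried
copies). The reparameterized covariance structure uses genomic relationship
matrices

    A_g  = W_α  W_α′  / k_α      k = tr(WW′)/n
    D_g  = W_δ  W_δ′  / k_δ
    A_gh = W_αh W_αh′ / k_αh

so Var(y) = σ²_α A_g + σ²_δ D_g + σ²_αh A_gh + σ²_e I. Variance components
are estimated by REML (EM steps with average-information acceleration);
genetic values by GBLUP, with validation individuals' phenotypes masked out
of the equations. Six model variants are compared: (1) A+D+H, (2) A+H,
(3) D+H, (4) H only, (5) A+D, (6) A only, where A/D/H are the SNP additive,
SNP dominance and haplotype additive components.

Haplotype-epistasis heritability is estimated by differencing model total
heritabilities: h²_E = h²_g − h²_s, where h²_g sums the component
heritabilities of a haplotype model (1–4) and h²_s those of the matched SNP
baseline (Model 6 for haplotype models 2/4, Model 5 for 1/3); the relative
form divides by the baseline SNP additive heritability. The difference is
interpretable as within-block epistasis because GREML/GBLUP are invariant to
duplicated SNPs, so adding haplotype columns changes the fit only through
what haplotype alleles capture beyond SNP dosages.

## Worked example

Simulate a phased panel with strong local LD, build 4-SNP haplotype blocks,
simulate a trait with 40% additive and 10% within-block epistasis variance,
and estimate the epistasis heritability and prediction accuracies:

```python
import numpy as np
from haplopred import *
from haplopred.epistasis_heritability import estimate_epistasis

config = SimConfig(n_individuals=500, chromosomes=[("1", 5_000_000)],
                   snp_density=100, ld_decay=0.9, seed=42)
panel = simulate_genotypes(config)
blocks = enumerate_haplotypes(blocks_fixed_count(panel.snp_map, 4), panel)
pheno, truth = simulate_phenotypes(
    panel, blocks, TraitArchitecture(additive=0.4, epistasis=0.1), seed=43)

grms = build_grms(build_model_matrices(panel, blocks))
X, _ = build_design(pheno, factors=["sex"], covariates=["age"])
y = pheno["y"].to_numpy()

fit_hap = greml_fit(y, X, {"hap_additive": grms.a_gh})   # Model 4
fit_snp = greml_fit(y, X, {"snp_additive": grms.a_g})    # Model 6
est = estimate_epistasis(fit_hap, fit_snp, hap_model_id=4)
print(f"haplotype total h2:  {est.h_g2:.3f}")
print(f"SNP total h2:        {est.h_s2:.3f}")
print(f"epistasis h2 (true 0.10): {est.h_e2:.3f}")

plan = make_folds(pheno["id"], k=10, seed=44)
acc_hap = cross_validate(y, X, grms.as_dict(), ModelSpec(4), plan)
acc_snp = cross_validate(y, X, grms.as_dict(), ModelSpec(6), plan)
print(f"haplotype model accuracy: {acc_hap.mean:.3f} +/- {acc_hap.sd:.3f}")
print(f"SNP model accuracy:       {acc_snp.mean:.3f} +/- {acc_snp.sd:.3f}")
print(f"gain: {accuracy_gain(acc_hap.mean, acc_snp.mean):.2f}%")
```

Output:

```
haplotype total h2:  0.543
SNP total h2:        0.453
epistasis h2 (true 0.10): 0.090
haplotype model accuracy: 0.494 +/- 0.111
SNP model accuracy:       0.481 +/- 0.097
gain: 2.68%
```

The haplotype model's total heritability exceeds the SNP model's by roughly
the simulated within-block epistasis fraction, and its ten-fold
cross-validated accuracy (Pearson correlation between phenotypes and
predicted total genetic values in validation folds) is correspondingly
higher.

A YAML-driven pipeline and a CLI wrap the same stages end to end
(`haplopred run config.yaml`, plus `simulate`, `prep`, `blocks`, `fit`,
`cv`, `epistasis` subcommands).

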