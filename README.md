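# survgwas

Survival-genetics analysis of lifespan in biobank-scale cohorts, for
statistical geneticists studying how common and rare variation shapes age at
death. The package implements the full analysis chain around a two-stage
survival GWAS:

1. **Martingale-residual GWAS.** A genotype-free Cox proportional-hazards
   model, H(t | z) = H₀(t)·exp(z'β) with sex and five principal components,
   is fitted on the age scale (age at death for the deceased, last-known age
   for administratively censored subjects). Each subject's Martingale
   residual M̂ᵢ = δᵢ − Ĥ₀(tᵢ)·exp(zᵢ'β̂) — observed minus expected deaths —
   then serves as a continuous phenotype, so that per-variant association
   reduces to OLS of residual on minor-allele dosage. QC (missingness > 5%,
   MAF < 1%, HWE exact p < 10⁻⁶) and sex-stratified scans are included.
2. **Gene-based rare-variant tests.** Variants are classed as predicted
   loss-of-function (nine consequence terms), AlphaMissense-damaging
   (score ≥ 0.7) or REVEL-damaging (score ≥ 0.75); per gene and class, sets
   of MAF < 1% variants with ≥ 10 carriers are tested by a carrier-collapsed
   burden test (Gᵢ = 1 iff Σⱼ gᵢⱼ > 0), SKAT with Beta(MAF; 1, 25) weights,
   and SKAT-O over ρ ∈ {0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1}. Tail
   probabilities of the quadratic forms come from a Davies-style
   characteristic-function inversion with an exact finite-sample
   (variance-ratio) null; the SKAT-O omnibus is computed exactly as a
   two-dimensional Gaussian event rather than by a moment approximation.
3. **Carrier characterization.** Kaplan-Meier curves, log-rank tests and
   covariate-adjusted Cox hazard ratios for carriers versus non-carriers,
   plus per-variant Cox screens (MAC ≥ 3, Bonferroni α/n_tested).
4. **Colocalization, CHIP, PheWAS.** Wakefield approximate-Bayes-factor
   colocalization (PP0–PP4) of GWAS against eQTL summary statistics;
   somatic-variant (clonal hematopoiesis) flagging from left-shifted variant
   allele fractions with 10,000-sample bootstrap CIs; and a phenome-wide
   screen of carrier status (logistic/linear, α/n_phenotypes threshold)
   with cause-of-death carrier-enrichment chi-squares.

Individual-level biobank data cannot ship with code, so the package includes
a first-class synthetic-cohort generator (Weibull-baseline proportional
hazards, administrative censoring, HWE genotypes, sparse rare-variant gene
architectures, germline/somatic read counts, LD-structured paired summary
statistics) that reproduces the statistical structure every stage assumes;
the test suite validates the machinery against closed forms, brute-force
oracles and permutation nulls on those cohorts. See `docs/methods.md` for
the modelling details and limitations.

## Worked example

Simulate a 20,000-subject cohort in which carriers of loss-of-function
variants in a gene ("TETX", carrier frequency ~0.3%/variant, hazard ratio 2)
die earlier, then run the gene-based stage end-to-end:

```python
import numpy as np
from survgwas.simulate import (SimConfig, GeneSpec, VariantSpec,
                               simulate_cohort, simulate_gene_burden)
from survgwas.survival import cohort_null_residuals, cox_carrier_hr
from survgwas.variant_classes import VariantClass, build_gene_sets
from survgwas.gene_based import collapse, run_gene_tests, results_table

config = SimConfig(
    n_subjects=20_000, seed=7,
    variants=[VariantSpec(maf=0.3, log_hr=0.1)],
    genes=[GeneSpec("TETX", n_variants=10, carrier_freq=0.003,
                    variant_class="LoF", log_hr=np.log(2))],
)
cohort, G, truth = simulate_cohort(config)
_, annotations = simulate_gene_burden(config)

fit, residuals = cohort_null_residuals(cohort)
print(f"events: {cohort.event.sum()} / {len(cohort)}; residual sum: {residuals.sum():.2e}")

gene_sets = build_gene_sets(G, annotations, VariantClass.LOF)
results = results_table(run_gene_tests(residuals, G, gene_sets))
print(results[["gene", "k", "carriers", "burden_p", "skat_p", "skato_p"]].to_string(index=False))

carrier = collapse(gene_sets[0].dosage(G))
hr = cox_carrier_hr(cohort, carrier)
print(f"carrier HR {hr['hr']:.2f} (95% CI {hr['ci'][0]:.2f}-{hr['ci'][1]:.2f}), p = {hr['p']:.1e}")
```

prints

```
events: 2982 / 20000; residual sum: -1.17e-12
gene  k  carriers     burden_p       skat_p      skato_p
TETX 10       566 5.944302e-15 3.773926e-12 8.437695e-15
carrier HR 2.01 (95% CI 1.70-2.38), p = 2.7e-16
```

The cohort shows ~15% observed mortality (the rest administratively
censored); the residuals sum to zero, as the Breslow estimating equation
requires; the gene's 566 carriers reach gene-level significance in all three
tests (SKAT-O tracking the stronger burden signal, as expected when all
variants act in one direction); and the follow-up Cox model recovers the
generative hazard ratio of 2. If the same carriers' sequencing reads are
simulated as clonal-somatic (clone fraction 0.5) instead of germline, the
VAF stage summarizes `mean VAF 0.24 [0.23, 0.25]` and flags the gene as
CHIP-like — a left-shifted allele-fraction distribution rather than the 0.5
expected of germline heterozygotes.

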