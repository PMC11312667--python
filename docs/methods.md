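# Methods

`survgwas` implements a survival-genetics analysis of lifespan in a large
biobank-style cohort: common-variant GWAS on Martingale residuals,
gene-based rare-variant tests by functional class, survival characterization
of carriers, Bayesian colocalization against eQTLs, somatic-variant (CHIP)
flagging from allele fractions, and a phenome-wide screen of carrier status.
A synthetic-cohort generator supplies data with exactly the structure each
stage assumes, so every statistical claim the package makes can be checked
against a known truth.

## Survival model and Martingale residuals

Time is age in years with no delayed entry: a subject contributes either an
age at death (event) or a last-known age (administratively censored). The
hazard model is Cox proportional hazards,

    H(t | z) = H0(t) · exp(z'β),

with covariates sex and the first five genetic principal components (sex is
dropped inside single-sex strata). `fit_cox` maximizes the partial
likelihood by Newton-Raphson with step-halving; convergence requires a
gradient norm below 1e-8 (relaxed proportionally to |log L| for large
cohorts, where float accumulation noise exceeds that scale), with at most 50
iterations. Tie handling defaults to Efron, with Breslow selectable; the
covariance is the inverse observed information; the baseline cumulative
hazard is the Breslow step estimator, which reduces to Nelson-Aalen in the
covariate-free model. Monotone likelihood (separation) raises a dedicated
error rather than returning divergent coefficients.

Martingale residuals are

    M_i = δ_i − H0(t_i) · exp(z_i'β̂),

with H0 evaluated right-continuously at the subject's own time (times beyond
the last step reuse the final value). Under the Breslow baseline the
residuals sum to zero as an estimating-equation identity; the test suite
asserts this at 1e-8 together with M_i ≤ 1. These residuals — "observed
minus expected deaths" — are the continuous phenotype for all downstream
association tests, which turns each per-variant survival analysis into a
single OLS fit. The two-stage shortcut tracks the one-stage Cox Wald test
closely (Pearson r > 0.95 on −log10 p across simulated causal SNPs; checked
in acceptance).

Left truncation at recruitment age is deliberately not applied: the model
treats age at death / last-known age directly, so estimated baselines are
cohort-conditional; all downstream inference uses residual contrasts and is
unaffected by that convention.

## Common-variant QC and scan

QC removes variants with missing rate > 0.05, minor allele frequency < 1%,
or Hardy-Weinberg exact-test p < 1e-6 (the boundary MAF = 1% is kept; the
rule is "< 1%" removed). The HWE test is the exact conditional test: given
the allele counts, heterozygote counts no more probable than the observed
one are summed; dosage (non-hard-call) data skip HWE with a warning. Missing
dosages are never imputed — MAF, MAC and the association scan are
complete-case per variant. The scan regresses Martingale residuals on
minor-allele dosage with an intercept and no further covariates (sex and PCs
are already absorbed by the Cox null model; re-adjustment exists as an
option for sensitivity analyses). Genome-wide significance is flagged at
5e-8. Sex-stratified scans refit the null model within the stratum.

## Rare-variant classes and gene sets

Three non-exclusive classes: predicted loss-of-function (nine consequence
terms: splice acceptor, splice donor, stop gained, frameshift, start loss,
stop loss, transcript ablation, feature elongation, feature truncation —
matched case-insensitively with spaces/underscores normalized, accepting
both bare and `*_variant`/`*_lost` serializations), AlphaMissense-damaging
(missense with score ≥ 0.7) and REVEL-damaging (missense with score ≥ 0.75);
both cutoffs inclusive. Gene sets keep class variants with cohort MAF < 1%
and are tested only with ≥ 10 carriers, a carrier being any subject with
dosage > 0 at at least one member variant. Whether the rare-MAF filter
should use cohort or external reference frequencies is genuinely open;
cohort frequencies are the default because they are always available and
self-consistent with the carrier definitions.

## Burden, SKAT and SKAT-O

The burden test regresses the residual on the collapsed binary carrier
indicator (OLS with intercept, two-sided t test). SKAT and SKAT-O operate on
the per-variant genotype matrix with Beta(MAF; 1, 25) weights. This split —
collapsed indicator for burden, per-variant matrix for SKAT/SKAT-O — is a
deliberate design choice: a variance-component test computed on one
collapsed variable would be algebraically identical to the burden test and
could never disagree with it, whereas opposite-direction variants within a
gene are exactly the case SKAT-O exists for.

SKAT's statistic is Q = ||W G'(y − ȳ)||² / σ̂² with σ̂² from the
intercept-only null model. Its reference distribution is computed two ways:

- **Exact (default).** {Q > q} is rewritten as a sign-indefinite quadratic
  form, {e'Ke − q·e'e/(n−1) > 0}, whose null distribution under Gaussian
  errors is an exact signed mixture of chi-squares — k eigenvalues ν_i − c
  plus −c with multiplicity n−1−k, free of the unknown σ². This removes the
  O(1/n) error of treating σ̂² as known and agrees with a 10⁶-permutation
  null within Monte-Carlo error at n = 50.
- **Asymptotic.** The classic Σ λ_i χ²₁ reference with λ the eigenvalues of
  the centered weighted Gram matrix.

Either way the tail probability comes from characteristic-function inversion
in the Davies style: a midpoint-rule Gil-Pelaez sum whose step is set by a
Chernoff bound on the aliasing tail and whose truncation point is set by the
envelope/oscillation decay of the integrand, with both error terms reported;
when the certified error is too large relative to p, Liu's kurtosis-matched
moment approximation takes over (flagged in the result). Absolute target
accuracy is 1e-9.

SKAT-O mixes Q_ρ = (1−ρ)·Q_SKAT + ρ·Q_burden over the grid
ρ ∈ {0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1}; ρ = 1 is the weighted-sum
burden score test, ρ = 0 is SKAT. The min-p omnibus, P(min_ρ p_ρ ≤ T) with
T the observed minimum (computed from the exact per-ρ nulls), is evaluated
without a moment approximation by observing that every Q_ρ is a function of
just two quantities of the Gaussian score vector S ~ N(0, A): its squared
norm and its squared burden projection x = 1'S. Conditioning on x makes
Q_SKAT a noncentral chi-square mixture (eigenvalues of A deflated along the
burden direction, noncentralities proportional to x²), so the omnibus tail
is a one-dimensional integral over x of a noncentral Davies tail
probability. Per-ρ thresholds are Gaussian-model quantiles at level T —
marginals and joint law come from the same model, so the only approximation
left is the Gaussian copula of the scores (O(1/n)); this matches a
10⁶-permutation omnibus within Monte-Carlo error at n = 50, where the
published one-factor moment approximation is off by an order of magnitude
more. Numerically, the integrand's kinks (the min over ρ switches linearly
in x²) are located analytically and each smooth segment is integrated by
48-point Gauss-Legendre, with a direct two-component Gaussian quadrature
replacing the CF inversion when the conditional mixture has at most two
eigenvalues. Degenerate geometry or integration failure falls back to
Bonferroni over the grid, flagged. The omnibus can never beat its best
component (p ≥ min_ρ p_ρ) nor exceed the grid Bonferroni bound; both are
asserted.

Gene-wide multiple-testing control divides α by the total number of tests
(genes × classes × methods, or a per-class gene-count vector); the
per-variant Cox screen inside significant genes tests every variant with
MAC ≥ 3 and uses α / n_tested.

## Colocalization

Per-variant evidence is the Wakefield approximate Bayes factor,
log ABF = ½ log(se²/(se²+W²)) + ½ z² W²/(se²+W²), with prior effect sd
W = 0.15 (quantitative-trait default) and priors p1 = p2 = 1e-4,
p12 = 1e-5 — the referenced method names no priors, so its software defaults
are adopted. Hypothesis sums use log-sum-exp stabilization; variants are
matched on chrom:pos:ref:alt with beta-sign flips for swapped alleles. The
posterior vector PP0..PP4 sums to one within 1e-12; PP4 is monotone in the
shared signal strength (checked on a grid).

## VAF and CHIP flagging

VAF is alternate reads over depth per heterozygous carrier. A gene/class
distribution is summarized by its mean with a percentile (2.5/97.5)
bootstrap 95% CI over 10,000 seeded resamples of carriers; variant-level
aggregation (mean per variant, then bootstrap variants) is available because
the natural bootstrap unit is genuinely ambiguous. The CHIP flag is
`upper CI bound < 0.5` — the simplest decision rule consistent with
reporting CI-based evidence of a left-shifted distribution. Operating
characteristics under the generator: germline (binomial p = 0.5) flag rate
≤ 5%, clone-fraction-0.5 somatic (p = 0.25) flag rate ≥ 95%, CI coverage
within [0.92, 0.98].

## PheWAS and enrichment

Binary phenotypes with < 100 cases and continuous phenotypes with < 100
non-missing values are removed, as are ICD chapters for injuries, external
causes, health-service contacts and special codes (implemented as
configurable code-prefix ranges; default S/T/V/W/X/Y/Z/U). Binary traits use
ML logistic regression, continuous traits OLS, both with age, sex and five
PCs and per-phenotype complete cases; perfect separation or non-convergence
yields an NA-flagged result with a diagnostic. Ordinal and multinomial
models are out of scope (biobank-specific categorical codings, not needed to
exercise the statistics). The phenome-wide threshold is α/n_phenotypes at
full precision, with a truncated two-significant-figure display value
(0.05/1,670 prints as 2.9e-5; comparisons always use full precision). The
cause-of-death enrichment is a per-category 2×2 chi-square (1 df, no
continuity correction; expected cells < 5 warn) of carrier status for
in-category deaths versus everyone else.

## Synthetic cohort generator

The generator emulates, at desk scale, the structure of a large elderly
biobank: n = 10,000 subjects by default (the analyses it stands in for used
~394,000); Weibull baseline hazard with shape 7 and scale 100 years, giving
a baseline median death age near 95; administrative censoring by a per-subject
"current age" drawn uniformly on 52.6–88.7 years (the cohort's
last-known-age range), which yields roughly 10–15% observed deaths, matching
the ~9% death fraction of the emulated cohort; male excess mortality with
log-HR 0.35; null PCs. Survival ages are inverse-transform draws,
t = scale·(E/exp(η))^(1/shape) with E ~ Exp(1), so proportional hazards
holds by construction and Cox refits recover the generative coefficients
(asserted at n = 10,000). Alternative censoring modes: none, a fixed age, or
a single administrative censor age placed at the baseline Weibull quantile
that leaves a requested fraction alive.

Common variants are HWE binomial genotypes; rare gene architectures are
per-variant Bernoulli heterozygous carriers with class labels, damaging
scores at or above the 0.7/0.75 cutoffs and optional sub-cutoff
"non-qualifying" missense variants so the filters are exercised; read depths
are Poisson (mean 30) truncated at ≥ 1 with binomial alternate reads at 0.5
(germline) or f/2 (clonal somatic at clone fraction f); colocalization
regions draw marginal z-scores MVN(Σλ, Σ) over AR(1) LD with the causal
configuration setting the truth label H0–H4. A single root seed expands into
fixed per-stage child seeds so any stage can be regenerated independently
and consistently.

What the generator does *not* emulate — realistic LD from reference panels,
relatedness, competing risks, genotyping error, imputation uncertainty,
phenotype correlation structure — bounds what passing tests show: they
validate the statistical machinery under its stated assumptions, not
robustness to those real-data features.

## Numerical choices and problem sizes

Tolerances: Newton gradient 1e-8 (scaled by |log L|); CF-inversion target
accuracy 1e-9 with certified error bounds; SKAT-O omnibus integration by
segmented 48-point Gauss-Legendre; posterior normalization checked at 1e-12;
bootstrap 10,000 resamples. Validation problem sizes were chosen so the full
suite runs in minutes on one CPU while keeping Monte-Carlo error well inside
each assertion's tolerance: 2,000-replicate calibration per test (binomial
99% bounds), 200-replicate recovery studies, 10⁶-permutation oracles at
n = 50, and n = 10,000 cohorts for the two-stage concordance check.

## Known limitations

- The exact quadratic-form null assumes Gaussian errors; Martingale
  residuals are skewed, so finite-sample calibration on real residuals rests
  on the score statistics' asymptotics (the calibration suite exercises
  exactly this path).
- Single-causal-variant colocalization only; no SuSiE-style multi-signal
  decomposition.
- No relatedness adjustment (no mixed-model tests) and no time-varying
  covariates, stratified baselines, frailty or competing risks.
- VCF parsing handles biallelic GT/AD/DP; BGEN/PLINK-bed and imputation
  INFO scores are out of scope.
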