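# Methods

## Generative model

Each simulation replicate draws `n` subjects.  The index SNP X₁ is
Bernoulli(p₁) under the binary coding (a dominant/recessive carrier
indicator) or Binomial(2, p₁) under the additive coding (minor-allele
count).  The second SNP is generated from the logistic model
logit P(X₂=1) = γ₀ + γ₁X₁, which induces LD-like dependence between the
pair; with the defaults γ₀ = 0, γ₁ = 0.3 the conditional carrier
probabilities are 0.5 and expit(0.3) ≈ 0.574.  The trait is
Y = β₀ + β₁X₁ + β₂X₂ + β_I X₁X₂ + ε with ε ~ N(0, σ²), σ = 1 by default.

Defaults (n = 1000 subjects, p₁ = 0.5, γ = (0, 0.3), β main effects 0.3 or
0, β_I swept from 0.3 to 1.0 in steps of 0.05, α = 5×10⁻⁸, 5000 replicates
at full scale) are the package's reference study conditions; the test
suite and the acceptance script run the sweep at 500 replicates per grid
point, which resolves majority statements and monotonicity comfortably
(binomial SE ≤ 0.022 per proportion).

**Additive coding of X₂.**  No canonical recipe exists for extending the
logistic rule to an allele count; we draw X₂ as the sum of two
conditionally independent allele indicators, each with per-allele success
probability expit(γ₀ + γ₁X₁).  This reduces to the binary rule on {0,1}
and keeps a Hardy–Weinberg-like structure.  It is a modelling choice, not
the only defensible one.

**σ = 0** is allowed as an exact-predictor mode so closed-form checks are
possible; the fitter then reports an exact fit (see below).

## Fitting and testing

All three models are fitted by weighted least squares (weights default to
1).  The solver uses a pivoted QR of the √w-scaled design; rank is
declared at a relative tolerance of 1e-10 on the pivoted diagonal.  On a
rank-deficient design, estimable columns are selected scanning left to
right (so the intercept always survives) and the remaining columns are
flagged aliased with NaN estimates.  An algorithm whose design loses any
genotype term (X₁, X₂ or X₁X₂) to aliasing returns `failed` rather than a
p-value — a conditional estimate computed on an aliased genotype pair is
meaningless.  Covariates enter as numeric columns only; categorical
covariates are expanded to indicators upstream (reference level = first
alphabetically).

Wald statistics use the t distribution with residual degrees of freedom;
at n = 1000 this is indistinguishable from the normal reference, and at
the small n used in unit tests it is the exact small-sample choice.
Exact fits (weighted RSS ≤ 1e-12 × max(1, total SS)) report p = 0 for
nonzero coefficients and p = 1 for zero ones, with an explicit
`exact_fit` flag, so scenario classification stays total.

Weights are normalised to sum to n before fitting; coefficients, standard
errors and p-values are therefore invariant to rescaling all weights by a
positive constant.

## Scenario classification

Rejection is strict (p < α; a p-value exactly at α does not reject — the
boundary had to be fixed somewhere and ties have probability zero under
continuous p-values).  Scenario 5 is decided by the marginal test alone;
failures of the conditional/interaction fits therefore only produce the
FAILED label when the marginal null was rejected.  FAILED replicates are
tabulated as their own category rather than dropped so that proportions
always sum to one.  With common variants at n = 1000 the FAILED proportion
is ≈ 0.

`run_study` also tabulates the per-algorithm rejection proportions
(`prop_reject_alg0/1/2`), which is the natural y-axis for power curves and
what the monotonicity check consumes.

## Cohort mode

`read_cohort` inner-joins a delimited phenotype/covariate table (first
column = sample id) with a VCF (DS dosages when present, otherwise GT hard
calls via cyvcf2) or a delimited dosage matrix, keeps complete cases with
a logged drop count, and expands categoricals.  Per SNP pair the analysis
is complete-case in the two genotypes, runs the covariate-adjusted
conditional and interaction models, and attaches:

* MAF = mean(dosage)/2 folded to ≤ 0.5 (orientation-independent);
* LD r² = squared Pearson correlation of dosages (composite LD) — phase is
  unavailable from dosages, and under HWE this estimator coincides with
  haplotype r²;
* flags: `rare_variant` when MAF < 0.01 or fewer than 10 carriers,
  `collinear` when r² > 0.95, `monomorphic` when LD is undefined.  The
  thresholds are configurable; rare-variant caution is a warning, never a
  filter — inflated conditional SEs under near-collinearity are surfaced,
  not suppressed.

The weights used by weighted least squares are caller-supplied data (a
`weight` column); the package imposes no weighting rule of its own.

## Synthetic cohorts

`simulate_cohort` emulates the structure of a three-cohort childhood
asthma study of a continuous bronchodilator-response-like trait: n = 892
split ≈ 560/206/126 across cohorts, one common index SNP (MAF 0.32),
companion SNPs at target r² 0.995 and 0.891, one rare variant
(MAF 0.001), covariates (cohort, age ~ U(5, 18) years, sex ~
Bernoulli(0.5), BMI category ~ multinomial(0.60, 0.25, 0.15), ancestry
score ~ N(0, 1)), optional weights, and a trait built from a fully
recorded linear model (truth record) plus N(0, σ²) noise.

Pairwise LD is constructed at the haplotype level: for allele frequencies
p, q and signed correlation r, D = r·√(p(1−p)q(1−q)) fills a 2×2 haplotype
table whose margins match the allele frequencies exactly; two haplotypes
per subject are drawn independently (HWE assumed) and summed to dosages.
Requested r must satisfy the Lewontin bounds
max(−pq, −(1−p)(1−q)) ≤ D ≤ min(p(1−q), q(1−p)); infeasible combinations
(e.g. r² = 0.9 between MAF 0.32 and MAF 0.001) raise a feasibility error
quoting the attainable bound.  Since r² is sign-free, the positive root is
taken by default with a sign flag available.  At MAF 0.001 and n = 892 a
monomorphic draw is possible; the generator retries (default 10 times) and
then emits the monomorphic sample with a warning — tests that need
carriers use larger n or a higher MAF.

Default trait coefficients (index-SNP effect −0.15 on a σ = 1 trait,
covariate effects of magnitude 0.01–0.2) are free parameters chosen to be
plausible for a standardised pulmonary-response trait; they anchor
parameter-recovery tests, not any external estimate.

## What the synthetic data do not capture

Real genotype data have genotyping error, missingness patterns correlated
with ancestry, more-than-pairwise LD structure, and population
stratification beyond a single ancestry score; the trait model is exactly
linear with homoscedastic Gaussian noise.  Passing tests demonstrate the
statistical machinery is correct under the stated generative model, not
that any particular real-data conclusion follows.

## Problem sizes and numerical choices

The test suite runs the sweep at 500 replicates per grid point and the
null calibration at 2000 replicates; the acceptance script uses the same
sizes with sweep endpoints (β_I ∈ {0.3, 1.0}).  Random streams derive from
one root seed via `numpy` SeedSequence spawning, so every replicate is
reproducible in isolation and grid points are independent.  Monte-Carlo
tolerances in tests are 3 (occasionally 4) standard errors; the LD-recovery
band is ±0.02 at n = 10 000.

## Known limitations

* Continuous traits only — no case-control outcome models, no robust or
  sandwich standard errors, no mixed models.
* Two-SNP machinery only; no haplotype simulation beyond pairwise LD
  targets and no GWAS-scale scanning.
* No multiple-testing correction: a single fixed α per analysis.
* Genetic-ancestry scores are accepted as input columns, never computed.
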