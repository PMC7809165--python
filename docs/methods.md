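# Methods

## Model overview

`medipath` estimates direct and microbiome-mediated effects of host genetic
variants on quantitative traits. For one marker dosage *G* (0/1/2 copies of
the minor allele), one microbial feature *M* (a CLR-transformed OTU
abundance) and one standardized trait *P*, the framework fits four related
single-feature models, each adjusted for a collapsed contemporary-group
covariate (CGb), the dam-line code (D, 1/2) and a collapsed sire covariate
(Sr):

| model | equation | quantity |
|---|---|---|
| Mod1 | P ~ G + covariates | total effect γ |
| Mod2 | P ~ M + covariates | mediator effect β |
| Mod3 | M ~ G + covariates | marker→mediator effect α |
| Mod4 | M ~ G + covs; P ~ M + G + covs | α′, β′, direct γ′, indirect α′β′ |

Mod4 is a recursive (triangular) two-equation system with uncorrelated
errors, so per-equation OLS is the joint maximum-likelihood solution; the
package verifies this against a numerically optimized joint Gaussian
likelihood in its test suite. Latent counterparts (Mod1L/Mod2L/Mod4L)
replace P with a factor Π measured by three indicators and adjust it with
two latent nuisance constructs (one over the three per-trait CGb
covariates, one over the three Sr covariates).

## Design-effect collapsing

Cross-classified factors are awkward inside SEMs, so they are collapsed
first. Per response (each trait and each CLR feature) the mixed model
`y = CG + D + S + pen + e` is fitted with pen as the single random effect.
Because every individual occupies exactly one pen, the marginal covariance
`V = I + λ ZZ'` is block diagonal with rank-one blocks; REML therefore
reduces to a one-dimensional profiled likelihood over log λ with
closed-form O(n) algebra per evaluation (bounded scalar minimization,
`xatol 1e-10`, λ searched in e^[-18, 12]). Fixed effects use drop-first
reference coding; rank-deficient design matrices (confounded levels) are
resolved by pivoted-QR column elimination, with dropped solutions set to 0.
The collapsed covariates are `CGb_i = CG solution + pen BLUP` and
`Sr_i = sire solution`, each standardized to mean 0, SD 1 — which removes
any dependence on the reference-coding choice. The implementation is
cross-checked in tests against closed-form balanced-ANOVA estimators,
statsmodels MixedLM and lme4-style fits.

## Association scans

One OLS engine serves Mod1/Mod2/Mod3 (the G→M scan literally reuses the
GWAS code path with roles swapped). The per-feature fit regresses the
response on [intercept, feature, CGb, D, Sr]; p-values are two-sided t
tests on n−5 df. The scan is vectorized across features by
Frisch–Waugh–Lovell residualization, which is numerically identical to the
per-feature normal-equations solve (asserted against a brute-force oracle).
Monomorphic features are flagged untestable, never dropped. Bonferroni and
Benjamini–Hochberg adjustments (via statsmodels) are applied per response
across the features tested for that response. The variance absorbed by a
mediator is `var(β·M)` (population convention); with standardized traits
this is directly a proportion of phenotypic variance.

## Latent-variable SEM

The SEM engine uses the RAM parameterization `v = A v + u`,
`Σ(θ) = F (I−A)⁻¹ S₀ (I−A)⁻ᵀ F'`, and minimizes the ML discrepancy
`F = log|Σ| + tr(SΣ⁻¹) − log|S| − k` with an analytic gradient
(`dF = tr[W dΣ]`, `W = Σ⁻¹(Σ−S)Σ⁻¹`, chained through the RAM structure).
Choices:

* **Identification** — marker-variable convention: the first loading of
  every latent construct (phenotype factor and both adjuster constructs) is
  fixed to 1. Standardized loadings `λ·sd(Π)` are reported in tests to make
  results constraint-invariant.
* **Optimization** — L-BFGS-B on a mixed parameterization (variances on the
  log scale, bounded below at log var = −18; an active bound is flagged as
  a Heywood case), gradient tolerance 1e-8, two deterministic starts
  (sample-moment-informed and the caller's warm start when resampling).
* **Exogenous observed predictors** (G, M where exogenous, D, mediator
  covariates) have their covariance block fixed at the sample moments — the
  conditional-ML, x-fixed convention. Latent adjusters keep free variances
  and free covariances with the other exogenous variables.
* **Standard errors** — inverse observed information, with the Hessian of
  the discrepancy obtained by central differences of the analytic gradient
  and the delta method mapping log-variance SEs back to the natural scale.

A 3-indicator one-factor model is exactly identified (F ≈ 0 at the
optimum), which the tests use as a saturated check; the no-predictor limit
is validated against scikit-learn's ML `FactorAnalysis` to 1e-4.

## Empirical significance

* **Percentile bootstrap** (default 1000 rounds, 95% level): records are
  resampled with replacement as whole rows (covariates travel with their
  record); significance ⇔ 0 outside the percentile interval. Plain
  percentile intervals are used, not BCa.
* **Path-breaking permutation**: only the mediator column is shuffled,
  severing G→M and M→P jointly; the permuted indirect estimates form the
  null interval and significance ⇔ the observed indirect falls outside it.
  The shuffle is unrestricted (no stratification), which also breaks
  mediator–covariate links — a documented caveat.
* **Joint rule**: a triple is a discovery only if both tests reject.

The two tests are calibrated at different null boundaries, and this is a
property of the methods, not of the implementation. Under the *partial*
null typical of a genome scan (marker inert, mediator genuinely predictive:
α=0, β≠0) the bootstrap rejects at ~5% while the permutation test — whose
reference distribution is a complete null — is anticonservative. Under the
*complete* null (α=β=0) the permutation test rejects at ~5% while the
bootstrap of a product of two null coefficients is strongly conservative
(<1%). The calibration runs in the test suite therefore evaluate each test
at its own null boundary; the pass-both joint rule is what keeps the
decision conservative across both regimes. Permutation per-coefficient
null intervals for α′ and β′ are retained for audit.

## Pipeline

Order of operations: OTU filter (total count ≥ 1200, zero fraction ≤ 80%,
both evaluated jointly on the original counts) → multiplicative zero
replacement (each zero set to 0.65 of one count at the row's depth;
deliberately a deterministic, parameter-transparent scheme rather than a
Bayesian-multiplicative routine with unstated priors) → CLR → trait
standardization (once, at ingest) → per-response design collapsing → MWAS →
mediator selection → GWAS → mediation fits → screens → empirical tests →
window grouping.

Mediator selection demands, per latent factor's trait triplet: Bonferroni
adjusted p < 0.05 on **all three** traits, variance absorbed > 1% on all
three, and temporal admissibility (a mediator sampled at stage S3 cannot
mediate a trait recorded at S2; stages are ordered S1 < S2 < S3 via the
`trait_stages` setting). Mediation triples with ratio > 1 (strictly) go to
empirical testing, prioritized by Sobel p and capped at `max_candidates`
(default 100); total-effect candidates need γ p < 0.01 (strictly) and are
tested by bootstrap only. Latent Mod4L models run on the marker set
surfaced by the measured analysis (top `max_latent_candidates` by Sobel p),
a deliberate economy: an SEM refit per resampling round is ~100× the cost
of the measured refit. Discovered markers are grouped greedily per
chromosome into windows seeded at the left-most member, joining markers
whose panel index is within 10 of the seed — the window rule operates in
panel-index space (consecutive genotyped SNPs), not base pairs. QTL-overlap
comparison is a generic interval-overlap counter over a user-supplied
BED-like annotation table.

## Synthetic cohorts

The generator emulates a commercial swine fat-deposition trial:

* **Scale presets** — `full_scale_config()`: 1,183 individuals, 40,542
  markers on 18 autosomes, 12 contemporary groups, 28 sires, 331 pens, 2
  dam lines, counts rarefied to 10,000. Default smoke preset: n=500,
  m=2,000, 100 OTUs.
* **Genotypes** — per-marker MAF ~ U(0.05, 0.5), dosage ~ Binomial(2, MAF).
  No linkage disequilibrium and no pedigree, by design.
* **Design** — pens are nested within contemporary groups (pens are
  physical batches within a trial week; the nesting is a modeling choice,
  not a data constraint); sires and dam lines are randomly balanced. Dam
  line is a binary 1/2 covariate. Nuisance variances default to CG 0.15,
  pen 0.05, sire 0.10, residual 0.60 on the latent-trait scale — chosen
  once so that planted mediators absorb ~1–10% of trait variance, the
  realistic range for strong single-OTU effects.
* **Microbiome** — latent log-abundances are a linear model in dosage and
  design effects plus Gaussian noise (baseline spread SD 2, feature noise
  SD 1); counts are multinomial draws at the rarefaction depth from the
  softmax of the latent row. Zero inflation arises implicitly from finite
  sampling of low-proportion features — no separate hurdle model. The
  mediator seen by the trait layer is the row-centered latent
  log-abundance, i.e. the noiseless CLR; the observed CLR adds multinomial
  sampling noise, so mediated signals attenuate as in real rarefied data.
* **Phenotypes** — six traits load on two latent factors (defaults: loadings
  1/0.85/0.70 and 1/0.80/0.60, uniqueness 0.30); planted direct and
  mediated marker effects enter the factor scores (or individual traits).
* **Reproducibility** — four independent RNG streams (genotype, design,
  microbiome, phenotype) spawned from one master seed; identical configs
  are bit-identical.

What the generator does **not** emulate: LD structure, relatedness,
longitudinal microbiome dynamics, taxonomic correlation between OTUs, and
library-size variation (rows are exactly rarefied). Passing tests therefore
demonstrate correctness of the estimation machinery under the stated
generative model, not robustness to population structure or compositional
dependence among mediators.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` run: decomposition and oracle
checks at n=200–250; empirical-test calibration on 200 datasets of n=400
with 500 resampling rounds; parameter recovery at n=5,000 (paths) and
n=2,000 (loadings); and the end-to-end pipeline on a cohort of n=1,000 with
2,000 markers, 50 OTUs, 20 planted mediated markers, 100 empirical-test
candidates at 200 rounds, plus a matched null cohort. These sizes keep a
full run in the tens of minutes on a single CPU while leaving every
statistical check well-powered.

## Known limitations

* One mediator at a time; simultaneous multi-mediator selection and latent
  mediators are out of scope.
* The permutation test's unrestricted shuffle breaks mediator–covariate
  links along with the mediated path.
* Mixed models support exactly one random effect (pen); no genomic
  relationship matrix, so polygenic confounding of the scans is not
  modeled.
* SEM supports continuous indicators and complete cases only (no FIML).
* The mediation ratio uses absolute values, so opposite-sign mediation is
  screened in; a ratio of exactly 1 is screened out (strict inequality).
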