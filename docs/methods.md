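# Methods

## Scope and design

`mrmediate` implements a mediating two-sample Mendelian randomization
pipeline for GWAS summary statistics: instrument selection, six causal
estimators, heterogeneity/pleiotropy diagnostics, three-leg pathway
screening, and product-of-coefficients mediation. The real analyses this
machinery serves use large public GWAS resources; the package is instead
exercised end to end on synthetic summary data with known causal structure,
so every quantitative claim in the test suite is a parameter-recovery or
calibration statement against a planted truth.

## Harmonization

Two-sample MR requires the exposure and outcome effect estimates at each
variant to refer to the same effect allele. We adopt the standard
convention: identical allele pairs are kept; swapped pairs flip the outcome
beta and replace EAF by 1 − EAF; strand flips are resolved by complementing
the outcome alleles before matching; palindromic variants (A/T, G/C) are
dropped whenever either EAF is missing or lies in [0.42, 0.58] (window
configurable), and otherwise oriented by frequency agreement. Pairs
matching no orientation are dropped as incompatible. Dropped pairs are
recorded with their reason and excluded from estimation.

## Instrument selection

Selection is a three-stage pipeline: (1) retain variants with p below the
threshold; (2) greedy LD clumping — repeatedly keep the smallest-p variant
(ties broken lexicographically by id, for determinism) and discard
remaining variants on the same chromosome within the window whose r² with
it meets the cutoff; variants absent from the LD reference are treated as
independent with a logged warning, keeping the operation total on partial
references; (3) strength filtering with R² = β²/(β² + se²·n) and
F = R²(n−2)/(1−R²), dropping F < 10 (the conventional weak-instrument
cutoff). R² and F use each record's own sample size. Two named presets
ship: `immune` (p < 1e-5, r² < 0.1, 500 kb) for high-dimensional molecular
exposures and `cytokine_outcome` (p < 5e-6, r² < 0.001, 10,000 kb) for
outcome- and mediator-origin legs.

## Estimators

All methods operate on first-order Wald ratios βʸⱼ/βˣⱼ with ratio variance
se²ʸⱼ/βˣⱼ² (no second-order or NOME-adjusted weights).

* **IVW** is computed as weighted regression through the origin of outcome
  on exposure betas with weights 1/se²ʸⱼ — algebraically the
  inverse-variance-weighted mean of the ratios. Fixed-effects
  SE = (Σwβˣ²)^−1/2; the multiplicative-random-effects SE multiplies this
  by max(1, √(Q/(J−1))), never shrinking below the fixed SE. Cochran's
  Q = Σwⱼ(βʸⱼ − β̂βˣⱼ)² is referred to χ²(J−1); Q p < 0.05 makes the
  multiplicative-random model primary (strict inequality: p = 0.05 keeps
  fixed effects).
* **MR-Egger** adds an intercept to the weighted regression after orienting
  all exposure betas non-negative; the slope is the pleiotropy-robust
  estimate under InSIDE, the intercept estimates the mean directional
  pleiotropic effect. Slope and intercept use a t reference with J−2 df
  and the estimated residual scale (the conventional unconstrained-σ fit).
  Other methods use the normal reference.
* **Weighted median**: ratios sorted ascending with normalized weights
  wⱼ = βˣⱼ²/se²ʸⱼ; cumulative percentiles pⱼ = Σₖ≤ⱼwₖ − wⱼ/2; the estimate
  linearly interpolates the ratios at p = 0.5.
* **Modes**: the mode of a normal-kernel density over the ratios, bandwidth
  = factor × 0.9·min(sd, MAD)·J^(−1/5) (modified Silverman rule; factor
  default 1, exposed), evaluated on a 512-point grid spanning the ratios
  ± 3 bandwidths. The weighted variant weights kernels by inverse ratio
  variance. Zero spread degenerates to the weighted median of the ratios.
* Median and mode SEs come from a seeded parametric bootstrap (default
  1000 resamples of both betas from their sampling normals). Bootstrap SEs
  are sign-symmetric in distribution only; the point estimates obey exact
  sign and scale equivariance.

Minimum instrument counts: 1 (Wald ratio, reported but never primary),
2 (IVW, median, modes), 3 (Egger). With ≥2 instruments the primary estimate
is the heterogeneity-gated IVW.

## MR-PRESSO

The global test computes RSS_obs = Σⱼ wⱼ(βʸⱼ − β̂₍₋ⱼ₎βˣⱼ)² with
leave-one-out IVW slopes, simulates `n_sim` outcome-beta vectors under the
no-pleiotropy model with the observed SEs, and reports the add-one
empirical p = (1 + #{RSS_sim ≥ RSS_obs})/(n_sim + 1), which is never 0 and
never exceeds 1. Per-variant squared residuals are referred to their own
simulated distributions with Bonferroni adjustment; flagged variants below
the significance level (default 0.05) are outliers. Note the adjusted
empirical p has a floor of J/(n_sim + 1): outlier flagging at α = 0.05 with
J = 20 requires n_sim ≥ 400 (default 1000). When outliers are flagged, the
distortion test compares the all-variant vs outlier-free IVW difference to
its permutation distribution over random outlier-sized removals. When the
global test fires and outliers are flagged, the pipeline re-runs all
methods on the outlier-free set and reports that fit as primary alongside
the uncorrected one.

## Mediation

For pathway coefficients (β₀, β₁, β₂) with SEs: mediated effect β₁β₂ with
first-order (Sobel) delta variance β₂²se₁² + β₁²se₂² (an exact
second-order + se₁²se₂² term by flag); direct effect β₀ − β₁β₂; proportion
β₁β₂/β₀ with delta CI via the gradient (−β₁β₂/β₀², β₂/β₀, β₁/β₀) and a
seeded Monte-Carlo percentile alternative approximating
distribution-of-the-product intervals. When sign(β₁β₂) ≠ sign(β₀) the
mediation is inconsistent: the proportion is reported NA while the mediated
effect and its CI are still given. β₀ = 0 makes the proportion undefined
(error). The p-value is the two-sided normal (Sobel) test, conservative
near the null of either path. Coefficient SEs may be omitted when only the
point decomposition is wanted — the published worked-example table prints
none — in which case uncertainty operations raise rather than guess.

Two classical assumptions of this decomposition — no mediator–outcome
confounding and no exposure–mediator interaction — are untestable from
summary data and are taken as modeling assumptions.

The bundled worked example carries a known editorial wrinkle: the source
table prints a total effect of 0.3017 for the CD39 rows while the matching
abstract odds ratio 1.0306 implies ln(1.0306) = 0.0301 — a decimal-place
misprint. The package does not silently "fix" inputs; the worked example
and the acceptance script construct β₀ = ln(OR) from the odds ratio, which
reproduces the printed proportions (8.43%, 5.1%) to within the rounding of
the printed coefficients, whereas β₀ = 0.3017 would not.

## Synthetic data

`SimConfig` defines the study conditions. Defaults emulate the
summary-data regime of molecular-trait MR: 30 independent instruments; a
small exposure cohort (n = 3757), a mid-sized quantitative mediator cohort
(n = 8293), and a case-control outcome cohort (n = 20,000, prevalence 0.1,
within the 9857–423,523 span typical of disease GWAS); MAF uniform on
(0.2, 0.5); per-variant exposure effects of magnitude 0.2 trait-SD per
allele (uniform ±20% spread, random sign), strong enough that planted
instruments clear F > 10 with margin under the exposure cohort's sampling
error. Causal truth defaults to β₀ = 0.2, β₁ = 0.3, β₂ = 0.2.

Two generators share this configuration and one master seed
(`numpy.random.SeedSequence` splitting; identical configs are
bit-reproducible):

* `simulate_triplet` draws genotypes in three disjoint cohorts (honoring
  the two-sample assumption; an overlap fraction exists for robustness
  experiments only), builds X = Σγⱼ Gⱼ + ε (SD 1),
  M = β₁X + Σδⱼ Gⱼ + ε (SD 1), and an outcome liability
  (β₀ − β₁β₂)X + β₂M + Σαⱼ Gⱼ + ε dichotomized at the prevalence
  threshold, then computes per-variant OLS (quantitative) or logistic
  (binary) summary statistics, and emits the empirical exposure-sample LD
  matrix. The mediator-specific δ variants are a deliberate extension of
  the plain chain model: without the mediator's own instruments the
  mediator→outcome leg would be inestimable. Infeasible variance budgets
  (genetic + causal contributions ≥ 0.95 of a unit-variance trait) raise a
  configuration error.
* `simulate_summary_direct` draws the per-variant summary betas directly
  from the same effect model, with SEs 1/√(n·v·2p(1−p)) (v = prevalence ×
  (1 − prevalence) for binary traits, else 1) — the fast path for
  large-replicate calibration suites.

Directional pleiotropy is injected by giving a fraction `prop_invalid` of
exposure variants direct outcome effects αⱼ ~ N(pleio_mean, pleio_sd);
balanced pleiotropy uses mean 0. LD blocks (size, within-block r²) use a
Gaussian copula at the individual level and tagged effects plus correlated
noise at the summary level; realized allelic correlation is mildly
attenuated relative to the latent one.

`simulate_screen_grid` builds a multi-trait panel (each trait owns its own
instruments; every table covers the union panel so reverse legs are
estimable) with exactly one planted mediated triple; all other trait pairs
are null. Outcome traits' own-variant effects are doubled so they clear
genome-wide-style selection under case-control SEs.

What the generators deliberately do **not** emulate: palindromic or
strand-ambiguous alleles (harmonization's palindrome logic is exercised by
hand-built fixtures instead, so that planted instruments are never silently
dropped), allele-frequency mismatch between cohorts, population
stratification, winner's-curse selection from genome-wide panels, and
realistic genetic architectures (polygenicity, MAF-dependent effects).
Passing tests therefore demonstrate correctness of the estimators and
pipeline logic under their stated assumptions, not robustness to every
pathology of real consortium data.

## Calibration experiments and problem sizes

The replicated experiments in `mrmediate.experiments` use these sizes,
chosen to put Monte-Carlo error well inside the assertion bands:

* IVW CI coverage: 200 replicates of the full selection→harmonize→IVW
  pipeline at default conditions. The fixed-effects interval is the one
  calibrated: the generator is homogeneous by construction, and gating on
  Cochran's Q would add conservatism (wider intervals) in the replicates
  where Q fires by chance.
* Egger intercept type-I error: 1000 direct-summary replicates in a
  dedicated high-instrument-strength regime (exposure n = 50,000, effect
  spread (0.3, 1.7)×scale, trait-increasing orientation, I²_GX ≈ 0.99).
  This is deliberate: with weak spread in the instrument–exposure effects
  the intercept test is genuinely miscalibrated — regression dilution
  leaks the causal slope into the intercept (we observe ≈8.5% rejection at
  nominal 5% at the desk-default conditions) — and a type-I-error
  measurement is meaningful only in the NOME regime the estimator assumes.
  The companion recovery experiment (30% invalid instruments, mean
  pleiotropic effect 0.05) checks the mean intercept against the analytic
  expectation 0.3 × 0.05 = 0.015.
* Mediation delta-CI coverage: 1000 coefficient redraws at z-scores ≥ 3,
  where the first-order interval is close to nominal.
* Median-vs-IVW robustness: 200 replicates with 30% directionally
  pleiotropic instruments (mean 0.05, trait-increasing orientation, so the
  pleiotropy is genuinely directional rather than sign-cancelling).
* MR-PRESSO: 100 runs, n_sim = 1000, J = 20, spike of 10 ratio-units.
* Pathway recovery: 50 replicate 5×3×2 grids with reduced bootstrap
  (n_boot = 100) and PRESSO simulation (n_sim = 200) counts per leg, which
  affect only reported SEs and diagnostics, not the IVW-based screening
  decisions.

## Numerical choices

* P-values from the normal reference everywhere except Egger (t, J−2).
* Bootstrap defaults n_boot = 1000, master seed 20240101, both exposed.
* Clumping ties broken lexicographically; cross-chromosome pairs never
  clump; window is |Δpos| ≤ window_kb × 1000 on the same chromosome.
* BH adjustment (statsmodels step-up) is applied within each
  (outcome, leg-type) family across exposures; the candidate rule defaults
  to raw primary p < 0.05 per leg with a strict BH variant available, and
  excludes a pathway when the reverse outcome→exposure leg has p < 0.05.
  An Egger-intercept p < 0.05 downgrades (flags) a leg without excluding it.
* `direct + indirect = β₀` holds exactly up to one floating-point rounding
  of (β₀ − p) + p.
* Degenerate inputs: zero exposure beta (Wald ratio), zero spread in
  exposure betas (Egger), zero total effect (proportion) raise typed
  errors; empty clump output and empty candidate sets are valid results.

## Known limitations

* First-order ratio weights throughout; no MR-RAPS, multivariable MR,
  Steiger filtering, or CAUSE — the method battery is fixed at the six
  named estimators plus the Wald fallback.
* The liability-threshold/logistic pairing in `simulate_triplet` means
  simulated "true" log-odds effects differ from liability effects by a
  link-dependent factor (~1.9 at 10% prevalence); ratio quantities such as
  the mediation proportion are invariant to it, and the calibration suites
  use the summary-direct generator where β₀ is planted on the reported
  scale directly.
* LD is supplied, not estimated from reference panels; no proxy-variant
  lookup, liftover, or GWAS-VCF parsing.
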