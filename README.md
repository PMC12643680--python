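# mrmediate

Mediating two-sample Mendelian randomization (MR) for summary-level GWAS
data: does an exposure trait (say, an immune-cell surface-marker phenotype)
causally affect a disease outcome (a lung-cancer subtype), and how much of
that effect flows through a circulating mediator (an inflammatory cytokine)?

The package implements the full screening-and-mediation pipeline:

* **Instrument selection** — p-value threshold, greedy LD clumping within a
  genomic window, and instrument-strength filtering with
  R² = β²/(β² + se²·n) and F = R²(n−2)/(1−R²), excluding F < 10.
* **Six MR estimators** on harmonized summary statistics — IVW under
  fixed and multiplicative-random-effects error models, MR-Egger regression,
  the weighted median, and the simple and weighted mode estimators (plus the
  single-variant Wald ratio fallback). Effects are reported per SD of the
  exposure, with odds ratios exp(β).
* **Sensitivity diagnostics** — Cochran's Q (p < 0.05 switches the primary
  IVW model to multiplicative random effects), the Egger intercept test for
  directional pleiotropy, and MR-PRESSO (simulation-based global test,
  per-variant outlier flagging, distortion test).
* **Three-leg pathway screening** — exposure→outcome, exposure→mediator and
  mediator→outcome legs, reverse-direction checks, Benjamini–Hochberg
  adjustment, and candidate-pathway assembly.
* **Product-of-coefficients mediation** — mediated effect β₁·β₂ with
  delta-method (Sobel) confidence intervals, direct effect β₀ − β₁·β₂, and
  mediation proportion β₁·β₂/β₀, reported NA when the mediated and total
  effects disagree in sign (inconsistent mediation).
* **Synthetic GWAS generators** — individual-level and summary-level
  simulators with known causal structure, configurable pleiotropy, LD
  blocks, and disjoint cohorts, so every stage is testable without any
  external data download.

## The model

For a pathway X → M → Y estimated from three two-sample MR fits,

```
indirect (mediated) effect  = β₁ · β₂
direct effect               = β₀ − β₁ · β₂
mediation proportion        = β₁ · β₂ / β₀
Var(β₁β₂) ≈ β₂² se₁² + β₁² se₂²          (first-order delta method)
```

where β₀ is the total exposure→outcome effect (log-odds per SD), β₁ the
exposure→mediator effect (SD per SD) and β₂ the mediator→outcome effect
(log-odds per SD). Each β comes from the leg's primary IVW fit; a genetic
variant enters a leg as an instrument only if it passes the selection
thresholds against the leg's exposure.

## Worked example

The numbered scripts under `analysis/` walk through the whole pipeline on
synthetic data. `analysis/06_mediation_worked_example.py` reproduces a
published immune-cell → cytokine → lung-cancer coefficient table from its
printed inputs (total-effect odds ratio per SD, β₁ and β₂):

```
                        exposure mediator outcome   beta0  beta1 beta2 direct_effect mediation_effect mediation_proportion_pct  consistent
     BAFF-R on IgD+ CD24+ B cell      MIF    LUAD 0.01666 -0.047 -0.05       0.01431          0.00235                    14.11        True
CD39 on CD39+ secreting CD4 Treg     IL-2    SCLC 0.03014 -0.043 -0.06       0.02756          0.00258                     8.56        True
CD39 on CD39+ secreting CD4 Treg     IL-6    SCLC 0.03014 -0.026 -0.06       0.02858          0.00156                    5.176        True
       CD28 on CD39+ CD4+ T cell    IL-16    LUSC 0.03295 -0.088  0.06       0.03823         -0.00528                       NA       False
```

Reading row 1: with a total effect of ln(1.0168) = 0.0167 log-odds of lung
adenocarcinoma per SD of BAFF-R expression, the MIF-mediated component
(−0.047)(−0.050) = 0.00235 accounts for 14.11% of the total. The IL-16 row
shows inconsistent mediation — a negative mediated effect against a positive
total effect — so its proportion is NA.

The same report is available from the command line:

```sh
mrmediate mediate --or0 1.0168 --beta1 -0.047 --beta2 -0.050
```

and `mrmediate simulate | mr | screen | report` drive the pipeline on files.

## Layout

```
src/mrmediate/    library: summary_io, iv_selection, mr_core, sensitivity,
                  mediation, pathway_screen, synthetic, experiments,
                  worked_example, report, cli
analysis/         numbered narrative drivers (simulate → select → estimate →
                  diagnose → screen → mediate)
tests/            pytest suite (unit, property, acceptance)
scripts/          acceptance.py
docs/methods.md   model, assumptions, simulation design, numerical choices
```
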