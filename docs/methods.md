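# Methods

## Setting and estimands

The package targets a nested case–control sample from a pregnancy cohort:
a binary outcome Y (e.g. preterm birth), an exposure biomarker A(t) and a
mediator biomarker M(t) measured in urine at visits t = 1, 2, 3,
time-invariant covariates V (maternal age, race/ethnicity, education,
insurance, pre-pregnancy BMI category) and urinary specific gravity L(t)
as a dilution covariate. Concentrations are natural-log transformed and
z-scored; effects are reported on the log-odds-ratio scale for a defined
exposure contrast (default: from one SD below the mean to the mean, or a
1-unit standardized increase at every visit for the longitudinal methods).

Identification rests on the usual counterfactual mediation assumptions: no
unmeasured confounding of the exposure–outcome, mediator–outcome and
exposure–mediator relations, and no mediator–outcome confounder affected
by exposure. For the longitudinal estimators the package additionally
assumes no time-varying confounding (specific gravity is a dilution proxy,
not a confounder), under which the g-formula for the randomized
interventional analogues of the natural effects reduces to the
longitudinal mediation formula and can be evaluated from marginal
structural models.

## Models and closed forms

Per-method models and effect expressions are listed in the README. Three
numerical details matter:

- **Rare-outcome approximation.** All odds-ratio decompositions assume the
  outcome is uncommon; `rare_ceiling` (default 0.10) triggers a warning
  when the IPW-weighted sample prevalence exceeds it. The Monte-Carlo
  g-formula evaluator (`effects_gformula_mc`) uses exact logistic
  probabilities and therefore quantifies the approximation error; on the
  default synthetic conditions (prevalence 0.08) the gap in the NIE is
  below 0.01 on the log-odds scale.
- **Joint mediator system.** Method 4 needs Var(M(1)+M(2)+M(3)) = σ²·1ᵀΣ1,
  so the three visit regressions are estimated jointly by iterated
  feasible GLS under ε ~ MVN(0, σ²Σ) with common variance and
  unit-diagonal unstructured correlation. Iteration alternates GLS
  coefficients and the weighted residual moment matrix, stops when the
  relative coefficient change falls below 1e-8 (cap 50 iterations), and
  fails loudly on a non-positive-definite correlation estimate. With Σ
  fixed to the identity the fit reproduces the separate per-visit
  least-squares fits exactly.
- **Logistic fitting.** Outcome models are fit by iteratively reweighted
  least squares with deviance-based step halving; divergence (coefficients
  beyond 1e4) or exhaustion of 100 iterations raises a convergence error
  carrying the step trace — perfectly separated data fail rather than
  returning garbage. Design matrices are rank-checked by pivoted QR and
  rank deficiencies are reported with the offending term names. Specific
  gravity is centered internally (values near 1.015 with SD below 0.01
  would otherwise make the design nearly collinear with the intercept);
  only intercepts change, and the covariate-fixing rule pins it at its
  mean (0 after centering).

## Design choices

- **Outcome models are unweighted by default.** Under case–control
  sampling, unweighted logistic regression estimates all slopes
  consistently (only the intercept absorbs the sampling fractions), and
  every effect expression uses slopes only. The mediator models, which are
  linear, are always IPW-weighted (cases 1, controls = source non-cases /
  controls sampled). `weighted_outcome=True` enables weighted outcome fits
  as a sensitivity analysis.
- **Imputation before transformation.** Missing visits are singly imputed
  on the concentration scale with the subject's geometric mean across
  observed visits (equivalently, the arithmetic mean of logs), then logs
  and z-scores are taken. Variants: `complete_case` and `population_mean`
  (per-visit geometric mean over observed subjects). Imputation is re-run
  inside every bootstrap replicate so its uncertainty propagates.
- **Standardization scopes.** Average-based methods z-score the
  subject-average logs; longitudinal methods use one pooled mean/SD across
  all visits per biomarker so that "one standardized unit at every visit"
  is a single common unit (`longitudinal_scope="per_visit"` switches to
  visit-specific scaling). Constants are recomputed on each (re)sample and
  are exposed through `StandardizationSpec` for external override and
  exact inversion.
- **Covariate fixing.** Where the direct effect depends on covariate
  levels (interaction methods), continuous covariates are fixed at their
  arithmetic means and categorical covariates at their declared reference
  levels; `most_frequent_reference=True` switches references to the modal
  categories as a sensitivity analysis.
- **Percent mediated** is reported rounded to the nearest integer in the
  tables, kept unrounded internally, and suppressed (flagged
  non-interpretable) when the direct and indirect effects have opposite
  signs. Its bootstrap interval is labelled descriptive: a percentile
  range of replicate ratios, not a calibrated CI.
- **Bootstrap.** Percentile intervals from subject-level resampling,
  stratified by case status so each replicate keeps exactly the original
  case and control counts; a master seed spawns one independent stream per
  replicate. Replicates whose refit fails are dropped and logged up to 1%
  of the requested replicates, beyond which the run aborts.
- **Interventional expectations in closed form.** Method 3/4 effects are
  evaluated analytically under the fitted normal mediator law rather than
  by simulation; a Monte-Carlo evaluator drawing mediator vectors from the
  fitted MVN is provided as an independent cross-check and agrees with the
  closed forms up to the rare-outcome approximation.

## Synthetic cohort generator

`generate_cohort` emulates the study conditions the analysis assumes and
returns the generating truths for recovery tests:

| quantity | default | rationale |
| --- | --- | --- |
| source cohort size | 2,000 | free parameter; large enough that 130 cases realize at 8% prevalence |
| case/control sample | 130 / 352 | nested case–control design of the emulated study |
| outcome prevalence | 0.08 (ceiling 0.10) | preterm birth is uncommon; intercept solved numerically on the realized linear predictor |
| log-exposure SD / within-subject corr. | 1.0 / 0.5 (exchangeable) | episodic urinary biomarker with moderate ICC |
| mediator model | log M(t) = 2.8 + 0.26·avg[log A(1..t)] + 10·(L−1.015) + small covariate effects + ε | linear in the running exposure average, mirroring the longitudinal mediator model |
| mediator error | σ = 0.6, exchangeable corr. 0.4 | within-subject correlation of an oxidative-stress marker |
| outcome slopes | β_ya = 0.088, β_ym = 0.14 per cumulative ln-unit, β_yi = 0 | direct effect 3·0.088 = 0.264 and indirect effect 0.14·3·0.26 ≈ 0.109 per ln-unit shift at every visit — magnitudes typical of the motivating setting |
| missingness | MCAR per visit at rates (0.015, 0.125, 0.15) | emulates visit-1/2/3 missing counts of roughly 2%, 13% and 15%; a subject never loses all three visits |
| specific gravity | mean 1.015, SD 0.0075, corr. 0.3 with log exposure | dilution proxy, not a confounder |

Closed-form truths (β_yi = 0): NDE = β_ya·Σδ(t) and
NIE = β_ym·Σ_t β_ma(t)·mean(δ(1..t)). With an interaction the truth is
computed by brute-force g-formula simulation (`true_effects_mc`, default
10⁶ counterfactual draws, exact logistic probabilities, covariates fixed
at reference levels).

What the generator does *not* emulate: informative (non-random)
missingness, laboratory batch effects, visit-timing variability, multiple
correlated exposure channels, nonlinear dose response, and real
within-subject biomarker trajectories. Passing tests demonstrate that the
estimators recover the effects of the stated data-generating process; they
do not certify behaviour under violations of it.

## Problem sizes used in validation

Parameter recovery uses fully observed cohorts of 50,000 subjects
(3-SE tolerance computed from the fitted covariances, plus the Monte-Carlo
error of the 10⁶-draw g-formula truth where applicable). Bootstrap
coverage uses 200 simulated case–control datasets of 482 subjects with 400
replicates each; the two directional comparisons use 30 and 50 datasets.
These sizes keep each check's Monte-Carlo error small relative to its
tolerance while keeping the default suite fast.

## Known limitations

- The directional sensitivity claims are fragile under the generator's
  completely-at-random missingness. With MCAR joint visit missingness,
  population-mean imputation behaves like shrinkage calibration (its
  imputed rows carry almost no leverage), so it tracks the complete-case
  indirect effect closely, while subject-mean imputation injects proxy
  error into the regressors and mildly attenuates it. Likewise, with
  visit-constant mediator slopes the average-based and longitudinal
  estimators are essentially equally efficient for a like-for-like
  contrast, so neither interval is systematically narrower. Both patterns
  are properties of the synthetic conditions, not implementation defects;
  the corresponding acceptance checks document this honestly.
- Percent mediated is unstable whenever the total effect is near zero
  (most visible in small complete-case subsamples with an interaction
  term).
- No analytic (delta-method or sandwich) standard errors are provided;
  inference is bootstrap-only by design.
- Time-varying confounders affected by prior exposure are out of scope:
  the longitudinal estimators implement the mediation formula, not the
  general sequential g-formula.
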