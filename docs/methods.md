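# Methods

## Model

Disease is defined by a continuous latent trait X crossing a fixed
threshold τ: diseased iff X ≥ τ (an individual exactly at τ counts as
diseased; under a continuous trait this is a probability-zero event, but
the convention also fixes tie handling for rounded simulated values).
X follows a finite normal mixture Σ_k w_k N(μ_k, σ_k²); the unimodal
case is the length-one mixture.  The test observes Z = X + b + ε with
ε ~ N(0, σ_e²), independent of X, and calls the test positive iff
Z ≥ t.  By default the test cut-off t equals the disease threshold τ
(the test is the thresholded estimate of the trait); a distinct t is
supported.

The error model is additive, homoscedastic, zero-mean Gaussian.  This is
the minimal error process consistent with smooth prevalence–performance
curves; heteroscedastic or trait-dependent error, differential
misclassification, imperfect reference standards and verification bias
are out of scope.

## Exact performance

Within component k, (X, Z) is bivariate normal with correlation
ρ_k = σ_k/√(σ_k² + σ_e²).  The four cells of the (disease, test) table
are orthant probabilities, and

  sensitivity = Σ_k w_k P_k(X ≥ τ, Z ≥ t) / Σ_k w_k P_k(X ≥ τ),

analogously for specificity.  The orthant probability is computed from
the bivariate normal CDF written in terms of Owen's T function, which is
accurate to ~1e-15 and — unlike generic multivariate-normal CDF routines
— remains stable as ρ → 1 (small σ_e).  For σ_e/σ_k below 1e-12 the
exact noise-free limit is substituted; the discontinuity this introduces
is far below every tolerance in the package.  An independent adaptive
quadrature engine (∫ P(test | X = x) f(x) dx with breakpoints at the
transition x ≈ t − b, absolute tolerance 1e-12) is provided and agrees
with the orthant engine to ~1e-10; the tests use it as the cross-check.

Likelihood ratios and predictive values follow from (sensitivity,
specificity, prevalence) by their definitions and Bayes' rule.  A
perfect-specificity test has LR+ = +∞ (a legitimate limit, not an
error); the 0/0 forms raise.  Internal values are never rounded;
display rounding (half away from zero, matching conventional clinical
reporting) lives in `percent`/`round_half_away` only.

## Default study conditions

* Threshold τ = 7 trait units (e.g. fasting glucose 7.0 mmol/L).
* Unimodal scenario: σ = 1; the mean is set as μ = τ − Φ⁻¹(1 − p) to hit
  a target prevalence p.  With these defaults μ = 5 gives prevalence
  2.275% (displays as 2.3%) and μ = 6.99 gives 49.6%.
* Bimodal scenario: modes N(4, 1) and N(9, 1); prevalence is targeted by
  the closed-form weight on the high mode (feasible range ≈ [0.135%,
  97.7%]).  The wide mode separation leaves few individuals near τ,
  which is what drives the higher accuracy at matched prevalence.
* Measurement error: σ_e is not a free dial; the reference value is
  calibrated once so that the unimodal model at 20% prevalence has
  analytic specificity 95%, giving σ_e ≈ 0.3125 and sensitivity 85.45%
  (85% to the nearest percent).  Calibration is bracketed Brent
  root-finding on the monotone map σ_e ↦ metric (xtol 1e-10, initial
  bracket [0, 10σ] doubled as needed); both sensitivity and specificity
  decrease monotonically in σ_e from 1 toward a large-noise limit, so a
  target below that limit is reported as infeasible together with the
  attainable range.
* Sweeps: 49 equally spaced prevalences from 2% to 50% (the bimodal
  sweep uses 5%–45% where needed to stay well inside its feasible
  range).  Analytic mode is the default and is bit-deterministic;
  simulation mode reproduces it within binomial sampling error.

Under these conditions the unimodal sweep over 2%–50% spans sensitivity
79.2%–90.4% (11.2 percentage points), specificity 90.4%–99.1%, and an
LR+ fold change of 9.06.  Larger swings — order-of-magnitude LR changes
and tens of percentage points of sensitivity — appear when the sweep is
extended to rarer-disease settings (e.g. LR+ fold 15.3 from 1%, 95 from
0.1%; sensitivity → 50% as prevalence → 0, because the diseased then
concentrate just above τ).  The quoted ranges are properties of this
calibrated reconstruction, computed by `analysis/03_prevalence_sweeps.py`.

## Synthetic cohorts

Cross-sectional cohorts draw x from the population model, z from the
measurement model, and classify both against τ.  Case-control cohorts
fix (n_cases, n_controls) and draw cases from the case population
conditional on X ≥ τ and controls from the control population
conditional on X < τ, by batched rejection sampling (an error is raised
when the truncation region's mass is below 1e-12).  With well-separated
case and control populations this reproduces the familiar inflation of
apparent accuracy in case-control designs.

Covariate effects, used for calibration studies of the subgroup
toolkit, enter as one of three declared generative modes for a named
standard-normal covariate: a linear shift of the trait mean, a linear
shift of log σ_e, or a direct logistic model for the test result within
each disease class (`logit_test`).  The third mode exists so that
logistic-recovery experiments have an exactly-known generative
coefficient; the first two change test performance through the latent
trait, where the induced logistic coefficient has no closed form.
Covariate effects are limited to cross-sectional designs.

All sampling uses per-call `numpy.random.Generator` (PCG64) instances
derived from an explicit integer seed via `SeedSequence`; there is no
global RNG state, and equal seeds give byte-identical cohorts.

What the generator does **not** emulate: real traits are rarely exact
normal mixtures, real error is rarely homoscedastic or Gaussian, disease
is rarely a sharp threshold on one dimension, and reference standards
are imperfect.  Passing tests therefore demonstrate internal
correctness of the machinery and the qualitative mechanisms, not
quantitative predictions for any particular clinical test.

## Subgroup toolkit

* Stratified metrics: per-stratum 2×2 tabulation; pooled sensitivity is
  the diseased-share-weighted combination of stratum sensitivities.
* Homogeneity: Pearson χ² of stratum × test-result within a disease
  class, no continuity correction by default (Yates optional); expected
  cells below 5 produce a warning, not an error.
* ROC/AUC: full threshold sweep (no convex simplification), trapezoidal
  area — identical to the Mann–Whitney estimate with ties counted half;
  standard error by Hanley–McNeil (Q1 = A/(2−A), Q2 = 2A²/(1+A)).
* Critical ratio: z = (A₁ − A₂)/√(se₁² + se₂²) referred to the standard
  normal.  The independent-samples SE is used because strata are
  disjoint; the correlated-curves variant and DeLong comparison are
  deliberately out of scope.
* Logistic performance models: test positivity regressed on covariates
  separately among diseased (→ sensitivity) and non-diseased (→ 1 −
  specificity), Newton/IRLS to tolerance 1e-8, at most 100 iterations;
  complete separation or non-convergence raises with the offending
  class.  Predictions at covariate values carry delta-method standard
  errors.

## Numerical choices and limitations

* Proportion CIs, when requested, use the Wilson score method only.
* Confusion-table inputs must have positive margins; every degenerate
  configuration raises an error naming the undefined quantity rather
  than returning NaN.
* The bimodal model at 20% prevalence with the calibrated σ_e gives
  sensitivity 98.8% and specificity 99.8% — the direction and magnitude
  of the matched-prevalence contrast with the unimodal model (85%/95%)
  is the robust statement; the exact bimodal percentages depend on the
  chosen mode separation.
* Analysis and test problem sizes (10⁴–10⁶ draws) were chosen so that
  binomial sampling error is well below the effects being demonstrated
  while the full suite runs in seconds.
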