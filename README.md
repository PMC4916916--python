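# spectrum-effect

Simulation and analysis of the **spectrum effect** — the variation in
diagnostic, screening and risk-prediction test performance across
populations with different disease prevalence and severity mixes — for
biostatisticians, epidemiologists and anyone evaluating a test outside
the population it was developed in.

## The model

A continuous latent trait X (true fasting glucose, true systolic blood
pressure, true 10-year risk, ...) defines disease by a fixed threshold:
an individual is diseased iff X ≥ τ.  The test dichotomises an
error-prone estimate Z of X at the same cut-off, with additive Gaussian
error:

    X ~ Σ_k w_k · Normal(μ_k, σ_k²)        (unimodal or bimodal mixture)
    Z = X + ε,   ε ~ Normal(0, σ_e²)
    disease = 1{X ≥ τ},   test = 1{Z ≥ τ}

Since (X, Z) is bivariate normal within each component with correlation
ρ = σ_k / √(σ_k² + σ_e²), sensitivity P(Z ≥ τ | X ≥ τ) and specificity
P(Z < τ | X < τ) are exact orthant probabilities (evaluated via Owen's T
function, cross-checked by adaptive quadrature).  Only individuals near
the threshold can be misclassified, so accuracy depends on how much of
the population sits near τ — which changes with prevalence and with the
shape of the trait distribution.  Sensitivity, specificity and
likelihood ratios are therefore *not* portable constants of a test.

The package provides:

* `metrics` — the 2×2-table measures (sensitivity, specificity, LR±,
  PPV/NPV) and odds-form Bayes updating of pre-test to post-test
  probability;
* `population` — normal-mixture trait models with analytic prevalence
  P(X ≥ τ) and its inversions (mean shift; mixture-weight solve);
* `measurement` — exact and Monte-Carlo test performance, and
  calibration of σ_e to a target operating point;
* `sweep` — performance-versus-prevalence curves under the mean-shift
  and mixture-weight mechanisms;
* `simulate` — synthetic cohorts, cross-sectional or case-control
  (cases and controls drawn from different populations truncated at τ),
  with optional covariate effects;
* `subgroup` — stratified metrics, χ² homogeneity tests, empirical
  ROC/AUC with Hanley–McNeil standard errors, the critical-ratio
  comparison of two AUCs, and within-class logistic models of test
  performance;
* a `spectrum-effect` CLI (`metrics`, `bayes`, `performance`, `sweep`,
  `simulate`, `subgroup`).

## Worked example

```python
from spectrum_effect import (
    MeasurementModel, analytic_test_performance, calibrate_error_sd,
    predictive_values_at_prevalence, scenario1_model,
)

# unimodal trait, threshold 7, mean set for 20% prevalence
pop = scenario1_model(0.20)

# calibrate the error sd so analytic specificity is exactly 95%
sigma_e = calibrate_error_sd(pop, "specificity", 0.95)
perf = analytic_test_performance(pop, MeasurementModel(sigma_e))
print(f"{sigma_e:.4f}  {perf.sensitivity:.4f}  {perf.specificity:.4f}")
# 0.3125  0.8545  0.9500

# the same test's PPV at 10% prevalence, from two published accuracy pairs
print(predictive_values_at_prevalence(0.97, 0.97, 0.10)[0])  # 0.7822... -> 78%
print(predictive_values_at_prevalence(0.72, 0.92, 0.10)[0])  # 0.5000... -> 50%
```

The calibrated operating point is sensitivity 85%, specificity 95% at
20% prevalence.  The two PPV lines show why a positive result means 78%
post-test probability under hospital case-control accuracy figures but
only 50% under general-population figures, at the identical 10%
prevalence: the accuracy pair itself carries the spectrum of the study
population.

The numbered scripts under `analysis/` run the full study: the Bayes
worked example (01), the operating-point calibration (02), the
prevalence sweeps under both mechanisms (03), the case-control versus
cross-sectional contrast (04), and subgroup detection with χ², ROC
critical ratio and logistic modelling (05).  Each writes its tables
under `results/`.

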