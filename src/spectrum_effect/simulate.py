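"""Synthetic cohorts with the statistical structure of the latent-trait
threshold model.

Cross-sectional cohorts draw the trait X from the population model, the
score Z from the measurement model, and classify both against the
threshold.  Case-control cohorts instead fix the case/control counts and
draw cases from a (possibly different) population conditional on X >= tau
and controls conditional on X < tau — the design in which diseased and
non-diseased individuals come from different clinical populations, which
widens their separation and inflates apparent accuracy.

Optional covariate effects let a named standard-normal covariate shift

* the individual's trait mean (``trait_mean``),
* the log of the individual's error sd (``log_error_sd``), or
* the log-odds of a positive test within each disease class
  (``logit_test`` — the test result is then drawn from a logistic model
  rather than by thresholding Z, giving cohorts with a known generative
  logistic coefficient for calibration studies).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import Cohort
from .measurement import MeasurementModel
from .population import PopulationModel, analytic_prevalence, sample_population

__all__ = [
    "CovariateEffect",
    "LogitTestModel",
    "ScenarioConfig",
    "generate_cohort",
    "generate_case_control",
]

_EFFECT_TARGETS = ("trait_mean", "log_error_sd")


@dataclass(frozen=True)
class CovariateEffect:
    """Linear effect of one standard-normal covariate on the generative
    process: ``on`` is 'trait_mean' or 'log_error_sd'."""

    on: str
    coef: float

    def __post_init__(self) -> None:
        if self.on not in _EFFECT_TARGETS:
            raise ValueError(
                f"covariate effect target must be one of {_EFFECT_TARGETS}, got {self.on!r}"
            )


@dataclass(frozen=True)
class LogitTestModel:
    """Direct logistic model for the test result within disease classes.

    P(test+ | class, covariates c) = expit(intercept + sum_j coef_j c_j),
    with separate intercept/coefficients among diseased and non-diseased.
    """

    intercept_diseased: float
    intercept_nondiseased: float
    coefs_diseased: dict[str, float] = field(default_factory=dict)
    coefs_nondiseased: dict[str, float] = field(default_factory=dict)

    @property
    def covariate_names(self) -> list[str]:
        return sorted(set(self.coefs_diseased) | set(self.coefs_nondiseased))


@dataclass
class ScenarioConfig:
    """Everything needed to generate one synthetic cohort."""

    scenario: str  # "scenario1" | "scenario2" | "case-control" | "custom"
    measurement: MeasurementModel
    seed: int
    population: PopulationModel | None = None
    n: int | None = None
    n_cases: int | None = None
    n_controls: int | None = None
    case_model: PopulationModel | None = None
    control_model: PopulationModel | None = None
    covariate_effects: dict[str, CovariateEffect] = field(default_factory=dict)
    logit_test: LogitTestModel | None = None

    def __post_init__(self) -> None:
        if self.scenario == "case-control":
            if self.n is not None or self.population is not None:
                raise ValueError("case-control design takes n_cases/n_controls, not n/population")
            for name in ("n_cases", "n_controls", "case_model", "control_model"):
                if getattr(self, name) is None:
                    raise ValueError(f"case-control design requires {name}")
        else:
            if self.population is None or self.n is None:
                raise ValueError(f"{self.scenario!r} design requires population and n")
            if self.n_cases is not None or self.n_controls is not None:
                raise ValueError("n_cases/n_controls only apply to the case-control design")

    def provenance(self) -> dict:
        return {
            "scenario": self.scenario,
            "measurement": (self.measurement.error_sd, self.measurement.bias),
            "seed": self.seed,
            "n": self.n,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
        }


def _covariate_frame(
    cfg: ScenarioConfig, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    names = sorted(cfg.covariate_effects)
    if cfg.logit_test is not None:
        names = sorted(set(names) | set(cfg.logit_test.covariate_names))
    return pd.DataFrame({name: rng.standard_normal(n) for name in names})


def _assemble(
    cfg: ScenarioConfig, x: np.ndarray, cov: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    tau = _threshold_of(cfg)
    mean_shift = np.zeros(len(x))
    log_sd_shift = np.zeros(len(x))
    for name, eff in cfg.covariate_effects.items():
        if eff.on == "trait_mean":
            mean_shift += eff.coef * cov[name].to_numpy()
        else:
            log_sd_shift += eff.coef * cov[name].to_numpy()
    x = x + mean_shift
    sd_i = cfg.measurement.error_sd * np.exp(log_sd_shift)
    z = x + cfg.measurement.bias + sd_i * rng.standard_normal(len(x))
    disease = (x >= tau).astype(int)
    if cfg.logit_test is None:
        test = (z >= tau).astype(int)
    else:
        lt = cfg.logit_test
        eta = np.where(disease == 1, lt.intercept_diseased, lt.intercept_nondiseased)
        for name in lt.covariate_names:
            c = cov[name].to_numpy()
            eta = eta + np.where(
                disease == 1,
                lt.coefs_diseased.get(name, 0.0) * c,
                lt.coefs_nondiseased.get(name, 0.0) * c,
            )
        test = (rng.random(len(x)) < expit(eta)).astype(int)
    df = pd.DataFrame({"x": x, "z": z, "disease": disease, "test": test})
    for name in cov.columns:
        df[name] = cov[name].to_numpy()
    return df


def _threshold_of(cfg: ScenarioConfig) -> float:
    if cfg.scenario == "case-control":
        return cfg.case_model.threshold
    return cfg.population.threshold


def generate_cohort(cfg: ScenarioConfig) -> Cohort:
    """Generate a cohort under ``cfg``; dispatches on the sampling design."""
    if cfg.scenario == "case-control":
        return generate_case_control(cfg)
    ss = np.random.SeedSequence(cfg.seed).generate_state(3)
    x = sample_population(cfg.population, cfg.n, int(ss[0]))
    cov = _covariate_frame(cfg, cfg.n, np.random.default_rng(int(ss[1])))
    df = _assemble(cfg, x, cov, np.random.default_rng(int(ss[2])))
    return Cohort(data=df, design="cross-sectional", provenance=cfg.provenance())


def _sample_truncated(
    model: PopulationModel, n: int, above: bool, seed: int
) -> np.ndarray:
    """Rejection-sample n values of X conditional on X >= tau (or < tau)."""
    mass = analytic_prevalence(model)
    if not above:
        mass = 1.0 - mass
    if mass < 1e-12:
        side = "X >= threshold" if above else "X < threshold"
        raise ValueError(f"truncation region {side} has negligible mass ({mass!r})")
    rng = np.random.default_rng(seed)
    out: list[np.ndarray] = []
    got = 0
    batch = max(int(2 * n / mass), 100)
    while got < n:
        draws_seed = int(rng.integers(0, 2**31 - 1))
        draws = sample_population(model, batch, draws_seed)
        keep = draws[draws >= model.threshold] if above else draws[draws < model.threshold]
        out.append(keep)
        got += len(keep)
    return np.concatenate(out)[:n]


def generate_case_control(cfg: ScenarioConfig) -> Cohort:
    """Fixed-size case-control cohort: cases truncated above the threshold
    from the case population, controls truncated below from the control
    population."""
    if cfg.covariate_effects or cfg.logit_test is not None:
        raise ValueError("covariate effects are not supported in the case-control design")
    if cfg.case_model.threshold != cfg.control_model.threshold:
        raise ValueError("case and control models must share the disease threshold")
    if cfg.n_cases < 1 or cfg.n_controls < 1:
        raise ValueError("n_cases and n_controls must be positive")
    ss = np.random.SeedSequence(cfg.seed).generate_state(3)
    x_cases = _sample_truncated(cfg.case_model, cfg.n_cases, above=True, seed=int(ss[0]))
    x_controls = _sample_truncated(cfg.control_model, cfg.n_controls, above=False, seed=int(ss[1]))
    x = np.concatenate([x_cases, x_controls])
    tau = cfg.case_model.threshold
    rng = np.random.default_rng(int(ss[2]))
    z = x + cfg.measurement.bias + cfg.measurement.error_sd * rng.standard_normal(len(x))
    df = pd.DataFrame(
        {
            "x": x,
            "z": z,
            "disease": (x >= tau).astype(int),
            "test": (z >= tau).astype(int),
        }
    )
    prov = cfg.provenance()
    return Cohort(data=df, design="case-control", provenance=prov)
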