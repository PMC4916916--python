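"""Accuracy measures for binary tests and Bayes pre/post-test updating.

All quantities derive from the 2x2 confusion table (or directly from
sensitivity, specificity and prevalence):

* sensitivity  = P(test+ | diseased)      = TP / (TP + FN)
* specificity  = P(test- | not diseased)  = TN / (TN + FP)
* LR+          = sensitivity / (1 - specificity)
* LR-          = (1 - sensitivity) / specificity
* PPV, NPV     = P(diseased | test+), P(not diseased | test-), obtained
  from sensitivity, specificity and prevalence through Bayes' rule.

Likelihood ratios multiply pre-test odds to give post-test odds; with
``lr = LR+`` the post-test probability equals the PPV at the same
prevalence.  Internal values are never rounded; ``percent`` implements
the display-level rounding (half away from zero) used for reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ConfusionCounts",
    "PerformanceMetrics",
    "BayesUpdate",
    "confusion_from_labels",
    "performance_from_counts",
    "likelihood_ratios",
    "predictive_values_at_prevalence",
    "post_test_probability",
    "performance_from_rates",
    "wilson_interval",
    "round_half_away",
    "percent",
]


def round_half_away(value: float, decimals: int = 0) -> float:
    """Round with ties going away from zero (display convention).

    Python's built-in ``round`` uses banker's rounding; printed clinical
    percentages conventionally round 0.5 upward, so 78.5% -> 79%.
    """
    factor = 10.0 ** decimals
    scaled = abs(value) * factor
    rounded = math.floor(scaled + 0.5)
    return math.copysign(rounded / factor, value)


def percent(proportion_value: float, decimals: int = 0) -> float:
    """Express a proportion as a percentage rounded for display."""
    return round_half_away(100.0 * proportion_value, decimals)


@dataclass(frozen=True)
class ConfusionCounts:
    """The 2x2 table of test result against true disease status."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_nondiseased(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class PerformanceMetrics:
    """Sensitivity, specificity, likelihood ratios and predictive values
    at a stated prevalence."""

    sensitivity: float
    specificity: float
    lr_pos: float
    lr_neg: float
    ppv: float
    npv: float
    prevalence: float

    def as_dict(self) -> dict[str, float]:
        return {
            "prevalence": self.prevalence,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "lr_pos": self.lr_pos,
            "lr_neg": self.lr_neg,
            "ppv": self.ppv,
            "npv": self.npv,
        }


@dataclass(frozen=True)
class BayesUpdate:
    """A single pre-test -> post-test probability update via odds."""

    pretest_prob: float
    pretest_odds: float
    lr: float
    posttest_odds: float
    posttest_prob: float


def _check_proportion(value: float, name: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


def confusion_from_labels(
    truth: Sequence[int], test: Sequence[int]
) -> ConfusionCounts:
    """Tabulate the 2x2 table from paired binary vectors.

    ``truth`` is disease status, ``test`` the test result; both must
    contain only 0/1 entries and have equal length.
    """
    t = np.asarray(truth)
    r = np.asarray(test)
    if t.shape != r.shape or t.ndim != 1:
        raise ValueError(
            f"truth and test must be 1-d sequences of equal length, "
            f"got shapes {t.shape} and {r.shape}"
        )
    for name, arr in (("truth", t), ("test", r)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} contains non-binary entries")
    t = t.astype(bool)
    r = r.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(t & r)),
        fp=int(np.sum(~t & r)),
        fn=int(np.sum(t & ~r)),
        tn=int(np.sum(~t & ~r)),
    )


def likelihood_ratios(sensitivity: float, specificity: float) -> tuple[float, float]:
    """Positive and negative likelihood ratios from (sens, spec).

    A perfect specificity with positive sensitivity yields LR+ = +inf
    (legitimate perfect-test limit); the 0/0 forms are errors.
    """
    _check_proportion(sensitivity, "sensitivity")
    _check_proportion(specificity, "specificity")
    if specificity == 1.0:
        if sensitivity == 0.0:
            raise ZeroDivisionError(
                "LR+ is the undefined form 0/0 at sensitivity 0, specificity 1"
            )
        lr_pos = math.inf
    else:
        lr_pos = sensitivity / (1.0 - specificity)
    if specificity == 0.0:
        if sensitivity == 1.0:
            raise ZeroDivisionError(
                "LR- is the undefined form 0/0 at sensitivity 1, specificity 0"
            )
        lr_neg = math.inf
    else:
        lr_neg = (1.0 - sensitivity) / specificity
    return lr_pos, lr_neg


def predictive_values_at_prevalence(
    sensitivity: float, specificity: float, prevalence: float
) -> tuple[float, float]:
    """PPV and NPV at a given prevalence via Bayes' rule."""
    _check_proportion(sensitivity, "sensitivity")
    _check_proportion(specificity, "specificity")
    _check_proportion(prevalence, "prevalence")
    p_pos = sensitivity * prevalence + (1.0 - specificity) * (1.0 - prevalence)
    p_neg = specificity * (1.0 - prevalence) + (1.0 - sensitivity) * prevalence
    if p_pos == 0.0:
        raise ZeroDivisionError(
            "PPV undefined: no positive results possible "
            f"(sens={sensitivity}, spec={specificity}, prev={prevalence})"
        )
    if p_neg == 0.0:
        raise ZeroDivisionError(
            "NPV undefined: no negative results possible "
            f"(sens={sensitivity}, spec={specificity}, prev={prevalence})"
        )
    ppv = sensitivity * prevalence / p_pos
    npv = specificity * (1.0 - prevalence) / p_neg
    return ppv, npv


def post_test_probability(pretest_prob: float, lr: float) -> BayesUpdate:
    """Update a pre-test probability by a likelihood ratio via odds."""
    if not 0.0 <= pretest_prob < 1.0:
        raise ValueError(
            f"pretest_prob must lie in [0, 1) (odds undefined at 1), got {pretest_prob!r}"
        )
    if lr < 0.0:
        raise ValueError(f"likelihood ratio must be non-negative, got {lr!r}")
    pretest_odds = pretest_prob / (1.0 - pretest_prob)
    posttest_odds = pretest_odds * lr
    posttest_prob = posttest_odds / (1.0 + posttest_odds)
    return BayesUpdate(
        pretest_prob=pretest_prob,
        pretest_odds=pretest_odds,
        lr=lr,
        posttest_odds=posttest_odds,
        posttest_prob=posttest_prob,
    )


def performance_from_rates(
    sensitivity: float, specificity: float, prevalence: float
) -> PerformanceMetrics:
    """Assemble full metrics from (sens, spec, prevalence)."""
    lr_pos, lr_neg = likelihood_ratios(sensitivity, specificity)
    ppv, npv = predictive_values_at_prevalence(sensitivity, specificity, prevalence)
    return PerformanceMetrics(
        sensitivity=sensitivity,
        specificity=specificity,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        ppv=ppv,
        npv=npv,
        prevalence=prevalence,
    )


def performance_from_counts(
    cc: ConfusionCounts, prevalence: float | str = "from-counts"
) -> PerformanceMetrics:
    """Metrics from a 2x2 table.

    With ``prevalence="from-counts"`` the prevalence is the diseased
    fraction of the table and PPV/NPV are the raw column proportions;
    with a numeric prevalence, PPV/NPV are recomputed at that prevalence
    by Bayes' rule (the standard correction when the sampling design does
    not reflect the target population, e.g. case-control studies).
    """
    if cc.n_diseased == 0:
        raise ZeroDivisionError("sensitivity undefined: no diseased individuals (tp+fn=0)")
    if cc.n_nondiseased == 0:
        raise ZeroDivisionError("specificity undefined: no non-diseased individuals (fp+tn=0)")
    sens = cc.tp / cc.n_diseased
    spec = cc.tn / cc.n_nondiseased
    if isinstance(prevalence, str):
        if prevalence != "from-counts":
            raise ValueError(f"unknown prevalence mode {prevalence!r}")
        prev = cc.n_diseased / cc.total
    else:
        prev = float(prevalence)
        _check_proportion(prev, "prevalence")
    lr_pos, lr_neg = likelihood_ratios(sens, spec)
    ppv, npv = predictive_values_at_prevalence(sens, spec, prev)
    return PerformanceMetrics(
        sensitivity=sens,
        specificity=spec,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        ppv=ppv,
        npv=npv,
        prevalence=prev,
    )


def wilson_interval(successes: int, trials: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion."""
    if trials <= 0:
        raise ValueError("trials must be positive")
    alpha = 1.0 - confidence
    lo, hi = proportion_confint(successes, trials, alpha=alpha, method="wilson")
    return float(lo), float(hi)
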