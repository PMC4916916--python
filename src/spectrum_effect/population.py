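"""Latent-trait populations: normal mixtures with a disease threshold.

The underlying characteristic X (e.g. true fasting glucose, true systolic
blood pressure, or true 10-year risk) is modelled as a finite mixture of
normal components; disease is defined by X >= tau for a fixed threshold
tau (an individual exactly at the threshold counts as diseased).  True
prevalence is then the analytic upper-tail mass

    P(X >= tau) = sum_k w_k * (1 - Phi((tau - mu_k) / sigma_k)).

Two inversions target a desired prevalence:

* shift-mean: a single normal component whose mean is moved while the
  threshold stays fixed (different settings, same trait dispersion);
* mixture-weight: a two-component (bimodal) trait in which the weight on
  the high, "clearly diseased" component is varied (different case mixes,
  e.g. severity spectra or case-control composition).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Component",
    "PopulationModel",
    "analytic_prevalence",
    "mean_for_prevalence",
    "weight_for_prevalence",
    "sample_population",
    "scenario1_model",
    "scenario2_model",
    "SCENARIO2_LOW",
    "SCENARIO2_HIGH",
    "DEFAULT_THRESHOLD",
]

#: Disease threshold used throughout the default scenarios (e.g. fasting
#: glucose 7.0 mmol/L for diabetes).
DEFAULT_THRESHOLD = 7.0

#: Default bimodal components: a "clearly healthy" and a "clearly diseased"
#: mode well separated across the threshold, leaving few individuals near it.
SCENARIO2_LOW = (4.0, 1.0)
SCENARIO2_HIGH = (9.0, 1.0)

_WEIGHT_TOL = 1e-12


@dataclass(frozen=True)
class Component:
    """One normal mixture component (mean, sd, weight) in trait units."""

    mean: float
    sd: float
    weight: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"component sd must be positive, got {self.sd!r}")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError(f"component weight must lie in [0, 1], got {self.weight!r}")


@dataclass(frozen=True)
class PopulationModel:
    """Distribution of the latent trait X plus the disease threshold tau."""

    components: tuple[Component, ...]
    threshold: float

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("model needs at least one component")
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > _WEIGHT_TOL:
            raise ValueError(f"component weights must sum to 1, got {total!r}")

    @classmethod
    def single(cls, mean: float, sd: float, threshold: float) -> "PopulationModel":
        return cls(components=(Component(mean, sd, 1.0),), threshold=threshold)

    @classmethod
    def mixture(
        cls,
        components: Sequence[tuple[float, float, float]],
        threshold: float,
    ) -> "PopulationModel":
        return cls(
            components=tuple(Component(m, s, w) for m, s, w in components),
            threshold=threshold,
        )


def analytic_prevalence(model: PopulationModel) -> float:
    """True disease prevalence P(X >= tau) of a mixture model."""
    return float(
        sum(
            c.weight * stats.norm.sf(model.threshold, loc=c.mean, scale=c.sd)
            for c in model.components
        )
    )


def mean_for_prevalence(target_p: float, sd: float, threshold: float) -> float:
    """Mean of a single normal component achieving a target prevalence.

    Solves P(X >= tau) = p for mu:  mu = tau - sd * Phi^{-1}(1 - p).
    """
    if not 0.0 < target_p < 1.0:
        raise ValueError(
            f"target prevalence must be strictly inside (0, 1); the mean "
            f"diverges at the endpoints (got {target_p!r})"
        )
    if sd <= 0:
        raise ValueError(f"sd must be positive, got {sd!r}")
    return float(threshold - sd * stats.norm.ppf(1.0 - target_p))


def weight_for_prevalence(
    target_p: float,
    low_component: tuple[float, float],
    high_component: tuple[float, float],
    threshold: float,
) -> float:
    """Weight on the high component of a two-part mixture hitting a target
    prevalence.

    Mixture prevalence is linear in the weight w on the high component:
    w * p_high + (1 - w) * p_low = target, so w has a closed form.  The
    target must lie strictly between the two component tail masses.
    """
    p_low = float(stats.norm.sf(threshold, loc=low_component[0], scale=low_component[1]))
    p_high = float(stats.norm.sf(threshold, loc=high_component[0], scale=high_component[1]))
    if p_low >= p_high:
        raise ValueError(
            f"low component tail mass ({p_low:.4g}) must be below the high "
            f"component's ({p_high:.4g})"
        )
    if not p_low <= target_p <= p_high:
        raise ValueError(
            f"target prevalence {target_p!r} is infeasible for these components; "
            f"attainable range is [{p_low:.6g}, {p_high:.6g}]"
        )
    return (target_p - p_low) / (p_high - p_low)


def sample_population(model: PopulationModel, n: int, seed: int) -> np.ndarray:
    """Draw n trait values: component by weight, then a normal draw.

    Uses a dedicated ``numpy.random.Generator`` (PCG64) per call; the same
    seed always yields the identical sequence.
    """
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n!r}")
    rng = np.random.default_rng(seed)
    weights = np.array([c.weight for c in model.components])
    means = np.array([c.mean for c in model.components])
    sds = np.array([c.sd for c in model.components])
    membership = rng.choice(len(weights), size=n, p=weights)
    return means[membership] + sds[membership] * rng.standard_normal(n)


def scenario1_model(
    prevalence: float,
    sd: float = 1.0,
    threshold: float = DEFAULT_THRESHOLD,
) -> PopulationModel:
    """Single-normal population with the mean set for a target prevalence."""
    mu = mean_for_prevalence(prevalence, sd, threshold)
    return PopulationModel.single(mu, sd, threshold)


def scenario2_model(
    prevalence: float,
    low_component: tuple[float, float] = SCENARIO2_LOW,
    high_component: tuple[float, float] = SCENARIO2_HIGH,
    threshold: float = DEFAULT_THRESHOLD,
) -> PopulationModel:
    """Bimodal population with the high-mode weight set for a target prevalence."""
    w = weight_for_prevalence(prevalence, low_component, high_component, threshold)
    return PopulationModel.mixture(
        [
            (low_component[0], low_component[1], 1.0 - w),
            (high_component[0], high_component[1], w),
        ],
        threshold,
    )
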