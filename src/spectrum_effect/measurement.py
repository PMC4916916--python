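"""Observed score Z = X + error, and test performance under the threshold rule.

The test applies a cut-off to the error-prone estimate Z of the latent
trait X (a measured value or a predicted risk), while true disease status
is defined by X against the same threshold (a distinct test cut-off may be
supplied but defaults to the disease threshold).  Because only individuals
near the threshold can be misclassified, sensitivity and specificity
depend on how much probability mass the population places near the
cut-off — the mechanism behind the spectrum effect.

For each normal mixture component, (X, Z) is bivariate normal with
correlation sigma_X / sqrt(sigma_X^2 + sigma_e^2), so the four cells of
the (disease, test) table are orthant probabilities:

    sensitivity = P(Z >= t, X >= tau) / P(X >= tau)
    specificity = P(Z <  t, X <  tau) / P(X <  tau)

Both an orthant-probability engine and an adaptive-quadrature engine are
provided; they agree to ~1e-10 and either can serve as a cross-check of
the other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize, special, stats

from .metrics import (
    PerformanceMetrics,
    confusion_from_labels,
    performance_from_counts,
    performance_from_rates,
)
from .population import PopulationModel, analytic_prevalence

__all__ = [
    "MeasurementModel",
    "apply_measurement_error",
    "analytic_test_performance",
    "simulate_test_performance",
    "calibrate_error_sd",
]

# below this error-to-trait sd ratio the exact noise-free limit is used;
# the difference from the true value is O(ratio) and far below tolerance
_DEGENERATE_RATIO = 1e-12


def _bvn_cdf(h: float, k: float, rho: float) -> float:
    """P(U <= h, V <= k) for standard bivariate normal with correlation rho.

    Owen's T representation; numerically stable for |rho| arbitrarily
    close to 1 (unlike generic multivariate-normal CDF routines).
    """
    if rho >= 1.0:
        return float(stats.norm.cdf(min(h, k)))
    if rho <= -1.0:
        return float(max(stats.norm.cdf(h) + stats.norm.cdf(k) - 1.0, 0.0))
    eps = 1e-15  # nudge exact zeros off the removable singularity at h=0/k=0
    hh = h if abs(h) > eps else eps
    kk = k if abs(k) > eps else eps
    denom = np.sqrt((1.0 - rho) * (1.0 + rho))
    a1 = (kk - rho * hh) / (hh * denom)
    a2 = (hh - rho * kk) / (kk * denom)
    beta = 0.5 if hh * kk < 0 else 0.0
    val = (
        0.5 * (stats.norm.cdf(h) + stats.norm.cdf(k))
        - special.owens_t(hh, a1)
        - special.owens_t(kk, a2)
        - beta
    )
    return float(min(max(val, 0.0), 1.0))


@dataclass(frozen=True)
class MeasurementModel:
    """Additive, homoscedastic Gaussian error: Z = X + bias + e,
    e ~ Normal(0, error_sd)."""

    error_sd: float
    bias: float = 0.0

    def __post_init__(self) -> None:
        if self.error_sd < 0:
            raise ValueError(f"error_sd must be non-negative, got {self.error_sd!r}")


def apply_measurement_error(
    x: np.ndarray, mm: MeasurementModel, seed: int
) -> np.ndarray:
    """Observed scores z_i = x_i + bias + e_i with independent Gaussian e_i."""
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("trait values must be finite")
    rng = np.random.default_rng(seed)
    return x + mm.bias + mm.error_sd * rng.standard_normal(x.shape)


def _cell_probs_orthant(
    mean: float, sd: float, tau: float, t: float, mm: MeasurementModel
) -> tuple[float, float]:
    """(P(X >= tau, Z >= t), P(X < tau, Z < t)) for one normal component."""
    if mm.error_sd <= _DEGENERATE_RATIO * sd:
        # noise-free limit: Z = X + bias exactly
        a = (tau - mean) / sd
        b = (t - mm.bias - mean) / sd
        p00 = float(stats.norm.cdf(min(a, b)))
        p11 = float(stats.norm.sf(max(a, b)))
        return p11, p00
    sz = float(np.hypot(sd, mm.error_sd))
    rho = sd / sz
    a = (tau - mean) / sd
    b = (t - mean - mm.bias) / sz
    p00 = _bvn_cdf(a, b, rho)
    p11 = float(1.0 - stats.norm.cdf(a) - stats.norm.cdf(b) + p00)
    return max(p11, 0.0), max(p00, 0.0)


def _cell_probs_quadrature(
    mean: float, sd: float, tau: float, t: float, mm: MeasurementModel
) -> tuple[float, float]:
    """Same cell probabilities by adaptive 1-d quadrature over X."""
    if mm.error_sd <= _DEGENERATE_RATIO * sd:
        return _cell_probs_orthant(mean, sd, tau, t, mm)

    def p_test_neg(x: float) -> float:
        return stats.norm.cdf((t - x - mm.bias) / mm.error_sd)

    def f00(x: float) -> float:
        return stats.norm.pdf(x, loc=mean, scale=sd) * p_test_neg(x)

    def f11(x: float) -> float:
        return stats.norm.pdf(x, loc=mean, scale=sd) * (1.0 - p_test_neg(x))

    lo, hi = mean - 12 * sd, mean + 12 * sd
    tb = t - mm.bias  # the P(test-|X=x) transition is centred here

    def _pts(a: float, b: float) -> list[float]:
        cand = (tb - 10 * mm.error_sd, tb, tb + 10 * mm.error_sd)
        return [p for p in cand if a < p < b]

    a0, b0 = lo, min(tau, hi)
    p00, _ = integrate.quad(
        f00, a0, b0, epsabs=1e-12, epsrel=1e-12, limit=200, points=_pts(a0, b0)
    )
    a1, b1 = max(tau, lo), hi
    p11, _ = integrate.quad(
        f11, a1, b1, epsabs=1e-12, epsrel=1e-12, limit=200, points=_pts(a1, b1)
    )
    return float(p11), float(p00)


def analytic_test_performance(
    pop: PopulationModel,
    mm: MeasurementModel,
    test_threshold: float | None = None,
    engine: str = "orthant",
) -> PerformanceMetrics:
    """Exact sensitivity/specificity (and derived metrics) of the
    thresholded score Z in population ``pop``.

    ``engine`` selects the bivariate-normal orthant computation (default)
    or adaptive quadrature; results agree to ~1e-10.
    """
    cell = {"orthant": _cell_probs_orthant, "quadrature": _cell_probs_quadrature}[engine]
    tau = pop.threshold
    t = tau if test_threshold is None else test_threshold
    prev = analytic_prevalence(pop)
    if prev <= 0.0 or prev >= 1.0:
        raise ValueError(
            f"prevalence {prev!r} leaves an empty disease margin; "
            "sensitivity/specificity undefined"
        )
    p11 = p00 = 0.0
    for c in pop.components:
        c11, c00 = cell(c.mean, c.sd, tau, t, mm)
        p11 += c.weight * c11
        p00 += c.weight * c00
    sens = min(p11 / prev, 1.0)
    spec = min(p00 / (1.0 - prev), 1.0)
    return performance_from_rates(sens, spec, prev)


def simulate_test_performance(
    pop: PopulationModel,
    mm: MeasurementModel,
    n: int,
    seed: int,
    test_threshold: float | None = None,
) -> PerformanceMetrics:
    """Monte-Carlo estimate of test performance from n simulated individuals."""
    if n < 1:
        raise ValueError(f"n must be at least 1, got {n!r}")
    from .population import sample_population  # local to avoid cycle at import time

    ss = np.random.SeedSequence(seed).generate_state(2)
    x = sample_population(pop, n, int(ss[0]))
    z = apply_measurement_error(x, mm, int(ss[1]))
    t = pop.threshold if test_threshold is None else test_threshold
    disease = (x >= pop.threshold).astype(int)
    test = (z >= t).astype(int)
    cc = confusion_from_labels(disease, test)
    if cc.n_diseased == 0 or cc.n_nondiseased == 0:
        raise ValueError(
            f"simulated cohort of n={n} has an empty disease margin "
            f"(diseased={cc.n_diseased}); increase n for this prevalence"
        )
    return performance_from_counts(cc, prevalence="from-counts")


def calibrate_error_sd(
    pop: PopulationModel,
    target_metric: str,
    target_value: float,
    test_threshold: float | None = None,
) -> float:
    """Error sd at which the analytic metric hits a target operating point.

    Both sensitivity and specificity decrease monotonically in the error
    sd (from 1 at sd 0 toward a large-noise limit), so the inverse is
    found by bracketed Brent root-finding.  Targets below the large-noise
    limit are infeasible and raise with the attainable range.
    """
    if target_metric not in ("sensitivity", "specificity"):
        raise ValueError(f"target_metric must be sensitivity or specificity, got {target_metric!r}")
    if not 0.0 < target_value <= 1.0:
        raise ValueError(f"target_value must lie in (0, 1], got {target_value!r}")
    if target_value == 1.0:
        return 0.0

    sd_ref = max(c.sd for c in pop.components)

    def metric(s: float) -> float:
        perf = analytic_test_performance(pop, MeasurementModel(error_sd=s), test_threshold)
        return getattr(perf, target_metric)

    lo = 1e-6 * sd_ref
    hi = 10.0 * sd_ref
    m_hi = metric(hi)
    while m_hi > target_value:
        hi_next = 2.0 * hi
        m_next = metric(hi_next)
        if hi_next > 1e5 * sd_ref or abs(m_next - m_hi) < 1e-10:
            raise ValueError(
                f"target {target_metric} {target_value} is infeasible: the "
                f"attainable range is approximately ({m_next:.6f}, 1.0]"
            )
        hi, m_hi = hi_next, m_next
    root = optimize.brentq(lambda s: metric(s) - target_value, lo, hi, xtol=1e-10)
    if abs(metric(root) - target_value) > 1e-6:
        raise RuntimeError(
            f"calibration failed to reach {target_metric}={target_value} "
            f"(achieved {metric(root)!r})"
        )
    return float(root)
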