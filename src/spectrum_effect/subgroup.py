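"""Detecting spectrum effects in individual-level data.

Subgroup variation in test performance is examined by:

* stratifying sensitivity/specificity on the characteristic defining the
  subgroup;
* a Pearson chi-square test of association between subgroup and test
  result within the diseased (sensitivity) or non-diseased (specificity)
  class;
* subgroup-specific empirical ROC curves, compared through the critical
  ratio — the AUC difference divided by the standard deviation of that
  difference (Hanley-McNeil standard errors, independent subgroups),
  referred to the standard normal;
* logistic models of the test result on covariates, fitted separately
  within disease classes so that predictions are covariate-specific
  sensitivity (among diseased) and 1 - specificity (among non-diseased).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_curve

from .cohort import Cohort
from .metrics import PerformanceMetrics, confusion_from_labels, performance_from_counts

__all__ = [
    "Chi2Result",
    "RocCurve",
    "SubgroupComparison",
    "LogisticPerformanceFit",
    "stratified_performance",
    "chi2_subgroup_test",
    "empirical_roc_auc",
    "auc_difference_critical_ratio",
    "logistic_performance_model",
    "compare_subgroups",
]


@dataclass(frozen=True)
class Chi2Result:
    chi2: float
    df: int
    p_value: float
    low_expected_cells: int = 0


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC curve with Hanley-McNeil AUC standard error."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    se_auc: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class SubgroupComparison:
    strata: tuple
    metrics: dict
    chi2_sens: Chi2Result
    chi2_spec: Chi2Result
    critical_ratio_z: float | None = None
    critical_ratio_p: float | None = None


def stratified_performance(
    cohort: Cohort, stratum_field: str = "stratum"
) -> dict[object, PerformanceMetrics]:
    """Per-stratum accuracy metrics (prevalence taken from each stratum)."""
    if stratum_field not in cohort.data.columns:
        raise ValueError(f"cohort has no column {stratum_field!r}")
    out: dict[object, PerformanceMetrics] = {}
    for label, grp in cohort.data.groupby(stratum_field, sort=True):
        cc = confusion_from_labels(grp["disease"].to_numpy(), grp["test"].to_numpy())
        try:
            out[label] = performance_from_counts(cc, prevalence="from-counts")
        except ZeroDivisionError as exc:
            raise ValueError(f"stratum {label!r}: {exc}") from exc
    return out


def chi2_subgroup_test(
    cohort: Cohort,
    stratum_field: str = "stratum",
    among: str = "diseased",
    yates: bool = False,
) -> Chi2Result:
    """Pearson chi-square test of stratum x test-result association within
    one disease class (no continuity correction unless ``yates``)."""
    if among not in ("diseased", "non-diseased"):
        raise ValueError(f"among must be 'diseased' or 'non-diseased', got {among!r}")
    sel = cohort.data["disease"] == (1 if among == "diseased" else 0)
    sub = cohort.data.loc[sel]
    if sub.empty:
        raise ValueError(f"no {among} individuals in the cohort")
    table = pd.crosstab(sub[stratum_field], sub["test"]).to_numpy()
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError(
            f"contingency table among the {among} is degenerate "
            f"(shape {table.shape}); a margin is empty"
        )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError(f"contingency table among the {among} has a zero margin")
    chi2, p, df, expected = stats.chi2_contingency(table, correction=yates)
    low = int((expected < 5).sum())
    if low:
        warnings.warn(
            f"{low} expected cell(s) below 5 in the {among} chi-square table; "
            "the chi-square approximation may be poor",
            stacklevel=2,
        )
    return Chi2Result(chi2=float(chi2), df=int(df), p_value=float(p), low_expected_cells=low)


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc * auc)
        + (n_neg - 1) * (q2 - auc * auc)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def empirical_roc_auc(scores, disease) -> RocCurve:
    """Empirical ROC curve and AUC from continuous scores.

    The full threshold sweep is kept (no convex simplification), so the
    trapezoidal area equals the Mann-Whitney estimate with ties counted
    half; identical scores for everyone yield the chance diagonal rather
    than an error.
    """
    scores = np.asarray(scores, dtype=float)
    disease = np.asarray(disease)
    if not np.isin(disease, (0, 1)).all():
        raise ValueError("disease labels must be binary")
    n_pos = int(disease.sum())
    n_neg = int(len(disease) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one diseased and one non-diseased individual")
    fpr, tpr, thresholds = roc_curve(disease, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
        auc=auc,
        se_auc=_hanley_mcneil_se(auc, n_pos, n_neg),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def auc_difference_critical_ratio(roc1: RocCurve, roc2: RocCurve) -> tuple[float, float]:
    """Critical ratio z for two AUCs from independent subgroups and its
    two-sided normal p-value."""
    se = float(np.sqrt(roc1.se_auc**2 + roc2.se_auc**2))
    if se == 0.0:
        raise ZeroDivisionError("combined AUC standard error is zero")
    z = (roc1.auc - roc2.auc) / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return float(z), p


@dataclass
class LogisticPerformanceFit:
    """Separate within-class logistic fits for test positivity.

    ``result_diseased`` models P(test+ | diseased) — sensitivity;
    ``result_nondiseased`` models P(test+ | non-diseased) — the false
    positive rate, i.e. 1 - specificity.
    """

    covariates: list[str]
    result_diseased: object
    result_nondiseased: object

    def params(self, among: str = "diseased") -> pd.Series:
        res = self.result_diseased if among == "diseased" else self.result_nondiseased
        return res.params

    def bse(self, among: str = "diseased") -> pd.Series:
        res = self.result_diseased if among == "diseased" else self.result_nondiseased
        return res.bse

    def predict_performance(self, covariate_values: dict[str, float]) -> dict[str, float]:
        """Sensitivity and specificity at given covariate values, with
        delta-method standard errors."""
        exog = pd.DataFrame([{**{"const": 1.0}, **{c: covariate_values[c] for c in self.covariates}}])
        exog = exog[["const", *self.covariates]]
        pred_d = self.result_diseased.get_prediction(exog)
        pred_n = self.result_nondiseased.get_prediction(exog)
        sens = float(np.asarray(pred_d.predicted)[0])
        fpr = float(np.asarray(pred_n.predicted)[0])
        return {
            "sensitivity": sens,
            "se_sensitivity": float(np.asarray(pred_d.se)[0]),
            "specificity": 1.0 - fpr,
            "se_specificity": float(np.asarray(pred_n.se)[0]),
        }


def _fit_logit(df: pd.DataFrame, covariates: list[str], label: str):
    exog = sm.add_constant(df[covariates], has_constant="add") if covariates else pd.DataFrame(
        {"const": np.ones(len(df))}, index=df.index
    )
    model = sm.Logit(df["test"].astype(float), exog)
    try:
        with warnings.catch_warnings():
            # separation/non-convergence warnings become errors below
            warnings.simplefilter("ignore")
            res = model.fit(disp=0, maxiter=100, tol=1e-8)
    except Exception as exc:  # statsmodels raises PerfectSeparationError etc.
        raise ValueError(
            f"logistic fit among the {label} failed (possible complete "
            f"separation in covariates {covariates}): {exc}"
        ) from exc
    if not res.mle_retvals.get("converged", True):
        raise ValueError(
            f"logistic fit among the {label} did not converge in 100 iterations "
            f"for covariates {covariates}"
        )
    return res


def logistic_performance_model(
    cohort: Cohort, covariates: list[str] | None = None
) -> LogisticPerformanceFit:
    """Model test positivity on covariates separately within disease classes."""
    covariates = list(covariates or [])
    for c in covariates:
        if c not in cohort.data.columns:
            raise ValueError(f"cohort has no covariate column {c!r}")
    diseased = cohort.data[cohort.data["disease"] == 1]
    nondiseased = cohort.data[cohort.data["disease"] == 0]
    if diseased.empty or nondiseased.empty:
        raise ValueError("both disease classes must be represented in the cohort")
    return LogisticPerformanceFit(
        covariates=covariates,
        result_diseased=_fit_logit(diseased, covariates, "diseased"),
        result_nondiseased=_fit_logit(nondiseased, covariates, "non-diseased"),
    )


def compare_subgroups(
    cohort: Cohort, stratum_field: str = "stratum", score_field: str = "z"
) -> SubgroupComparison:
    """Full subgroup comparison: stratified metrics, chi-square tests of
    sensitivity and specificity homogeneity, and (for exactly two strata
    with scores) the ROC critical ratio."""
    metrics = stratified_performance(cohort, stratum_field)
    chi2_sens = chi2_subgroup_test(cohort, stratum_field, among="diseased")
    chi2_spec = chi2_subgroup_test(cohort, stratum_field, among="non-diseased")
    strata = tuple(metrics)
    cr_z = cr_p = None
    if len(strata) == 2 and score_field in cohort.data.columns:
        rocs = []
        for label in strata:
            grp = cohort.data[cohort.data[stratum_field] == label]
            rocs.append(empirical_roc_auc(grp[score_field], grp["disease"]))
        cr_z, cr_p = auc_difference_critical_ratio(rocs[0], rocs[1])
    return SubgroupComparison(
        strata=strata,
        metrics=metrics,
        chi2_sens=chi2_sens,
        chi2_spec=chi2_spec,
        critical_ratio_z=cr_z,
        critical_ratio_p=cr_p,
    )
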