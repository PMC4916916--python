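"""Subgroup toolkit: stratified metrics, chi-square, ROC/AUC, logistic fits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spectrum_effect.cohort import Cohort, combine_strata
from spectrum_effect.measurement import MeasurementModel, analytic_test_performance
from spectrum_effect.metrics import confusion_from_labels, performance_from_counts
from spectrum_effect.population import PopulationModel, scenario1_model
from spectrum_effect.simulate import LogitTestModel, ScenarioConfig, generate_cohort
from spectrum_effect.subgroup import (
    RocCurve,
    auc_difference_critical_ratio,
    chi2_subgroup_test,
    compare_subgroups,
    empirical_roc_auc,
    logistic_performance_model,
    stratified_performance,
)


def _cohort_from_counts(strata_counts):
    """Build a cohort from {stratum: (tp, fp, fn, tn)}."""
    rows = []
    for label, (tp, fp, fn, tn) in strata_counts.items():
        rows += [{"disease": 1, "test": 1, "stratum": label}] * tp
        rows += [{"disease": 0, "test": 1, "stratum": label}] * fp
        rows += [{"disease": 1, "test": 0, "stratum": label}] * fn
        rows += [{"disease": 0, "test": 0, "stratum": label}] * tn
    return Cohort(data=pd.DataFrame(rows))


def _simulated_stratum(prev, trait_sd, error_sd, n, seed):
    pop = scenario1_model(prev, sd=trait_sd)
    cfg = ScenarioConfig(
        scenario="custom",
        measurement=MeasurementModel(error_sd),
        seed=seed,
        population=pop,
        n=n,
    )
    return generate_cohort(cfg)


class TestStratifiedPerformance:
    def test_single_stratum_equals_whole_cohort(self):
        cohort = _cohort_from_counts({"all": (30, 3, 10, 57)})
        per = stratified_performance(cohort)["all"]
        whole = performance_from_counts(
            confusion_from_labels(cohort.data.disease, cohort.data.test)
        )
        assert per == whole

    def test_hand_built_cohort_matches_manual_tabulation(self):
        cohort = _cohort_from_counts({"A": (3, 1, 1, 2), "B": (1, 1, 2, 1)})
        assert len(cohort) == 12
        per = stratified_performance(cohort)
        assert per["A"].sensitivity == pytest.approx(3 / 4)
        assert per["A"].specificity == pytest.approx(2 / 3)
        assert per["B"].sensitivity == pytest.approx(1 / 3)
        assert per["B"].specificity == pytest.approx(1 / 2)

    def test_pooled_sensitivity_recombines(self):
        cohort = _cohort_from_counts({"A": (30, 3, 10, 57), "B": (20, 10, 20, 50)})
        per = stratified_performance(cohort)
        diseased = cohort.data[cohort.data.disease == 1]
        pooled = sum(
            (diseased.stratum == s).mean() * per[s].sensitivity for s in ("A", "B")
        )
        whole = performance_from_counts(
            confusion_from_labels(cohort.data.disease, cohort.data.test)
        )
        assert pooled == pytest.approx(whole.sensitivity, abs=1e-12)

    def test_dispersion_difference_moves_lr(self):
        # same prevalence and error sd, but stratum B has three times the
        # trait dispersion, so its relative error is smaller and LR+ higher —
        # the analytic model fixes the expected direction
        mm = MeasurementModel(0.5)
        ana_a = analytic_test_performance(scenario1_model(0.2, sd=1.0), mm)
        ana_b = analytic_test_performance(scenario1_model(0.2, sd=3.0), mm)
        assert ana_b.lr_pos > ana_a.lr_pos  # direction fixed analytically
        cohort = combine_strata(
            {
                "A": _simulated_stratum(0.2, 1.0, 0.5, 20_000, seed=1),
                "B": _simulated_stratum(0.2, 3.0, 0.5, 20_000, seed=2),
            }
        )
        per = stratified_performance(cohort)
        assert per["B"].lr_pos > per["A"].lr_pos

    def test_empty_margin_names_stratum(self):
        cohort = _cohort_from_counts({"A": (3, 1, 1, 2), "B": (0, 2, 0, 2)})
        with pytest.raises(ValueError, match="'B'"):
            stratified_performance(cohort)


class TestChi2SubgroupTest:
    def test_identical_proportions_give_null_chi2(self):
        cohort = _cohort_from_counts({"A": (30, 5, 10, 55), "B": (30, 5, 10, 55)})
        res = chi2_subgroup_test(cohort, among="diseased")
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_two_by_two(self):
        # rows (30,10)/(10,50): expected 16/24/24/36, chi2 = sum (O-E)^2/E
        cohort = _cohort_from_counts(
            {"A": (30, 0, 10, 1), "B": (10, 0, 50, 1)}
        )
        res = chi2_subgroup_test(cohort, among="diseased")
        expected = sum(
            (o - e) ** 2 / e
            for o, e in zip((30, 10, 10, 50), (16, 24, 24, 36))
        )
        assert res.chi2 == pytest.approx(expected, abs=1e-10)
        assert res.chi2 == pytest.approx(34.03, abs=0.005)
        assert res.df == 1

    def test_three_strata_df(self):
        cohort = _cohort_from_counts(
            {"A": (30, 5, 10, 55), "B": (20, 5, 20, 55), "C": (25, 5, 15, 55)}
        )
        assert chi2_subgroup_test(cohort, among="diseased").df == 2

    def test_two_by_two_equals_squared_proportion_z(self):
        cohort = _cohort_from_counts({"A": (30, 0, 10, 1), "B": (10, 0, 50, 1)})
        res = chi2_subgroup_test(cohort, among="diseased")
        p1, n1, p2, n2 = 30 / 40, 40, 10 / 60, 60
        p = (30 + 10) / (n1 + n2)
        z = (p1 - p2) / np.sqrt(p * (1 - p) * (1 / n1 + 1 / n2))
        assert res.chi2 == pytest.approx(z**2, abs=1e-10)

    def test_low_expected_cells_warn_not_error(self):
        cohort = _cohort_from_counts({"A": (3, 0, 2, 1), "B": (2, 0, 3, 1)})
        with pytest.warns(UserWarning, match="expected cell"):
            res = chi2_subgroup_test(cohort, among="diseased")
        assert res.low_expected_cells > 0

    def test_degenerate_table_rejected(self):
        cohort = _cohort_from_counts({"A": (5, 1, 0, 1), "B": (5, 1, 0, 1)})
        with pytest.raises(ValueError, match="degenerate|margin"):
            chi2_subgroup_test(cohort, among="diseased")

    def test_yates_correction_reduces_statistic(self):
        cohort = _cohort_from_counts({"A": (30, 0, 10, 1), "B": (10, 0, 50, 1)})
        plain = chi2_subgroup_test(cohort, among="diseased")
        yates = chi2_subgroup_test(cohort, among="diseased", yates=True)
        assert yates.chi2 < plain.chi2


class TestEmpiricalRoc:
    def test_perfect_separation(self):
        roc = empirical_roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert roc.auc == pytest.approx(1.0)

    def test_toy_scores_with_one_tie(self):
        # diseased {3,4,5} vs non-diseased {1,2,3}: 8 wins + 1 tie of 9 pairs
        roc = empirical_roc_auc([3, 4, 5, 1, 2, 3], [1, 1, 1, 0, 0, 0])
        assert roc.auc == pytest.approx(8.5 / 9, abs=1e-12)

    def test_curve_endpoints(self):
        roc = empirical_roc_auc([3, 4, 5, 1, 2, 3], [1, 1, 1, 0, 0, 0])
        assert (roc.fpr[0], roc.tpr[0]) == (0.0, 0.0)
        assert (roc.fpr[-1], roc.tpr[-1]) == (1.0, 1.0)

    def test_trapezoid_equals_mann_whitney(self, rng):
        scores = np.round(rng.normal(size=400), 1)  # rounding forces ties
        disease = rng.integers(0, 2, size=400)
        roc = empirical_roc_auc(scores, disease)
        u = stats.mannwhitneyu(
            scores[disease == 1], scores[disease == 0], alternative="two-sided"
        ).statistic
        mw_auc = u / (roc.n_pos * roc.n_neg)
        assert roc.auc == pytest.approx(mw_auc, abs=1e-12)

    def test_null_labels_give_chance_auc(self, rng):
        scores = rng.normal(size=2000)
        disease = rng.permutation([1] * 1000 + [0] * 1000)
        roc = empirical_roc_auc(scores, disease)
        assert abs(roc.auc - 0.5) < 3 * roc.se_auc

    def test_constant_scores_fall_on_the_diagonal(self):
        roc = empirical_roc_auc([5, 5, 5, 5], [1, 0, 1, 0])
        assert roc.auc == pytest.approx(0.5)
        assert len(roc.fpr) == 2

    def test_thresholded_operating_point_on_curve(self):
        z = np.array([6.1, 6.4, 7.2, 7.9, 6.8, 7.5])
        disease = np.array([0, 0, 1, 1, 0, 1])
        test = (z >= 7.0).astype(int)
        perf = performance_from_counts(confusion_from_labels(disease, test))
        roc = empirical_roc_auc(z, disease)
        pts = set(zip(np.round(roc.fpr, 12), np.round(roc.tpr, 12)))
        assert (round(1 - perf.specificity, 12), round(perf.sensitivity, 12)) in pts

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            empirical_roc_auc([1, 2, 3], [1, 1, 1])


class TestCriticalRatio:
    def _roc(self, auc, n_pos=50, n_neg=50):
        from spectrum_effect.subgroup import _hanley_mcneil_se

        return RocCurve(
            fpr=np.array([0.0, 1.0]),
            tpr=np.array([0.0, 1.0]),
            thresholds=np.array([np.inf, 0.0]),
            auc=auc,
            se_auc=_hanley_mcneil_se(auc, n_pos, n_neg),
            n_pos=n_pos,
            n_neg=n_neg,
        )

    def test_equal_aucs_give_zero(self):
        z, p = auc_difference_critical_ratio(self._roc(0.8), self._roc(0.8))
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_antisymmetry(self):
        r1, r2 = self._roc(0.9), self._roc(0.7)
        z12, _ = auc_difference_critical_ratio(r1, r2)
        z21, _ = auc_difference_critical_ratio(r2, r1)
        assert z12 == pytest.approx(-z21, abs=1e-15)

    def test_hand_computed_hanley_mcneil(self):
        # manual evaluation of the SE formula for AUC 0.9, 50+50
        a, n1, n2 = 0.9, 50, 50
        q1, q2 = a / (2 - a), 2 * a * a / (1 + a)
        se = np.sqrt(
            (a * (1 - a) + (n1 - 1) * (q1 - a * a) + (n2 - 1) * (q2 - a * a))
            / (n1 * n2)
        )
        r1, r2 = self._roc(0.9), self._roc(0.7)
        z, _ = auc_difference_critical_ratio(r1, r2)
        assert r1.se_auc == pytest.approx(se, abs=1e-10)
        assert z == pytest.approx((0.9 - 0.7) / np.sqrt(r1.se_auc**2 + r2.se_auc**2), abs=1e-10)

    def test_zero_combined_se_rejected(self):
        r = self._roc(1.0)
        with pytest.raises(ZeroDivisionError):
            auc_difference_critical_ratio(r, r)


class TestLogisticPerformanceModel:
    def _logit_cohort(self, beta_d, beta_n, n, seed):
        lt = LogitTestModel(
            intercept_diseased=1.5,
            intercept_nondiseased=-2.0,
            coefs_diseased={"age": beta_d},
            coefs_nondiseased={"age": beta_n},
        )
        cfg = ScenarioConfig(
            scenario="custom",
            measurement=MeasurementModel(0.3),
            seed=seed,
            population=scenario1_model(0.3),
            n=n,
            logit_test=lt,
        )
        return generate_cohort(cfg)

    def test_intercept_only_matches_raw_proportion(self):
        cohort = self._logit_cohort(0.0, 0.0, 2000, seed=5)
        fit = logistic_performance_model(cohort, covariates=[])
        raw_sens = cohort.data.loc[cohort.data.disease == 1, "test"].mean()
        pred = fit.predict_performance({})
        assert pred["sensitivity"] == pytest.approx(raw_sens, abs=1e-8)

    def test_known_coefficient_recovered(self):
        cohort = self._logit_cohort(0.8, 0.0, 10_000, seed=6)
        fit = logistic_performance_model(cohort, covariates=["age"])
        beta_hat = fit.params("diseased")["age"]
        se = fit.bse("diseased")["age"]
        assert abs(beta_hat - 0.8) < 3 * se

    def test_null_coefficient_calibrated(self):
        cohort = self._logit_cohort(0.0, 0.0, 10_000, seed=7)
        fit = logistic_performance_model(cohort, covariates=["age"])
        for among in ("diseased", "non-diseased"):
            z = fit.params(among)["age"] / fit.bse(among)["age"]
            assert abs(z) < 4

    def test_predicted_performance_with_standard_errors(self):
        cohort = self._logit_cohort(0.8, -0.5, 5000, seed=8)
        fit = logistic_performance_model(cohort, covariates=["age"])
        pred = fit.predict_performance({"age": 1.0})
        assert 0 < pred["sensitivity"] < 1
        assert 0 < pred["specificity"] < 1
        assert pred["se_sensitivity"] > 0
        assert pred["se_specificity"] > 0

    def test_complete_separation_raises(self):
        df = pd.DataFrame(
            {
                "disease": [1] * 20 + [0] * 20,
                "test": [1] * 10 + [0] * 10 + [0] * 20,
                "sep": [1.0] * 10 + [-1.0] * 10 + [0.0] * 20,
            }
        )
        with pytest.raises(ValueError, match="diseased"):
            logistic_performance_model(Cohort(data=df), covariates=["sep"])


class TestCompareSubgroups:
    def test_full_comparison_on_simulated_strata(self):
        cohort = combine_strata(
            {
                "narrow": _simulated_stratum(0.2, 1.0, 0.5, 5000, seed=3),
                "wide": _simulated_stratum(0.2, 3.0, 0.5, 5000, seed=4),
            }
        )
        comp = compare_subgroups(cohort)
        assert comp.strata == ("narrow", "wide")
        assert comp.chi2_sens.df == 1
        assert comp.critical_ratio_z is not None
        # the wide stratum separates better: its AUC is higher, and the
        # comparison should flag the spectrum effect
        assert comp.chi2_spec.p_value < 0.01
        assert abs(comp.critical_ratio_z) > 2
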