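"""Validation harness: classification rule, odds ratios, logistic suites, CV."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit

from driglucose import (
    DiabetesModelSuite,
    auc_score,
    classification_metrics,
    classify_diabetes,
    cross_validate,
    fit_logistic,
    odds_ratio_2x2,
    stratified_split,
)
from driglucose.validation import (
    MissingDataError,
    SeparationError,
    ZeroCellError,
    youden_threshold,
)


class TestClassifyDiabetes:
    def test_fpg_boundary_inclusive(self):
        assert classify_diabetes(False, False, 7.0) is True
        assert classify_diabetes(False, False, 6.99) is False

    def test_normal_glucose_negative(self):
        assert classify_diabetes(False, False, 5.0) is False

    def test_medication_alone_positive(self):
        assert classify_diabetes(False, True, None) is True

    def test_self_report_alone_positive(self):
        assert classify_diabetes(True, None, None) is True

    def test_all_missing_flagged(self):
        with pytest.raises(MissingDataError):
            classify_diabetes(None, None, None)


class TestOddsRatio2x2:
    def test_cross_product_arithmetic(self):
        """(20 cases / 80) exposed vs (10 / 90) reference -> OR 2.25."""
        res = odds_ratio_2x2(20, 80, 10, 90)
        assert res.odds_ratio == pytest.approx(2.25)

    def test_symmetric_table_is_null(self):
        res = odds_ratio_2x2(30, 30, 30, 30)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.ci_low < 1 < res.ci_high

    def test_zero_cell_requires_correction(self):
        with pytest.raises(ZeroCellError):
            odds_ratio_2x2(0, 50, 10, 40)
        res = odds_ratio_2x2(0, 50, 10, 40, continuity_correction=True)
        assert res.odds_ratio < 1

    def test_wald_interval_hand_oracle(self):
        a, b, c, d = 20, 80, 10, 90
        res = odds_ratio_2x2(a, b, c, d)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        lo = np.exp(np.log(2.25) - 1.959963984540054 * se)
        assert res.ci_low == pytest.approx(lo, rel=1e-9)


class TestFitLogistic:
    def test_intercept_only_recovers_logit_prevalence(self):
        y = np.array([1] * 30 + [0] * 70)
        table = fit_logistic(pd.DataFrame(index=range(100)), y)
        assert table.loc["const", "coef"] == pytest.approx(logit(0.3), abs=1e-6)

    def test_binary_covariate_equals_2x2_oracle(self):
        """Logistic OR for one binary covariate equals the closed-form table OR."""
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, 400)
        y = (rng.random(400) < np.where(x == 1, 0.3, 0.15)).astype(int)
        table = fit_logistic(pd.DataFrame({"x": x}), y)
        a = int(((x == 1) & (y == 1)).sum())
        b = int(((x == 1) & (y == 0)).sum())
        c = int(((x == 0) & (y == 1)).sum())
        d = int(((x == 0) & (y == 0)).sum())
        oracle = odds_ratio_2x2(a, b, c, d)
        assert table.loc["x", "odds_ratio"] == pytest.approx(oracle.odds_ratio, abs=1e-8)
        assert table.loc["x", "ci_low"] == pytest.approx(oracle.ci_low, rel=1e-4)

    def test_simulation_recovery_within_2se(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=5000)
        y = (rng.random(5000) < expit(-2.0 + 0.6 * x)).astype(int)
        table = fit_logistic(pd.DataFrame({"x": x}), y)
        assert abs(table.loc["x", "coef"] - 0.6) < 2 * table.loc["x", "se"]

    def test_separation_detected(self):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        y = x.astype(int)
        with pytest.raises(SeparationError):
            fit_logistic(pd.DataFrame({"x": x}), y)

    def test_rank_deficiency_detected(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=100)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        y = (rng.random(100) < 0.3).astype(int)
        with pytest.raises(np.linalg.LinAlgError):
            fit_logistic(X, y)


class TestStratifiedSplit:
    def test_forced_counts(self):
        y = np.array([1] * 100 + [0] * 900)
        train, test = stratified_split(y, test_fraction=0.2, seed=0)
        assert y[test].sum() == 20 and len(test) == 200
        assert y[train].sum() == 80 and len(train) == 800

    def test_partition_properties(self):
        y = (np.random.default_rng(2).random(500) < 0.3).astype(int)
        train, test = stratified_split(y, 0.2, seed=3)
        assert len(np.intersect1d(train, test)) == 0
        assert len(np.union1d(train, test)) == len(y)

    def test_seed_changes_membership_not_counts(self):
        y = np.array([1] * 50 + [0] * 450)
        _, t1 = stratified_split(y, 0.2, seed=1)
        _, t2 = stratified_split(y, 0.2, seed=2)
        assert not np.array_equal(t1, t2)
        assert y[t1].sum() == y[t2].sum()

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(np.array([1, 1, 0, 0, 0, 0, 0, 0]), 0.2, seed=0)


class TestMetrics:
    def test_perfect_classifier(self):
        y = np.array([0, 0, 1, 1])
        p = np.array([0.1, 0.2, 0.8, 0.9])
        m = classification_metrics(p, y, threshold=0.5)
        assert m["youden_j"] == 1.0 and m["accuracy"] == 1.0 and m["aroc"] == 1.0

    def test_anti_ranked_aroc_zero(self):
        y = np.array([1, 1, 0, 0])
        p = np.array([0.1, 0.2, 0.8, 0.9])
        assert auc_score(p, y) == 0.0

    def test_single_class_undefined(self):
        with pytest.raises(ValueError):
            classification_metrics(np.array([0.5, 0.6]), np.array([1, 1]))

    def test_probability_range_enforced(self):
        with pytest.raises(ValueError):
            classification_metrics(np.array([1.5, 0.2]), np.array([1, 0]))

    def test_aroc_matches_pairwise_concordance(self):
        """Rank-method AROC equals the O(n^2) concordance count on 50 points."""
        rng = np.random.default_rng(5)
        p = rng.random(50)
        y = (rng.random(50) < 0.4).astype(int)
        conc = half = total = 0
        for i in np.flatnonzero(y == 1):
            for j in np.flatnonzero(y == 0):
                total += 1
                if p[i] > p[j]:
                    conc += 1
                elif p[i] == p[j]:
                    half += 1
        assert auc_score(p, y) == pytest.approx((conc + 0.5 * half) / total, abs=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 500))
    def test_youden_identity_property(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        p = rng.random(n)
        y = np.concatenate([[0, 1], (rng.random(n - 2) < 0.5).astype(int)])
        m = classification_metrics(p, y, threshold=0.5)
        assert m["youden_j"] == pytest.approx(
            m["sensitivity"] + m["specificity"] - 1, abs=1e-12
        )
        assert 0 <= m["aroc"] <= 1


class TestCrossValidate:
    def test_near_separable_data_near_perfect_accuracy(self):
        """Almost perfectly separated classes score ~1.0; a few deliberately
        mislabeled points keep each training fold non-separable (a perfectly
        separable fold is a fit error by design, not accuracy 1.0)."""
        rng = np.random.default_rng(0)
        n = 400
        x = np.concatenate([rng.normal(-2, 0.5, n // 2), rng.normal(2, 0.5, n // 2)])
        y = np.repeat([0, 1], n // 2)
        flip = rng.choice(n, 10, replace=False)
        y[flip] = 1 - y[flip]
        out = cross_validate(pd.DataFrame({"x": x}), y, k=5, seed=1)
        assert out.loc["accuracy", "mean"] > 0.95

    def test_label_permutation_null_aroc(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=600)
        y = rng.permutation(np.repeat([0, 1], 300))
        out = cross_validate(pd.DataFrame({"x": x}), y, k=10, seed=2)
        assert out.loc["aroc", "mean"] == pytest.approx(0.5, abs=0.08)

    def test_k_exceeding_minority_rejected(self):
        y = np.array([1] * 5 + [0] * 95)
        with pytest.raises(ValueError):
            cross_validate(pd.DataFrame({"x": np.arange(100.0)}), y, k=10)


@pytest.fixture(scope="module")
def suite_cohort(small_scenario):
    """1200-person cohort on the shared synthetic city (for stable fits)."""
    from driglucose import ScenarioConfig, gen_cohort

    cfg = ScenarioConfig(**{
        **small_scenario.config.__dict__, "n_participants": 1200, "seed": 77,
    })
    return gen_cohort(cfg, small_scenario.network, small_scenario.areas)


class TestModelSuite:
    @staticmethod
    def _cohort(cohort, scores=None):
        return cohort, (cohort["true_index"].to_numpy() if scores is None else scores)

    def test_model_c_adds_four_lifestyle_covariates(self, suite_cohort):
        cohort, scores = self._cohort(suite_cohort)
        report = DiabetesModelSuite(cohort, scores).fit(seed=0, k=3)
        semi = set(report.semi_adjusted.index) - {"const"}
        full = set(report.fully_adjusted.index) - {"const"}
        assert full - semi == {"smoker", "drinker", "ahei", "met_high"}
        assert semi == {"index", "age", "female", "bmi", "income_cat", "urban"}

    def test_bivariate_tables_for_all_predictors(self, suite_cohort):
        cohort, scores = self._cohort(suite_cohort)
        report = DiabetesModelSuite(cohort, scores).fit(seed=0, k=3)
        assert "index" in report.bivariate
        assert len(report.bivariate) >= 10

    def test_null_cohort_ci_coverage(self, small_scenario):
        """No true index effect: the bivariate index CI covers 1.0 in >= 90%
        of 100 seeds."""
        from driglucose import ScenarioConfig, gen_cohort
        base = small_scenario.config.__dict__
        covered = 0
        for seed in range(100):
            cfg = ScenarioConfig(**{
                **base, "seed": seed, "true_index_log_or": 0.0,
                "covariate_effects": {}, "n_participants": 400,
            })
            cohort = gen_cohort(cfg, small_scenario.network, small_scenario.areas)
            table = fit_logistic(cohort[["true_index"]], cohort["diabetes"])
            if table.loc["true_index", "ci_low"] <= 1.0 <= table.loc["true_index", "ci_high"]:
                covered += 1
        assert covered >= 90

    def test_positive_effect_attenuates_with_mediator(self):
        """A mediator correlated with the index soaks up part of its OR."""
        rng = np.random.default_rng(9)
        n = 4000
        index = rng.normal(size=n)
        mediator = 0.8 * index + 0.6 * rng.normal(size=n)
        y = (rng.random(n) < expit(-2.2 + 0.5 * index + 0.5 * mediator)).astype(int)
        alone = fit_logistic(pd.DataFrame({"index": index}), y)
        both = fit_logistic(pd.DataFrame({"index": index, "mediator": mediator}), y)
        assert alone.loc["index", "odds_ratio"] > 1
        assert both.loc["index", "odds_ratio"] < alone.loc["index", "odds_ratio"]

    def test_report_summary_mentions_metrics(self, suite_cohort):
        cohort, scores = self._cohort(suite_cohort)
        report = DiabetesModelSuite(cohort, scores).fit(seed=1, k=3)
        text = report.summary()
        assert "AROC" in text and "semi-adjusted" in text
        for metrics in report.test_metrics.values():
            assert metrics["youden_j"] == pytest.approx(
                metrics["sensitivity"] + metrics["specificity"] - 1, abs=1e-12
            )

    def test_whr_swap_requires_column(self, suite_cohort):
        cohort, scores = self._cohort(suite_cohort)
        with pytest.raises(KeyError):
            DiabetesModelSuite(cohort, scores, adiposity="whr")
        with_whr = cohort.assign(whr=np.random.default_rng(0).normal(0.86, 0.09, len(cohort)))
        report = DiabetesModelSuite(with_whr, scores, adiposity="whr").fit(seed=0, k=3)
        assert "whr" in report.semi_adjusted.index
        assert "bmi" not in report.semi_adjusted.index
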