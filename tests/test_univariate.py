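"""Univariate logistic fits and k-fold cross-validated AUC."""

import numpy as np
import pytest

from cipdus import (
    ContingencyTable,
    assess_feature,
    cv_auc,
    fit_logistic,
    odds_ratio,
    predict_prob,
)
from cipdus.univariate import SLOPE_CAP


def table_data(tp, fn, fp, tn):
    """Expand a 2x2 table into (predictor, outcome) vectors."""
    x = [1] * tp + [0] * fn + [1] * fp + [0] * tn
    y = [1] * (tp + fn) + [0] * (fp + tn)
    return np.array(x, float), np.array(y, float)


class TestFitLogistic:
    def test_slope_exponentiates_to_contingency_or(self):
        """exp(slope) equals the uncorrected OR of the table (published 9.4 row)."""
        x, y = table_data(15, 7, 10, 44)
        fit = fit_logistic(x, y)
        assert fit.converged and not fit.separation_detected
        expected = odds_ratio(ContingencyTable(15, 7, 10, 44),
                              correction="none").or_value
        assert np.exp(fit.slope) == pytest.approx(expected, rel=1e-6)

    def test_matches_statsmodels_mle(self, rng):
        import statsmodels.api as sm

        x = rng.normal(size=300)
        y = (rng.random(300) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(float)
        fit = fit_logistic(x, y)
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert fit.intercept == pytest.approx(ref.params[0], abs=1e-6)
        assert fit.slope == pytest.approx(ref.params[1], abs=1e-6)

    def test_perfect_separation_is_flagged_and_capped(self):
        y = np.array([0.0] * 10 + [1.0] * 10)
        fit = fit_logistic(y, y)
        assert fit.separation_detected
        assert abs(fit.slope) == SLOPE_CAP
        assert not fit.converged

    def test_independent_predictor_gives_null_slope(self, rng):
        x = rng.integers(0, 2, size=4000).astype(float)
        y = rng.integers(0, 2, size=4000).astype(float)
        fit = fit_logistic(x, y)
        table_or = odds_ratio(
            ContingencyTable(*(int(v) for v in (
                ((x == 1) & (y == 1)).sum(), ((x == 0) & (y == 1)).sum(),
                ((x == 1) & (y == 0)).sum(), ((x == 0) & (y == 0)).sum()))),
            correction="none").or_value
        assert np.exp(fit.slope) == pytest.approx(table_or, rel=1e-6)
        assert abs(fit.slope) < 0.15

    def test_refuses_constant_predictor_and_single_class(self):
        with pytest.raises(ValueError, match="constant"):
            fit_logistic([1, 1, 1, 1], [0, 1, 0, 1])
        with pytest.raises(ValueError, match="single class"):
            fit_logistic([0, 1, 0, 1], [1, 1, 1, 1])

    def test_missing_values_dropped_complete_case(self):
        x = np.array([np.nan, 0, 1, 0, 1, 1, 0, 1])
        y = np.array([1, 0, 1, 0, 1, 0, 0, 1])
        assert fit_logistic(x, y).n_used == 7

    def test_permutation_invariance(self, rng):
        x, y = table_data(15, 7, 10, 44)
        perm = rng.permutation(len(x))
        a, b = fit_logistic(x, y), fit_logistic(x[perm], y[perm])
        assert a.slope == pytest.approx(b.slope, abs=1e-9)
        assert a.intercept == pytest.approx(b.intercept, abs=1e-9)


class TestPredictProb:
    def test_null_model_predicts_half(self):
        from cipdus.univariate import LogisticFit
        fit = LogisticFit(0.0, 0.0, True, False, 10)
        assert np.all(predict_prob(fit, [0, 1, 5]) == 0.5)

    def test_extreme_negative_intercept_limits_to_zero(self):
        from cipdus.univariate import LogisticFit
        fit = LogisticFit(-1000.0, 0.0, True, False, 10)
        assert np.all(predict_prob(fit, [0.0, 1.0]) == pytest.approx(0.0))

    def test_saturated_binary_fit_predicts_group_event_rates(self):
        x, y = table_data(15, 7, 10, 44)
        probs = predict_prob(fit_logistic(x, y), x)
        distinct = np.unique(np.round(probs, 10))
        assert distinct == pytest.approx([7 / 51, 15 / 25], abs=1e-8)


class TestCvAuc:
    def test_perfect_predictor_reaches_one(self):
        y = np.array([0.0] * 30 + [1.0] * 30)
        x = y * 2 - 1 + np.linspace(0, 0.1, 60)   # separating, non-constant folds
        assert cv_auc(x, y, k=10, seed=0) == 1.0

    def test_null_predictor_stays_near_half(self, rng):
        x = rng.normal(size=760)
        y = np.array([1.0] * 220 + [0.0] * 540)
        assert cv_auc(x, y, k=10, seed=3) == pytest.approx(0.5, abs=0.05)

    def test_scaled_cohort_recovers_published_skin_score_cvauc(self, big_frame):
        """mRSS>8 at x100 scale: cvAUC within 0.03 of the published 0.73."""
        value = cv_auc(big_frame["mrss_gt8"].to_numpy(float),
                       big_frame["outcome"].to_numpy(float), k=10, seed=0)
        assert value == pytest.approx(0.73, abs=0.03)

    def test_single_class_training_fold_is_refused_loudly(self):
        y = np.zeros(20)
        y[0] = 1.0
        x = np.arange(20.0)
        with pytest.raises(ValueError, match="single outcome class"):
            cv_auc(x, y, k=10, seed=0)

    def test_no_optimistic_bias_for_null_feature(self, rng):
        """Mean over seeds: cvAUC of a null feature <= apparent AUC + 0.02."""
        from cipdus import auc_mann_whitney

        diffs = []
        for seed in range(20):
            local = np.random.default_rng(seed)
            x = local.normal(size=76)
            y = np.array([1.0] * 22 + [0.0] * 54)
            apparent = auc_mann_whitney(x, y)
            diffs.append(cv_auc(x, y, k=10, seed=seed) - apparent)
        assert np.mean(diffs) <= 0.02

    def test_fold_assignment_is_seed_controlled(self):
        x = np.concatenate([np.random.default_rng(1).normal(1, 1, 22),
                            np.random.default_rng(2).normal(0, 1, 54)])
        y = np.array([1.0] * 22 + [0.0] * 54)
        assert cv_auc(x, y, seed=5) == cv_auc(x, y, seed=5)
        assert cv_auc(x, y, seed=5) != cv_auc(x, y, seed=6)


class TestAssessFeature:
    def test_binary_auc_identity_on_synthetic_cohort(self, small_frame):
        """For a binary predictor, apparent AUC = (se + sp)/2 exactly."""
        for feature in ("mrss_gt8", "diffuse_subtype", "present_du_ps"):
            fa = assess_feature(small_frame, feature, seed=0)
            assert fa.auc == pytest.approx(
                (fa.sensitivity + fa.specificity) / 2, abs=1e-12)

    def test_perfect_feature_gets_top_weight(self, small_frame):
        frame = small_frame.copy()
        frame["oracle"] = frame["outcome"]
        fa = assess_feature(frame, "oracle", seed=0)
        assert fa.cv_auc == 1.0 and fa.weight == 3

    def test_null_feature_is_excluded(self, rng):
        import pandas as pd

        frame = pd.DataFrame({
            "patient_id": [str(i) for i in range(760)],
            "outcome": [1] * 220 + [0] * 540,
            "noise": rng.integers(0, 2, 760),
        })
        fa = assess_feature(frame, "noise", seed=0)
        assert fa.weight is None

    def test_scaled_cohort_recovers_published_skin_score_or(self, big_frame):
        fa = assess_feature(big_frame, "mrss_gt8", seed=0)
        assert fa.or_estimate.or_value == pytest.approx(9.4, rel=0.10)

    def test_separated_feature_or_comes_from_corrected_table(self, small_frame):
        """history of ulcers separates quasi-completely; the reported OR must be
        the Haldane-corrected contingency OR, finite and flagged corrected."""
        fa = assess_feature(small_frame, "history_du_ps", seed=0)
        assert fa.or_estimate.corrected
        assert np.isfinite(fa.or_estimate.or_value)
        assert fa.sensitivity == 1.0
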