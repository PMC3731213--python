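"""Correlation statistics, robust Z, ROC, semi-partial correlation."""

import numpy as np
import pytest

from thermoccupancy.evaluation import (
    accessibility_filtered_scores,
    cc_pvalue,
    gamma_expression_consistency,
    modified_zscore,
    pearson_cc,
    roc_auc,
    semi_partial_cc,
    subset_ccs,
)
from thermoccupancy.training import FitParams, FitResult, CVFolds


class TestPearson:
    def test_affine_and_inverted_relations(self):
        x = np.arange(10.0)
        assert pearson_cc(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_cc(x, -x) == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x, y = rng.normal(size=(2, 15))
            cov = np.mean((x - x.mean()) * (y - y.mean()))
            oracle = cov / (x.std() * y.std())
            assert pearson_cc(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pearson_cc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            pearson_cc([1.0, 2.0], [1.0, 2.0])


class TestCCPvalue:
    def test_reference_threshold_is_below_1e11(self):
        assert cc_pvalue(0.15, 2000, tail="one") < 1e-11

    def test_null_correlation_has_unit_two_sided_pvalue(self):
        assert cc_pvalue(0.0, 100, tail="two") == pytest.approx(1.0)

    def test_matches_numeric_integration_of_t_density(self):
        from math import lgamma, exp, pi, sqrt

        r, n = 0.5, 10
        df = n - 2
        t_obs = r * sqrt(df / (1 - r * r))

        def t_density(t):
            c = exp(lgamma((df + 1) / 2) - lgamma(df / 2)) / sqrt(df * pi)
            return c * (1 + t * t / df) ** (-(df + 1) / 2)

        grid = np.linspace(t_obs, 60.0, 400000)
        tail = np.trapezoid([t_density(t) for t in grid], grid)
        assert cc_pvalue(r, n, tail="one") == pytest.approx(tail, rel=1e-6)

    def test_perfect_correlation(self):
        assert cc_pvalue(1.0, 10) == 0.0


class TestModifiedZscore:
    def test_hand_computed_outlier(self):
        assert modified_zscore(100, [1, 2, 3, 4, 100]) == pytest.approx(
            0.6745 * 97 / 1.0
        )

    def test_median_scores_zero(self):
        assert modified_zscore(3.0, [1, 2, 3, 4, 5]) == 0.0

    def test_antisymmetric_around_symmetric_pool(self):
        pool = [-2, -1, 0, 1, 2]
        assert modified_zscore(1.7, pool) == pytest.approx(
            -modified_zscore(-1.7, pool)
        )

    def test_zero_mad_falls_back_to_mean_deviation(self):
        pool = [1.0, 1.0, 1.0, 1.0, 9.0]
        z = modified_zscore(9.0, pool)
        assert z == pytest.approx((9.0 - 1.0) / (1.253314 * np.mean([0, 0, 0, 0, 8])))

    def test_degenerate_pool_rejected(self):
        with pytest.raises(ValueError):
            modified_zscore(1.0, [2.0, 2.0, 2.0])
        with pytest.raises(ValueError):
            modified_zscore(1.0, [1.0, 2.0])


class TestRocAuc:
    def test_perfect_separation_and_pure_ties(self):
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert roc_auc([1, 2, 3, 4, 5, 6], labels) == 1.0
        assert roc_auc([2, 2, 2, 2, 2, 2], labels) == 0.5

    def test_matches_pairwise_comparison_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            scores = rng.integers(0, 6, size=14).astype(float)  # force ties
            labels = rng.integers(0, 2, size=14)
            if labels.min() == labels.max():
                continue
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            wins = sum(
                1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg
            )
            assert roc_auc(scores, labels) == pytest.approx(
                wins / (pos.size * neg.size), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], np.array([1, 1]))


class TestAccessibilityFilter:
    def test_identity_and_annihilation(self):
        scores = np.array([1.0, 2.0, 3.0])
        assert np.array_equal(
            accessibility_filtered_scores(scores, [True] * 3), scores
        )
        assert np.array_equal(
            accessibility_filtered_scores(scores, [False] * 3), np.zeros(3)
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            accessibility_filtered_scores([1.0, 2.0], [True])


class TestSemiPartialCC:
    def test_reduces_to_plain_cc_when_z_uncorrelated(self):
        # z orthogonal to both x and y by construction
        x = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        y = 2 * x + np.array([0.3, -0.3] * 4)
        z = np.array([1.0, -1, -1, 1, 1, -1, -1, 1])
        assert abs(pearson_cc(x, z)) < 1e-9
        assert abs(pearson_cc(y, z)) < 1e-9
        assert semi_partial_cc(x, y, z) == pytest.approx(pearson_cc(x, y), abs=1e-12)

    def test_matches_residual_regression_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = int(rng.integers(10, 60))
            x, y, z = rng.normal(size=(3, n))
            y = y + 0.5 * z
            resid = y - np.polyval(np.polyfit(z, y, 1), z)
            assert semi_partial_cc(x, y, z) == pytest.approx(
                pearson_cc(x, resid), abs=1e-10
            )

    def test_collinear_confound_rejected(self):
        y = np.arange(10.0)
        with pytest.raises(ValueError):
            semi_partial_cc(np.random.default_rng(0).normal(size=10), y, y)


def test_overall_cc_is_not_weighted_mean_of_subset_ccs():
    # perfect within-label fits whose separation drives the overall correlation
    chip = np.array([10.0, 11, 12, 13, 0.0, 1, 2, 3])
    pred = np.array([5.0, 5.2, 5.4, 5.6, 0.0, 0.2, 0.4, 0.6])
    labels = np.array(["peak"] * 4 + ["nonpeak"] * 4)
    ccs = subset_ccs(pred, chip, labels)
    assert ccs["peak"] == pytest.approx(1.0)
    assert ccs["nonpeak"] == pytest.approx(1.0)
    weighted_mean = 0.5 * (ccs["peak"] + ccs["nonpeak"])
    assert ccs["overall"] != pytest.approx(weighted_mean, abs=1e-6)


class TestGammaExpressionConsistency:
    @staticmethod
    def _fit(lg):
        params = [FitParams((lg,), 1.0, 0.5)] * 4
        return FitResult(params, np.zeros(4), [0.5] * 4, True,
                         CVFolds(4, np.arange(4), 0))

    def test_first_and_third_quadrants_agree_in_sign(self):
        g_ratio, e_ratio, same = gamma_expression_consistency(
            self._fit(2.0), self._fit(1.0), 2.0, 1.0
        )
        assert g_ratio > 0 and e_ratio > 0 and same
        g_ratio, e_ratio, same = gamma_expression_consistency(
            self._fit(1.0), self._fit(2.0), 0.5, 1.0
        )
        assert g_ratio < 0 and e_ratio < 0 and same

    def test_zero_expression_rejected(self):
        with pytest.raises(ValueError):
            gamma_expression_consistency(self._fit(1.0), self._fit(1.0), 0.0, 1.0)

    def test_planted_concentration_change_recovered(self):
        """Two 'stages' generated at different true gamma: the fitted ratio
        tracks the concentration ratio in sign."""
        from thermoccupancy.synthetic_data import TruthModel, simulate_dataset
        from thermoccupancy.training import CVFolds, ModelConfig, cross_validate

        base = TruthModel.cooperative(seed=41, noise_sd=0.0)
        base.secondary_given_primary = 0.0
        base.mode = "single"
        fits = []
        for lg in (0.5, 1.5):  # ten-fold concentration change
            truth = TruthModel(
                primary=base.primary, mode="single", log10_gamma=(lg, lg),
                noise_sd=0.0, secondary_given_primary=0.0,
            )
            ds, _ = simulate_dataset(truth, 80, 80, seed=41)
            folds = CVFolds.stratified(ds.labels, seed=41)
            fits.append(
                cross_validate(ds, ModelConfig(mode="single"), folds,
                               pwms=[truth.primary])
            )
        g_ratio, e_ratio, same = gamma_expression_consistency(
            fits[1], fits[0], expr_a=10.0, expr_b=1.0
        )
        assert g_ratio > 0 and same


def test_accessibility_filtering_improves_fit_on_gated_data():
    """When accessibility truly gates the signal, zeroing predictions in
    inaccessible windows raises the correlation."""
    from thermoccupancy.synthetic_data import TruthModel, simulate_dataset
    from thermoccupancy.training import CVFolds, ModelConfig, cross_validate

    truth = TruthModel.accessibility_mediated(seed=42)
    ds, _ = simulate_dataset(truth, 100, 100, seed=42)
    folds = CVFolds.stratified(ds.labels, seed=42)
    fit = cross_validate(ds, ModelConfig(mode="single"), folds, pwms=[truth.primary])
    plain = pearson_cc(fit.cv_predictions, ds.chip)
    filtered = pearson_cc(
        accessibility_filtered_scores(fit.cv_predictions, ds.accessible), ds.chip
    )
    assert filtered > plain
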