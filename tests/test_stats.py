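"""Association statistics: closed forms, oracles, threshold conventions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from cstlesion import stats


class TestWelch:
    def test_identical_samples(self):
        t, df, p = stats.welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_formula_oracle(self, rng):
        """Matches the textbook Welch/Satterthwaite closed form."""
        a = rng.normal(0, 1, 15)
        b = rng.normal(0.5, 2, 20)
        t, df, p = stats.welch_t_test(a, b)
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        t_ref = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_ref = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        p_ref = 2 * sps.t.sf(abs(t_ref), df_ref)
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert df == pytest.approx(df_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_zero_variance_unequal_means_rejected(self):
        with pytest.raises(ValueError):
            stats.welch_t_test([1.0, 1.0], [2.0, 2.0])

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            stats.welch_t_test([1.0], [1.0, 2.0])


class TestCohensD:
    def test_table_values(self):
        """HC vs patient brain/brainstem MTR effect sizes from cohort stats."""
        assert round(stats.cohens_d(42.817, 0.948, 28, 42.438, 1.556, 46), 2) == 0.28
        assert round(stats.cohens_d(46.610, 0.826, 28, 46.221, 1.254, 46), 2) == 0.35

    def test_equal_means_is_zero(self):
        assert stats.cohens_d(5.0, 1.0, 10, 5.0, 2.0, 12) == 0.0

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            stats.cohens_d(1.0, 0.0, 10, 2.0, 0.0, 10)


class TestChiSquare:
    def test_balanced_table(self):
        chi2, p = stats.chi_square_test([[15, 15], [15, 15]])
        assert chi2 == 0.0 and p == 1.0

    def test_closed_form(self):
        """Expected-count formula: chi2 = sum (o-e)^2/e with e = 15."""
        chi2, p = stats.chi_square_test([[10, 20], [20, 10]])
        assert chi2 == pytest.approx(4 * 25 / 15, abs=1e-10)
        assert p == pytest.approx(float(sps.chi2.sf(4 * 25 / 15, 1)), abs=1e-12)

    def test_brute_force_oracle(self, rng):
        for _ in range(20):
            table = rng.integers(1, 40, (2, 2)).astype(float)
            chi2, _ = stats.chi_square_test(table)
            total = table.sum()
            expected = np.outer(table.sum(1), table.sum(0)) / total
            ref = ((table - expected) ** 2 / expected).sum()
            assert chi2 == pytest.approx(ref, abs=1e-10)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            stats.chi_square_test([[0, 0], [5, 5]])


class TestPartialCorrelation:
    def test_no_covariates_is_plain_pearson(self, rng):
        x = rng.normal(0, 1, 30)
        y = x + rng.normal(0, 1, 30)
        r, p = stats.partial_correlation_pearson(x, y)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert r == pytest.approx(r_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_self_correlation(self, rng):
        x = rng.normal(0, 1, 30)
        cov = rng.normal(0, 1, (30, 2))
        r, p = stats.partial_correlation_pearson(x, x, cov)
        assert r == pytest.approx(1.0)

    def test_two_stage_residualization_oracle(self, rng):
        """Matches explicit two-stage OLS residual correlation."""
        n = 50
        cov = rng.normal(0, 1, (n, 3))
        x = cov @ [1.0, -0.5, 0.2] + rng.normal(0, 1, n)
        y = cov @ [0.3, 0.8, -1.0] + 0.5 * x + rng.normal(0, 1, n)
        r, _ = stats.partial_correlation_pearson(x, y, cov)
        design = np.column_stack([np.ones(n), cov])
        rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
        ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
        assert r == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-10)

    def test_collinear_covariates_rejected(self, rng):
        x = rng.normal(0, 1, 20)
        c = rng.normal(0, 1, 20)
        with pytest.raises(ValueError):
            stats.partial_correlation_pearson(x, x, np.column_stack([c, 2 * c]))


class TestScreening:
    def test_strict_threshold(self, rng):
        n = 60
        y = rng.normal(0, 1, n)
        candidates = pd.DataFrame({
            "strong": y + rng.normal(0, 0.5, n),
            "noise": rng.normal(0, 1, n),
        })
        kept = stats.screen_predictors(y, candidates, alpha=0.2)
        assert "strong" in kept
        _, p_noise = stats.partial_correlation_pearson(
            candidates["noise"].to_numpy(), y
        )
        assert ("noise" in kept) == (p_noise < 0.2)

    def test_boundary_p_dropped(self, monkeypatch, rng):
        y = rng.normal(0, 1, 20)
        candidates = pd.DataFrame({"x": rng.normal(0, 1, 20)})
        monkeypatch.setattr(
            stats, "partial_correlation_pearson", lambda *a, **k: (0.1, 0.2)
        )
        assert stats.screen_predictors(y, candidates, alpha=0.2) == []


class TestLinearModel:
    def test_noise_free_proportionality(self, rng):
        x = rng.normal(0, 1, 50)
        res = stats.fit_multivariable_linear(2 * x, pd.DataFrame({"x": x}))
        assert res.beta["x"] == pytest.approx(1.0, abs=1e-10)
        assert res.adj_r2 == pytest.approx(1.0, abs=1e-10)

    def test_duplicated_predictor_rejected(self, rng):
        x = rng.normal(0, 1, 30)
        X = pd.DataFrame({"a": x, "b": x})
        with pytest.raises(ValueError, match="'a' and 'b'"):
            stats.fit_multivariable_linear(rng.normal(0, 1, 30), X)

    def test_standardized_beta_scale_invariance(self, rng):
        n = 80
        X = pd.DataFrame(rng.normal(0, 1, (n, 3)), columns=list("abc"))
        y = X @ [0.5, -0.3, 0.0] + rng.normal(0, 1, n)
        res1 = stats.fit_multivariable_linear(y, X)
        X2 = X.copy()
        X2["a"] = X2["a"] * 1000.0  # rescaling must not move standardized beta
        res2 = stats.fit_multivariable_linear(y, X2)
        np.testing.assert_allclose(res1.beta, res2.beta, atol=1e-10)
        assert (res1.vif >= 1.0 - 1e-9).all()

    def test_ranked_predictors_by_magnitude(self, rng):
        n = 500
        X = pd.DataFrame(rng.normal(0, 1, (n, 2)), columns=["big", "small"])
        y = X @ [1.0, 0.1] + rng.normal(0, 0.5, n)
        res = stats.fit_multivariable_linear(y, X)
        assert res.ranked_predictors()[0] == "big"


class TestLogistic:
    def test_single_binary_predictor_matches_sample_odds_ratio(self, rng):
        """MLE odds ratio equals the 2x2 closed form ad/bc."""
        n = 400
        x = (rng.random(n) < 0.5).astype(float)
        p = np.where(x == 1, 0.7, 0.4)
        y = (rng.random(n) < p).astype(float)
        res = stats.fit_logistic(y, pd.DataFrame({"x": x}))
        a = ((x == 1) & (y == 1)).sum()
        b = ((x == 1) & (y == 0)).sum()
        c = ((x == 0) & (y == 1)).sum()
        d = ((x == 0) & (y == 0)).sum()
        assert res.odds_ratios["x"] == pytest.approx(a * d / (b * c), rel=1e-4)
        assert res.ci_low["x"] < res.odds_ratios["x"] < res.ci_high["x"]

    def test_zero_variance_predictor_rejected(self, rng):
        y = (rng.random(30) < 0.5).astype(float)
        with pytest.raises(ValueError):
            stats.fit_logistic(y, pd.DataFrame({"x": np.ones(30)}))

    def test_single_class_outcome_rejected(self, rng):
        with pytest.raises(ValueError):
            stats.fit_logistic(np.ones(30), pd.DataFrame({"x": rng.normal(0, 1, 30)}))

    def test_perfect_separation_detected(self):
        x = np.r_[np.zeros(15), np.ones(15)]
        y = x.copy()
        with pytest.raises(stats.SeparationError):
            stats.fit_logistic(y, pd.DataFrame({"x": x}))

    def test_auc_extremes(self):
        """Random scores give AUC ~ 0.5 on average; strong scores approach 1."""
        n = 500
        aucs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            score = rng.normal(0, 1, n)
            y_random = (rng.random(n) < 0.5).astype(float)
            aucs.append(stats.fit_logistic(y_random, pd.DataFrame({"s": score})).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.05
        rng = np.random.default_rng(1)
        score = rng.normal(0, 1, n)
        y_strong = (rng.random(n) < 1 / (1 + np.exp(-4 * score))).astype(float)
        assert stats.fit_logistic(y_strong, pd.DataFrame({"s": score})).auc > 0.85


class TestThresholdsAndTransforms:
    def test_cmct_status_conventions(self):
        z, status = stats.cmct_status(14.89, 14.89, 3.07)
        assert z == 0.0 and status == "normal"
        _, status = stats.cmct_status(14.89 + 2.1 * 3.07, 14.89, 3.07)
        assert status == "abnormal"
        _, status = stats.cmct_status(14.89 + 1.96 * 3.07, 14.89, 3.07)
        assert status == "normal"  # strict inequality
        _, status = stats.cmct_status(2.0, 14.89, 3.07)
        assert status == "normal"  # shortening is never abnormal
        with pytest.raises(ValueError):
            stats.cmct_status(10.0, 14.89, 0.0)

    def test_log_transform_closed_forms(self):
        assert stats.log_transform_fraction([0.0])[0] == pytest.approx(
            np.log(0.01), abs=1e-12
        )
        assert stats.log_transform_fraction([np.e - 0.01])[0] == pytest.approx(1.0)
        with pytest.raises(ValueError):
            stats.log_transform_fraction([-0.1])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0, 100), min_size=2, max_size=10, unique=True))
    def test_log_transform_monotone(self, values):
        order = np.argsort(values)
        transformed = stats.log_transform_fraction(values)
        assert (np.argsort(transformed) == order).all()

    def test_bonferroni(self):
        assert stats.bonferroni_threshold(0.05, 5) == 0.01
        assert stats.bonferroni_threshold(0.05, 10) == 0.005
        assert stats.bonferroni_threshold(0.07, 1) == 0.07
        with pytest.raises(ValueError):
            stats.bonferroni_threshold(0.05, 0)

    def test_normal_tail_calibration(self):
        assert stats.normal_tail_probability(1.96) == pytest.approx(0.05, abs=5e-5)
        assert stats.normal_tail_probability(1.96, two_sided=False) == pytest.approx(
            0.025, abs=3e-5
        )
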