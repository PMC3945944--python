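"""Poisson GLM/GLMM fitting, AICc ranking, Akaike weights, model averaging,
and prediction — including the external mixed-model oracle (lme4)."""

import os
import subprocess
import tempfile

import numpy as np
import pandas as pd
import pytest

from foragedive.aggregate import ScaleTable
from foragedive.models import (ModelError, ModelFit, aicc, aicc_weights,
                               enumerate_and_rank, fit_poisson_glmm,
                               model_average, predict)
from foragedive.synthetic import GlmmTruth, simulate_model_table


def table_from(df, predictors):
    return ScaleTable("dive", df, tuple(predictors))


@pytest.fixture(scope="module")
def mixed_data():
    truth = GlmmTruth(intercept=0.2, beta={"x1": 0.3, "x2": -0.3, "x3": 0.3},
                      re_sd=0.5)
    return truth, simulate_model_table(2000, 10, truth, seed=42)


class TestGlm:
    def test_null_model_intercept_is_log_mean(self, mixed_data):
        _, df = mixed_data
        fit = fit_poisson_glmm(table_from(df, ()), (), use_random_intercept=False)
        assert fit.coef[0] == pytest.approx(np.log(df["pca_count"].mean()), abs=1e-6)

    def test_matches_statsmodels(self, mixed_data):
        import statsmodels.api as sm
        _, df = mixed_data
        fit = fit_poisson_glmm(table_from(df, ("x1", "x2")), ("x1", "x2"),
                               use_random_intercept=False)
        ref = sm.GLM(df["pca_count"], sm.add_constant(df[["x1", "x2"]]),
                     family=sm.families.Poisson()).fit()
        assert np.allclose(fit.coef, ref.params.values, atol=1e-8)
        assert np.allclose(fit.ensure_se(), ref.bse.values, atol=1e-6)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-8)

    def test_degenerate_column_raises(self, mixed_data):
        _, df = mixed_data
        df2 = df.copy()
        df2["flat"] = 1.0
        with pytest.raises(ModelError, match="degenerate"):
            fit_poisson_glmm(table_from(df2, ("flat",)), ("flat",), False)


class TestGlmm:
    def test_sigma_zero_data_collapses_to_glm(self):
        truth = GlmmTruth(intercept=0.2, beta={"x1": 0.3}, re_sd=0.0)
        df = simulate_model_table(2000, 10, truth, seed=7)
        t = table_from(df, ("x1",))
        mixed = fit_poisson_glmm(t, ("x1",), True)
        plain = fit_poisson_glmm(t, ("x1",), False)
        assert mixed.re_sd < 0.05
        assert np.allclose(mixed.coef, plain.coef, atol=1e-3)

    def test_recovers_true_parameters_within_3se(self, mixed_data):
        truth, df = mixed_data
        subset = ("x1", "x2", "x3")
        fit = fit_poisson_glmm(table_from(df, subset), subset, True)
        se = fit.ensure_se()
        tv = np.array([truth.intercept] + [truth.beta[p] for p in subset])
        assert np.all(np.abs(fit.coef[1:] - tv[1:]) <= 3 * se[1:])
        assert fit.re_sd == pytest.approx(0.5, rel=0.5)

    def test_agrees_with_lme4_glmer(self):
        truth = GlmmTruth(intercept=0.3, beta={"x1": 0.4, "x2": -0.2}, re_sd=0.5)
        df = simulate_model_table(300, 6, truth, seed=5)
        t = table_from(df, ("x1", "x2"))
        full = fit_poisson_glmm(t, ("x1", "x2"), True)
        nested = fit_poisson_glmm(t, ("x1",), True)
        with tempfile.TemporaryDirectory() as td:
            csv = os.path.join(td, "d.csv")
            df.to_csv(csv, index=False)
            script = f'''
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m1 <- glmer(pca_count ~ x1 + x2 + (1|individual_id), data=d,
                        family=poisson, nAGQ=15)
            m0 <- glmer(pca_count ~ x1 + (1|individual_id), data=d,
                        family=poisson, nAGQ=15)
            cat(fixef(m1), sqrt(unlist(VarCorr(m1))),
                as.numeric(logLik(m1)) - as.numeric(logLik(m0)), sep=",")
            '''
            out = subprocess.run(["Rscript", "-e", script],
                                 capture_output=True, text=True, timeout=300)
            assert out.returncode == 0, out.stderr
            vals = [float(v) for v in out.stdout.strip().split(",")]
        assert np.allclose(full.coef, vals[:3], atol=2e-3)
        assert full.re_sd == pytest.approx(vals[3], abs=5e-3)
        # lme4's AGQ logLik differs by a data-only constant; differences agree
        assert full.loglik - nested.loglik == pytest.approx(vals[4], abs=2e-3)


class TestAicc:
    def test_formula_and_small_sample_guard(self):
        assert aicc(-100.0, 3, 1000) == pytest.approx(
            200 + 6 + 2 * 3 * 4 / 996)
        with pytest.raises(ModelError):
            aicc(-10.0, 5, 6)

    def test_limits_to_aic_for_large_n(self):
        assert aicc(-100.0, 5, 10 ** 6) - (200 + 10) < 0.01

    def test_weights_for_known_deltas(self):
        fits = [_dummy(aicc_val=100.0), _dummy(aicc_val=102.0)]
        w = aicc_weights(fits)
        assert w[0] == pytest.approx(0.731, abs=0.001)
        assert w[1] == pytest.approx(0.269, abs=0.001)

    def test_equal_aicc_symmetric(self):
        w = aicc_weights([_dummy(100.0), _dummy(100.0)])
        assert np.allclose(w, [0.5, 0.5])


def _dummy(aicc_val, predictors=(), coef=None, se=None):
    coef = np.asarray(coef if coef is not None else [0.0])
    se = np.asarray(se if se is not None else [0.1] * len(coef))
    return ModelFit(tuple(predictors), coef, se, None, -aicc_val / 2, 1,
                    1000, aicc_val, True)


class TestEnumeration:
    def test_subset_counts(self, mixed_data):
        _, df = mixed_data
        t = table_from(df, ("x1", "x2", "x3"))
        fits = enumerate_and_rank(t, ("x1", "x2", "x3"), 3, False)
        assert len(fits) == 8  # 2^3
        assert fits[0].aicc == min(f.aicc for f in fits)

    def test_binomial_sum_with_cap(self, mixed_data):
        _, df = mixed_data
        t = table_from(df, ("x1", "x2", "x3"))
        fits = enumerate_and_rank(t, ("x1", "x2", "x3"), 2, False)
        assert len(fits) == 1 + 3 + 3

    def test_cap_violating_rows_per_variable_rule(self, mixed_data):
        _, df = mixed_data
        small = df.head(25)
        with pytest.raises(ModelError, match="rows-per-variable"):
            enumerate_and_rank(table_from(small, ("x1", "x2", "x3")),
                               ("x1", "x2", "x3"), 3, False)

    def test_ranking_invariant_to_candidate_order(self, mixed_data):
        _, df = mixed_data
        a = enumerate_and_rank(table_from(df, ("x1", "x2")), ("x1", "x2"), 2, False)
        b = enumerate_and_rank(table_from(df, ("x2", "x1")), ("x2", "x1"), 2, False)
        assert [set(f.predictors) for f in a] == [set(f.predictors) for f in b]
        assert np.allclose([f.aicc for f in a], [f.aicc for f in b])


class TestModelAverage:
    def test_weighted_arithmetic(self):
        fits = [_dummy(100.0, ("x",), coef=[0.5, 1.0], se=[0.1, 0.2]),
                _dummy(100.0, (), coef=[0.4], se=[0.1])]
        w = np.array([0.6, 0.4])
        avg = model_average(fits, w, threshold=0.95, use_random_intercept=False)
        assert avg.coef["x"] == pytest.approx(0.6)
        assert avg.importance["x"] == pytest.approx(0.6)
        # unconditional SE: within variance + between-model spread
        expect = 0.6 * np.sqrt(0.2 ** 2 + 0.4 ** 2) + 0.4 * np.sqrt(0.6 ** 2)
        assert avg.se["x"] == pytest.approx(expect)

    def test_single_dominant_model(self):
        fits = [_dummy(100.0, ("x",), coef=[0.5, 1.0], se=[0.1, 0.2]),
                _dummy(200.0, (), coef=[0.4], se=[0.1])]
        w = aicc_weights(fits)
        avg = model_average(fits, w, 0.95, use_random_intercept=False)
        assert len(avg.candidates) == 1
        assert avg.coef["x"] == pytest.approx(1.0)

    def test_importance_matches_bruteforce(self, mixed_data):
        _, df = mixed_data
        t = table_from(df, ("x1", "x2", "x3"))
        fits = enumerate_and_rank(t, ("x1", "x2", "x3"), 3, False)
        w = aicc_weights(fits)
        avg = model_average(fits, w, 0.95, use_random_intercept=False)
        # recompute from the candidate list directly
        for p in ("x1", "x2", "x3"):
            expect = sum(wt for preds, wt in avg.candidates if p in preds)
            assert avg.importance[p] == pytest.approx(expect, abs=1e-12)

    def test_weights_sum_to_one(self, mixed_data):
        _, df = mixed_data
        fits = enumerate_and_rank(table_from(df, ("x1", "x2", "x3")),
                                  ("x1", "x2", "x3"), 3, False)
        assert aicc_weights(fits).sum() == pytest.approx(1.0, abs=1e-9)


class TestPredict:
    def test_zero_row_predicts_exp_intercept(self):
        fits = [_dummy(100.0, ("x",), coef=[0.5, 1.0], se=[0.1, 0.2])]
        avg = model_average(fits, np.array([1.0]), 0.95,
                            use_random_intercept=False)
        df = pd.DataFrame({"x": [0.0], "pca_count": [0]})
        mu = predict(avg, ScaleTable("dive", df, ("x",)))
        assert mu[0] == pytest.approx(np.exp(0.5))

    def test_link_linearity(self):
        fits = [_dummy(100.0, ("x",), coef=[0.5, 1.0], se=[0.1, 0.2])]
        avg = model_average(fits, np.array([1.0]), 0.95,
                            use_random_intercept=False)
        df = pd.DataFrame({"x": [1.0, 3.0], "pca_count": [0, 0]})
        mu = predict(avg, ScaleTable("dive", df, ("x",)))
        assert np.log(mu[1]) - np.log(mu[0]) == pytest.approx(2.0)

    def test_missing_column_raises(self):
        fits = [_dummy(100.0, ("x",), coef=[0.5, 1.0], se=[0.1, 0.2])]
        avg = model_average(fits, np.array([1.0]), 0.95,
                            use_random_intercept=False)
        df = pd.DataFrame({"z": [1.0], "pca_count": [0]})
        with pytest.raises(ModelError, match="missing predictor"):
            predict(avg, ScaleTable("dive", df, ("z",)))

    def test_predictions_track_true_rates(self, mixed_data):
        truth, df = mixed_data
        from scipy.stats import spearmanr
        subset = ("x1", "x2", "x3")
        fit = fit_poisson_glmm(table_from(df, subset), subset, True)
        mu = predict(fit, table_from(df, subset))
        lam = np.exp(truth.intercept +
                     sum(truth.beta[p] * df[p] for p in subset))
        assert spearmanr(mu, lam).statistic > 0.95
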