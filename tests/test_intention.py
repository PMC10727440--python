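"""Intention workflow: univariate screen, OLS with diagnostics, ordinal check."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.outliers_influence import variance_inflation_factor
import statsmodels.api as sm

from kanopr.intention import (
    IntentionRegression,
    OrdinalIntentionModel,
    encode_predictors,
    fit_intention_regression,
    fit_ordinal_check,
    significance_agreement,
    univariate_screen,
)


@pytest.fixture(scope="module")
def linear_frame():
    """Synthetic frame with a known linear signal in two of four covariates."""
    rng = np.random.default_rng(7)
    n = 600
    x1 = rng.normal(size=n)
    x2 = rng.choice(["yes", "no"], size=n)
    x_noise = rng.normal(size=n)
    cat_noise = rng.choice(list("abc"), size=n)
    latent = 3.0 + 0.8 * x1 + 0.9 * (x2 == "yes")
    intention = np.clip(np.rint(latent + rng.normal(0, 0.5, n)), 1, 5).astype(int)
    return pd.DataFrame(
        {
            "x_signal": x1,
            "flag_signal": x2,
            "x_noise": x_noise,
            "cat_noise": cat_noise,
            "constant": 1.0,
            "intention": intention,
        }
    )


class TestScreen:
    def test_detects_signal_and_flags_constant(self, linear_frame):
        results = univariate_screen(
            linear_frame,
            {
                "x_signal": "quantitative",
                "flag_signal": "categorical",
                "x_noise": "quantitative",
                "cat_noise": "categorical",
                "constant": "quantitative",
            },
        )
        by_name = {r.variable: r for r in results}
        assert by_name["x_signal"].significant and by_name["x_signal"].test == "anova"
        assert by_name["flag_signal"].significant
        assert not by_name["x_noise"].significant
        assert not by_name["cat_noise"].significant
        assert by_name["constant"].test == "none" and not by_name["constant"].significant

    def test_undeclared_type_rejected(self, linear_frame):
        with pytest.raises(ValueError, match="undeclared"):
            univariate_screen(linear_frame, {"x_signal": "ordinal"})

    def test_null_type_i_error_rate(self):
        # a covariate independent of intention should pass the screen rarely
        rng = np.random.default_rng(11)
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            frame = pd.DataFrame(
                {
                    "intention": rng.integers(1, 6, size=200),
                    "noise": rng.normal(size=200),
                }
            )
            (res,) = univariate_screen(frame, {"noise": "quantitative"})
            hits += res.significant
        assert hits / n_sim <= 0.10  # nominal 0.05 plus simulation slack


class TestLinearModel:
    def test_noiseless_recovery(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        y = 1.5 + X @ np.array([0.5, -1.0, 2.0])
        fit = IntentionRegression().fit(X, y)
        assert fit.intercept_ == pytest.approx(1.5)
        assert fit.coef_ == pytest.approx([0.5, -1.0, 2.0])
        assert fit.diagnostics_["r_squared"] == pytest.approx(1.0)
        assert fit.predict(X) == pytest.approx(np.asarray(y))

    def test_orthogonal_predictors_match_simple_slopes(self):
        # standardized orthogonal design: multiple-OLS slopes equal the
        # closed-form simple-regression slopes cov(x,y)/var(x)
        rng = np.random.default_rng(5)
        raw = rng.normal(size=(300, 2))
        q, _ = np.linalg.qr(raw - raw.mean(0))
        X = pd.DataFrame(q, columns=["u", "v"])
        y = 2.0 + 1.2 * X["u"] - 0.7 * X["v"] + rng.normal(0, 0.3, 300)
        fit = IntentionRegression().fit(X, y)
        for j, col in enumerate(X.columns):
            x = X[col] - X[col].mean()
            simple = float((x * (y - y.mean())).sum() / (x**2).sum())
            assert fit.coef_[j] == pytest.approx(simple)

    def test_tolerance_vif_identity_and_statsmodels_oracle(self, linear_frame):
        X = encode_predictors(linear_frame, ["x_signal", "flag_signal", "x_noise"])
        fit = IntentionRegression().fit(X, linear_frame["intention"])
        tol = fit.diagnostics_["tolerance"]
        vif = fit.diagnostics_["vif"]
        assert np.allclose(tol * vif, 1.0)
        design = sm.add_constant(X).to_numpy()
        for j, name in enumerate(X.columns, start=1):
            assert vif[name] == pytest.approx(variance_inflation_factor(design, j))

    def test_durbin_watson_diagnostics(self):
        from statsmodels.stats.stattools import durbin_watson

        n = 2000
        alternating = np.tile([1.0, -1.0], n // 2)
        assert durbin_watson(alternating) == pytest.approx(4 * (n - 1) / n)
        assert durbin_watson(alternating) == pytest.approx(4.0, abs=0.01)
        rng = np.random.default_rng(1)
        assert durbin_watson(rng.normal(size=5000)) == pytest.approx(2.0, abs=0.1)

    def test_shapiro_and_dw_reported(self, linear_frame):
        fit = fit_intention_regression(linear_frame, ["x_signal", "flag_signal"])
        assert 0 <= fit.diagnostics_["shapiro_wilk_p"] <= 1
        assert 0 <= fit.diagnostics_["durbin_watson"] <= 4

    def test_rank_deficient_design_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        with pytest.raises(ValueError, match="rank-deficient"):
            IntentionRegression().fit(X, [1, 2, 3, 4])

    def test_small_sample_warns(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(15, 3)))
        with pytest.warns(UserWarning, match="10 per predictor"):
            IntentionRegression().fit(X, rng.normal(size=15))

    def test_summary_frame_layout(self, linear_frame):
        fit = fit_intention_regression(linear_frame, ["x_signal"])
        table = fit.summary_frame()
        assert list(table.columns) == ["coefficient", "std_error", "t_value", "p_value"]
        assert "const" in table.index


class TestEncoding:
    def test_yes_no_and_one_hot(self, linear_frame):
        X = encode_predictors(linear_frame, ["flag_signal", "cat_noise", "x_signal"])
        assert set(X["flag_signal"].unique()) <= {0.0, 1.0}
        assert "cat_noise[b]" in X.columns and "cat_noise[c]" in X.columns
        assert "cat_noise[a]" not in X.columns  # first sorted level is reference

    def test_unknown_predictor(self, linear_frame):
        with pytest.raises(KeyError, match="unknown predictor"):
            encode_predictors(linear_frame, ["bogus"])


class TestOrdinalCheck:
    def test_agreement_on_generated_data(self, linear_frame):
        predictors = ["x_signal", "flag_signal", "x_noise"]
        linear = fit_intention_regression(linear_frame, predictors)
        ordinal = fit_ordinal_check(linear_frame, predictors)
        report = significance_agreement(linear, ordinal)
        assert report.loc[["x_signal", "flag_signal"], "agree"].all()
        assert report.loc[["x_signal", "flag_signal"], "sign_agree"].all()

    def test_sign_agreement_over_replicates(self):
        # proportional-odds generator: the two fits should agree in sign on
        # the signal coefficient in nearly all replicates
        rng = np.random.default_rng(31)
        agree = 0
        n_rep = 30
        for _ in range(n_rep):
            n = 300
            x = rng.normal(size=n)
            latent = 1.1 * x + rng.logistic(size=n)
            y = 1 + (latent[:, None] > np.array([-1.5, -0.5, 0.5, 1.5])).sum(axis=1)
            frame = pd.DataFrame({"x": x, "intention": y})
            linear = fit_intention_regression(frame, ["x"])
            ordinal = fit_ordinal_check(frame, ["x"])
            agree += bool(
                np.sign(linear.params_["x"]) == np.sign(ordinal.params_["x"])
            )
        assert agree / n_rep >= 0.95

    def test_single_level_outcome_rejected(self):
        X = pd.DataFrame({"x": [0.0, 1, 2, 3]})
        with pytest.raises(ValueError, match="single level"):
            OrdinalIntentionModel().fit(X, [3, 3, 3, 3])
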