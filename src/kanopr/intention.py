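"""Participation-intention modelling: screen, regress, cross-check.

The workflow mirrors the standard two-stage survey analysis of a 1-5
intention score:

1. **Univariate screen** — every candidate covariate is tested against the
   five intention levels (one-way ANOVA for quantitative covariates,
   chi-square / Fisher for categorical ones); covariates significant at
   ``alpha`` move on.
2. **Multiple linear regression** — ordinary least squares of the intention
   score (treated as continuous) on the screened predictors, with the usual
   diagnostic battery: Shapiro-Wilk residual normality, Durbin-Watson serial
   correlation, and per-predictor tolerance / VIF from auxiliary regressions
   (tolerance = 1 - R-squared of regressing that predictor on the others;
   VIF = 1 / tolerance).
3. **Ordinal cross-check** — a proportional-odds logistic model of the same
   outcome; the predictors significant under both models should agree when
   the linear treatment is adequate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.stats.stattools import durbin_watson


@dataclass(frozen=True)
class ScreenResult:
    """Univariate association of one candidate variable with intention."""

    variable: str
    test: str  # anova | chi-square | fisher | none
    statistic: float
    p_value: float
    significant: bool
    note: str = ""


def encode_predictors(frame: pd.DataFrame, predictors: Sequence[str]) -> pd.DataFrame:
    """Numeric design columns for the requested predictors.

    Numeric columns pass through; yes/no columns become 0/1 indicators;
    other categorical columns are expanded to one-hot indicators dropping the
    first (reference) level in sorted label order.
    """
    out = {}
    for name in predictors:
        if name not in frame.columns:
            raise KeyError(f"unknown predictor column {name!r}")
        col = frame[name]
        if pd.api.types.is_numeric_dtype(col):
            out[name] = col.astype(float)
            continue
        values = col.astype(str)
        uniq = sorted(values.dropna().unique())
        if set(uniq) <= {"yes", "no"}:
            out[name] = (values == "yes").astype(float)
        else:
            for level in uniq[1:]:
                out[f"{name}[{level}]"] = (values == level).astype(float)
    return pd.DataFrame(out, index=frame.index)


def _categorical_test(table: np.ndarray) -> tuple[str, float, float]:
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("degenerate contingency table")
    res = stats.chi2_contingency(table, correction=False)
    if (res.expected_freq >= 5).all():
        return "chi-square", float(res.statistic), float(res.pvalue)
    if table.shape == (2, 2):
        _, p = stats.fisher_exact(table.astype(int))
        return "fisher", float(res.statistic), float(p)
    return "chi-square", float(res.statistic), float(res.pvalue)


def univariate_screen(
    frame: pd.DataFrame,
    variables: Mapping[str, str],
    outcome: str = "intention",
    alpha: float = 0.05,
) -> list[ScreenResult]:
    """Test each candidate variable against the intention levels.

    ``variables`` maps variable name to ``"quantitative"`` (one-way ANOVA
    across intention levels) or ``"categorical"`` (chi-square with Fisher
    fallback).  Constant or otherwise untestable variables are returned
    flagged rather than dropped silently.
    """
    y = frame[outcome]
    results: list[ScreenResult] = []
    for name, kind in variables.items():
        if kind not in ("quantitative", "categorical"):
            raise ValueError(f"variable {name!r} has undeclared type {kind!r}")
        col = frame[name]
        mask = col.notna() & y.notna()
        sub, ysub = col[mask], y[mask]
        if sub.nunique() < 2:
            results.append(
                ScreenResult(name, "none", np.nan, np.nan, False, "constant variable")
            )
            continue
        if kind == "quantitative":
            groups = [g.to_numpy(dtype=float) for _, g in sub.groupby(ysub)]
            if len(groups) < 2:
                results.append(
                    ScreenResult(name, "none", np.nan, np.nan, False, "single outcome level")
                )
                continue
            stat, p = stats.f_oneway(*groups)
            results.append(ScreenResult(name, "anova", float(stat), float(p), p < alpha))
        else:
            table = pd.crosstab(sub, ysub).to_numpy(dtype=float)
            try:
                test, stat, p = _categorical_test(table)
            except ValueError as exc:
                results.append(ScreenResult(name, "none", np.nan, np.nan, False, str(exc)))
                continue
            results.append(ScreenResult(name, test, stat, p, p < alpha))
    return results


def screen_to_frame(results: Sequence[ScreenResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results]).set_index("variable")


class IntentionRegression(BaseEstimator, RegressorMixin):
    """OLS of the 1-5 intention score with the survey diagnostic battery.

    Parameters
    ----------
    add_intercept : bool, default True

    Attributes
    ----------
    params_, bse_, tvalues_, pvalues_ : pandas.Series
        Coefficient table (including ``const`` when an intercept is fitted).
    coef_ : ndarray of slope coefficients; ``intercept_`` : float.
    diagnostics_ : dict with ``shapiro_wilk_p``, ``durbin_watson``, and
        per-predictor ``tolerance`` / ``vif`` Series.
    resid_ : ndarray of residuals in input order.
    """

    def __init__(self, add_intercept: bool = True):
        self.add_intercept = add_intercept

    def fit(self, X, y):
        X = pd.DataFrame(X).astype(float)
        y = np.asarray(y, dtype=float)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        if X.shape[0] < 10 * X.shape[1]:
            warnings.warn(
                f"only {X.shape[0]} observations for {X.shape[1]} predictors "
                "(guideline: at least 10 per predictor)",
                UserWarning,
                stacklevel=2,
            )
        design = sm.add_constant(X, has_constant="add") if self.add_intercept else X
        if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
            raise ValueError("rank-deficient design matrix (collinear predictors)")
        ols = sm.OLS(y, design).fit()
        self.model_ = ols
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.params_ = ols.params
        self.bse_ = ols.bse
        self.tvalues_ = ols.tvalues
        self.pvalues_ = ols.pvalues
        self.intercept_ = float(ols.params.get("const", 0.0))
        self.coef_ = ols.params.drop("const", errors="ignore").to_numpy()
        self.resid_ = np.asarray(ols.resid)
        tolerance = pd.Series(
            {name: 1.0 - self._auxiliary_r2(X, name) for name in X.columns}
        )
        self.diagnostics_ = {
            "shapiro_wilk_p": float(stats.shapiro(self.resid_).pvalue),
            "durbin_watson": float(durbin_watson(self.resid_)),
            "tolerance": tolerance,
            "vif": 1.0 / tolerance,
            "r_squared": float(ols.rsquared),
        }
        return self

    @staticmethod
    def _auxiliary_r2(X: pd.DataFrame, name: str) -> float:
        if X.shape[1] == 1:
            return 0.0
        others = sm.add_constant(X.drop(columns=[name]), has_constant="add")
        return float(sm.OLS(X[name], others).fit().rsquared)

    def predict(self, X):
        X = pd.DataFrame(X).astype(float)
        design = sm.add_constant(X, has_constant="add") if self.add_intercept else X
        return np.asarray(self.model_.predict(design[self.params_.index]))

    def summary_frame(self) -> pd.DataFrame:
        """Coefficient / SE / t / p table in reporting order."""
        return pd.DataFrame(
            {
                "coefficient": self.params_.round(2),
                "std_error": self.bse_.round(2),
                "t_value": self.tvalues_.round(2),
                "p_value": self.pvalues_,
            }
        )


class OrdinalIntentionModel(BaseEstimator):
    """Proportional-odds logistic model of the ordered 1-5 intention score.

    Attributes
    ----------
    params_, pvalues_ : pandas.Series over the slope coefficients
        (threshold parameters are kept in ``model_`` but not reported here).
    converged_ : bool; ``separation_flag_`` is True when quasi-separation is
        suspected (non-convergence or exploding coefficients).
    """

    def __init__(self, method: str = "bfgs", maxiter: int = 200):
        self.method = method
        self.maxiter = maxiter

    def fit(self, X, y):
        X = pd.DataFrame(X).astype(float)
        y = pd.Series(np.asarray(y)).astype(int)
        if y.nunique() < 2:
            raise ValueError("outcome has a single level; ordinal model undefined")
        model = OrderedModel(y, X, distr="logit")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(method=self.method, maxiter=self.maxiter, disp=0)
        self.model_ = res
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.params_ = res.params[X.columns]
        self.pvalues_ = res.pvalues[X.columns]
        self.converged_ = bool(res.mle_retvals.get("converged", True))
        self.separation_flag_ = bool(
            (~np.isfinite(self.params_)).any()
            or np.abs(self.params_).max() > 15
            or not self.converged_
        )
        return self

    def predict(self, X):
        """Most probable intention level per row."""
        X = pd.DataFrame(X).astype(float)
        probs = self.model_.predict(X)
        levels = np.sort(np.unique(self.model_.model.endog))
        return levels[np.argmax(np.asarray(probs), axis=1)]


def fit_intention_regression(
    frame: pd.DataFrame, predictors: Sequence[str], outcome: str = "intention"
) -> IntentionRegression:
    """Encode predictors and fit the linear intention model."""
    X = encode_predictors(frame, predictors)
    return IntentionRegression().fit(X, frame[outcome].astype(float))


def fit_ordinal_check(
    frame: pd.DataFrame, predictors: Sequence[str], outcome: str = "intention"
) -> OrdinalIntentionModel:
    """Encode predictors and fit the proportional-odds cross-check."""
    X = encode_predictors(frame, predictors)
    return OrdinalIntentionModel().fit(X, frame[outcome])


def significance_agreement(
    linear: IntentionRegression,
    ordinal: OrdinalIntentionModel,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-predictor significance under both models, with agreement flags."""
    names = [n for n in linear.params_.index if n != "const"]
    rows = []
    for name in names:
        sig_lin = bool(linear.pvalues_[name] < alpha)
        sig_ord = bool(ordinal.pvalues_.get(name, np.nan) < alpha)
        rows.append(
            {
                "predictor": name,
                "significant_linear": sig_lin,
                "significant_ordinal": sig_ord,
                "agree": sig_lin == sig_ord,
                "sign_agree": bool(
                    np.sign(linear.params_[name]) == np.sign(ordinal.params_.get(name, 0.0))
                ),
            }
        )
    return pd.DataFrame(rows).set_index("predictor")
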