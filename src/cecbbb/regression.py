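"""Multivariate linear log BB model.

log BB (the log10 brain-to-plasma concentration ratio) is modeled as a
linear function of three in vitro descriptors:

    log BB = b0 + b1 * k' + b2 * logD7.4 + b3 * pKa

fitted by ordinary least squares on natural (unstandardized) predictor
scales. The estimator exposes the full OLS diagnostics (R^2, overall F test
and its p-value, residual sigma) plus exact t-based prediction intervals.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import NotFittedError
from sklearn.utils.validation import check_array, check_is_fitted

from .exceptions import InsufficientDataError, InvalidInputError, SingularDesignError

PREDICTORS = ("k_prime", "logd74", "pka")


class LogBBRegressor(RegressorMixin, BaseEstimator):
    """OLS regression of log BB on [k', logD7.4, pKa].

    Parameters
    ----------
    level : float
        Default coverage level for prediction intervals.

    Attributes
    ----------
    intercept_ : float
    coef_ : ndarray of shape (3,)
        Slopes on k', logD7.4 and pKa, in that order.
    se_ : ndarray of shape (4,)
        Standard errors of (intercept, slopes).
    r2_, adj_r2_, f_stat_, f_pvalue_, sigma_ : float
        Coefficient of determination, adjusted R^2, overall F statistic on
        (3, n-4) degrees of freedom, its p-value, and the residual standard
        deviation.
    xtx_inv_ : ndarray of shape (4, 4)
        (X'X)^-1 of the design including the intercept column; used for
        interval construction.
    """

    def __init__(self, level: float = 0.95):
        self.level = level

    def fit(self, X, y):
        X = check_array(X, ensure_min_samples=1, ensure_min_features=3)
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[1] != 3:
            raise InvalidInputError(
                f"expected 3 predictor columns (k', logD7.4, pKa), got {X.shape[1]}"
            )
        if X.shape[0] != y.shape[0]:
            raise InvalidInputError("X and y have different numbers of rows")
        n = X.shape[0]
        if n < 5:
            raise InsufficientDataError(
                f"need at least 5 records to fit 4 coefficients, got {n}"
            )
        design = sm.add_constant(X, has_constant="add")
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise SingularDesignError("design matrix is rank deficient")
        res = sm.OLS(y, design).fit()

        self.n_features_in_ = 3
        self.n_ = n
        self.df_resid_ = n - 4
        self.intercept_ = float(res.params[0])
        self.coef_ = np.asarray(res.params[1:], dtype=float)
        self.se_ = np.asarray(res.bse, dtype=float)
        self.r2_ = float(res.rsquared)
        self.adj_r2_ = float(res.rsquared_adj)
        self.f_stat_ = float(res.fvalue)
        self.f_pvalue_ = float(res.f_pvalue)
        self.sigma_ = float(np.sqrt(res.mse_resid))
        self.xtx_inv_ = np.linalg.inv(design.T @ design)
        self.tvalues_ = np.asarray(res.tvalues, dtype=float)
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X, ensure_min_features=3)
        if X.shape[1] != 3:
            raise InvalidInputError("predictor matrix must have 3 columns")
        return self.intercept_ + X @ self.coef_

    def prediction_interval(self, X, level: float | None = None):
        """t-based prediction interval for new observations.

        Half-width is t_{(1-level)/2, n-4} * sigma * sqrt(1 + x'(X'X)^-1 x);
        it widens away from the predictor centroid and collapses to the point
        estimate as level -> 0.
        """
        check_is_fitted(self, "coef_")
        level = self.level if level is None else level
        if not (0.0 < level < 1.0):
            raise InvalidInputError("level must lie strictly between 0 and 1")
        X = check_array(X, ensure_min_features=3)
        yhat = self.predict(X)
        design = np.column_stack([np.ones(X.shape[0]), X])
        lever = np.einsum("ij,jk,ik->i", design, self.xtx_inv_, design)
        tcrit = stats.t.ppf(0.5 + level / 2.0, self.df_resid_)
        half = tcrit * self.sigma_ * np.sqrt(1.0 + lever)
        return yhat - half, yhat + half

    def parity(self, X, y, level: float | None = None) -> pd.DataFrame:
        """Observed/predicted/interval table for parity plotting."""
        yhat = self.predict(X)
        lo, hi = self.prediction_interval(X, level=level)
        return pd.DataFrame(
            {"observed": np.asarray(y, float), "predicted": yhat,
             "lower": lo, "upper": hi}
        )

    # -- plain-text round-trippable serialization ---------------------------

    def to_dict(self) -> dict:
        check_is_fitted(self, "coef_")
        return {
            "intercept": self.intercept_,
            "coef": self.coef_.tolist(),
            "se": self.se_.tolist(),
            "r2": self.r2_,
            "adj_r2": self.adj_r2_,
            "f_stat": self.f_stat_,
            "f_pvalue": self.f_pvalue_,
            "sigma": self.sigma_,
            "n": self.n_,
            "df_resid": self.df_resid_,
            "xtx_inv": self.xtx_inv_.tolist(),
            "predictors": list(PREDICTORS),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "LogBBRegressor":
        est = cls()
        est.n_features_in_ = 3
        est.intercept_ = float(d["intercept"])
        est.coef_ = np.asarray(d["coef"], float)
        est.se_ = np.asarray(d["se"], float)
        est.r2_ = float(d["r2"])
        est.adj_r2_ = float(d["adj_r2"])
        est.f_stat_ = float(d["f_stat"])
        est.f_pvalue_ = float(d["f_pvalue"])
        est.sigma_ = float(d["sigma"])
        est.n_ = int(d["n"])
        est.df_resid_ = int(d["df_resid"])
        est.xtx_inv_ = np.asarray(d["xtx_inv"], float)
        return est

    @classmethod
    def load(cls, path: str | Path) -> "LogBBRegressor":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _design_from_records(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    missing = [c for c in (*PREDICTORS, "logbb") if c not in records.columns]
    if missing:
        raise InvalidInputError(f"records table missing columns: {missing}")
    X = records.loc[:, list(PREDICTORS)].to_numpy(dtype=float)
    y = records["logbb"].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise InvalidInputError("records contain non-finite predictor or response values")
    return X, y


def fit_ols(records: pd.DataFrame) -> LogBBRegressor:
    """Fit the log BB model from a compound table (thin estimator wrapper)."""
    X, y = _design_from_records(records)
    return LogBBRegressor().fit(X, y)


def predict_logbb(fit: LogBBRegressor, k_prime, logd74, pka) -> np.ndarray | float:
    """Point estimate of log BB for one or more predictor triples."""
    if not hasattr(fit, "coef_"):
        raise NotFittedError("model must be fitted before prediction")
    X = np.column_stack(
        [np.atleast_1d(k_prime), np.atleast_1d(logd74), np.atleast_1d(pka)]
    )
    out = fit.predict(X)
    return float(out[0]) if out.size == 1 else out


def parity_data(fit: LogBBRegressor, records: pd.DataFrame) -> pd.DataFrame:
    X, y = _design_from_records(records)
    return fit.parity(X, y)
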