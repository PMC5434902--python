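"""OLS and two-stage least squares estimators with shared conventions.

Both estimators are exposed twice: as scikit-learn style regressors
(`OLSRegressor`, `TSLSRegressor`) that compose with pipelines and model
selection, and as functions over :class:`~spsliv.data.RegressionData`
(`fit_ols`, `fit_tsls`) returning an :class:`EstimatorFit`.

Conventions shared with the shrinkage machinery:

* coefficient order is [endogenous block; exogenous block], matching
  X = [X1 X2];
* OLS:   beta_ols = (X'X)^{-1} X'y,   Var = s2_ols (X'X)^{-1},
  s2_ols = ||y - X beta_ols||^2 / (n - k);
* TSLS:  beta_iv = (Xh'Xh)^{-1} Xh'y with Xh the projection of X onto the
  column space of Z = [Z1 X2]; Var = s2_iv (Xh'Xh)^{-1}.  The residual
  variance s2_iv uses the ORIGINAL regressors, ||y - X beta_iv||^2/(n-k);
* all solves go through a QR decomposition — the n x n hat matrix is never
  materialized — and closed forms are reproduced to ~1e-8.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .data import RANK_RTOL, RegressionData, _deficient_columns, _numerical_rank
from .exceptions import (
    ContractError,
    IdentificationError,
    InsufficientDataError,
    UnderIdentifiedError,
)

__all__ = [
    "EstimatorFit",
    "FStatResult",
    "OLSRegressor",
    "TSLSRegressor",
    "fit_ols",
    "fit_tsls",
    "empirical_bias_sq",
    "first_stage_f",
]


@dataclass
class EstimatorFit:
    """Coefficients, covariance and residual variance for one method."""

    method: str
    coefficients: np.ndarray
    covariance: np.ndarray
    sigma2: float
    dof: int
    names: tuple[str, ...] = ()

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, float).ravel()
        self.covariance = np.asarray(self.covariance, float)
        k = self.coefficients.shape[0]
        if self.covariance.shape != (k, k):
            raise ContractError(
                f"covariance shape {self.covariance.shape} does not match k={k}"
            )
        if not self.names:
            self.names = tuple(f"b{j}" for j in range(k))

    @property
    def k(self) -> int:
        return self.coefficients.shape[0]

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "coefficients": dict(zip(self.names, self.coefficients.tolist())),
            "covariance": {
                nm: dict(zip(self.names, row.tolist()))
                for nm, row in zip(self.names, self.covariance)
            },
            "se": dict(zip(self.names, self.se.tolist())),
            "sigma2": float(self.sigma2),
            "dof": int(self.dof),
        }


@dataclass
class FStatResult:
    """Partial-F diagnostic for the instruments in one first-stage model."""

    statistic: float
    df1: int
    df2: int
    endogenous_column: str

    @property
    def pvalue(self) -> float:
        return float(stats.f.sf(self.statistic, self.df1, self.df2))

    def to_dict(self) -> dict:
        return {
            "statistic": float(self.statistic),
            "df1": int(self.df1),
            "df2": int(self.df2),
            "endogenous_column": self.endogenous_column,
            "pvalue": self.pvalue,
        }


# ---------------------------------------------------------------------------
# QR machinery


def _qr_reduced(A: np.ndarray, label: str, names=None):
    """Economy QR with a rank check at the shared relative tolerance."""
    rank, s = _numerical_rank(A)
    if rank < A.shape[1]:
        bad = _deficient_columns(A, list(names) if names else
                                 [f"col{j}" for j in range(A.shape[1])])
        raise IdentificationError(
            f"{label} is rank deficient (rank {rank} < {A.shape[1]}); "
            f"offending columns: {bad}"
        )
    Q, R = linalg.qr(A, mode="economic")
    return Q, R


def _lstsq_via_qr(A: np.ndarray, y: np.ndarray, label: str, names=None):
    """Solve min ||y - A b|| by QR; return (b, Rinv) with A'A = R'R."""
    Q, R = _qr_reduced(A, label, names)
    b = linalg.solve_triangular(R, Q.T @ y)
    Rinv = linalg.solve_triangular(R, np.eye(R.shape[0]))
    return b, Rinv


def _project_onto(Q: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Projection of M's columns onto span(Q) without forming the hat matrix."""
    return Q @ (Q.T @ M)


# ---------------------------------------------------------------------------
# scikit-learn estimators


class OLSRegressor(RegressorMixin, BaseEstimator):
    """Ordinary least squares with the (n - k) residual-variance convention.

    No intercept is added; include a constant column if one is wanted.

    Attributes
    ----------
    coef_ : ndarray of shape (k,)
    cov_ : ndarray of shape (k, k)
        ``sigma2_ * (X'X)^{-1}``.
    sigma2_ : float
        Residual variance with divisor ``n - k``.
    dof_ : int
        Residual degrees of freedom ``n - k``.
    """

    method = "OLS"

    def fit(self, X, y, feature_names=None):
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, float).ravel()
        n, k = X.shape
        if y.shape[0] != n:
            raise ContractError(f"X has {n} rows but y has {y.shape[0]}")
        if n <= k:
            raise InsufficientDataError(f"need n > k: n={n}, k={k}")
        names = tuple(feature_names) if feature_names else tuple(
            f"b{j}" for j in range(k)
        )
        beta, Rinv = _lstsq_via_qr(X, y, "X", names)
        resid = y - X @ beta
        sigma2 = float(resid @ resid) / (n - k)
        self.coef_ = beta
        self.cov_ = sigma2 * (Rinv @ Rinv.T)
        self.sigma2_ = sigma2
        self.dof_ = n - k
        self.n_features_in_ = k
        self.feature_names_ = names
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        return X @ self.coef_

    def to_fit(self) -> EstimatorFit:
        check_is_fitted(self, "coef_")
        return EstimatorFit(
            method=self.method,
            coefficients=self.coef_,
            covariance=self.cov_,
            sigma2=self.sigma2_,
            dof=self.dof_,
            names=self.feature_names_,
        )


class TSLSRegressor(RegressorMixin, BaseEstimator):
    """Two-stage least squares for a design with leading endogenous columns.

    Parameters
    ----------
    n_endog : int
        Number of leading columns of ``X`` treated as endogenous (the X1
        block); the remaining columns are exogenous and instrument
        themselves.

    ``fit(X, y, instruments=Z1)`` takes the excluded instruments as a fit
    parameter, so the estimator slots into sklearn pipelines whose steps
    pass fit parameters through.

    Attributes mirror :class:`OLSRegressor`; ``cov_`` is
    ``sigma2_ * (Xh'Xh)^{-1}`` with ``Xh`` the instrument-projected design,
    while ``sigma2_`` is computed from residuals against the original
    regressors with divisor ``n - k``.
    """

    method = "TSLS"

    def __init__(self, n_endog: int = 1):
        self.n_endog = n_endog

    def fit(self, X, y, instruments=None, feature_names=None):
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, float).ravel()
        n, k = X.shape
        k1 = int(self.n_endog)
        if not 1 <= k1 <= k:
            raise ContractError(f"n_endog={k1} out of range for k={k} columns")
        if instruments is None:
            raise ContractError("TSLSRegressor.fit requires instruments=Z1")
        Z1 = np.asarray(instruments, float)
        if Z1.ndim == 1:
            Z1 = Z1[:, None]
        l1 = Z1.shape[1]
        if l1 < k1:
            raise UnderIdentifiedError(
                f"order condition fails: l1={l1} < k1={k1}"
            )
        X2 = X[:, k1:]
        Z = np.hstack([Z1, X2])
        if n <= Z.shape[1]:
            raise InsufficientDataError(f"need n > l: n={n}, l={Z.shape[1]}")
        names = tuple(feature_names) if feature_names else tuple(
            f"b{j}" for j in range(k)
        )
        Qz, _ = _qr_reduced(Z, "Z = [Z1 X2]")
        Xh = _project_onto(Qz, X)
        rank_xh, _ = _numerical_rank(Xh)
        if rank_xh < k:
            raise IdentificationError(
                f"Z'X is rank deficient (projected design has rank {rank_xh} < "
                f"k={k}); the instruments do not identify all coefficients"
            )
        beta, Rinv = _lstsq_via_qr(Xh, y, "projected X", names)
        resid = y - X @ beta  # residuals against the original regressors
        sigma2 = float(resid @ resid) / (n - k)
        self.coef_ = beta
        self.cov_ = sigma2 * (Rinv @ Rinv.T)
        self.sigma2_ = sigma2
        self.dof_ = n - k
        self.n_features_in_ = k
        self.feature_names_ = names
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        return X @ self.coef_

    def to_fit(self) -> EstimatorFit:
        check_is_fitted(self, "coef_")
        return EstimatorFit(
            method=self.method,
            coefficients=self.coef_,
            covariance=self.cov_,
            sigma2=self.sigma2_,
            dof=self.dof_,
            names=self.feature_names_,
        )


# ---------------------------------------------------------------------------
# functional surface over RegressionData


def fit_ols(data: RegressionData) -> EstimatorFit:
    """OLS of y on [X1 X2]; instruments in ``data`` are ignored."""
    est = OLSRegressor().fit(data.X, data.y, feature_names=data.names)
    return est.to_fit()


def fit_tsls(data: RegressionData) -> EstimatorFit:
    """TSLS of y on [X1 X2] using Z = [Z1 X2] as instruments."""
    if data.l1 < data.k1:
        raise UnderIdentifiedError(
            f"order condition fails: l1={data.l1} < k1={data.k1}"
        )
    est = TSLSRegressor(n_endog=data.k1).fit(
        data.X, data.y, instruments=data.Z1, feature_names=data.names
    )
    return est.to_fit()


def empirical_bias_sq(candidate: EstimatorFit, tsls: EstimatorFit) -> np.ndarray:
    """Empirical squared-bias matrix (b_cand - b_iv)(b_cand - b_iv)'.

    The asymptotically unbiased TSLS fit anchors the estimate; the trace of
    the result is the squared Euclidean distance between the coefficient
    vectors (the numerator of the Hausman statistic, unnormalized).
    """
    if candidate.k != tsls.k:
        raise ContractError(
            f"dimension mismatch: candidate k={candidate.k}, tsls k={tsls.k}"
        )
    if candidate.names != tsls.names:
        raise ContractError("fits have different coefficient names/ordering")
    d = candidate.coefficients - tsls.coefficients
    return np.outer(d, d)


def first_stage_f(data: RegressionData, endogenous_index: int = 0) -> FStatResult:
    """Partial F for the instruments in one first-stage regression.

    Compares the regression of the selected X1 column on [Z1 X2] against
    the regression on X2 alone: F = ((RSS0 - RSS1)/l1) / (RSS1/(n - l)).
    """
    if data.l1 < 1:
        raise ContractError("no instruments present (l1 = 0)")
    if not 0 <= endogenous_index < data.k1:
        raise ContractError(
            f"endogenous_index {endogenous_index} out of range for k1={data.k1}"
        )
    x = data.X1[:, endogenous_index]
    rank_z, _ = _numerical_rank(data.Z)
    if rank_z < data.l:
        bad = _deficient_columns(data.Z, list(data.names_Z))
        raise IdentificationError(
            f"instruments collinear with exogenous regressors: {bad}"
        )
    Qf, _ = _qr_reduced(data.Z, "Z = [Z1 X2]")
    rss1 = float(np.sum((x - _project_onto(Qf, x)) ** 2))
    if data.k2:
        Qr, _ = _qr_reduced(data.X2, "X2", data.names_X2)
        rss0 = float(np.sum((x - _project_onto(Qr, x)) ** 2))
    else:
        rss0 = float(x @ x)
    df1 = data.l1
    df2 = data.n - data.l
    scale = RANK_RTOL * max(float(x @ x), 1.0)
    if rss1 <= scale:
        # noiseless first stage: F is 0 if the instruments add nothing,
        # infinite if they absorb a nonzero residual exactly
        stat = 0.0 if rss0 <= scale else np.inf
    else:
        stat = max((rss0 - rss1) / df1 / (rss1 / df2), 0.0)
    return FStatResult(
        statistic=stat,
        df1=df1,
        df2=df2,
        endogenous_column=data.names_X1[endogenous_index],
    )
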