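"""The semi-parametric Stein-like (SPSL) combined estimator.

The SPSL estimator is the affine combination

    beta_bar(alpha) = alpha * beta_iv + (1 - alpha) * beta_ols,

with the shrinkage weight alpha chosen to minimize the trace of the
combination's mean squared error.  Expanding the MSE of the combination,

    MSE(beta_bar(a)) = a^2 MSE_iv + 2 a (1-a) CSE + (1-a)^2 MSE_ols,

where CSE = E[(beta_iv - beta)(beta_ols - beta)'] is the cross squared
error between the two component estimators.  The trace of this expression
is a convex quadratic in ``a`` whenever tr(MSE_iv - 2 CSE + MSE_ols) > 0,
with unique minimizer

    alpha = tr(MSE_ols - CSE) / tr(MSE_iv - 2 CSE + MSE_ols).

(Sanity check: when the dose is exogenous, MSE_ols = CSE and alpha = 0 —
all weight on OLS; when the instruments reproduce the regressors,
MSE_iv = CSE and alpha = 1 — all weight on TSLS.)

The empirical weight replaces the unknown theoretical quantities with
their sample estimates.  Anchoring the bias estimates at the
asymptotically unbiased TSLS component gives, with d = b_ols - b_iv,

    MSE_iv^  = Var_iv^            (empirical TSLS bias is null)
    MSE_ols^ = Var_ols^ + d d'    (empirical OLS squared bias)
    CSE^     = s2_iv (X'X)^{-1}   (cross-bias null; see below)

    alpha_hat = tr(MSE_ols^ - CSE^) / tr(MSE_iv^ - 2 CSE^ + MSE_ols^).

Writing tau_hat = tr(Var_iv^ - CSE^) for the Stein numerator (the
estimated excess risk of TSLS over its covariance with OLS), this is

    alpha_hat = (tr(Var_ols^ - CSE^) + ||d||^2)
                / (tau_hat + tr(Var_ols^ - CSE^) + ||d||^2),

a Stein-like pull of the TSLS fit back toward OLS: the weight tends to 1
as the instruments strengthen (tau_hat -> 0) and to 0 as they weaken
(tau_hat explodes).  Note E||d||^2 = tr(MSE_iv - 2 CSE + MSE_ols), so
replacing the denominator's variance traces by the realized squared
distance gives the asymptotically equivalent ratio tau-over-distance
sometimes quoted for this estimator; that rewriting is unstable in
finite samples (the distance can be arbitrarily small while tau_hat is
not) and is not used here.  ``alpha_hat`` is deliberately NOT clamped to
[0, 1]; with positive-definite plug-ins it lands there in practice, but
nothing forces it.

CSE plug-in
-----------
Under exogenous instruments the analytic covariance of the OLS and TSLS
estimators is sigma^2 (X'X)^{-1}: writing Xh for the projection of X onto
the instrument span, X'Xh = Xh'Xh, so

    Cov(beta_iv, beta_ols) = sigma^2 (Xh'Xh)^{-1} Xh'X (X'X)^{-1}
                           = sigma^2 (X'X)^{-1}.

The plug-in uses the TSLS residual-variance estimate for sigma^2.  A
consequence worth noting: tau_hat = s2_iv * tr[(Xh'Xh)^{-1} - (X'X)^{-1}]
is nonnegative, so the empirical weight always points from OLS toward
TSLS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .data import RegressionData
from .estimators import (
    EstimatorFit,
    OLSRegressor,
    TSLSRegressor,
    _qr_reduced,
    fit_ols,
    fit_tsls,
)
from .exceptions import (
    BootstrapInstabilityError,
    ContractError,
    DegenerateShrinkageError,
    IdentificationError,
    InsufficientDataError,
    SpslivError,
)

__all__ = [
    "ShrinkageDiagnostics",
    "SPSLFit",
    "SPSLRegressor",
    "estimate_cse",
    "theoretical_alpha",
    "alpha_hat",
    "fit_spsl",
    "bootstrap_se",
]

#: below this squared distance the component estimators are treated as equal
DEGENERATE_DIST_SQ = 1e-12


@dataclass
class ShrinkageDiagnostics:
    """Everything that goes into the empirical shrinkage weight.

    ``alpha_hat`` is the affine weight on the TSLS fit (the closed-form
    weight evaluated at the empirical MSE plug-ins), ``tau_hat`` the
    Stein numerator tr(Var_iv - CSE), ``dist_sq`` the squared Euclidean
    distance between the component coefficient vectors, and ``cse`` the
    plug-in cross-squared-error matrix.  When the components coincide
    (``dist_sq`` below tolerance) every weight yields the same estimator;
    ``degenerate`` is set and alpha_hat, tau_hat are reported as 0.
    """

    alpha_hat: float
    tau_hat: float
    dist_sq: float
    cse: np.ndarray
    ols_fit: EstimatorFit
    tsls_fit: EstimatorFit
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "alpha_hat": float(self.alpha_hat),
            "tau_hat": float(self.tau_hat),
            "dist_sq": float(self.dist_sq),
            "degenerate": bool(self.degenerate),
        }


@dataclass
class SPSLFit:
    """An SPSL fit: the combined EstimatorFit plus its diagnostics."""

    fit: EstimatorFit
    diagnostics: ShrinkageDiagnostics
    bootstrap_se: Optional[np.ndarray] = None
    n_bootstrap: int = 0
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        out = self.fit.to_dict()
        out.update(self.diagnostics.to_dict())
        if self.bootstrap_se is not None:
            out["bootstrap_se"] = dict(
                zip(self.fit.names, np.asarray(self.bootstrap_se).tolist())
            )
            out["bootstrap"] = {"B": int(self.n_bootstrap), "seed": self.seed}
        return out


# ---------------------------------------------------------------------------
# building blocks


def estimate_cse(
    ols: EstimatorFit, tsls: EstimatorFit, data: RegressionData
) -> np.ndarray:
    """Plug-in cross-squared-error estimate s2_iv * (X'X)^{-1}.

    This is the analytic covariance of the OLS and TSLS estimators under
    exogenous instruments (see module docstring), evaluated at the TSLS
    residual-variance estimate.  The empirical cross-bias is taken as zero
    because the TSLS fit anchors the bias estimates.
    """
    if ols.k != tsls.k or ols.k != data.k:
        raise ContractError("fits and data disagree on the number of coefficients")
    _, R = _qr_reduced(data.X, "X = [X1 X2]", data.names)
    Rinv = linalg.solve_triangular(R, np.eye(R.shape[0]))
    return tsls.sigma2 * (Rinv @ Rinv.T)


def theoretical_alpha(
    mse_tsls: np.ndarray, mse_ols: np.ndarray, cse: np.ndarray
) -> float:
    """Closed-form minimizer of a |-> tr MSE(beta_bar(a)).

    alpha = tr(MSE_ols - CSE) / tr(MSE_iv - 2 CSE + MSE_ols), the argmin
    of the quadratic a^2 tr MSE_iv + 2a(1-a) tr CSE + (1-a)^2 tr MSE_ols.
    The supplied matrices are used as given (no PSD check).  Raises
    :class:`DegenerateShrinkageError` when the denominator trace is
    numerically zero — the case of equal component risks and zero
    distance, where the minimizer is not unique.
    """
    mse_tsls = np.asarray(mse_tsls, float)
    mse_ols = np.asarray(mse_ols, float)
    cse = np.asarray(cse, float)
    if not (mse_tsls.shape == mse_ols.shape == cse.shape) or mse_tsls.ndim != 2:
        raise ContractError("all three matrices must share a k x k shape")
    num = float(np.trace(mse_ols - cse))
    den = float(np.trace(mse_tsls - 2.0 * cse + mse_ols))
    scale = max(
        abs(np.trace(mse_tsls)), abs(np.trace(mse_ols)), abs(np.trace(cse)), 1.0
    )
    if abs(den) <= 1e-12 * scale:
        raise DegenerateShrinkageError(
            "tr(MSE_iv - 2 CSE + MSE_ols) is numerically zero; the two "
            "estimators have equal risk and the shrinkage weight is not unique"
        )
    return num / den


def alpha_hat(
    ols: EstimatorFit, tsls: EstimatorFit, cse: np.ndarray
) -> ShrinkageDiagnostics:
    """Empirical shrinkage weight from two fitted components.

    Evaluates the closed-form weight at the sample estimates
    MSE_iv^ = Var_iv^, MSE_ols^ = Var_ols^ + dd' (d the coefficient
    difference) and the supplied CSE plug-in; ``tau_hat`` = tr(Var_iv^ -
    CSE^) is reported alongside as the Stein numerator.  When the
    components coincide (dist_sq below tolerance) every weight gives the
    same combination: the weight is reported as 0 with the degenerate
    flag set.
    """
    if ols.k != tsls.k:
        raise ContractError("component fits have different dimensions")
    cse = np.asarray(cse, float)
    if cse.shape != (ols.k, ols.k):
        raise ContractError(f"cse shape {cse.shape} does not match k={ols.k}")
    d = ols.coefficients - tsls.coefficients
    dist_sq = float(d @ d)
    tau = float(np.trace(tsls.covariance - cse))
    if dist_sq < DEGENERATE_DIST_SQ:
        return ShrinkageDiagnostics(
            alpha_hat=0.0,
            tau_hat=tau,
            dist_sq=dist_sq,
            cse=cse,
            ols_fit=ols,
            tsls_fit=tsls,
            degenerate=True,
        )
    mse_ols_hat = ols.covariance + np.outer(d, d)
    try:
        a = theoretical_alpha(tsls.covariance, mse_ols_hat, cse)
    except DegenerateShrinkageError:
        return ShrinkageDiagnostics(
            alpha_hat=0.0,
            tau_hat=tau,
            dist_sq=dist_sq,
            cse=cse,
            ols_fit=ols,
            tsls_fit=tsls,
            degenerate=True,
        )
    return ShrinkageDiagnostics(
        alpha_hat=a,
        tau_hat=tau,
        dist_sq=dist_sq,
        cse=cse,
        ols_fit=ols,
        tsls_fit=tsls,
    )


def _combine(
    ols: EstimatorFit, tsls: EstimatorFit, diag: ShrinkageDiagnostics
) -> EstimatorFit:
    a = diag.alpha_hat
    coef = a * tsls.coefficients + (1.0 - a) * ols.coefficients
    # plug-in covariance at the estimated weight (alpha's own randomness
    # ignored; the pairs bootstrap is the recommended SE)
    cov = (
        a**2 * tsls.covariance
        + 2.0 * a * (1.0 - a) * diag.cse
        + (1.0 - a) ** 2 * ols.covariance
    )
    sigma2 = a * tsls.sigma2 + (1.0 - a) * ols.sigma2
    return EstimatorFit(
        method="SPSL",
        coefficients=coef,
        covariance=cov,
        sigma2=sigma2,
        dof=ols.dof,
        names=ols.names,
    )


def fit_spsl(
    data: RegressionData,
    n_bootstrap: int = 0,
    seed: Optional[int] = None,
) -> SPSLFit:
    """Fit OLS and TSLS and combine them with the empirical Stein weight.

    With ``n_bootstrap`` > 0 a pairs bootstrap of the SPSL coefficients is
    run and its elementwise standard deviations attached.
    """
    ols = fit_ols(data)
    tsls = fit_tsls(data)
    cse = estimate_cse(ols, tsls, data)
    diag = alpha_hat(ols, tsls, cse)
    fit = _combine(ols, tsls, diag)
    boot = None
    if n_bootstrap > 0:
        boot = bootstrap_se(data, "SPSL", n_bootstrap, seed)
    return SPSLFit(
        fit=fit,
        diagnostics=diag,
        bootstrap_se=boot,
        n_bootstrap=n_bootstrap,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# pairs bootstrap

_FITTERS = {
    "OLS": fit_ols,
    "TSLS": fit_tsls,
    "SPSL": lambda d: fit_spsl(d).fit,
}


def bootstrap_se(
    data: RegressionData,
    method: str,
    n_bootstrap: int = 1000,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Pairs (row-resampling) bootstrap standard errors.

    Resamples rows with replacement, refits the chosen method, and returns
    the elementwise standard deviation of the ``n_bootstrap`` coefficient
    vectors.  Resamples on which the refit fails (rank deficiency in the
    resampled design) are redrawn, with a hard cap of 10 x ``n_bootstrap``
    total draws, beyond which a :class:`BootstrapInstabilityError` reports
    the failure rate.
    """
    method = method.upper()
    if method not in _FITTERS:
        raise ContractError(f"unknown method {method!r}; use OLS, TSLS or SPSL")
    if n_bootstrap < 2:
        raise ContractError("n_bootstrap must be at least 2")
    fitter = _FITTERS[method]
    rng = np.random.default_rng(seed)
    n = data.n
    coefs = np.empty((n_bootstrap, data.k))
    done = 0
    draws = 0
    cap = 10 * n_bootstrap
    while done < n_bootstrap:
        if draws >= cap:
            rate = (draws - done) / draws
            raise BootstrapInstabilityError(
                f"bootstrap refits kept failing ({draws - done}/{draws} draws, "
                f"failure rate {rate:.1%})",
                failure_rate=rate,
            )
        idx = rng.integers(0, n, size=n)
        draws += 1
        try:
            coefs[done] = fitter(data.resample(idx)).coefficients
        except (IdentificationError, InsufficientDataError, linalg.LinAlgError):
            continue
        done += 1
    return coefs.std(axis=0, ddof=1)


# ---------------------------------------------------------------------------
# scikit-learn estimator


class SPSLRegressor(RegressorMixin, BaseEstimator):
    """Stein-like affine combination of OLS and TSLS as an sklearn estimator.

    Parameters
    ----------
    n_endog : int
        Number of leading endogenous columns of ``X``.
    n_bootstrap : int
        If positive, attach pairs-bootstrap standard errors with this many
        replications (the recommended SE for the combined estimator).
    random_state : int or None
        Seed for the bootstrap.

    Attributes
    ----------
    coef_, cov_, sigma2_, dof_ : fitted combination (cov_ is the plug-in
        covariance at the estimated weight).
    alpha_ : float
        Empirical shrinkage weight on the TSLS component (not clamped to
        [0, 1]).
    tau_, dist_sq_, degenerate_ : diagnostics; see
        :class:`ShrinkageDiagnostics`.
    ols_, tsls_ : component :class:`EstimatorFit` objects.
    bootstrap_se_ : ndarray, only when ``n_bootstrap > 0``.
    """

    method = "SPSL"

    def __init__(
        self,
        n_endog: int = 1,
        n_bootstrap: int = 0,
        random_state: Optional[int] = None,
    ):
        self.n_endog = n_endog
        self.n_bootstrap = n_bootstrap
        self.random_state = random_state

    def fit(self, X, y, instruments=None, feature_names=None):
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, float).ravel()
        k1 = int(self.n_endog)
        if instruments is None:
            raise ContractError("SPSLRegressor.fit requires instruments=Z1")
        Z1 = np.asarray(instruments, float)
        if Z1.ndim == 1:
            Z1 = Z1[:, None]
        names = tuple(feature_names) if feature_names else ()
        data = RegressionData(
            y=y,
            X1=X[:, :k1],
            X2=X[:, k1:],
            Z1=Z1,
            names_X1=names[:k1] if names else (),
            names_X2=names[k1:] if names else (),
        )
        res = fit_spsl(
            data, n_bootstrap=int(self.n_bootstrap), seed=self.random_state
        )
        self.coef_ = res.fit.coefficients
        self.cov_ = res.fit.covariance
        self.sigma2_ = res.fit.sigma2
        self.dof_ = res.fit.dof
        self.alpha_ = res.diagnostics.alpha_hat
        self.tau_ = res.diagnostics.tau_hat
        self.dist_sq_ = res.diagnostics.dist_sq
        self.degenerate_ = res.diagnostics.degenerate
        self.ols_ = res.diagnostics.ols_fit
        self.tsls_ = res.diagnostics.tsls_fit
        self.diagnostics_ = res.diagnostics
        if res.bootstrap_se is not None:
            self.bootstrap_se_ = res.bootstrap_se
        self.n_features_in_ = X.shape[1]
        self.feature_names_ = res.fit.names
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        return X @ self.coef_

    def to_fit(self) -> SPSLFit:
        check_is_fitted(self, "coef_")
        return SPSLFit(
            fit=EstimatorFit(
                method="SPSL",
                coefficients=self.coef_,
                covariance=self.cov_,
                sigma2=self.sigma2_,
                dof=self.dof_,
                names=self.feature_names_,
            ),
            diagnostics=self.diagnostics_,
            bootstrap_se=getattr(self, "bootstrap_se_", None),
            n_bootstrap=int(self.n_bootstrap),
            seed=self.random_state,
        )
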