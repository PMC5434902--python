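"""Chained-equations multiple imputation and Rubin's-rule pooling.

The workflow mirrors standard practice for trial analyses with missing
outcomes or covariates under a missing-at-random (MAR) mechanism:

1. (testing only) :func:`ampute_mar` removes values with logistic
   missingness probabilities driven by fully observed columns;
2. :func:`impute_chained` cycles Bayesian normal-linear conditional
   models over the incomplete columns to produce ``I`` completed copies
   (predictive mean matching available as an option);
3. each copy is analyzed with any of the estimators, and
   :func:`pool_rubin` combines the per-imputation estimates:

       pooled estimate = mean of the I estimates
       pooled SE^2     = W_bar + (1 + 1/I) B

   with W_bar the mean within-imputation variance and
   B = (1/(I-1)) sum (est_i - mean)^2 the between-imputation variance —
   equivalently the (I+1)/(I(I-1)) between factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .estimators import EstimatorFit
from .exceptions import ContractError, IdentificationError

__all__ = [
    "IncompleteTable",
    "PooledFit",
    "ampute_mar",
    "impute_chained",
    "pool_rubin",
]

logger = logging.getLogger(__name__)


@dataclass
class IncompleteTable:
    """A rectangular table with explicit missingness.

    ``frame`` holds NaN at missing cells; ``mask`` is True where missing.
    At least one column must be fully observed and no row may be entirely
    missing.
    """

    frame: pd.DataFrame
    missing_fraction: float = field(init=False)

    def __post_init__(self):
        self.frame = self.frame.copy()
        if self.frame.shape[1] == 0 or self.frame.shape[0] == 0:
            raise ContractError("empty table")
        mask = self.frame.isna()
        fully_observed = [c for c in self.frame.columns if not mask[c].any()]
        if not fully_observed:
            raise ContractError("at least one column must be fully observed")
        if mask.all(axis=1).any():
            bad = list(self.frame.index[mask.all(axis=1)])[:5]
            raise ContractError(f"rows entirely missing: {bad}")
        self.missing_fraction = float(mask.to_numpy().mean())

    @property
    def mask(self) -> pd.DataFrame:
        return self.frame.isna()

    @property
    def incomplete_columns(self) -> list[str]:
        m = self.mask
        return [c for c in self.frame.columns if m[c].any()]


def ampute_mar(
    frame: pd.DataFrame,
    spec: Mapping[str, Mapping],
    seed: Optional[int] = None,
) -> IncompleteTable:
    """Remove values under a MAR mechanism with logistic probabilities.

    ``spec`` maps each target column to ``{"intercept": a, "slopes":
    {col: b, ...}}``; the missingness probability for a row is
    ``expit(a + sum b * value)``.  Slope columns must not themselves be
    amputation targets (missingness may depend only on observed data).
    """
    targets = set(spec)
    for target, model in spec.items():
        if target not in frame.columns:
            raise ContractError(f"amputation target {target!r} not in table")
        for col in model.get("slopes", {}):
            if col in targets:
                raise ContractError(
                    f"missingness for {target!r} depends on {col!r}, which is "
                    "itself allowed to be missing (violates MAR-by-design)"
                )
            if col not in frame.columns:
                raise ContractError(f"missingness predictor {col!r} not in table")
    rng = np.random.default_rng(seed)
    out = frame.copy().astype(float)
    for target, model in spec.items():
        lin = np.full(len(frame), float(model.get("intercept", 0.0)))
        for col, slope in model.get("slopes", {}).items():
            lin += float(slope) * frame[col].to_numpy(float)
        prob = expit(lin)
        drop = rng.random(len(frame)) < prob
        out.loc[drop, target] = np.nan
    return IncompleteTable(out)


# ---------------------------------------------------------------------------
# chained-equations imputation


def _bayes_normal_draw(Xo, yo, Xm, rng, pmm_donors=0, pool_y=None):
    """One Bayesian normal-linear imputation draw for a single column.

    Regresses the observed values on the completed predictors, draws the
    residual variance from its scaled inverse-chi-square posterior and the
    coefficients from their normal posterior, then either draws imputations
    from the predictive normal (pmm_donors=0) or matches each predictive
    draw to the nearest observed value among ``pmm_donors`` candidates.
    """
    n_obs, p = Xo.shape
    beta_hat, res, rank, sv = np.linalg.lstsq(Xo, yo, rcond=None)
    if rank < p:
        raise IdentificationError("conditional imputation model is rank deficient")
    resid = yo - Xo @ beta_hat
    rss = float(resid @ resid)
    nu = max(n_obs - p, 1)
    if rss <= 1e-12 * max(float(yo @ yo), 1.0):
        # perfectly linear column: deterministic prediction
        return Xm @ beta_hat
    sigma2 = rss / rng.chisquare(nu)
    XtX = Xo.T @ Xo
    cov = sigma2 * np.linalg.inv(XtX)
    beta = rng.multivariate_normal(beta_hat, cov, method="cholesky")
    pred = Xm @ beta
    if pmm_donors <= 0:
        return pred + rng.normal(0.0, np.sqrt(sigma2), size=Xm.shape[0])
    # predictive mean matching against observed fitted values
    fitted_obs = Xo @ beta_hat
    out = np.empty(Xm.shape[0])
    for i, pv in enumerate(pred):
        order = np.argsort(np.abs(fitted_obs - pv))[: min(pmm_donors, n_obs)]
        out[i] = yo[rng.choice(order)]
    return out


def impute_chained(
    table: IncompleteTable,
    n_imputations: int = 100,
    sweeps: int = 10,
    seed: Optional[int] = None,
    pmm_donors: int = 0,
    columns: Optional[Sequence[str]] = None,
) -> list[pd.DataFrame]:
    """Multiple imputation by chained equations.

    Each incomplete column is imputed from a Bayesian normal-linear model
    on all other columns (plus an intercept), cycling ``sweeps`` times;
    the ``n_imputations`` copies use independent RNG streams spawned from
    ``seed`` so they differ and are reproducible.  Columns taking only
    values {0, 1} are imputed by thresholding the draw at 1/2 (logged).

    ``pmm_donors`` > 0 switches to predictive mean matching with that many
    donor candidates.  ``columns`` restricts which columns serve as
    predictors (default: all).
    """
    if n_imputations < 2:
        raise ContractError("n_imputations must be at least 2")
    if sweeps < 1:
        raise ContractError("sweeps must be at least 1")
    frame = table.frame
    cols = list(columns) if columns is not None else list(frame.columns)
    incomplete = [c for c in table.incomplete_columns if c in cols]
    mask = table.mask
    binary_cols = {
        c
        for c in incomplete
        if set(np.unique(frame[c].dropna().to_numpy(float))) <= {0.0, 1.0}
    }
    for c in binary_cols:
        logger.info("column %r looks binary; imputing by thresholded draw", c)
    children = np.random.SeedSequence(seed).spawn(max(n_imputations, 1))
    completed: list[pd.DataFrame] = []
    col_means = frame[cols].mean()
    for i in range(n_imputations):
        rng = np.random.default_rng(children[i])
        work = frame.copy()
        if not incomplete:
            completed.append(work)
            continue
        # initialize missing cells with column means
        work = work.fillna(col_means)
        for _ in range(sweeps):
            for c in incomplete:
                miss = mask[c].to_numpy()
                preds = [q for q in cols if q != c]
                Xall = np.column_stack(
                    [np.ones(len(work))] + [work[q].to_numpy(float) for q in preds]
                )
                yo = frame.loc[~miss, c].to_numpy(float)
                try:
                    draws = _bayes_normal_draw(
                        Xall[~miss], yo, Xall[miss], rng, pmm_donors=pmm_donors
                    )
                except IdentificationError as err:
                    raise IdentificationError(
                        f"conditional model for column {c!r} is rank deficient"
                    ) from err
                if c in binary_cols:
                    draws = (draws >= 0.5).astype(float)
                work.loc[miss, c] = draws
        completed.append(work)
    return completed


# ---------------------------------------------------------------------------
# Rubin's rules


@dataclass
class PooledFit:
    """Rubin's-rule pooled coefficients and standard errors."""

    n_imputations: int
    names: tuple[str, ...]
    estimates: np.ndarray          # (I, k) per-imputation coefficients
    within: np.ndarray             # (I, k) per-imputation variances
    coefficients: np.ndarray = field(init=False)
    within_variance: np.ndarray = field(init=False)
    between_variance: np.ndarray = field(init=False)
    se: np.ndarray = field(init=False)

    def __post_init__(self):
        I = self.n_imputations
        if I < 2:
            raise ContractError("pooling requires at least 2 imputations")
        if self.estimates.shape != (I, len(self.names)) or self.within.shape != (
            I,
            len(self.names),
        ):
            raise ContractError("estimate/variance arrays do not match I x k")
        self.coefficients = self.estimates.mean(axis=0)
        self.within_variance = self.within.mean(axis=0)
        self.between_variance = self.estimates.var(axis=0, ddof=1)
        self.se = np.sqrt(
            self.within_variance + (1.0 + 1.0 / I) * self.between_variance
        )

    def to_dict(self) -> dict:
        return {
            "n_imputations": int(self.n_imputations),
            "coefficients": dict(zip(self.names, self.coefficients.tolist())),
            "se": dict(zip(self.names, self.se.tolist())),
            "within_variance": dict(zip(self.names, self.within_variance.tolist())),
            "between_variance": dict(
                zip(self.names, self.between_variance.tolist())
            ),
        }


def pool_rubin(
    fits: Sequence[EstimatorFit],
    within_variances: Optional[Sequence[np.ndarray]] = None,
) -> PooledFit:
    """Pool per-imputation fits with Rubin's rules.

    By default the within-imputation variances are the diagonals of each
    fit's covariance; ``within_variances`` overrides them (e.g. with
    per-imputation bootstrap variances for the combined estimator, whose
    plug-in covariance ignores the randomness of the shrinkage weight).
    """
    fits = list(fits)
    if len(fits) < 2:
        raise ContractError("pooling requires at least 2 imputations")
    names = fits[0].names
    for f in fits[1:]:
        if f.names != names:
            raise ContractError(
                f"inconsistent coefficient names across imputations: "
                f"{f.names} vs {names}"
            )
    est = np.vstack([f.coefficients for f in fits])
    if within_variances is not None:
        win = np.vstack([np.asarray(w, float).ravel() for w in within_variances])
        if win.shape != est.shape:
            raise ContractError("within_variances shape does not match fits")
    else:
        win = np.vstack([np.diag(f.covariance) for f in fits])
    return PooledFit(
        n_imputations=len(fits), names=names, estimates=est, within=win
    )
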