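"""Standardized two-stage data-generating model and Monte Carlo harness.

The generator emulates a two-arm randomized trial with a dose-response
structure:

    Y_i = beta_B B_i + beta_S S_i + eta U_i + eps_i
    S_i = c B_i + c R_i + c R_i B_i + eta U_i + delta_i

where B is a baseline covariate ~ N(0, sigma_B^2), U an unobserved
confounder ~ N(0, 1), R ~ Bernoulli(p) the randomization indicator, and
eps, delta independent mean-zero normal errors.  The three first-stage
coefficients are set equal (the minimal choice consistent with a single
instrument-strength constraint), and the error variances are solved so
that, writing W := B + R + RB,

    Var(S) = Var(Y) = 1,   Cor(S, U) = eta,   Cor(S, W) = kappa.

``eta`` is the degree of endogeneity of the dose and ``kappa`` the
strength of the instruments.  With unit marginal variances the dose
effect beta_S is a standardized regression coefficient.

Moment algebra (B and R independent, E B = 0):

    E W      = p
    Var W    = sigma_B^2 (1 + 3p) + p(1 - p)
    Cov(B,W) = sigma_B^2 (1 + p)

so S = c W + eta U + delta gives c = kappa / sd(W) and

    sigma_delta^2 = 1 - kappa^2 - eta^2
    sigma_eps^2   = 1 - beta_B^2 sigma_B^2 - beta_S^2 - eta^2 (1 + 2 beta_S)
                    - 2 beta_B beta_S c sigma_B^2 (1 + p).

Estimation on simulated data uses X1 = {S}, X2 = {B}, Z1 = {R, R*B} with
no intercept (the generating model has none); ``include_intercept`` adds
one for robustness experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .data import RegressionData
from .estimators import fit_ols
from .exceptions import ContractError, InfeasibleScenarioError, MonteCarloHarnessError, SpslivError
from .shrinkage import fit_spsl

__all__ = [
    "Scenario",
    "SolvedScenario",
    "SimulatedDataset",
    "MonteCarloSummary",
    "GRID_ETAS",
    "GRID_KAPPAS",
    "default_grid",
    "solve_scenario",
    "simulate_trial",
    "run_monte_carlo",
]

#: the endogeneity / instrument-strength grid used throughout
GRID_ETAS = (0.0, 0.25, 0.5)
GRID_KAPPAS = (0.01, 0.25, 0.5)


@dataclass(frozen=True)
class Scenario:
    """One simulation condition.

    Parameters
    ----------
    eta : float
        Target Cor(S, U) — degree of endogeneity of the dose. In [0, 1).
    kappa : float
        Target Cor(S, B + R + RB) — instrument strength. In [0, 1).
    n : int
        Sample size per simulated trial (>= 10).
    beta_S : float
        True standardized dose effect (default 1/4).
    beta_B : float
        Baseline-covariate effect on the outcome (default 1/4).
    sigma_B2 : float
        Variance of the baseline covariate (default 0.3).
    p : float
        Randomization probability (default 1/2).
    """

    eta: float
    kappa: float
    n: int = 500
    beta_S: float = 0.25
    beta_B: float = 0.25
    sigma_B2: float = 0.3
    p: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.eta < 1.0:
            raise ContractError(f"eta must be in [0, 1), got {self.eta}")
        if not 0.0 <= self.kappa < 1.0:
            raise ContractError(f"kappa must be in [0, 1), got {self.kappa}")
        if self.n < 10:
            raise ContractError(f"n must be >= 10, got {self.n}")
        if self.sigma_B2 <= 0:
            raise ContractError(f"sigma_B2 must be positive, got {self.sigma_B2}")
        if not 0.0 < self.p < 1.0:
            raise ContractError(f"p must be in (0, 1), got {self.p}")


@dataclass(frozen=True)
class SolvedScenario:
    """A scenario plus the first-stage coefficient and error variances."""

    scenario: Scenario
    c: float
    sigma_eps2: float
    sigma_delta2: float

    def __post_init__(self):
        # self-check of the solver's moment algebra
        sc = self.scenario
        var_w = _var_w(sc)
        var_s = self.c**2 * var_w + sc.eta**2 + self.sigma_delta2
        cov_bs = self.c * sc.sigma_B2 * (1.0 + sc.p)
        var_y = (
            sc.beta_B**2 * sc.sigma_B2
            + sc.beta_S**2 * var_s
            + sc.eta**2
            + self.sigma_eps2
            + 2.0 * sc.beta_B * sc.beta_S * cov_bs
            + 2.0 * sc.beta_S * sc.eta**2
        )
        if abs(var_s - 1.0) > 1e-8 or abs(var_y - 1.0) > 1e-8:
            raise ContractError(
                f"solved scenario violates unit-variance constraints: "
                f"Var(S)={var_s:.10f}, Var(Y)={var_y:.10f}"
            )


def _var_w(sc: Scenario) -> float:
    """Var(B + R + RB) in closed form from independence of B and R."""
    return sc.sigma_B2 * (1.0 + 3.0 * sc.p) + sc.p * (1.0 - sc.p)


def solve_scenario(scenario: Scenario) -> SolvedScenario:
    """Solve the standardization constraints for (c, sigma_eps2, sigma_delta2).

    Raises :class:`InfeasibleScenarioError` when no positive error
    variances satisfy the constraints (eta and kappa jointly too large).
    """
    sc = scenario
    var_w = _var_w(sc)
    c = sc.kappa / np.sqrt(var_w)
    sigma_delta2 = 1.0 - sc.kappa**2 - sc.eta**2
    if sigma_delta2 <= 0.0:
        raise InfeasibleScenarioError(
            f"implied Var(delta) = 1 - kappa^2 - eta^2 = {sigma_delta2:.6f} <= 0 "
            f"for eta={sc.eta}, kappa={sc.kappa}"
        )
    cov_bs = c * sc.sigma_B2 * (1.0 + sc.p)
    sigma_eps2 = (
        1.0
        - sc.beta_B**2 * sc.sigma_B2
        - sc.beta_S**2
        - sc.eta**2 * (1.0 + 2.0 * sc.beta_S)
        - 2.0 * sc.beta_B * sc.beta_S * cov_bs
    )
    if sigma_eps2 <= 0.0:
        raise InfeasibleScenarioError(
            f"implied Var(eps) = {sigma_eps2:.6f} <= 0 for eta={sc.eta}, "
            f"kappa={sc.kappa} at the given effect sizes"
        )
    return SolvedScenario(
        scenario=sc, c=float(c), sigma_eps2=float(sigma_eps2),
        sigma_delta2=float(sigma_delta2),
    )


@dataclass
class SimulatedDataset:
    """One simulated trial; U is oracle-only and never enters estimation."""

    Y: np.ndarray
    S: np.ndarray
    B: np.ndarray
    R: np.ndarray
    U: np.ndarray
    solved: SolvedScenario

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def instrument_score(self) -> np.ndarray:
        """The combined instrument score W = B + R + RB."""
        return self.B + self.R + self.R * self.B

    def to_regression_data(self, include_intercept: bool = False) -> RegressionData:
        """Analysis view: X1={S}, X2={B[, const]}, Z1={R, R*B}; U excluded."""
        x2 = self.B[:, None]
        names_x2 = ("B",)
        if include_intercept:
            x2 = np.column_stack([x2, np.ones(self.n)])
            names_x2 = ("B", "const")
        return RegressionData(
            y=self.Y,
            X1=self.S[:, None],
            X2=x2,
            Z1=np.column_stack([self.R, self.R * self.B]),
            names_X1=("S",),
            names_X2=names_x2,
            names_Z1=("R", "RB"),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"Y": self.Y, "S": self.S, "B": self.B, "R": self.R, "U": self.U}
        )


def simulate_trial(
    solved: SolvedScenario,
    seed=None,
    n: Optional[int] = None,
) -> SimulatedDataset:
    """Draw one trial from the solved model; same seed, same bits.

    ``seed`` may be an int, a ``numpy.random.SeedSequence`` or a
    ``Generator``; ``n`` overrides the scenario's sample size.
    """
    sc = solved.scenario
    n = sc.n if n is None else int(n)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    B = rng.normal(0.0, np.sqrt(sc.sigma_B2), size=n)
    U = rng.normal(0.0, 1.0, size=n)
    R = (rng.random(n) < sc.p).astype(float)
    delta = rng.normal(0.0, np.sqrt(solved.sigma_delta2), size=n)
    eps = rng.normal(0.0, np.sqrt(solved.sigma_eps2), size=n)
    S = solved.c * (B + R + R * B) + sc.eta * U + delta
    Y = sc.beta_B * B + sc.beta_S * S + sc.eta * U + eps
    return SimulatedDataset(Y=Y, S=S, B=B, R=R, U=U, solved=solved)


# ---------------------------------------------------------------------------
# Monte Carlo harness

_METHODS = ("OLS", "TSLS", "SPSL")


@dataclass
class MonteCarloSummary:
    """Replicated-fit summaries for one scenario.

    ``estimates[method]`` is the (m_ok, k) array of coefficient vectors in
    the order (S, B[, const]); summary arrays are per coefficient.  The
    variance uses the divisor m (not m-1) so that RMSE^2 = bias^2 +
    variance holds exactly.
    """

    scenario: Scenario
    m: int
    seed: Optional[int]
    names: tuple[str, ...]
    truth: np.ndarray
    estimates: dict[str, np.ndarray]
    alpha_hats: np.ndarray
    n_failures: int = 0
    mean: dict[str, np.ndarray] = field(default_factory=dict)
    bias: dict[str, np.ndarray] = field(default_factory=dict)
    variance: dict[str, np.ndarray] = field(default_factory=dict)
    rmse: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for meth, est in self.estimates.items():
            mu = est.mean(axis=0)
            self.mean[meth] = mu
            self.bias[meth] = mu - self.truth
            self.variance[meth] = est.var(axis=0)  # ddof=0 by design
            self.rmse[meth] = np.sqrt(self.bias[meth] ** 2 + self.variance[meth])

    def trace_mse(self, method: str) -> float:
        """Trace of the Monte Carlo MSE matrix over all coefficients."""
        dev = self.estimates[method] - self.truth
        return float(np.mean(np.sum(dev**2, axis=1)))

    def root_trace_mse(self, method: str) -> float:
        """Scalar RMSE := (tr MSE)^{1/2}."""
        return float(np.sqrt(self.trace_mse(method)))

    def ecdf(self, method: str, grid, coefficient: int = 0) -> np.ndarray:
        """Empirical CDF F(b) = m^{-1} sum I{est <= b} of one coefficient."""
        est = np.sort(self.estimates[method][:, coefficient])
        grid = np.atleast_1d(np.asarray(grid, float))
        return np.searchsorted(est, grid, side="right") / est.shape[0]

    def to_dict(self) -> dict:
        sc = self.scenario
        out = {
            "scenario": {
                "eta": sc.eta, "kappa": sc.kappa, "n": sc.n,
                "beta_S": sc.beta_S, "beta_B": sc.beta_B,
                "sigma_B2": sc.sigma_B2, "p": sc.p,
            },
            "m": int(self.m),
            "seed": self.seed,
            "n_failures": int(self.n_failures),
            "names": list(self.names),
            "alpha_hat_mean": float(self.alpha_hats.mean()),
            "estimators": {},
        }
        for meth in self.estimates:
            out["estimators"][meth] = {
                "mean": dict(zip(self.names, self.mean[meth].tolist())),
                "bias": dict(zip(self.names, self.bias[meth].tolist())),
                "variance": dict(zip(self.names, self.variance[meth].tolist())),
                "rmse": dict(zip(self.names, self.rmse[meth].tolist())),
                "root_trace_mse": self.root_trace_mse(meth),
            }
        return out


def run_monte_carlo(
    scenario: Scenario,
    m: int,
    seed: Optional[int] = None,
    include_intercept: bool = False,
) -> MonteCarloSummary:
    """Simulate ``m`` trials and fit OLS, TSLS and SPSL on each.

    Per-replicate RNG streams are spawned from ``SeedSequence(seed)`` so
    replicates are independent yet reproducible.  Replicate-level fit
    failures are skipped and counted; more than 1% of them aborts the run.
    """
    if m < 2:
        raise ContractError("m must be at least 2")
    solved = solve_scenario(scenario)
    children = np.random.SeedSequence(seed).spawn(m)
    k = 2 + int(include_intercept)
    est = {meth: np.empty((m, k)) for meth in _METHODS}
    alphas = np.empty(m)
    failures = 0
    ok = 0
    names: tuple[str, ...] = ()
    for t in range(m):
        rng = np.random.default_rng(children[t])
        data = simulate_trial(solved, seed=rng).to_regression_data(
            include_intercept=include_intercept
        )
        try:
            ols = fit_ols(data)
            spsl = fit_spsl(data)
        except SpslivError:
            failures += 1
            continue
        names = names or data.names
        est["OLS"][ok] = ols.coefficients
        est["TSLS"][ok] = spsl.diagnostics.tsls_fit.coefficients
        est["SPSL"][ok] = spsl.fit.coefficients
        alphas[ok] = spsl.diagnostics.alpha_hat
        ok += 1
    if failures > 0.01 * m:
        raise MonteCarloHarnessError(
            f"{failures}/{m} replicates failed to fit (> 1% tolerated)"
        )
    truth = np.array(
        [scenario.beta_S, scenario.beta_B] + ([0.0] if include_intercept else [])
    )
    return MonteCarloSummary(
        scenario=scenario,
        m=m,
        seed=seed,
        names=names,
        truth=truth,
        estimates={meth: est[meth][:ok] for meth in _METHODS},
        alpha_hats=alphas[:ok],
        n_failures=failures,
    )


def default_grid(n: int = 500, **kwargs) -> list[Scenario]:
    """The 3 x 3 endogeneity-by-instrument-strength scenario grid."""
    return [
        Scenario(eta=e, kappa=kp, n=n, **kwargs)
        for e in GRID_ETAS
        for kp in GRID_KAPPAS
    ]
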