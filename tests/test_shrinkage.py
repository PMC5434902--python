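import numpy as np
import pytest

from spsliv import (
    RegressionData,
    Scenario,
    alpha_hat,
    bootstrap_se,
    estimate_cse,
    fit_ols,
    fit_spsl,
    fit_tsls,
    simulate_trial,
    solve_scenario,
    theoretical_alpha,
)
from spsliv.estimators import EstimatorFit, _qr_reduced
from spsliv.exceptions import BootstrapInstabilityError, DegenerateShrinkageError
from spsliv.shrinkage import SPSLRegressor, _combine

from .oracles import grid_search_alpha, random_psd, trace_mse_quadratic


def _self_instrumented(seed=21, n=60):
    """Z1 = X1, so OLS and TSLS coincide exactly."""
    rng = np.random.default_rng(seed)
    x1 = rng.normal(size=(n, 1))
    x2 = rng.normal(size=(n, 1))
    y = x1[:, 0] + x2[:, 0] + rng.normal(size=n)
    return RegressionData(y=y, X1=x1, X2=x2, Z1=x1.copy(), names_Z1=("zz",))


# ---------------------------------------------------------------------------
# CSE plug-in


def test_cse_projection_identity(trial_data):
    """X'Xh = Xh'Xh — the identity behind the plug-in CSE form."""
    d = trial_data
    Qz, _ = _qr_reduced(d.Z, "Z")
    Xh = Qz @ (Qz.T @ d.X)
    np.testing.assert_allclose(d.X.T @ Xh, Xh.T @ Xh, atol=1e-8)


def test_cse_equals_ols_covariance_when_z_spans_x():
    d = _self_instrumented()
    ols, tsls = fit_ols(d), fit_tsls(d)
    cse = estimate_cse(ols, tsls, d)
    # same matrix up to which sigma^2 estimate scales it
    np.testing.assert_allclose(cse, ols.covariance * tsls.sigma2 / ols.sigma2,
                               rtol=1e-10)


def test_cse_symmetric_psd(trial_data):
    cse = estimate_cse(fit_ols(trial_data), fit_tsls(trial_data), trial_data)
    np.testing.assert_allclose(cse, cse.T, atol=1e-12)
    assert np.linalg.eigvalsh(cse).min() >= 0.0


def test_cse_matches_monte_carlo_cross_moment():
    """MC cross-moment (1/m) sum (b_iv - b)(b_ols - b)' vs the plug-in.

    Run under an exogenous-dose scenario so both estimators are unbiased
    and the cross moment is a pure covariance.
    """
    scenario = Scenario(eta=0.0, kappa=0.5, n=1000)
    solved = solve_scenario(scenario)
    truth = np.array([scenario.beta_S, scenario.beta_B])
    m = 3000
    children = np.random.SeedSequence(314).spawn(m)
    cross = np.zeros((2, 2))
    plug = np.zeros((2, 2))
    for t in range(m):
        d = simulate_trial(solved, seed=np.random.default_rng(children[t]))
        data = d.to_regression_data()
        ols, tsls = fit_ols(data), fit_tsls(data)
        cross += np.outer(tsls.coefficients - truth, ols.coefficients - truth)
        plug += estimate_cse(ols, tsls, data)
    cross /= m
    plug /= m
    assert np.trace(cross) == pytest.approx(np.trace(plug), rel=0.15)


# ---------------------------------------------------------------------------
# closed-form shrinkage weight


def test_alpha_half_for_symmetric_risks():
    rng = np.random.default_rng(1)
    M = random_psd(rng, 3)
    C = 0.1 * random_psd(rng, 3)
    assert theoretical_alpha(M, M, C) == pytest.approx(0.5)


def test_alpha_endpoints():
    rng = np.random.default_rng(2)
    M_iv, M_ols = random_psd(rng, 3), random_psd(rng, 3)
    # CSE equal to the OLS risk: zero numerator, all weight on OLS
    assert theoretical_alpha(M_iv, M_ols, M_ols) == pytest.approx(0.0)
    # CSE equal to the TSLS risk: all weight on TSLS
    assert theoretical_alpha(M_iv, M_ols, M_iv) == pytest.approx(1.0)


def test_alpha_degenerate_raises():
    M = np.eye(2)
    with pytest.raises(DegenerateShrinkageError):
        theoretical_alpha(M, M, M)


def test_alpha_matches_grid_search_oracle():
    rng = np.random.default_rng(99)
    for _ in range(25):
        M_iv = random_psd(rng, 3)
        M_ols = random_psd(rng, 3)
        C = 0.3 * random_psd(rng, 3)
        a = theoretical_alpha(M_iv, M_ols, C)
        a_grid = grid_search_alpha(M_iv, M_ols, C)
        assert a == pytest.approx(a_grid, abs=1e-3)


def test_trace_objective_convex_and_minimized_at_alpha():
    rng = np.random.default_rng(55)
    M_iv, M_ols, C = random_psd(rng, 2), random_psd(rng, 2), 0.2 * random_psd(rng, 2)
    grid = np.linspace(-2, 3, 501)
    vals = np.array([trace_mse_quadratic(a, M_iv, M_ols, C) for a in grid])
    second_diff = np.diff(vals, 2)
    assert second_diff.min() >= -1e-10
    a_star = theoretical_alpha(M_iv, M_ols, C)
    assert np.all(vals >= trace_mse_quadratic(a_star, M_iv, M_ols, C) - 1e-12)


# ---------------------------------------------------------------------------
# empirical weight and the combined fit


def test_alpha_hat_degenerate_when_components_coincide():
    d = _self_instrumented()
    res = fit_spsl(d)
    assert res.diagnostics.degenerate
    np.testing.assert_allclose(
        res.fit.coefficients, fit_ols(d).coefficients, atol=1e-10
    )


def test_alpha_hat_arithmetic_oracle():
    """Hand-computed ratio of traces for fixed small covariance matrices."""
    ols = EstimatorFit("OLS", [1.0, 0.0], np.diag([0.2, 0.3]), 1.0, 10)
    tsls = EstimatorFit("TSLS", [0.0, 1.0], np.diag([0.8, 0.7]), 1.2, 10)
    cse = np.diag([0.1, 0.1])
    diag = alpha_hat(ols, tsls, cse)
    d2 = 2.0  # ||(1,0)-(0,1)||^2
    # num = tr(Var_ols + dd' - cse) = (0.2+0.3) + 2 - 0.2 = 2.3
    # den = tr(Var_iv - 2 cse + Var_ols + dd') = 1.5 - 0.4 + 0.5 + 2 = 3.6
    assert diag.dist_sq == pytest.approx(d2)
    assert diag.tau_hat == pytest.approx(1.5 - 0.2)
    assert diag.alpha_hat == pytest.approx(2.3 / 3.6)


def test_spsl_at_forced_endpoints(trial_data):
    ols, tsls = fit_ols(trial_data), fit_tsls(trial_data)
    cse = estimate_cse(ols, tsls, trial_data)
    diag = alpha_hat(ols, tsls, cse)
    diag.alpha_hat = 1.0
    np.testing.assert_allclose(
        _combine(ols, tsls, diag).coefficients, tsls.coefficients, atol=1e-12
    )
    diag.alpha_hat = 0.0
    np.testing.assert_allclose(
        _combine(ols, tsls, diag).coefficients, ols.coefficients, atol=1e-12
    )


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_spsl_collinear_with_components(seed):
    solved = solve_scenario(Scenario(eta=0.25, kappa=0.25, n=200))
    data = simulate_trial(solved, seed=seed).to_regression_data()
    res = fit_spsl(data)
    b_ols = res.diagnostics.ols_fit.coefficients
    b_iv = res.diagnostics.tsls_fit.coefficients
    dev = res.fit.coefficients - b_ols
    direction = b_iv - b_ols
    # deviation from OLS is parallel to the OLS->TSLS segment
    cross = dev[0] * direction[1] - dev[1] * direction[0]
    assert abs(cross) < 1e-10
    # affine-combination identity
    np.testing.assert_allclose(
        res.fit.coefficients,
        res.diagnostics.alpha_hat * b_iv
        + (1 - res.diagnostics.alpha_hat) * b_ols,
        atol=1e-12,
    )


def test_spsl_sklearn_estimator(trial_data):
    d = trial_data
    est = SPSLRegressor(n_endog=1, n_bootstrap=25, random_state=5)
    est.fit(d.X, d.y, instruments=d.Z1, feature_names=d.names)
    assert hasattr(est, "alpha_") and hasattr(est, "bootstrap_se_")
    ref = fit_spsl(d, n_bootstrap=25, seed=5)
    np.testing.assert_allclose(est.coef_, ref.fit.coefficients, atol=1e-12)
    np.testing.assert_allclose(est.bootstrap_se_, ref.bootstrap_se, atol=1e-12)
    params = est.get_params()
    assert params["n_bootstrap"] == 25 and params["random_state"] == 5


# ---------------------------------------------------------------------------
# bootstrap


def test_bootstrap_reproducible_and_noiseless_zero():
    rng = np.random.default_rng(77)
    X1 = rng.normal(size=(40, 1))
    X2 = np.column_stack([np.ones(40), rng.normal(size=40)])
    y = X1[:, 0] * 2.0 + X2 @ np.array([1.0, -0.5])  # exact, no noise
    d = RegressionData(y=y, X1=X1, X2=X2, names_X2=("const", "w"))
    se1 = bootstrap_se(d, "OLS", n_bootstrap=30, seed=123)
    se2 = bootstrap_se(d, "OLS", n_bootstrap=30, seed=123)
    np.testing.assert_array_equal(se1, se2)
    np.testing.assert_allclose(se1, 0.0, atol=1e-10)


def test_bootstrap_ols_approaches_analytic_se():
    solved = solve_scenario(Scenario(eta=0.0, kappa=0.5, n=5000))
    data = simulate_trial(solved, seed=6).to_regression_data()
    boot = bootstrap_se(data, "OLS", n_bootstrap=300, seed=7)
    analytic = np.sqrt(np.diag(fit_ols(data).covariance))
    np.testing.assert_allclose(boot, analytic, rtol=0.10)


def test_bootstrap_instability_reported():
    # indicator-style design: the resampled X is full rank only when rows
    # 1..8 all reappear, which happens far too rarely for the 10x cap
    n = 10
    X2 = np.zeros((n, 8))
    for j in range(8):
        X2[j + 1, j] = 1.0
    X1 = np.ones((n, 1))
    y = np.arange(float(n))
    d = RegressionData(y=y, X1=X1, X2=X2)
    with pytest.raises(BootstrapInstabilityError) as exc:
        bootstrap_se(d, "OLS", n_bootstrap=200, seed=1)
    assert 0.0 < exc.value.failure_rate <= 1.0
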