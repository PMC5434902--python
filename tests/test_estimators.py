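import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from spsliv import (
    OLSRegressor,
    RegressionData,
    TSLSRegressor,
    empirical_bias_sq,
    first_stage_f,
    fit_ols,
    fit_tsls,
)
from spsliv.exceptions import ContractError

from .oracles import (
    iv_closed_form,
    nested_f,
    ols_normal_equations,
    outer_product_loop,
    two_stage_sequential,
)


def _rand_iv_data(seed, n=120, k1=1, k2=2, l1=2):
    rng = np.random.default_rng(seed)
    z1 = rng.normal(size=(n, l1))
    x2 = rng.normal(size=(n, k2))
    u = rng.normal(size=n)
    x1 = (
        z1 @ rng.normal(scale=0.8, size=(l1, k1))
        + x2 @ rng.normal(scale=0.3, size=(k2, k1))
        + u[:, None]
        + rng.normal(size=(n, k1))
    )
    beta = rng.normal(size=k1 + k2)
    y = np.hstack([x1, x2]) @ beta + u + rng.normal(size=n)
    return RegressionData(y=y, X1=x1, X2=x2, Z1=z1)


# ---------------------------------------------------------------------------
# OLS


def test_ols_noiseless_recovers_exactly():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(15, 3))
    b = np.array([2.0, -1.0, 0.5])
    fit = OLSRegressor().fit(X, X @ b).to_fit()
    np.testing.assert_allclose(fit.coefficients, b, atol=1e-10)
    assert fit.sigma2 == pytest.approx(0.0, abs=1e-18)


def test_ols_orthonormal_design():
    rng = np.random.default_rng(4)
    Q, _ = np.linalg.qr(rng.normal(size=(20, 3)))
    y = rng.normal(size=20)
    fit = OLSRegressor().fit(Q, y).to_fit()
    np.testing.assert_allclose(fit.coefficients, Q.T @ y, atol=1e-12)


def test_ols_matches_normal_equation_oracle(small_ols_data):
    X, y = small_ols_data
    fit = OLSRegressor().fit(X, y).to_fit()
    np.testing.assert_allclose(fit.coefficients, ols_normal_equations(X, y), atol=1e-10)
    # residual orthogonality to the design
    resid = y - X @ fit.coefficients
    np.testing.assert_allclose(X.T @ resid, 0.0, atol=1e-10)


def test_ols_variance_matches_statsmodels(small_ols_data):
    X, y = small_ols_data
    fit = OLSRegressor().fit(X, y).to_fit()
    sm_fit = sm.OLS(y, X).fit()
    np.testing.assert_allclose(fit.coefficients, sm_fit.params, atol=1e-10)
    np.testing.assert_allclose(fit.sigma2, sm_fit.mse_resid, rtol=1e-10)
    np.testing.assert_allclose(fit.covariance, sm_fit.cov_params(), rtol=1e-8)


# ---------------------------------------------------------------------------
# TSLS


def test_tsls_equals_ols_when_instruments_span_design():
    # Z1 = X1: the projection leaves X unchanged
    d = _rand_iv_data(11)
    d_self = RegressionData(y=d.y, X1=d.X1, X2=d.X2, Z1=d.X1.copy(),
                            names_Z1=("selfz",))
    ols, tsls = fit_ols(d_self), fit_tsls(d_self)
    np.testing.assert_allclose(tsls.coefficients, ols.coefficients, atol=1e-10)
    assert tsls.sigma2 == pytest.approx(ols.sigma2, abs=1e-12)


def test_tsls_exactly_identified_closed_form(exact_iv_data):
    d = exact_iv_data
    fit = fit_tsls(d)
    np.testing.assert_allclose(
        fit.coefficients, iv_closed_form(d.Z, d.X, d.y), atol=1e-9
    )


def test_tsls_matches_two_stage_oracle(small_iv_data):
    d = small_iv_data
    fit = fit_tsls(d)
    np.testing.assert_allclose(
        fit.coefficients, two_stage_sequential(d.y, d.X1, d.X2, d.Z1), atol=1e-9
    )
    # sigma2 uses the ORIGINAL regressors, not the projected ones
    resid = d.y - d.X @ fit.coefficients
    assert fit.sigma2 == pytest.approx(float(resid @ resid) / (d.n - d.k), rel=1e-12)


def test_tsls_sklearn_interface(trial_data):
    d = trial_data
    est = TSLSRegressor(n_endog=1).fit(d.X, d.y, instruments=d.Z1)
    np.testing.assert_allclose(est.coef_, fit_tsls(d).coefficients, atol=1e-12)
    assert est.get_params() == {"n_endog": 1}
    pred = est.predict(d.X)
    assert pred.shape == d.y.shape


@pytest.mark.parametrize("seed", range(5))
def test_variance_ordering_projected_gram(seed):
    """The projected design's inverse Gram dominates the OLS one (PSD)."""
    d = _rand_iv_data(seed)
    ols, tsls = fit_ols(d), fit_tsls(d)
    # compare at a common sigma^2: covariance / sigma2 = inverse Gram
    diff = tsls.covariance / tsls.sigma2 - ols.covariance / ols.sigma2
    eig = np.linalg.eigvalsh((diff + diff.T) / 2)
    assert eig.min() >= -1e-8


# ---------------------------------------------------------------------------
# empirical squared bias


def test_bias_sq_of_tsls_itself_is_zero(small_iv_data):
    tsls = fit_tsls(small_iv_data)
    np.testing.assert_array_equal(empirical_bias_sq(tsls, tsls), 0.0)


def test_bias_sq_hand_example():
    from spsliv.estimators import EstimatorFit

    a = EstimatorFit("OLS", [2.0, -1.0], np.eye(2), 1.0, 5, names=("p", "q"))
    b = EstimatorFit("TSLS", [1.0, 1.0], np.eye(2), 1.0, 5, names=("p", "q"))
    out = empirical_bias_sq(a, b)
    np.testing.assert_array_equal(out, [[1.0, -2.0], [-2.0, 4.0]])
    assert np.trace(out) == pytest.approx(5.0)


def test_bias_sq_matches_loop_oracle_and_is_psd():
    from spsliv.estimators import EstimatorFit

    rng = np.random.default_rng(8)
    v1, v2 = rng.normal(size=3), rng.normal(size=3)
    a = EstimatorFit("OLS", v1, np.eye(3), 1.0, 5)
    b = EstimatorFit("TSLS", v2, np.eye(3), 1.0, 5)
    out = empirical_bias_sq(a, b)
    np.testing.assert_allclose(out, outer_product_loop(v1 - v2), atol=1e-12)
    assert np.linalg.eigvalsh(out).min() >= -1e-12


@given(st.permutations(range(4)))
@settings(deadline=None, max_examples=20, derandomize=True)
def test_bias_sq_trace_invariant_under_reordering(perm):
    from spsliv.estimators import EstimatorFit

    rng = np.random.default_rng(5)
    v1, v2 = rng.normal(size=4), rng.normal(size=4)
    names = ("a", "b", "c", "d")
    perm = list(perm)

    def mk(v, order):
        nm = tuple(names[i] for i in order)
        return EstimatorFit("OLS", v[order], np.eye(4), 1.0, 5, names=nm)

    base = np.trace(empirical_bias_sq(mk(v1, list(range(4))), mk(v2, list(range(4)))))
    permuted = np.trace(empirical_bias_sq(mk(v1, perm), mk(v2, perm)))
    assert permuted == pytest.approx(base, rel=1e-12)


def test_bias_sq_dimension_mismatch():
    from spsliv.estimators import EstimatorFit

    a = EstimatorFit("OLS", [1.0], np.eye(1), 1.0, 5)
    b = EstimatorFit("TSLS", [1.0, 2.0], np.eye(2), 1.0, 5)
    with pytest.raises(ContractError):
        empirical_bias_sq(a, b)


# ---------------------------------------------------------------------------
# first-stage partial F


def test_first_stage_f_zero_when_instruments_add_nothing():
    rng = np.random.default_rng(9)
    n = 40
    x2 = rng.normal(size=(n, 2))
    x1 = x2 @ np.array([1.0, -0.5])  # depends on X2 only, noiselessly
    z1 = rng.normal(size=(n, 2))
    y = rng.normal(size=n)
    d = RegressionData(y=y, X1=x1[:, None], X2=x2, Z1=z1, validate=False)
    assert first_stage_f(d).statistic == 0.0


def test_first_stage_f_degrees_of_freedom():
    rng = np.random.default_rng(10)
    n, l1, k2 = 100, 5, 7
    x2 = rng.normal(size=(n, k2))
    z1 = rng.normal(size=(n, l1))
    x1 = z1.sum(axis=1) + rng.normal(size=n)
    y = x1 + rng.normal(size=n)
    d = RegressionData(y=y, X1=x1[:, None], X2=x2, Z1=z1)
    res = first_stage_f(d)
    assert (res.df1, res.df2) == (5, 88)


def test_first_stage_f_matches_two_regression_oracle():
    rng = np.random.default_rng(12)
    n = 20
    x2 = rng.normal(size=(n, 2))
    z1 = rng.normal(size=(n, 3))
    x1 = 0.6 * z1[:, 0] + x2 @ np.array([0.2, -0.1]) + rng.normal(size=n)
    y = x1 + rng.normal(size=n)
    d = RegressionData(y=y, X1=x1[:, None], X2=x2, Z1=z1)
    res = first_stage_f(d)
    expect = nested_f(x1, d.Z, d.X2, d.l1, d.n - d.l)
    assert res.statistic == pytest.approx(expect, rel=1e-9)
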