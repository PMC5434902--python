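"""Independent brute-force oracles used to cross-check the estimators.

Everything here is deliberately naive — explicit matrix inversion,
sequential regressions, loops, grid search — and shares no code with the
package's QR-based implementations.
"""

import numpy as np


def ols_normal_equations(X, y):
    """Solve the normal equations by explicit inversion."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    return np.linalg.inv(X.T @ X) @ (X.T @ y)


def iv_closed_form(Z, X, y):
    """Classical IV estimator (Z'X)^{-1} Z'y for the exactly identified case."""
    Z = np.asarray(Z, float)
    return np.linalg.inv(Z.T @ X) @ (Z.T @ y)


def two_stage_sequential(y, X1, X2, Z1):
    """Run two literal least-squares stages.

    Stage 1: regress each endogenous column on [Z1 X2], keep fitted values.
    Stage 2: OLS of y on [X1_fitted X2].
    """
    Z = np.hstack([Z1, X2]) if X2.size else Z1
    gamma = ols_normal_equations(Z, X1)
    X1_hat = Z @ gamma
    design = np.hstack([X1_hat, X2]) if X2.size else X1_hat
    return ols_normal_equations(design, y)


def outer_product_loop(d):
    """Elementwise outer product via explicit loops."""
    d = np.asarray(d, float)
    k = d.shape[0]
    out = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            out[i, j] = d[i] * d[j]
    return out


def nested_f(x, Z_full, X_reduced, df1, df2):
    """Partial F from two separate regressions' residual sums of squares."""
    x = np.asarray(x, float)
    r1 = x - Z_full @ ols_normal_equations(Z_full, x)
    if X_reduced.size:
        r0 = x - X_reduced @ ols_normal_equations(X_reduced, x)
    else:
        r0 = x
    rss1, rss0 = float(r1 @ r1), float(r0 @ r0)
    return ((rss0 - rss1) / df1) / (rss1 / df2)


def trace_mse_quadratic(alpha, mse_iv, mse_ols, cse):
    """tr MSE of the affine combination at weight alpha, from the expansion."""
    return float(
        alpha**2 * np.trace(mse_iv)
        + 2.0 * alpha * (1.0 - alpha) * np.trace(cse)
        + (1.0 - alpha) ** 2 * np.trace(mse_ols)
    )


def grid_search_alpha(mse_iv, mse_ols, cse, lo=-2.0, hi=3.0, step=1e-4):
    """Argmin of the trace quadratic by exhaustive grid search."""
    grid = np.arange(lo, hi + step / 2, step)
    vals = [trace_mse_quadratic(a, mse_iv, mse_ols, cse) for a in grid]
    return float(grid[int(np.argmin(vals))])


def rmse_loop(estimates, truth):
    """Root mean squared deviation from the truth, one value per coefficient."""
    estimates = np.asarray(estimates, float)
    out = []
    for j in range(estimates.shape[1]):
        acc = 0.0
        for v in estimates[:, j]:
            acc += (v - truth[j]) ** 2
        out.append(np.sqrt(acc / estimates.shape[0]))
    return np.array(out)


def random_psd(rng, k, scale=1.0):
    """A random positive semi-definite k x k matrix."""
    A = rng.normal(size=(k, k))
    return scale * (A @ A.T) / k
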