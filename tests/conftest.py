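import numpy as np
import pytest

from spsliv import (
    RegressionData,
    Scenario,
    run_monte_carlo,
    simulate_trial,
    solve_scenario,
)

# fixed, well-conditioned small datasets used by the oracle checks; the
# generating seeds are arbitrary constants


@pytest.fixture(scope="session")
def small_ols_data():
    """8 rows, 2 columns, pure OLS (no instruments needed)."""
    rng = np.random.default_rng(20170221)
    X = rng.normal(size=(8, 2))
    y = X @ np.array([1.5, -0.7]) + rng.normal(scale=0.3, size=8)
    return X, y


@pytest.fixture(scope="session")
def small_iv_data():
    """12 rows, one endogenous column, two instruments, one exogenous."""
    rng = np.random.default_rng(7265)
    n = 12
    z1 = rng.normal(size=(n, 2))
    x2 = rng.normal(size=(n, 1))
    u = rng.normal(size=n)
    x1 = z1 @ np.array([0.8, -0.5]) + 0.4 * x2[:, 0] + u + rng.normal(size=n)
    y = 0.6 * x1 - 0.3 * x2[:, 0] + u + rng.normal(scale=0.5, size=n)
    return RegressionData(
        y=y, X1=x1, X2=x2, Z1=z1,
        names_X1=("x",), names_X2=("w",), names_Z1=("z1", "z2"),
    )


@pytest.fixture(scope="session")
def exact_iv_data():
    """Exactly identified: one endogenous column, one instrument."""
    rng = np.random.default_rng(41)
    n = 30
    z = rng.normal(size=(n, 1))
    u = rng.normal(size=n)
    x1 = 0.9 * z[:, 0] + u + rng.normal(scale=0.5, size=n)
    y = 0.5 * x1 + u + rng.normal(scale=0.5, size=n)
    return RegressionData(y=y, X1=x1, Z1=z, names_X1=("x",), names_Z1=("z",))


@pytest.fixture(scope="session")
def trial_data():
    """A moderately sized simulated trial with confounding."""
    solved = solve_scenario(Scenario(eta=0.5, kappa=0.5, n=400))
    return simulate_trial(solved, seed=99).to_regression_data()


@pytest.fixture(scope="session")
def mc_grid():
    """Monte Carlo summaries for the full 3 x 3 scenario grid.

    n=100 subjects, m=2000 replicates per scenario; shared by the risk
    ordering and shrinkage-monotonicity checks.
    """
    out = {}
    for eta in (0.0, 0.25, 0.5):
        for kappa in (0.01, 0.25, 0.5):
            out[(eta, kappa)] = run_monte_carlo(
                Scenario(eta=eta, kappa=kappa, n=100), m=2000, seed=0
            )
    return out
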