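"""Exception hierarchy for spsliv.

Every contract violation maps to a distinct exception type so the CLI can
translate failures into stable machine-readable error codes.
"""


class SpslivError(Exception):
    """Base class for all spsliv errors."""

    code = "error"


class IdentificationError(SpslivError):
    """A design or instrument matrix is rank deficient."""

    code = "identification"


class UnderIdentifiedError(IdentificationError):
    """Fewer instruments than endogenous regressors (order condition fails)."""

    code = "under_identified"


class InsufficientDataError(SpslivError):
    """Not enough rows to estimate the model (n <= number of parameters)."""

    code = "insufficient_data"


class DegenerateShrinkageError(SpslivError):
    """The shrinkage objective has no unique minimizer.

    Raised when the denominator tr(MSE_tsls - 2 CSE + MSE_ols) of the
    closed-form shrinkage weight is numerically zero, i.e. the two
    component estimators have equal risk and zero distance.
    """

    code = "degenerate_shrinkage"


class InfeasibleScenarioError(SpslivError):
    """No positive error variances satisfy the standardization constraints."""

    code = "infeasible_scenario"


class BootstrapInstabilityError(SpslivError):
    """Too many bootstrap resamples failed to refit."""

    code = "bootstrap_instability"

    def __init__(self, message: str, failure_rate: float):
        super().__init__(message)
        self.failure_rate = failure_rate


class MonteCarloHarnessError(SpslivError):
    """More than the tolerated fraction of Monte Carlo replicates failed."""

    code = "monte_carlo_harness"


class ContractError(SpslivError, ValueError):
    """Mismatched dimensions, inconsistent names, or invalid configuration."""

    code = "contract"


class ConfigError(SpslivError):
    """Malformed run configuration."""

    code = "config"


class RoleError(SpslivError):
    """Role map references missing columns or overlapping roles."""

    code = "roles"
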