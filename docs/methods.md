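# Methods

This note records the models, estimators, numerical conventions and design
choices behind `spsliv`, and what the simulation-based tests do and do not
establish.

## Two-stage linear model and component estimators

The analysis model is the linear system

    y = X₁β₁ + X₂β₂ + ε           (outcome equation)
    X = Z₁Γ₁ + X₂Γ₂ + δ           (first stage, X = [X₁ X₂])

with k₁ endogenous regressors X₁, k₂ exogenous regressors X₂ and l₁ excluded
instruments Z₁; Z := [Z₁ X₂], k := k₁+k₂, l := l₁+k₂.  Identification
requires n > l, l₁ ≥ k₁, rank(X) = k and rank(Z′X) = k.  Errors are assumed
homoscedastic given X and given Z; no robust or clustered covariances are
offered.

- OLS: β̃ = (X′X)⁻¹X′y, Var̃ = σ̃²(X′X)⁻¹, σ̃² = ‖y−Xβ̃‖²/(n−k).
- TSLS: β̂ = (X̂′X̂)⁻¹X̂′y with X̂ = H_Z X, Var̂ = σ̂²(X̂′X̂)⁻¹.  The residual
  variance σ̂² deliberately uses the *original* regressors, ‖y−Xβ̂‖²/(n−k):
  residuals against X̂ would measure the wrong disturbance.
- Empirical squared bias of any candidate β† is the outer product
  (β†−β̂)(β†−β̂)′, anchored at the asymptotically unbiased TSLS fit; its trace
  is the (unnormalized) numerator of the Hausman statistic.
- Instrument strength: the partial F comparing the regression of each X₁
  column on [Z₁ X₂] against X₂ alone, with df₁ = l₁ and df₂ = n − l.

All solves use thin QR decompositions; the n×n projection H_Z is never
formed (the projection is applied as Q(Q′·)).  Rank decisions use a relative
singular-value cutoff of 1e-10 times the largest singular value, and
rank-deficiency errors name the offending columns via column-pivoted QR.
Closed forms are reproduced to ~1e-8 or better on well-conditioned data.
No intercept is ever added implicitly; users opt in by placing a constant
column in X₂ (the simulation model below has none by construction).

## The combined (SPSL) estimator

The combination β̄(α) = αβ̂ + (1−α)β̃ has trace-MSE

    tr MSE(β̄(α)) = α² tr MSE(β̂) + 2α(1−α) tr CSE + (1−α)² tr MSE(β̃),

a quadratic in α, convex whenever tr(MSE(β̂) − 2CSE + MSE(β̃)) > 0, with
unique argmin

    α = tr(MSE(β̃) − CSE) / tr(MSE(β̂) − 2 CSE + MSE(β̃)).

When that denominator trace is numerically zero (equal component risks and
zero distance) the weight is not unique and `theoretical_alpha` raises a
degenerate-shrinkage error rather than guessing.

**Cross-term plug-in.**  CSE(β̂, β̃) = E[(β̂−β)(β̃−β)′] is estimated by
σ̂²(X′X)⁻¹.  Rationale: the projection identity X′X̂ = X̂′X̂ gives, under
exogenous instruments and homoscedasticity,

    Cov(β̂, β̃) = σ²(X̂′X̂)⁻¹X̂′X(X′X)⁻¹ = σ²(X′X)⁻¹,

and the cross-bias term vanishes because bias estimates are anchored at the
TSLS fit.  The identity and the plug-in are both verified in the test suite,
the latter against a Monte Carlo cross-moment oracle.

**Empirical weight.**  α̂ evaluates the closed form at sample estimates:

    MSÊ(β̂) = Var̂(β̂)                   (empirical TSLS bias is null)
    MSÊ(β̃) = Var̃(β̃) + dd′,  d = β̃−β̂   (empirical OLS squared bias)
    CSÊ     = σ̂²(X′X)⁻¹

    α̂ = tr(MSÊ(β̃) − CSÊ) / tr(MSÊ(β̂) − 2 CSÊ + MSÊ(β̃)).

A frequently quoted rewriting replaces the denominator by the squared
coefficient distance ‖d‖² (its expectation) and the numerator by its
complement, giving the Stein-like form β̂ − (τ̂/‖d‖²)(β̂−β̃) with
τ̂ = tr(Var̂(β̂) − CSÊ).  We compute and report τ̂ as a diagnostic but do
*not* use the distance-normalized form to build the estimator: ‖d‖² can be
arbitrarily close to zero while τ̂ is not (and under weak instruments TSLS
collapses toward OLS, shrinking ‖d‖ exactly when the variance-based τ̂
explodes), so the ratio estimator has unbounded realizations and a divergent
Monte Carlo mean squared error.  The full plug-in is algebraically the same
quantity with the variance traces kept in the denominator, is stable, and —
because τ̂ ≥ 0 by the variance ordering — lands in [0, 1] for all
positive-definite inputs encountered in practice.  α̂ is nevertheless not
clamped; the degenerate case (components numerically coincident) returns
α̂ = 0 with a flag, every weight then giving the same estimator.

The reported covariance for the combined fit is the plug-in
α̂²Var̂ + 2α̂(1−α̂)CSÊ + (1−α̂)²Var̃, which ignores the sampling variability of
α̂ itself; the recommended standard errors are from the pairs bootstrap
(row resampling with refit; default B = 1000; resamples whose refit is rank
deficient are redrawn, capped at 10B total draws before an instability error
reports the failure rate).

## Standardized simulation model

The generator emulates a two-arm trial with an endogenous dose:

    Y = β_B B + β_S S + η U + ε
    S = c·(B + R + RB) + η U + δ

with B ~ N(0, σ_B²), U ~ N(0, 1), R ~ Bernoulli(p), mutually independent,
ε ⟂ δ normal.  Defaults: β_S = β_B = 1/4, σ_B² = 0.3, p = 1/2; these are the
study conditions, not tuning knobs.  The three first-stage coefficients are
set equal — the minimal choice consistent with a single instrument-strength
constraint (the equal-coefficient scheme is this package's construction; the
moment-recovery tests, not the algebra, are the authority for correctness).

Writing W := B + R + RB, independence of B and R gives exactly

    E W = p,  Var W = σ_B²(1+3p) + p(1−p),  Cov(B, W) = σ_B²(1+p),

and the standardization Var(S) = Var(Y) = 1, Cor(S,U) = η, Cor(S,W) = κ is
solved in closed form:

    c        = κ / sd(W)
    σ_δ²     = 1 − κ² − η²
    σ_ε²     = 1 − β_B²σ_B² − β_S² − η²(1+2β_S) − 2β_Bβ_S c σ_B²(1+p).

Feasibility requires both variances positive (κ² + η² < 1 and the ε
condition); infeasible (η, κ) combinations raise an error naming the
violated variance.  At the defaults Var W = 1 exactly, so c = κ.  The solved
object re-checks its own moment algebra at construction, and large-sample
tests (10⁶ draws, tolerance 0.01) confirm unit variances and recovery of
(η, κ) for the full grid η ∈ {0, 0.25, 0.5} × κ ∈ {0.01, 0.25, 0.5}.

Estimation on simulated data uses X₁ = {S}, X₂ = {B}, Z₁ = {R, RB}, no
intercept (the generating model has none); a flag adds one for robustness
experiments.  The unobserved confounder U is carried in the dataset for
oracle checks but excluded from every analysis view.

**Monte Carlo harness.**  Per-replicate RNG streams are spawned from the
master seed via `numpy.random.SeedSequence.spawn`, so replicates are
independent, reproducible, and insensitive to execution order.  Replicate
fit failures are skipped and counted; more than 1% aborts the run.  Reported
summaries per estimator and coefficient: mean, bias, variance (divisor m, so
RMSE² = bias² + variance holds exactly), RMSE, plus the scalar
root-trace-MSE and the empirical CDF of the dose-effect estimates.

Problem sizes in the shipped tests — m = 2000 replicates of n = 100 subjects
per grid scenario for the risk-ordering and shrinkage-monotonicity checks,
10⁶ draws for moment recovery, 10⁵ for the design-correlation targets —
were chosen as the smallest sizes at which the Monte Carlo error bands are
decisively narrower than the effects being demonstrated.

## Missing data

`ampute_mar` (a testing utility) removes values with logistic probabilities
driven by fully observed columns only, so the mechanism is MAR by
construction.  `impute_chained` cycles Bayesian normal-linear conditional
models over the incomplete columns: for each, the observed part is regressed
on all other variables plus an intercept, the residual variance is drawn
from its scaled inverse-χ² posterior, coefficients from their conditional
normal, and missing cells from the predictive normal — so the I completed
copies differ, as proper multiple imputation requires.  Binary columns are
imputed by thresholding the draw at 1/2 (logged).  Predictive mean matching
is available (`pmm_donors > 0`), default off.  Perfectly linear columns
(zero residual variance) impute deterministically.  Products such as
interaction columns are treated passively: impute components, recompute the
product, unless the product column is supplied as data in its own right.

`pool_rubin` combines per-imputation fits: pooled estimate = mean; pooled
SE² = W̄ + (1 + 1/I)·B with W̄ the mean within-imputation variance and B the
(I−1)-divisor between-imputation variance — the standard rules, equivalently
the (I+1)/(I(I−1)) between factor.  Within-imputation variances default to
the analytic covariance diagonals (OLS/TSLS); for the combined estimator the
per-imputation bootstrap variance is the appropriate input, and the CLI
wires it that way.  Defaults I = 100 imputations, B = 1000 bootstrap
replications.  Degrees-of-freedom corrections for pooled inference
(Barnard–Rubin) are out of scope; only SEs are reported.

## What the tests do and do not show

The generator draws B and U normal, uses a homoscedastic ε, equal
first-stage coefficients and a single endogenous regressor.  Real trial data
offer none of these guarantees: doses are counts, missingness need not be
MAR, error variances may differ by arm, and several endogenous variables
(e.g. dose and dose×alliance interactions) may enter jointly.  Passing tests
therefore establish internal correctness of the estimators and the
documented finite-sample behavior *under the stated conditions* — they are
not evidence about robustness to heteroscedasticity, non-normality or MNAR
missingness, all of which are explicitly out of scope.

Known limitations: the shrinkage weight is global (one α for the whole
coefficient vector), so individual SPSL coordinates need not lie between
their OLS and TSLS counterparts; TSLS moments need not exist at low degrees
of overidentification, so Monte Carlo summaries of TSLS (and hence the
paired comparisons) are heavy-tailed in the weak-instrument scenarios; and
the plug-in SPSL covariance understates uncertainty relative to the
bootstrap because it conditions on α̂.
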