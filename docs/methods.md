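# Methods

## Model and assumptions

The target of inference is the generalized partially linear model
`E(Y | X, Z) = mu(X' beta + theta(Z))` with a known, strictly monotone,
continuously differentiable link `mu`, `X` a p-vector of primary covariates,
`Z` a scalar smoothing covariate, and `theta` an unknown smooth function.
The outcome is missing at random given the always-observed variables:
`Pr(R=1 | X, Z, U, Y) = pi(X, Z, U)`, where `U` are auxiliary covariates
that may be needed to make the MAR assumption credible (e.g. a cheap
screening test that influenced referral to the gold-standard test). The
selection probability is either known by design (two-stage sampling) or
modelled parametrically (logistic). Identification additionally needs
`pi > 0` on the support and at least two distinct values of `Z`; local
estimation is only meaningful in the interior of the `Z` distribution.

## Estimation procedure

For a given `beta`, `theta-hat(z, beta)` is the first component of the root
`alpha = (alpha0, alpha1)` of the local-linear weighted estimating equation
with kernel weights `K_h(Z_i - z)`, working-variance weights `1/V_i`, link
derivative `mu1_i`, basis `G(Z_i - z) = (1, Z_i - z)'`, and a branch-specific
bracket:

| branch | bracket |
| --- | --- |
| naive | `R_i (Y_i - mu_i)` |
| IPW   | `R_i/pi_i (Y_i - mu_i)` |
| AIPW  | `R_i/pi_i (Y_i - mu_i) - (R_i/pi_i - 1)(delta_i - mu_i)` |

`beta-hat` solves the corresponding profile equation in which
`G(Z_i - z)` is replaced by `X_i + phi(Z_i, beta)` with
`phi = d theta-hat / d beta`, so the kernel stage is profiled out exactly.
The full algorithm is: fit the nuisances; compute a root-n-consistent
initial estimate by running the IPW loop with the working variance frozen at
1 for two sweeps (the naive branch uses its own unweighted loop — weighting
a deliberately unweighted estimator would contaminate the branch); estimate
the working-variance parameter `zeta` once from the squared per-unit
residuals of the initial fit (nonlinear least squares; for the constant
family this is the sample mean); then alternate kernel and profile stages
until the sup-norm change in `beta` is below `tol = 1e-6` (cap 50 sweeps).
Re-estimating `zeta` each sweep is available as a switch but off by
default — the asymptotic distribution does not depend on the working
variance, only efficiency does.

With the identity link and a working variance that does not change across
sweeps, both stages are linear in the (pseudo-)outcome and are computed in
closed form: the kernel stage is a weighted local-linear regression of the
branch pseudo-outcome minus `X' beta` on `G`, the profile stage an exact
weighted least squares in the partialled-out variables `(I - S)X`, `(I - S)
y-tilde`, where `S` is the local-linear smoother. The generic damped-Newton
solvers (analytic local Jacobian, step halving, warm starts across
neighbouring grid points, tolerance 1e-8) handle the logit and log links;
a `force_iterative` switch routes identity-link fits through them, and the
test suite asserts agreement with the closed forms to machine precision.
`phi` is computed by implicit differentiation of the local system (solve
`J_alpha d(alpha)/d(beta) = -J_beta` at the root); a central finite
difference is retained as a cross-check oracle.

### Nuisance models

* **Selection**: logistic MLE by Newton–Raphson with step halving (score
  tolerance 1e-10, 100 iterations). Degenerate designs (no variation in R,
  rank deficiency, (quasi-)separation — fitted logits beyond 20) raise
  informative errors. Fitted probabilities below `pi_floor` (default 0.01)
  are truncated with a logged count; probabilities known by design are never
  truncated. In known-pi mode the selection-score correction of the
  sandwich is exactly zero.
* **Outcome**: linear least squares of `Y` on user-supplied design columns
  among complete cases, optionally weighted by `1/pi-hat`. Unweighted is the
  default: under MAR, `E(Y|X,Z,U,R=1) = E(Y|X,Z,U)`, so the unweighted fit
  is consistent whenever the model is correct. `delta` is evaluated at every
  unit, observed or not. A fixed, user-supplied `delta` (e.g. the true
  conditional mean, in simulations) bypasses the fit, and then no
  outcome-score correction enters the sandwich.
* **Working variance**: families `constant` and `exp(zeta0 + zeta1 * lp)`.
  The regressand is the squared branch residual evaluated at the initial
  fit (AIPW: the full augmented residual; IPW: `R/pi (Y-Q)^2`; naive:
  complete-case `(Y-Q)^2`). Misspecifying this model affects efficiency
  only; with the constant family it cancels from all point estimates and
  from the sandwich.

## Variance estimation

`Omega-hat = A^{-1} B A^{-1}` with bread
`A = n^{-1} sum b_i mu1_i^2 V_i^{-1} Xt_i Xt_i'`, `Xt_i = X_i + phi(Z_i)`,
and branch bread weights `b_i` (1, `R_i/pi-hat_i`, `R_i`). The meat is the
outer product of `D_i eps_i` minus least-squares projections onto the
selection score `S_i` and the outcome estimating function `l_i`, each
present only when the corresponding nuisance was actually estimated.
Standard errors are `sqrt(diag(Omega-hat)/n)`. In the complete-data identity
case the whole construction reduces to the classical
heteroskedasticity-robust sandwich of the profile least-squares estimator.

The pointwise variance of `theta-hat(z)` uses the local sandwich
`Sigma(z)/(nh)` with
`Sigma(z) = c0(K^2) E[r(X,Z) s2 | Z=z] / (t(z)^2 f_Z(z))`,
`t(z) = E[mu1^2/V | Z=z]`, `r = mu1^2/V^2`. The conditional "braces" term of
the asymptotic theory equals the conditional second moment of the branch
residual, so the plug-in kernel-averages `r_i eps_i-hat^2` directly rather
than assembling `var(Y|X,Z,U)`, `(E[Y|X,Z,U]-mu)^2` and `(E-delta)^2`
separately; `f_Z` is a kernel density estimate with Silverman's rule
(constant 2.34 for the Epanechnikov kernel, 1.06 for the Gaussian). All
conditional expectations reuse the fit kernel and bandwidth, so one
smoothing parameter governs the whole fit.

## Bandwidth selection (EBBS)

The leading smoothing bias of the local-linear stage is
`0.5 h^2 theta''(z) c2(K)`, so for each evaluation point the bandwidth path
`h -> theta-hat_h(z)` over a grid of candidates is modelled locally (sliding
window of 5 grid points) as `a0 + a1 h^2 + a2 h^3`; the empirical bias at
`h` is the fitted value minus `a0`, the variance comes from the plug-in
above, and the selected `h` minimizes estimated bias^2 + variance. The
default grid is 15 log-spaced points on `[0.05, 0.25] x range(Z)`. The upper
end is deliberately moderate: the polynomial bias model is a small-h
expansion, and once the window spans an entire feature of `theta` the bias
path bends back towards zero and empirical-bias estimation breaks down —
in oracle experiments on the shipped design a `0.5 x range` grid selected
grossly oversmoothed bandwidths near inflection regions for exactly this
reason. The procedure is deterministic given its inputs, and scale
equivariant in `Z`.

## Synthetic-data generator

`generate_dataset` emulates a designed two-stage study:
`Z ~ Uniform(0,1)`; `X | Z ~ N((Z-0.5)^2, 1)`;
`U = Uniform(0,6) + N(X, 0.05^2) + N(Z, 0.05^2)`;
`Y | X,Z,U ~ N(X beta1 + m(Z) + U beta2, sigma_Y^2)` with
`m(z) = 2 x Beta(8,8) density` and defaults
`beta1 = beta2 = 1, sigma_Y = 1`; and selection
`logit pi = tau0 + tau1 (U - a1) 1{a1 < U <= a2} + tau1 (a2 - a1) 1{U > a2}`
with `tau0 = -2, tau1 = 1, a1 = 0.5, a2 = 5.5`, giving a median missing
fraction near 35%. Because `E(U | X, Z) = 3 + X + Z`, the implied marginal
model is exactly `E(Y | X, Z) = 2X + theta(Z)` with
`theta(z) = m(z) + z + 3` — the analytic truth all battery metrics use.
Replication seeds derive from `SeedSequence(seed, spawn_key=(rep,))`, so
every estimator sees the same datasets within a replication (paired,
variance-reducing comparisons) and everything is reproducible bit for bit.

What the generator does *not* emulate: discrete or heavy-tailed outcomes,
multivariate `Z`, measurement error in covariates, selection depending on
`(X, Z)` jointly, or selection probabilities approaching zero. Passing
simulation checks therefore demonstrates correctness of the estimating
machinery under a well-behaved continuous design, not robustness to those
features of real data.

## Monte-Carlo battery

`run_battery` fits up to nine estimator/nuisance scenarios per replication
(naive; IPW with true / fitted / wrong selection model; AIPW with all four
correct/misspecified nuisance combinations plus true-both). The correctly
specified selection model is the logistic GLM in the constructed ramp
regressor with the knots fixed at their design values; the correct outcome
model regresses `Y` on `(1, X, U, m(Z))` with `m` known (a real analysis
would use a flexible basis); the misspecified models are the logistic in
`(1, X, Z)` and the linear model in `(1, Z, X)`. Reported per scenario:
integrated relative bias, integrated empirical and estimated SE, and
empirical MISE of `theta-hat` (averaging over a fixed 99-point grid on
[0.01, 0.99], i.e. `F(z) = Uniform(0,1)`); and signed bias, averaged
relative bias `mean|beta-hat - beta|/beta`, empirical SE, mean estimated
(sandwich) SE, and empirical MSE of `beta-hat`. Failed replications are
counted and excluded, never silently dropped.

Default problem sizes are 100 replications of n = 500. The profile stage
runs at a fixed bandwidth `h = 0.15` — the `beta` summaries are insensitive
to `h` across [0.08, 0.25] in this design — while the reported curve can use
`theta_bandwidth="ebbs-local"`, per-replication per-point EBBS selection,
which is essential for the curve metrics: `theta''` at the Beta(8,8) peak is
about −350, so any fixed global bandwidth either oversmooths the peak or
undersmooths the flat regions.

## Efficiency bound

For the identity-link design the semiparametric variance bound is
`V_eff = E[sigma^{-2}(X,Z) (X - phi_eff(Z))^2]^{-1}` with
`phi_eff(z) = E[sigma^{-2} X | Z=z] / E[sigma^{-2} | Z=z]` and
`sigma^2(X,Z) = var(eps* | X, Z)` for the augmented residual `eps*`.
`efficiency_bound_mc` evaluates it by nested Monte Carlo: outer draws of
`(Z, X)`, an inner simulation of `(U, Y, R)` per outer draw for
`sigma^2`, and a binned kernel regression (200 bins, Epanechnikov,
bandwidth 0.05) over the outer sample for `phi_eff` — avoiding a third
nesting level. Monte-Carlo standard errors come from ten batch means.
Defaults are 1e5 outer x 200 inner draws; the test suite uses 2e4 x 400,
which resolves the bound to about 1%. With selection switched off the
design has `sigma^2 = var(U|X,Z) + sigma_Y^2 = 4.005` constant and
`E[var(X|Z)] = 1`, so the bound equals 4.005 exactly — the closed-form
oracle used in testing. Inner-simulation noise in `sigma^2-hat` biases the
bound down by Jensen's inequality by roughly `2/(n_inner - 1)` relative,
about 0.5% at the defaults.

## Numerical choices and degenerate inputs

Logit/log linear predictors are clamped at |eta| <= 30 (logged). Local
windows with fewer than two contributing units, or with no spread in `Z`,
raise errors advising a larger bandwidth rather than returning NaN.
Non-convergent fits are flagged on the returned object, not raised.
Plug-in variances are floored at zero. The evaluation grid for reporting is
the observed `Z` plus 101 uniform points between the 5th and 95th
percentiles; battery metrics use the fixed interior grid above so that
integrated summaries are comparable across replications.

## Known limitations

Local-linear smoothing only (no higher-order local polynomials); a single
scalar smoothing covariate; parametric selection models only; the shipped
variance families are constant and log-linear; confidence statements for
`theta-hat` are pointwise, not uniform. The modified augmentation that
guarantees efficiency dominance over IPW even under a misspecified outcome
model is not implemented. IPW and AIPW weights are truncated rather than
stabilized, so designs with selection probabilities near zero should be
treated with caution.
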