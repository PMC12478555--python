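# aipwgplm

Doubly robust estimation for **generalized partially linear models with
outcomes missing at random**.

Many observational and two-stage studies measure covariates on everyone but
the outcome only on a subsample: an expensive gold-standard test is ordered
only for some patients, a second-stage questionnaire goes only to selected
respondents. When selection depends on observed data — including auxiliary
variables `U` that are not part of the target regression — a complete-case
analysis is biased. This package estimates the generalized partially linear
model (GPLM)

```
E(Y | X, Z) = mu( X' beta + theta(Z) )
```

with a known monotone link `mu` (identity, logit, log), a parametric index
`X' beta`, and an unknown smooth function `theta` of a scalar covariate `Z`
(e.g. age), when `Y` is **missing at random** given `(X, Z, U)`:

```
Pr(R = 1 | X, Z, U, Y) = pi(X, Z, U)        (R = 1 when Y is observed)
```

It is aimed at biostatisticians analysing two-phase designs and
outcome-dependent subsampling, and at methodologists studying doubly robust
semiparametric inference.

## Estimators

Three kernel–profile estimators are provided; each alternates a local-linear
kernel stage for `theta(·, beta)` with a profile stage for `beta` that
propagates `phi(z) = d theta-hat(z, beta)/d beta`:

* **naive** — unweighted complete cases: kernel stage
  `sum_i R_i K_h(Z_i - z) mu1_i V_i^{-1} G(Z_i - z) (Y_i - mu_i) = 0`;
  inconsistent under outcome-dependent selection.
* **IPW** — complete cases weighted by `1/pi-hat`, with `pi` either known by
  design or fitted by a parametric (logistic) model. Consistent when the
  selection model is correct.
* **AIPW** — adds the augmentation built from an outcome working model
  `delta(X,Z,U; eta) ≈ E(Y|X,Z,U)`; the kernel stage solves, in
  `alpha = (alpha0, alpha1)` with `mu_i = mu(X_i' beta + alpha0 + alpha1 (Z_i - z))`,

  ```
  sum_i K_h(Z_i - z) mu1_i V_i^{-1} G(Z_i - z)
        [ R_i/pi_i (Y_i - mu_i) - (R_i/pi_i - 1)(delta_i - mu_i) ] = 0,
  ```

  and analogously for the profile stage with `G` replaced by
  `X_i + phi(Z_i)`. The AIPW estimators of **both** `beta` and `theta` are
  *doubly robust*: consistent if either the selection model or the outcome
  model is correctly specified. With both correct, `beta-hat` attains the
  semiparametric efficiency bound.

Standard errors come from a sandwich estimator whose meat corrects for the
estimated selection (`tau-hat`) and outcome (`eta-hat`) nuisances; pointwise
variances for `theta-hat` use a plug-in of the local-linear asymptotic
variance. Bandwidths can be fixed or selected by empirical-bias bandwidth
selection (EBBS).

## Worked example

Simulate one two-stage study (n = 500; `Z ~ U(0,1)`, `X|Z` normal, auxiliary
`U` driving selection, ~35% of outcomes missing; the implied marginal model
has `beta = 2` and `theta(z) = m(z) + z + 3`) and fit the naive and AIPW
estimators:

```python
import numpy as np
from aipwgplm import FitConfig, SimConfig, fit_gplm, generate_dataset
from aipwgplm.simulation import scenario_config

cfg = SimConfig(n=500, seed=4)
data, truth = generate_dataset(cfg, rep=0)
print("missing fraction:", round(data.missing_fraction, 3))

base = FitConfig(link="identity", bandwidth=0.15)
aipw = fit_gplm(data, scenario_config("aipw-fitted-both", cfg, base))
naive = fit_gplm(data, scenario_config("naive", cfg, base))
print(aipw.summary_frame().round(4))
print(naive.summary_frame().round(4))
```

which prints

```
missing fraction: 0.354
    estimate      se        z  p_value
x1    1.9702  0.0952  20.6898      0.0
    estimate      se        z  p_value
x1    1.8014  0.0993  18.1337      0.0
```

The AIPW estimate (1.970 ± 0.095) covers the true slope 2; the complete-case
estimate (1.801) is biased by the outcome-dependent selection — the
`z`-statistic tests `beta = 0`, but the ~0.2 shortfall against the truth is
roughly two standard errors. The fitted object also carries the smooth
component: `aipw.theta` holds `theta-hat(z)`, its local slope, `phi`, and
pointwise standard errors on a reporting grid.

A command-line layer wraps the same functionality:

```sh
aipwgplm fit --input study.csv --y y --r r --x x1 --z z --u u1 \
             --estimator aipw --link identity --bandwidth ebbs \
             --pi-cols u1 --delta-cols x1,u1
aipwgplm simulate --n 500 --reps 100 --seed 1 --scenarios all
```

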