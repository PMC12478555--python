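"""Sandwich covariance, pointwise theta variance, efficiency bound."""

import numpy as np
import pytest

from aipwgplm import (FitConfig, FixedDelta, KnownPi, LinearDelta,
                      ObservedData, SimConfig, efficiency_bound_mc, fit_gplm,
                      sandwich_beta, theta_pointwise_variance, theta_curve)
from aipwgplm.model_core import get_kernel

from conftest import make_complete_data


def test_complete_data_sandwich_equals_classical_robust_sandwich():
    import statsmodels.api as sm
    data, _ = make_complete_data(n=250, seed=42)
    cfg = FitConfig(estimator="naive", link="identity", bandwidth=0.2)
    fit = fit_gplm(data, cfg)
    # oracle: HC0 on the profiled-out (partialled) variables; the profile
    # estimator is the OLS of yc on xc with xc = (I-S)X and yc = (I-S)y
    xc = data.x + fit.theta_obs.phi
    resid = data.y - data.x @ fit.beta_hat - fit.theta_obs.alpha0
    yc = xc @ fit.beta_hat + resid
    ref = sm.OLS(yc, xc).fit(cov_type="HC0")
    assert np.allclose(fit.beta_hat, ref.params, atol=1e-8)
    cov_ours = fit.omega_hat / data.n
    assert np.allclose(cov_ours, ref.cov_params(), rtol=1e-6, atol=1e-10)


def test_known_pi_and_fixed_delta_mode_has_no_correction_terms():
    rng = np.random.default_rng(9)
    n = 300
    z = rng.uniform(0, 1, n)
    x = rng.normal(size=(n, 1))
    u = rng.normal(size=n)
    y = x[:, 0] + np.sin(2 * np.pi * z) + 0.4 * rng.normal(size=n)
    pi = 1 / (1 + np.exp(-(0.5 + 0.8 * u)))
    r = (rng.uniform(size=n) < pi).astype(int)
    data = ObservedData(np.where(r == 1, y, np.nan), r, x, z, u)
    cfg = FitConfig(estimator="aipw", link="identity", bandwidth=0.25,
                    pi_spec=KnownPi(pi),
                    delta_spec=FixedDelta(np.zeros(n)))
    fit = fit_gplm(data, cfg)
    # direct recomputation: meat must be exactly var of D_i eps_i
    mu1 = np.ones(n)
    v = fit.nuis.v_values
    x_tilde = data.x + fit.theta_obs.phi
    rp = data.r / pi
    mu = data.x @ fit.beta_hat + fit.theta_obs.alpha0
    eps = rp * (data.y_filled - mu) - (rp - 1) * (0.0 - mu)
    d = x_tilde * (mu1 / v)[:, None]
    meat_direct = (d * eps[:, None]).T @ (d * eps[:, None]) / n
    assert np.allclose(fit.meat, meat_direct, atol=1e-10)


def test_estimated_pi_correction_reduces_meat():
    # fitting the selection model never inflates the AIPW/IPW meat relative
    # to plugging the same fitted probabilities in as known
    rng = np.random.default_rng(14)
    n = 500
    z = rng.uniform(0, 1, n)
    x = rng.normal(size=(n, 1))
    u = rng.normal(size=n)
    y = 2 * x[:, 0] + np.sin(2 * np.pi * z) + u + 0.5 * rng.normal(size=n)
    pi = 1 / (1 + np.exp(-(0.3 + 0.9 * u)))
    r = (rng.uniform(size=n) < pi).astype(int)
    data = ObservedData(np.where(r == 1, y, np.nan), r, x, z, u)
    from aipwgplm import LogisticPi
    spec = LogisticPi(lambda d: np.column_stack([np.ones(d.n), d.u[:, 0]]))
    cfg_fit = FitConfig(estimator="ipw", link="identity", bandwidth=0.25,
                        pi_spec=spec, pi_floor=0.0)
    f1 = fit_gplm(data, cfg_fit)
    cfg_known = FitConfig(estimator="ipw", link="identity", bandwidth=0.25,
                          pi_spec=KnownPi(f1.nuis.pi_hat))
    f2 = fit_gplm(data, cfg_known)
    assert np.allclose(f1.beta_hat, f2.beta_hat, atol=1e-10)
    assert f1.meat[0, 0] <= f2.meat[0, 0] + 1e-10


def test_theta_variance_reduces_to_textbook_local_linear_formula():
    data, beta = make_complete_data(n=300, seed=2)
    cfg = FitConfig(estimator="naive", link="identity", bandwidth=0.2)
    fit = fit_gplm(data, cfg)
    grid = np.linspace(0.2, 0.8, 9)
    curve = theta_curve(data, fit.nuis, fit.beta_hat, grid, 0.2, cfg)
    var = theta_pointwise_variance(data, fit.nuis, fit.beta_hat, curve, cfg)

    # independent reimplementation of c0 * E[eps^2|z] / (f_Z(z) n h)
    k = get_kernel("epanechnikov")
    theta_at_obs = np.interp(data.z, curve.z_eval, curve.alpha0)
    eps = data.y - data.x @ fit.beta_hat - theta_at_obs
    sd = np.std(data.z, ddof=1)
    iqr = np.subtract(*np.percentile(data.z, [75, 25]))
    h_f = 2.34 * min(sd, iqr / 1.34) * data.n ** (-0.2)
    ref = np.empty(grid.size)
    for j, z0 in enumerate(grid):
        w = k.k((data.z - z0) / 0.2) / 0.2
        s2 = np.sum(w * eps ** 2) / np.sum(w)
        f = np.mean(k.k((data.z - z0) / h_f) / h_f)
        ref[j] = k.c0 * s2 / (f * data.n * 0.2)
    assert np.allclose(var, ref, rtol=1e-6)


def test_variance_branches_collapse_when_pi_is_one():
    data, _ = make_complete_data(n=250, seed=19)
    pi = KnownPi(np.ones(data.n))
    delta = FixedDelta(np.zeros(data.n))
    out = {}
    for est in ("naive", "ipw", "aipw"):
        cfg = FitConfig(estimator=est, link="identity", bandwidth=0.25,
                        pi_spec=pi, delta_spec=delta)
        fit = fit_gplm(data, cfg)
        grid = np.linspace(0.2, 0.8, 7)
        curve = theta_curve(data, fit.nuis, fit.beta_hat, grid, 0.25, cfg)
        out[est] = theta_pointwise_variance(data, fit.nuis, fit.beta_hat,
                                            curve, cfg)
    assert np.allclose(out["naive"], out["ipw"], atol=1e-12)
    assert np.allclose(out["naive"], out["aipw"], atol=1e-12)


def test_sandwich_is_invariant_to_row_permutation():
    data, _ = make_complete_data(n=200, seed=25)
    cfg = FitConfig(estimator="naive", link="identity", bandwidth=0.25)
    fit = fit_gplm(data, cfg)
    rng = np.random.default_rng(0)
    perm = rng.permutation(data.n)
    data_p = ObservedData(data.y[perm], data.r[perm], data.x[perm],
                          data.z[perm], data.u[perm])
    fit_p = fit_gplm(data_p, cfg)
    assert np.allclose(fit.beta_hat, fit_p.beta_hat, atol=1e-9)
    assert np.allclose(fit.omega_hat, fit_p.omega_hat, atol=1e-7)


def test_efficiency_bound_matches_full_observation_closed_form():
    # with pi = 1 the design has sigma^2(X,Z) = var(U|X,Z) + sigma_Y^2
    # = 3 + 2*0.05^2 + 1 constant, and E[var(X|Z)] = 1, so the bound is
    # exactly that constant
    cfg = SimConfig()
    analytic = 3.0 + 2 * cfg.noise_sd_u ** 2 + cfg.sigma_y ** 2
    res = efficiency_bound_mc(cfg, n_outer=6000, n_inner=300, seed=101,
                              pi_is_one=True)
    assert abs(res.v_eff[0, 0] - analytic) < 3 * res.mc_se[0, 0] + 0.05


def test_efficiency_bound_is_seed_stable():
    cfg = SimConfig()
    vals, ses = [], []
    for seed in (1, 2, 3):
        res = efficiency_bound_mc(cfg, n_outer=4000, n_inner=250, seed=seed)
        vals.append(res.v_eff[0, 0])
        ses.append(res.mc_se[0, 0])
    spread = max(vals) - min(vals)
    assert spread < 3 * (max(ses) * np.sqrt(2)) + 0.1
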