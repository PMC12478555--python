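"""Local-linear kernel stage: closed forms, oracles, derivative checks."""

import numpy as np
import pytest
from dataclasses import replace

from aipwgplm import (FitConfig, FixedDelta, KnownPi, ObservedData,
                      fit_outcome_model, phi_derivative, phi_fd, solve_local,
                      theta_curve)
from aipwgplm.nuisance import NuisanceFit

from conftest import local_linear_smoother, make_complete_data


def _nuis_complete(n):
    nu = NuisanceFit(pi_hat=np.ones(n))
    nu.zeta_hat = np.array([1.0])
    nu.variance_spec = "constant"
    return nu


def test_identity_solver_equals_closed_form_to_machine_precision():
    data, beta = make_complete_data(n=150, seed=3)
    nuis = _nuis_complete(data.n)
    cfg = FitConfig(estimator="naive", link="identity", bandwidth=0.2)
    cfg_it = replace(cfg, force_iterative=True)
    for z0 in (0.25, 0.5, 0.8):
        a_cf, ok1 = solve_local(data, nuis, beta, z0, 0.2, cfg)
        a_it, ok2 = solve_local(data, nuis, beta, z0, 0.2, cfg_it)
        assert ok1 and ok2
        assert np.allclose(a_cf, a_it, rtol=0, atol=1e-10)


def test_identity_alpha_is_local_linear_regression_of_partial_residual():
    data, beta = make_complete_data(n=150, seed=3)
    nuis = _nuis_complete(data.n)
    cfg = FitConfig(estimator="naive", link="identity", bandwidth=0.2)
    z0 = 0.4
    alpha, _ = solve_local(data, nuis, beta, z0, 0.2, cfg)
    s = local_linear_smoother(data.z, [z0], 0.2)
    oracle = (s @ (data.y - data.x @ beta))[0]
    assert np.allclose(alpha[0], oracle, atol=1e-10)


def test_aipw_equals_ipw_when_delta_matches_mu_at_root():
    # the augmentation term vanishes when delta_i = mu_i at the solution
    rng = np.random.default_rng(11)
    n = 150
    z = rng.uniform(0, 1, n)
    x = rng.normal(size=(n, 1))
    y = x[:, 0] + np.cos(2 * np.pi * z) + 0.3 * rng.normal(size=n)
    r = (rng.uniform(size=n) < 0.7).astype(int)
    data = ObservedData(np.where(r == 1, y, np.nan), r, x, z, rng.normal(size=n))
    pi = np.full(n, 0.7)
    beta = np.array([1.0])
    cfg_ipw = FitConfig(estimator="ipw", link="identity", bandwidth=0.25,
                        pi_spec=KnownPi(pi))
    nu_ipw = _nuis_complete(n)
    nu_ipw.pi_hat = pi
    z0 = 0.5
    a_ipw, _ = solve_local(data, nu_ipw, beta, z0, 0.25, cfg_ipw)
    mu_at_root = x[:, 0] * beta[0] + a_ipw[0] + a_ipw[1] * (z - z0)
    nu_aipw = _nuis_complete(n)
    nu_aipw.pi_hat = pi
    nu_aipw.delta_hat = mu_at_root
    cfg_aipw = replace(cfg_ipw, estimator="aipw")
    a_aipw, _ = solve_local(data, nu_aipw, beta, z0, 0.25, cfg_aipw)
    assert np.allclose(a_ipw, a_aipw, atol=1e-8)


def test_logit_local_root_matches_grid_search_oracle():
    rng = np.random.default_rng(21)
    n = 120
    z = rng.uniform(0.3, 0.7, n)
    x = rng.normal(size=(n, 1))
    p = 1 / (1 + np.exp(-(0.5 * x[:, 0] + 0.3)))
    y = (rng.uniform(size=n) < p).astype(float)
    data = ObservedData(y, np.ones(n, int), x, z, rng.normal(size=n))
    nuis = _nuis_complete(n)
    cfg = FitConfig(estimator="naive", link="logit", bandwidth=0.4)
    beta = np.array([0.5])
    z0 = 0.5
    alpha, ok = solve_local(data, nuis, beta, z0, 0.4, cfg)
    assert ok

    # derivative-free oracle: iterative dense-grid refinement of the
    # estimating-equation norm over (alpha0, alpha1)
    from aipwgplm.model_core import get_kernel, get_link
    link = get_link("logit")
    k = get_kernel("epanechnikov")
    w = k.k((z - z0) / 0.4) / 0.4
    g = np.column_stack([np.ones(n), z - z0])

    def eqnorm(a0, a1):
        lp = x[:, 0] * 0.5 + a0 + a1 * (z - z0)
        mu = link.mu(lp)
        f = g.T @ (w * link.mu1(lp) * (y - mu))
        return np.linalg.norm(f)

    lo = np.array([-3.0, -5.0]); hi = np.array([3.0, 5.0])
    best = None
    for _ in range(14):
        a0s = np.linspace(lo[0], hi[0], 41)
        a1s = np.linspace(lo[1], hi[1], 41)
        vals = np.array([[eqnorm(a0, a1) for a1 in a1s] for a0 in a0s])
        i, j = np.unravel_index(vals.argmin(), vals.shape)
        best = np.array([a0s[i], a1s[j]])
        span = (hi - lo) / 4.0
        lo, hi = best - span, best + span
    assert np.allclose(alpha, best, atol=1e-4)
    assert eqnorm(*alpha) < 1e-8


def test_constant_theta_is_interpolated_exactly():
    rng = np.random.default_rng(5)
    n = 80
    z = rng.uniform(0, 1, n)
    x = rng.normal(size=(n, 1))
    c = 2.5
    y = 3.0 * x[:, 0] + c                      # no noise, constant theta
    data = ObservedData(y, np.ones(n, int), x, z, rng.normal(size=n))
    nuis = _nuis_complete(n)
    cfg = FitConfig(estimator="naive", link="identity", bandwidth=0.3)
    curve = theta_curve(data, nuis, np.array([3.0]),
                        np.linspace(0.15, 0.85, 15), 0.3, cfg)
    assert np.allclose(curve.alpha0, c, atol=1e-10)
    assert np.allclose(curve.alpha1, 0.0, atol=1e-9)


def test_bias_scales_quadratically_in_bandwidth():
    # noiseless smooth theta: doubling h multiplies the smoothing bias ~4x
    n = 4000
    z = np.linspace(0.001, 0.999, n)
    theta = np.sin(2 * np.pi * z)
    x = np.zeros((n, 1))
    data = ObservedData(theta.copy(), np.ones(n, int), x, z, np.zeros(n))
    nuis = _nuis_complete(n)
    cfg = FitConfig(estimator="naive", link="identity", bandwidth=0.05)
    z0 = np.array([0.25])                       # curvature peak of sin
    h = 0.04
    b1 = theta_curve(data, nuis, np.zeros(1), z0, h, cfg).alpha0[0] - np.sin(2 * np.pi * 0.25)
    b2 = theta_curve(data, nuis, np.zeros(1), z0, 2 * h, cfg).alpha0[0] - np.sin(2 * np.pi * 0.25)
    assert 3.0 < b2 / b1 < 5.0


def test_phi_identity_closed_form_is_minus_smoothed_x():
    data, beta = make_complete_data(n=160, seed=13, p=2)
    nuis = _nuis_complete(data.n)
    cfg = FitConfig(estimator="naive", link="identity", bandwidth=0.25)
    grid = np.linspace(0.2, 0.8, 7)
    curve = theta_curve(data, nuis, beta, grid, 0.25, cfg)
    s = local_linear_smoother(data.z, grid, 0.25)
    assert np.allclose(curve.phi, -(s @ data.x), atol=1e-10)


@pytest.mark.parametrize("link", ["identity", "logit"])
def test_phi_implicit_matches_finite_difference(link):
    rng = np.random.default_rng(31)
    n = 200
    z = rng.uniform(0, 1, n)
    x = rng.normal(size=(n, 1))
    if link == "identity":
        y = x[:, 0] + np.sin(2 * np.pi * z) + 0.4 * rng.normal(size=n)
        beta = np.array([1.0])
    else:
        p = 1 / (1 + np.exp(-(0.8 * x[:, 0] + np.sin(2 * np.pi * z))))
        y = (rng.uniform(size=n) < p).astype(float)
        beta = np.array([0.8])
    u = y * 0.5 + rng.normal(size=n)
    pi = 1 / (1 + np.exp(-(0.8 + 0.5 * u)))
    r = (rng.uniform(size=n) < pi).astype(int)
    data = ObservedData(np.where(r == 1, y, np.nan), r, x, z, u)
    nuis = _nuis_complete(n)
    nuis.pi_hat = pi
    spec = FixedDelta(lambda d: np.full(d.n, float(np.nanmean(d.y))))
    fit_outcome_model(data, spec, nuis)
    cfg = FitConfig(estimator="aipw", link=link, bandwidth=0.3,
                    force_iterative=True)
    grid = np.linspace(0.25, 0.75, 5)
    curve = theta_curve(data, nuis, beta, grid, 0.3, cfg)
    fd = phi_fd(data, nuis, beta, grid, 0.3, cfg)
    assert np.allclose(curve.phi, fd, atol=1e-4)


def test_too_narrow_window_raises_helpful_error():
    data, beta = make_complete_data(n=60, seed=8)
    nuis = _nuis_complete(data.n)
    cfg = FitConfig(estimator="naive", link="identity", bandwidth=1e-4)
    with pytest.raises(ValueError, match="bandwidth"):
        theta_curve(data, nuis, beta, np.array([0.5]), 1e-4, cfg)
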