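"""Nuisance-model fitting: selection, outcome regression, working variance."""

import numpy as np
import pytest

from aipwgplm import (FitConfig, FixedDelta, KnownPi, LinearDelta, LogisticPi,
                      ObservedData, fit_missingness, fit_outcome_model,
                      fit_working_variance, initial_fit)
from aipwgplm.nuisance import NuisanceFit

from conftest import make_complete_data, profile_ls_oracle


def _toy_two_cell():
    # 8 units, binary U: Pr(R=1|U=1)=3/4 and Pr(R=1|U=0)=1/4
    u = np.array([1, 1, 1, 1, 0, 0, 0, 0])
    r = np.array([1, 1, 1, 0, 1, 0, 0, 0])
    y = np.where(r == 1, 1.0, np.nan)
    z = np.linspace(0, 1, 8)
    x = np.ones((8, 1))
    return ObservedData(y, r, x, z, u), u


def test_saturated_logistic_recovers_cell_proportions():
    data, u = _toy_two_cell()
    spec = LogisticPi(np.column_stack([np.ones(8), u]))
    nuis = fit_missingness(data, spec, pi_floor=0.0)
    assert np.allclose(nuis.pi_hat[u == 1], 0.75, atol=1e-8)
    assert np.allclose(nuis.pi_hat[u == 0], 0.25, atol=1e-8)
    # score has mean ~0 at the MLE
    assert np.abs(nuis.score_tau.mean(axis=0)).max() < 1e-9


def test_logistic_mle_matches_statsmodels():
    import statsmodels.api as sm
    rng = np.random.default_rng(3)
    n = 300
    u = rng.normal(size=n)
    pi = 1 / (1 + np.exp(-(0.3 + 0.9 * u)))
    r = (rng.uniform(size=n) < pi).astype(int)
    data = ObservedData(np.where(r == 1, 1.0, np.nan), r,
                        rng.normal(size=(n, 1)), rng.uniform(0, 1, n), u)
    d = np.column_stack([np.ones(n), u])
    nuis = fit_missingness(data, LogisticPi(d), pi_floor=0.0)
    ref = sm.GLM(r, d, family=sm.families.Binomial()).fit()
    assert np.allclose(nuis.tau_hat, ref.params, atol=1e-8)


def test_degenerate_missingness_detected():
    n = 20
    data = ObservedData(np.arange(n, dtype=float), np.ones(n, dtype=int),
                        np.ones((n, 1)), np.linspace(0, 1, n))
    with pytest.raises(ValueError, match="identically 1"):
        fit_missingness(data, LogisticPi(np.ones((n, 1))))


def test_separation_reported():
    # U perfectly separates R -> MLE diverges
    u = np.r_[np.ones(10), -np.ones(10)]
    r = np.r_[np.ones(10, int), np.zeros(10, int)]
    data = ObservedData(np.where(r == 1, 0.0, np.nan), r,
                        np.ones((20, 1)), np.linspace(0, 1, 20), u)
    with pytest.raises(ValueError):
        fit_missingness(data, LogisticPi(np.column_stack([np.ones(20), u])))


def test_outcome_model_interpolates_noiseless_data():
    rng = np.random.default_rng(1)
    n = 50
    x = rng.normal(size=n)
    u = rng.normal(size=n)
    y = 1.0 + 2.0 * x - 0.5 * u
    r = (rng.uniform(size=n) < 0.7).astype(int)
    data = ObservedData(np.where(r == 1, y, np.nan), r, x,
                        rng.uniform(0, 1, n), u)
    nuis = NuisanceFit(pi_hat=np.full(n, 0.7))
    spec = LinearDelta(lambda d: np.column_stack([np.ones(d.n), d.x[:, 0],
                                                  d.u[:, 0]]))
    fit_outcome_model(data, spec, nuis)
    assert np.allclose(nuis.delta_hat, y, atol=1e-8)   # evaluated at ALL units
    assert np.allclose(nuis.eta_hat, [1.0, 2.0, -0.5], atol=1e-8)


def test_constant_weight_invariance_of_eta():
    rng = np.random.default_rng(2)
    n = 80
    x = rng.normal(size=n)
    y = x + rng.normal(size=n)
    r = (rng.uniform(size=n) < 0.6).astype(int)
    data = ObservedData(np.where(r == 1, y, np.nan), r, x,
                        rng.uniform(0, 1, n), rng.normal(size=n))
    spec = LinearDelta(lambda d: np.column_stack([np.ones(d.n), d.x[:, 0]]))
    n1 = NuisanceFit(pi_hat=np.full(n, 0.37))
    fit_outcome_model(data, spec, n1, weighted=False)
    n2 = NuisanceFit(pi_hat=np.full(n, 0.37))
    fit_outcome_model(data, spec, n2, weighted=True)   # 1/pi constant
    assert np.allclose(n1.eta_hat, n2.eta_hat, atol=1e-10)


def test_working_variance_constant_is_mean_of_s():
    rng = np.random.default_rng(4)
    n = 60
    y = rng.normal(size=n)
    r = (rng.uniform(size=n) < 0.7).astype(int)
    data = ObservedData(np.where(r == 1, y, np.nan), r, rng.normal(size=n),
                        rng.uniform(0, 1, n), rng.normal(size=n))
    pi = np.full(n, 0.7)
    nuis = NuisanceFit(pi_hat=pi)
    nuis.delta_hat = rng.normal(size=n)
    q = rng.normal(size=n)
    fit_working_variance(data, nuis, q, "constant", "aipw")
    rp = r / pi
    s = (rp * (data.y_filled - q) - (rp - 1) * (nuis.delta_hat - q)) ** 2
    assert np.allclose(nuis.zeta_hat[0], s.mean(), atol=1e-12)


def test_working_variance_collapses_without_missingness():
    rng = np.random.default_rng(5)
    n = 40
    y = rng.normal(size=n)
    data = ObservedData(y, np.ones(n, int), rng.normal(size=n),
                        rng.uniform(0, 1, n), rng.normal(size=n))
    nuis = NuisanceFit(pi_hat=np.ones(n))
    nuis.delta_hat = rng.normal(size=n)   # arbitrary: pi-terms annihilate it
    q = rng.normal(size=n)
    fit_working_variance(data, nuis, q, "constant", "aipw")
    assert np.allclose(nuis.zeta_hat[0], ((y - q) ** 2).mean(), atol=1e-12)


def test_initial_fit_matches_profile_ls_without_missingness():
    data, beta_true = make_complete_data(n=220, seed=9)
    nuis = NuisanceFit(pi_hat=np.ones(data.n))
    cfg = FitConfig(estimator="ipw", link="identity", bandwidth=0.2,
                    pi_spec=KnownPi(np.ones(data.n)))
    beta_check, theta_check = initial_fit(data, nuis, cfg, h=0.2)
    beta_oracle, _, _ = profile_ls_oracle(data, h=0.2)
    assert np.allclose(beta_check, beta_oracle, atol=1e-8)
    assert theta_check.shape == (data.n,)


def test_known_pi_equals_saturated_fit_downstream():
    # on a two-cell design the saturated logistic MLE equals the cell
    # proportions, so known-pi and fitted-pi runs must agree exactly
    rng = np.random.default_rng(7)
    n = 120
    u = rng.integers(0, 2, n).astype(float)
    pi = np.where(u == 1, 0.8, 0.4)
    r = (rng.uniform(size=n) < pi).astype(int)
    if r[u == 1].mean() in (0, 1) or r[u == 0].mean() in (0, 1):
        pytest.skip("degenerate draw")
    x = rng.normal(size=n)
    z = rng.uniform(0, 1, n)
    y = 1.5 * x + np.sin(2 * np.pi * z) + 0.3 * rng.normal(size=n)
    data = ObservedData(np.where(r == 1, y, np.nan), r, x, z, u)
    cell = np.where(u == 1, r[u == 1].mean(), r[u == 0].mean())
    from aipwgplm import fit_gplm
    cfg_known = FitConfig(estimator="ipw", link="identity", bandwidth=0.25,
                          pi_spec=KnownPi(cell))
    cfg_fit = FitConfig(estimator="ipw", link="identity", bandwidth=0.25,
                        pi_spec=LogisticPi(np.column_stack([np.ones(n), u])),
                        pi_floor=0.0)
    b1 = fit_gplm(data, cfg_known).beta_hat
    b2 = fit_gplm(data, cfg_fit).beta_hat
    assert np.allclose(b1, b2, atol=1e-6)
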