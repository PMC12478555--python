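"""Variance estimation: sandwich for beta-hat, plug-in pointwise variance
for theta-hat, and Monte-Carlo evaluation of the semiparametric bound.

Sandwich
--------
With D_i = mu1_i V_i^{-1} (X_i + phi(Z_i)) and the branch residual eps_i,
the estimated covariance is Omega = A^{-1} B A^{-1} where

    A = (1/n) sum_i b_i mu1_i^2 V_i^{-1} Xt_i Xt_i',
    B = (1/n) sum_i psi_i psi_i',
    psi_i = D_i eps_i - C_tau M_tau^{-1} S_i - C_eta M_eta^{-1} l_i,

b_i the branch bread weight (1 / R_i/pi_i / R_i), S_i and l_i the selection
and outcome estimating functions, and C, M the empirical cross-derivative
and information matrices.  The correction terms are present only when the
corresponding nuisance was actually estimated; with probabilities known by
design or a fixed delta they are exactly zero.  Per-coefficient standard
errors are sqrt(diag(Omega)/n).

Pointwise variance of theta-hat
-------------------------------
The asymptotic variance of the local-linear stage has the sandwich form

    Sigma(z) / (n h),  Sigma(z) = c0(K^2) E[r(X,Z) s2(X,Z,U) | Z=z]
                                   / { t(z)^2 f_Z(z) },

with t(z) = E[mu1^2/V | Z=z], r = mu1^2/V^2 and s2 the conditional second
moment of the branch residual.  The plug-in replaces the conditional
expectations by kernel averages at the fit bandwidth, s2 by the squared
per-unit residual eps_i^2 (whose conditional mean is exactly s2 for each
branch), and f_Z by a kernel density estimate with Silverman's rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .model_core import FitConfig, ObservedData
from .nuisance import NuisanceFit
from .theta_kernel import ThetaCurve

__all__ = ["sandwich_beta", "theta_pointwise_variance", "EfficiencyBound",
           "efficiency_bound_mc"]


# ---------------------------------------------------------------------------
# shared per-unit pieces
# ---------------------------------------------------------------------------


def _unit_pieces(data: ObservedData, nuis: NuisanceFit, beta: np.ndarray,
                 theta_at_obs: np.ndarray, config: FitConfig):
    link = config.link_obj
    lp = data.x @ beta + theta_at_obs
    mu = link.mu(lp)
    mu1 = link.mu1(lp)
    v = nuis.v_values if nuis.v_values is not None else nuis.v_of(data.x @ beta)
    rp = data.r / nuis.pi_hat
    y = data.y_filled
    if config.estimator == "aipw":
        eps = rp * (y - mu) - (rp - 1.0) * (nuis.delta_hat - mu)
        bw = np.ones(data.n)
    elif config.estimator == "ipw":
        eps = rp * (y - mu)
        bw = rp
    else:
        eps = data.r * (y - mu)
        bw = data.r.astype(float)
    return mu, mu1, v, rp, eps, bw


# ---------------------------------------------------------------------------
# sandwich for beta
# ---------------------------------------------------------------------------


def sandwich_beta(data: ObservedData, nuis: NuisanceFit, beta: np.ndarray,
                  theta_obs: ThetaCurve, config: FitConfig):
    """Bread, meat and sandwich covariance of beta-hat.

    ``theta_obs`` is the fitted curve (with phi) at the observed Z_i.
    Returns ``(bread, meat, omega)``; SE = sqrt(diag(omega)/n).
    """
    beta = np.asarray(beta, dtype=float).ravel()
    mu, mu1, v, rp, eps, bw = _unit_pieces(data, nuis, beta, theta_obs.alpha0, config)
    if theta_obs.phi is None:
        raise ValueError("theta_obs must carry phi")
    x_tilde = data.x + theta_obs.phi
    n = data.n

    bread = (x_tilde * (bw * mu1 ** 2 / v)[:, None]).T @ x_tilde / n
    cond = np.linalg.cond(bread)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"singular bread matrix (condition number {cond:.3g})")

    d_mat = x_tilde * (mu1 / v)[:, None]          # D_i rows
    psi = d_mat * eps[:, None]

    # correction for the estimated selection model
    if (not nuis.pi_known and nuis.score_tau is not None
            and config.estimator in ("ipw", "aipw")):
        pi = nuis.pi_hat
        if config.estimator == "aipw":
            deps_dpi = (data.r / pi ** 2) * (nuis.delta_hat - mu - (data.y_filled - mu))
        else:
            deps_dpi = -(data.r / pi ** 2) * (data.y_filled - mu)
        dpi_dtau = (pi * (1.0 - pi))[:, None] * nuis.pi_design
        deps_dtau = deps_dpi[:, None] * dpi_dtau          # (n, k)
        c_tau = d_mat.T @ deps_dtau / n                   # (p, k)
        psi -= nuis.score_tau @ np.linalg.solve(nuis.info_tau, c_tau.T)

    # correction for the estimated outcome model
    if (config.estimator == "aipw" and not nuis.delta_fixed
            and nuis.score_eta is not None):
        deps_deta = -(rp - 1.0)[:, None] * nuis.delta_design  # (n, d)
        c_eta = d_mat.T @ deps_deta / n
        psi -= nuis.score_eta @ np.linalg.solve(nuis.info_eta, c_eta.T)

    meat = psi.T @ psi / n
    bread_inv = np.linalg.inv(bread)
    omega = bread_inv @ meat @ bread_inv
    omega = 0.5 * (omega + omega.T)
    return bread, meat, omega


# ---------------------------------------------------------------------------
# pointwise variance of theta-hat
# ---------------------------------------------------------------------------

_SILVERMAN_CONST = {"gaussian": 1.06, "epanechnikov": 2.34}


def theta_pointwise_variance(data: ObservedData, nuis: NuisanceFit,
                             beta: np.ndarray, curve: ThetaCurve,
                             config: FitConfig) -> np.ndarray:
    """Plug-in estimate of var{theta-hat(z)} at the curve's grid points."""
    z_eval = np.asarray(curve.z_eval, dtype=float)
    h_used = curve.h_used
    if (z_eval.min() < data.z.min() - h_used
            or z_eval.max() > data.z.max() + h_used):
        raise ValueError("evaluation points fall outside the kernel-covered "
                         "range of the observed Z")
    kernel = config.kernel_obj
    h = curve.h_used
    theta_at_obs = np.interp(data.z, curve.z_eval, curve.alpha0)
    mu, mu1, v, rp, eps, bw = _unit_pieces(data, nuis, np.asarray(beta, float).ravel(),
                                           theta_at_obs, config)
    t_contrib = bw * mu1 ** 2 / v
    meat_contrib = (mu1 ** 2 / v ** 2) * eps ** 2

    sd = np.std(data.z, ddof=1)
    iqr = np.subtract(*np.percentile(data.z, [75, 25]))
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    h_f = _SILVERMAN_CONST.get(kernel.name, 1.06) * scale * data.n ** (-0.2)

    dmat = data.z[None, :] - z_eval[:, None]
    w = kernel.k(dmat / h) / h
    w_sum = w.sum(axis=1)
    if np.any(w_sum <= 0):
        raise ValueError("empty kernel window; increase the bandwidth h")
    t_hat = (w @ t_contrib) / w_sum
    meat_hat = (w @ meat_contrib) / w_sum
    f_hat = (kernel.k(dmat / h_f) / h_f).mean(axis=1)
    f_hat = np.clip(f_hat, 1e-12, None)
    if np.any(t_hat <= 0):
        raise ValueError("degenerate local information (no complete cases in "
                         "some window); increase h")
    sigma = kernel.c0 * meat_hat / (t_hat ** 2 * f_hat)
    return np.clip(sigma / (data.n * h), 0.0, None)


# ---------------------------------------------------------------------------
# semiparametric efficiency bound by Monte Carlo
# ---------------------------------------------------------------------------


@dataclass
class EfficiencyBound:
    """MC estimate of the efficiency bound V_eff for beta."""

    v_eff: np.ndarray              # (p, p)
    phi_eff: Callable[[np.ndarray], np.ndarray]
    mc_draws: int
    mc_se: np.ndarray              # (p, p) batch-based standard error


def efficiency_bound_mc(cfg, n_outer: int = 100_000, n_inner: int = 200,
                        seed: int = 0, pi_is_one: bool = False,
                        n_bins: int = 200) -> EfficiencyBound:
    """Monte-Carlo semiparametric variance bound for the two-stage design.

    For the shipped simulation design (identity link) the bound is

        V_eff = E[ sigma^{-2}(X,Z) (X - phi_eff(Z))^2 ]^{-1},
        phi_eff(z) = E[sigma^{-2} X | Z=z] / E[sigma^{-2} | Z=z],

    with sigma^2(X,Z) = var(eps* | X,Z) computed by an inner simulation of
    (U, Y, R) given (X, Z).  phi_eff is estimated by a binned kernel
    regression over the outer draws.  ``pi_is_one`` forces full observation
    (eps* = eps), the case with a closed-form oracle.

    Parameters ``cfg`` must provide the two-stage design fields of
    :class:`aipwgplm.simulation.SimConfig`.
    """
    from .simulation import selection_probability

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    z = rng.uniform(0.0, 1.0, n_outer)
    x = rng.normal((z - 0.5) ** 2, 1.0)
    sigma2 = np.empty(n_outer)
    chunk = max(1, 4_000_000 // n_inner)
    for lo in range(0, n_outer, chunk):
        hi = min(lo + chunk, n_outer)
        xs = x[lo:hi, None]
        zs = z[lo:hi, None]
        nb = hi - lo
        u = (rng.uniform(0.0, 6.0, (nb, n_inner))
             + rng.normal(xs, cfg.noise_sd_u)
             + rng.normal(zs, cfg.noise_sd_u))
        g = cfg.beta2 * (u - 3.0 - xs - zs)   # E(eps | X,Z,U)
        e = rng.normal(0.0, cfg.sigma_y, (nb, n_inner))
        if pi_is_one:
            eps_star = g + e
        else:
            pi = selection_probability(u, cfg)
            r = rng.uniform(size=(nb, n_inner)) < pi
            rpi = r / pi
            eps_star = rpi * (g + e) - (rpi - 1.0) * g
        sigma2[lo:hi] = eps_star.var(axis=1, ddof=1)

    inv_s2 = 1.0 / sigma2
    # binned kernel regression for phi_eff(z)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.digitize(z, edges) - 1, 0, n_bins - 1)
    num_b = np.bincount(idx, weights=inv_s2 * x, minlength=n_bins)
    den_b = np.bincount(idx, weights=inv_s2, minlength=n_bins)
    h_b = 0.05
    kw = np.clip(1.0 - ((centers[:, None] - centers[None, :]) / h_b) ** 2, 0.0, None)
    num_s = kw @ num_b
    den_s = kw @ den_b
    if np.any(den_s <= 0):
        raise RuntimeError("empty phi_eff smoothing window; increase n_outer")
    phi_c = num_s / den_s

    def phi_eff(zz):
        return np.interp(np.asarray(zz, dtype=float), centers, phi_c)

    contrib = inv_s2 * (x - phi_eff(z)) ** 2
    mean_c = contrib.mean()
    if mean_c <= 0:
        raise RuntimeError("degenerate bound average; increase n_outer")
    v_eff = np.array([[1.0 / mean_c]])

    n_batch = 10
    splits = np.array_split(np.arange(n_outer), n_batch)
    vals = np.array([1.0 / contrib[s].mean() for s in splits])
    mc_se = np.array([[vals.std(ddof=1) / np.sqrt(n_batch)]])
    return EfficiencyBound(v_eff=v_eff, phi_eff=phi_eff,
                           mc_draws=n_outer * n_inner, mc_se=mc_se)
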