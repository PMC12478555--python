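"""Local-linear kernel stage: theta-hat(z, beta) and its beta-derivative.

For a fixed beta and each evaluation point z the local parameters
alpha = (alpha0, alpha1) solve the weighted kernel estimating equation

    sum_i K_h(Z_i - z) mu1_i V_i^{-1} G(Z_i - z) T_i(alpha) = 0,
    G(u) = (1, u)',  mu_i = mu(X_i' beta + alpha0 + alpha1 (Z_i - z)),

where the bracket T_i carries the estimator branch:

    aipw : R_i/pi_i (Y_i - mu_i) - (R_i/pi_i - 1)(delta_i - mu_i)
    ipw  : R_i/pi_i (Y_i - mu_i)
    naive: R_i (Y_i - mu_i)

theta-hat(z, beta) = alpha0.  With the identity link the equation is linear
in alpha and the exact generalized-least-squares solution is returned in one
step; otherwise a damped Newton iteration with analytic Jacobian is used.
The derivative phi(z, beta) = d theta-hat / d beta is obtained by implicit
differentiation of the local system.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model_core import FitConfig, ObservedData, kernel_weights
from .nuisance import NuisanceFit

__all__ = ["ThetaCurve", "solve_local", "theta_curve", "phi_derivative", "phi_fd"]


@dataclass
class ThetaCurve:
    """theta-hat, local slope and beta-derivative on an evaluation grid."""

    z_eval: np.ndarray
    alpha0: np.ndarray
    alpha1: np.ndarray
    phi: Optional[np.ndarray]  # (m, p) or None if not requested
    h_used: float
    converged: np.ndarray
    se: Optional[np.ndarray] = None  # filled by the inference module


# ---------------------------------------------------------------------------
# branch bookkeeping
# ---------------------------------------------------------------------------


def _branch_arrays(data: ObservedData, nuis: NuisanceFit, estimator: str):
    """Per-unit (c, y_tilde, rp, delta) for the estimating-equation branch.

    ``c`` multiplies -mu in the bracket (the derivative of T wrt mu is -c)
    and also serves as the effective unit weight in the identity-link
    closed form, where the bracket collapses to c * (y_tilde - mu) with the
    pseudo-outcome y_tilde.
    """
    rp = data.r / nuis.pi_hat
    y = data.y_filled
    if estimator == "aipw":
        if nuis.delta_hat is None:
            raise ValueError("AIPW estimation requires delta_hat in the nuisance fit")
        delta = nuis.delta_hat
        c = np.ones(data.n)
        y_tilde = rp * y - (rp - 1.0) * delta
    elif estimator == "ipw":
        delta = None
        c = rp
        y_tilde = y
    elif estimator == "naive":
        delta = None
        c = data.r.astype(float)
        y_tilde = y
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return c, y_tilde, rp, delta


def _v_at(nuis: NuisanceFit, lp: np.ndarray) -> np.ndarray:
    if nuis.v_values is not None and nuis.v_values.shape == lp.shape:
        return nuis.v_values
    return nuis.v_of(lp)


# ---------------------------------------------------------------------------
# single-point solver
# ---------------------------------------------------------------------------


def solve_local(data: ObservedData, nuis: NuisanceFit, beta: np.ndarray,
                z0: float, h: float, config: FitConfig,
                alpha_init: Optional[np.ndarray] = None):
    """Solve the 2-D local estimating equation at one point.

    Returns ``(alpha, converged)``.  Identity link: exact weighted-least-
    squares solution in one step (unless ``config.force_iterative``).
    """
    link = config.link_obj
    kernel = config.kernel_obj
    beta = np.asarray(beta, dtype=float).ravel()
    c, y_tilde, rp, delta = _branch_arrays(data, nuis, config.estimator)
    w = kernel_weights(data.z, z0, h, kernel)
    d = data.z - z0
    offset = data.x @ beta
    v = _v_at(nuis, offset)  # V fixed per unit during local solves

    active = w * np.abs(c) > 0
    if config.estimator in ("ipw", "naive"):
        if int(np.count_nonzero(active & (data.r == 1))) < 2:
            raise ValueError(
                f"fewer than 2 complete cases receive kernel weight at z0={z0:g}; "
                "increase the bandwidth h")
    if int(np.count_nonzero(active)) < 2 or np.unique(data.z[active]).size < 2:
        raise ValueError(
            f"local design at z0={z0:g} is degenerate (all Z equal in window); "
            "increase the bandwidth h")

    base_w = w / v

    if link.name == "identity" and not config.force_iterative:
        ww = base_w * c
        s0 = ww.sum(); s1 = (ww * d).sum(); s2 = (ww * d * d).sum()
        res = y_tilde - offset
        t0 = (ww * res).sum(); t1 = (ww * d * res).sum()
        det = s0 * s2 - s1 * s1
        if not np.isfinite(det) or abs(det) < 1e-14 * max(s0 * s2, 1e-300):
            raise ValueError(
                f"singular local system at z0={z0:g}; increase the bandwidth h")
        alpha = np.array([(s2 * t0 - s1 * t1) / det, (s0 * t1 - s1 * t0) / det])
        return alpha, True

    # damped Newton with analytic Jacobian
    if alpha_init is None:
        # seed from the identity-link solution of the mu-transformed problem
        alpha = np.array([float(np.sum(base_w * c * (y_tilde - offset)) /
                                max(np.sum(base_w * c), 1e-12)), 0.0])
        if link.name == "logit":
            m = np.clip(alpha[0], 1e-4, 1 - 1e-4)
            alpha = np.array([np.log(m / (1 - m)), 0.0])
        elif link.name == "log":
            alpha = np.array([np.log(max(alpha[0], 1e-8)), 0.0])
    else:
        alpha = np.asarray(alpha_init, dtype=float).copy()

    g_mat = np.column_stack([np.ones(data.n), d])

    def residual(a):
        lp = offset + a[0] + a[1] * d
        mu = link.mu(lp)
        mu1 = link.mu1(lp)
        if config.estimator == "aipw":
            t = rp * (data.y_filled - mu) - (rp - 1.0) * (delta - mu)
        elif config.estimator == "ipw":
            t = rp * (data.y_filled - mu)
        else:
            t = data.r * (data.y_filled - mu)
        f = g_mat.T @ (base_w * mu1 * t)
        return f, mu, mu1, t

    f, mu, mu1, t = residual(alpha)
    norm = np.linalg.norm(f)
    converged = norm <= config.local_tol
    for _ in range(config.max_local_iter):
        if converged:
            break
        lp = offset + alpha[0] + alpha[1] * d
        mu2 = link.mu2(lp)
        m_scal = base_w * (mu2 * t - c * mu1 ** 2)
        jac = (g_mat * m_scal[:, None]).T @ g_mat
        try:
            step = np.linalg.solve(jac, -f)
        except np.linalg.LinAlgError:
            # Fisher-scoring fallback
            m_scal = -base_w * c * mu1 ** 2
            jac = (g_mat * m_scal[:, None]).T @ g_mat
            try:
                step = np.linalg.solve(jac, -f)
            except np.linalg.LinAlgError as exc:
                raise ValueError(
                    f"singular local Jacobian at z0={z0:g}; increase the bandwidth h") from exc
        lam = 1.0
        for _ in range(30):
            cand = alpha + lam * step
            f_new, mu, mu1, t = residual(cand)
            if np.linalg.norm(f_new) < norm * (1 - 1e-4 * lam) + 1e-300:
                break
            lam *= 0.5
        alpha = alpha + lam * step
        f, mu, mu1, t = residual(alpha)
        norm = np.linalg.norm(f)
        converged = norm <= config.local_tol
    return alpha, bool(converged)


# ---------------------------------------------------------------------------
# curve over a grid
# ---------------------------------------------------------------------------


def theta_curve(data: ObservedData, nuis: NuisanceFit, beta: np.ndarray,
                z_eval: np.ndarray, h: float, config: FitConfig,
                compute_phi: bool = True) -> ThetaCurve:
    """Evaluate theta-hat(., beta), the local slope and (optionally) phi.

    Identity link uses a fully vectorized closed form over the grid; other
    links solve point by point with warm starts between neighbours.
    """
    link = config.link_obj
    kernel = config.kernel_obj
    z_eval = np.asarray(z_eval, dtype=float).ravel()
    beta = np.asarray(beta, dtype=float).ravel()
    m = z_eval.size
    c, y_tilde, rp, delta = _branch_arrays(data, nuis, config.estimator)
    offset = data.x @ beta
    v = _v_at(nuis, offset)

    if link.name == "identity" and not config.force_iterative:
        dmat = data.z[None, :] - z_eval[:, None]           # (m, n)
        wmat = kernel.k(dmat / h) / h
        ww = wmat * (c / v)[None, :]
        s0 = ww.sum(axis=1)
        s1 = (ww * dmat).sum(axis=1)
        s2 = (ww * dmat * dmat).sum(axis=1)
        res = y_tilde - offset
        t0 = ww @ res
        t1 = (ww * dmat) @ res
        det = s0 * s2 - s1 * s1
        bad = ~np.isfinite(det) | (np.abs(det) < 1e-14 * np.maximum(s0 * s2, 1e-300))
        if bad.any():
            raise ValueError(
                f"singular local system at z0={z_eval[bad][0]:g}; increase the bandwidth h")
        n_cc = (wmat * (np.abs(c) > 0)[None, :] > 0).sum(axis=1)
        if (n_cc < 2).any():
            raise ValueError(
                f"fewer than 2 contributing units at z0={z_eval[n_cc < 2][0]:g}; "
                "increase the bandwidth h")
        alpha0 = (s2 * t0 - s1 * t1) / det
        alpha1 = (s0 * t1 - s1 * t0) / det
        phi = None
        if compute_phi:
            # theta-hat is linear in the pseudo-outcome: alpha0 = s(z)'(ytilde - X beta)
            # hence phi = d alpha0 / d beta = -s(z)' X, the local-linear smooth of X.
            smo = ww * (s2[:, None] - s1[:, None] * dmat)
            phi = -(smo @ data.x) / det[:, None]
        return ThetaCurve(z_eval, alpha0, alpha1, phi, h,
                          np.ones(m, dtype=bool))

    alpha0 = np.empty(m)
    alpha1 = np.empty(m)
    conv = np.empty(m, dtype=bool)
    order = np.argsort(z_eval)
    warm = None
    for idx in order:
        try:
            alpha, ok = solve_local(data, nuis, beta, z_eval[idx], h, config,
                                    alpha_init=warm)
        except ValueError as exc:
            raise ValueError(f"kernel stage failed at z0={z_eval[idx]:g}: {exc}") from exc
        alpha0[idx], alpha1[idx] = alpha
        conv[idx] = ok
        warm = alpha.copy()
    curve = ThetaCurve(z_eval, alpha0, alpha1, None, h, conv)
    if compute_phi:
        curve.phi = phi_derivative(data, nuis, beta, curve, config)
    return curve


# ---------------------------------------------------------------------------
# derivative of theta-hat with respect to beta
# ---------------------------------------------------------------------------


def phi_derivative(data: ObservedData, nuis: NuisanceFit, beta: np.ndarray,
                   theta: ThetaCurve, config: FitConfig) -> np.ndarray:
    """phi(z, beta) = d theta-hat(z, beta) / d beta by implicit differentiation.

    At each root solve J_alpha (d alpha / d beta) = -J_beta where J_alpha,
    J_beta are the analytic Jacobians of the local estimating function; the
    first row of the solution is phi.
    """
    link = config.link_obj
    kernel = config.kernel_obj
    beta = np.asarray(beta, dtype=float).ravel()
    c, y_tilde, rp, delta = _branch_arrays(data, nuis, config.estimator)
    offset = data.x @ beta
    v = _v_at(nuis, offset)
    m = theta.z_eval.size
    phi = np.empty((m, data.p))
    for j in range(m):
        z0 = theta.z_eval[j]
        d_z = data.z - z0
        w = kernel.k(d_z / theta.h_used) / theta.h_used
        base_w = w / v
        lp = offset + theta.alpha0[j] + theta.alpha1[j] * d_z
        mu = link.mu(lp)
        mu1 = link.mu1(lp)
        mu2 = link.mu2(lp)
        if config.estimator == "aipw":
            t = rp * (data.y_filled - mu) - (rp - 1.0) * (delta - mu)
        elif config.estimator == "ipw":
            t = rp * (data.y_filled - mu)
        else:
            t = data.r * (data.y_filled - mu)
        m_scal = base_w * (mu2 * t - c * mu1 ** 2)
        g_mat = np.column_stack([np.ones(data.n), d_z])
        j_alpha = (g_mat * m_scal[:, None]).T @ g_mat
        j_beta = (g_mat * m_scal[:, None]).T @ data.x
        try:
            dalpha = np.linalg.solve(j_alpha, -j_beta)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular local Jacobian at z0={z0:g}; increase the bandwidth h") from exc
        phi[j] = dalpha[0]
    return phi


def phi_fd(data: ObservedData, nuis: NuisanceFit, beta: np.ndarray,
           z_eval: np.ndarray, h: float, config: FitConfig,
           step: Optional[float] = None) -> np.ndarray:
    """Central finite-difference phi, retained as a cross-check oracle."""
    beta = np.asarray(beta, dtype=float).ravel()
    if step is None:
        step = 1e-5 * (1.0 + np.abs(beta).max())
    phi = np.empty((np.size(z_eval), beta.size))
    for k in range(beta.size):
        bp = beta.copy(); bp[k] += step
        bm = beta.copy(); bm[k] -= step
        up = theta_curve(data, nuis, bp, z_eval, h, config, compute_phi=False)
        dn = theta_curve(data, nuis, bm, z_eval, h, config, compute_phi=False)
        phi[:, k] = (up.alpha0 - dn.alpha0) / (2.0 * step)
    return phi
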