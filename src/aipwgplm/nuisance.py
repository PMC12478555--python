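"""Working (nuisance) models: missingness, outcome regression, variance.

Three parametric working models support the weighted estimating equations:

* the selection model  Pr(R=1 | X,Z,U) = pi(X,Z,U; tau)  (logistic MLE, or
  probabilities known by design);
* the outcome model    E(Y | X,Z,U) = delta(X,Z,U; eta)  (least squares on
  complete cases, optionally weighted by 1/pi-hat);
* the working variance var(eps*_delta | X,Z) = V(X,Z; zeta) (nonlinear least
  squares of the per-unit squared AIPW residual on the variance family).

Every per-unit estimating-function piece needed later by the sandwich
variance (scores, information matrices) is produced and stored here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from .model_core import FitConfig, ObservedData, get_kernel, get_link

logger = logging.getLogger("aipwgplm")

__all__ = [
    "KnownPi",
    "LogisticPi",
    "FixedDelta",
    "LinearDelta",
    "NuisanceFit",
    "fit_missingness",
    "fit_outcome_model",
    "fit_working_variance",
    "initial_fit",
]

DesignLike = Union[np.ndarray, Callable[[ObservedData], np.ndarray]]


def _resolve(design: DesignLike, data: ObservedData, ncol_min: int = 1) -> np.ndarray:
    mat = design(data) if callable(design) else design
    mat = np.asarray(mat, dtype=float)
    if mat.ndim == 1:
        mat = mat[:, None]
    if mat.shape[0] != data.n:
        raise ValueError("design matrix row count does not match the data")
    if mat.shape[1] < ncol_min:
        raise ValueError("design matrix needs at least one column")
    return mat


# ---------------------------------------------------------------------------
# model specifications
# ---------------------------------------------------------------------------


@dataclass
class KnownPi:
    """Selection probabilities known by design (two-stage studies)."""

    probs: DesignLike


@dataclass
class LogisticPi:
    """Logistic selection model expit(D tau); D built by ``design``.

    ``design`` is either an (n, k) matrix (include the intercept column
    yourself) or a callable mapping :class:`ObservedData` to one.  Column
    names are optional and only used in error messages.
    """

    design: DesignLike
    names: Optional[list] = None


@dataclass
class FixedDelta:
    """A fixed, user-specified delta(X,Z,U) — e.g. the true E(Y|X,Z,U)."""

    values: DesignLike


@dataclass
class LinearDelta:
    """Linear outcome working model delta = D eta fitted on complete cases."""

    design: DesignLike
    names: Optional[list] = None


# ---------------------------------------------------------------------------
# fitted container
# ---------------------------------------------------------------------------


@dataclass
class NuisanceFit:
    """Fitted nuisance models plus the per-unit pieces the sandwich needs.

    ``info_tau`` / ``info_eta`` are the empirical mean derivatives
    (1/n) sum_i dS_i/dtau' and (1/n) sum_i dl_i/deta' (negative definite).
    In known-pi / fixed-delta mode the corresponding score pieces are None
    and the sandwich drops the matching correction term.
    """

    pi_hat: np.ndarray
    pi_known: bool = True
    tau_hat: Optional[np.ndarray] = None
    pi_design: Optional[np.ndarray] = None
    score_tau: Optional[np.ndarray] = None
    info_tau: Optional[np.ndarray] = None
    n_pi_truncated: int = 0

    delta_hat: Optional[np.ndarray] = None
    delta_fixed: bool = True
    eta_hat: Optional[np.ndarray] = None
    delta_design: Optional[np.ndarray] = None
    eta_weights: Optional[np.ndarray] = None
    score_eta: Optional[np.ndarray] = None
    info_eta: Optional[np.ndarray] = None

    zeta_hat: Optional[np.ndarray] = None
    variance_spec: str = "constant"
    v_values: Optional[np.ndarray] = None

    def v_of(self, lp: np.ndarray) -> np.ndarray:
        """Working variance V evaluated at linear-predictor values."""
        lp = np.asarray(lp, dtype=float)
        if self.zeta_hat is None:
            return np.ones_like(lp)
        if self.variance_spec == "constant":
            return np.full_like(lp, float(self.zeta_hat[0]))
        if self.variance_spec == "loglinear":
            return np.exp(self.zeta_hat[0] + self.zeta_hat[1] * lp)
        raise ValueError(f"unknown variance_spec {self.variance_spec!r}")


# ---------------------------------------------------------------------------
# missingness model
# ---------------------------------------------------------------------------


def fit_missingness(data: ObservedData, pi_spec, pi_floor: float = 0.01) -> NuisanceFit:
    """Fit Pr(R=1|X,Z,U) or install known selection probabilities.

    Logistic MLE by Newton-Raphson with step halving (tol 1e-10 on the score
    norm, max 100 iterations).  Returns per-unit scores S_i = (R_i - pi_i) d_i
    and the empirical information for the sandwich correction.
    """
    if isinstance(pi_spec, KnownPi):
        pi = np.asarray(pi_spec.probs(data) if callable(pi_spec.probs) else pi_spec.probs,
                        dtype=float).ravel()
        if pi.shape != (data.n,):
            raise ValueError("known probabilities must have length n")
        if np.any(pi <= 0.0) or np.any(pi > 1.0):
            raise ValueError("known selection probabilities must lie in (0, 1]")
        return NuisanceFit(pi_hat=pi, pi_known=True)

    if not isinstance(pi_spec, LogisticPi):
        raise TypeError("pi_spec must be a KnownPi or LogisticPi instance")

    r = data.r
    if r.min() == 1:
        raise ValueError(
            "all outcomes are observed (R identically 1): the missingness MLE "
            "is not identified; use estimator='naive' or KnownPi(1)")
    if r.max() == 0:
        raise ValueError("no outcomes are observed (R identically 0)")

    d = _resolve(pi_spec.design, data)
    k = d.shape[1]
    names = pi_spec.names or [f"col{j}" for j in range(k)]
    rank = np.linalg.matrix_rank(d)
    if rank < k:
        raise ValueError(
            f"selection design matrix is rank deficient (rank {rank} < {k}); "
            f"columns: {names}")

    tau = np.zeros(k)

    def negloglik(t):
        eta = np.clip(d @ t, -500, 500)
        return float(np.sum(np.log1p(np.exp(eta)) - r * eta))

    nll = negloglik(tau)
    converged = False
    for _ in range(100):
        p = expit(d @ tau)
        score = d.T @ (r - p) / data.n
        if np.linalg.norm(score) < 1e-10:
            converged = True
            break
        w = np.clip(p * (1.0 - p), 1e-12, None)
        info = (d * w[:, None]).T @ d / data.n
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"singular information in the selection model; columns {names} "
                "may be collinear or separated") from exc
        lam = 1.0
        for _ in range(30):
            cand = tau + lam * step
            cand_nll = negloglik(cand)
            if cand_nll <= nll + 1e-12:
                break
            lam *= 0.5
        tau = tau + lam * step
        nll = negloglik(tau)
    if not converged:
        raise ValueError(
            "selection-model MLE failed to converge (possible separation); "
            f"columns {names}, |tau| up to {np.abs(tau).max():.2f}")
    lin = d @ tau
    if np.abs(lin).max() > 20.0:
        raise ValueError(
            "selection model shows (quasi-)separation: fitted logits exceed "
            f"25 in magnitude; columns {names}")

    pi = expit(d @ tau)
    n_trunc = int(np.count_nonzero(pi < pi_floor))
    if n_trunc:
        logger.warning("truncated %d fitted selection probabilities below %.3g",
                       n_trunc, pi_floor)
        pi = np.clip(pi, pi_floor, None)
    score_tau = d * (r - expit(d @ tau))[:, None]
    w = expit(d @ tau) * (1.0 - expit(d @ tau))
    info_tau = -(d * w[:, None]).T @ d / data.n
    return NuisanceFit(pi_hat=pi, pi_known=False, tau_hat=tau, pi_design=d,
                       score_tau=score_tau, info_tau=info_tau,
                       n_pi_truncated=n_trunc)


# ---------------------------------------------------------------------------
# outcome working model
# ---------------------------------------------------------------------------


def fit_outcome_model(data: ObservedData, delta_spec, nuis: NuisanceFit,
                      weighted: bool = False) -> NuisanceFit:
    """Fit E(Y|X,Z,U) = delta(X,Z,U; eta) on complete cases, or install a
    fixed delta.  Updates ``nuis`` in place and returns it.

    Default is unweighted least squares (valid under MAR since
    E(Y|X,Z,U,R=1) = E(Y|X,Z,U)); ``weighted=True`` uses 1/pi-hat weights.
    delta is evaluated at every unit, including those with missing Y.
    """
    if isinstance(delta_spec, FixedDelta):
        vals = np.asarray(delta_spec.values(data) if callable(delta_spec.values)
                          else delta_spec.values, dtype=float).ravel()
        if vals.shape != (data.n,):
            raise ValueError("fixed delta must have length n")
        nuis.delta_hat = vals
        nuis.delta_fixed = True
        return nuis

    if not isinstance(delta_spec, LinearDelta):
        raise TypeError("delta_spec must be a FixedDelta or LinearDelta instance")

    d = _resolve(delta_spec.design, data)
    cc = data.r == 1
    k = d.shape[1]
    if cc.sum() < k:
        raise ValueError(f"fewer complete cases ({cc.sum()}) than outcome-model "
                         f"parameters ({k})")
    omega = 1.0 / nuis.pi_hat if weighted else np.ones(data.n)
    sw = np.sqrt(omega[cc])
    sol, _, rank, _ = np.linalg.lstsq(d[cc] * sw[:, None], data.y[cc] * sw, rcond=None)
    if rank < k:
        names = delta_spec.names or [f"col{j}" for j in range(k)]
        raise ValueError(f"outcome-model design rank deficient among complete "
                         f"cases (rank {rank} < {k}); columns {names}")
    eta = sol
    delta = d @ eta
    resid = np.where(cc, data.y_filled - delta, 0.0)
    score_eta = (data.r * omega * resid)[:, None] * d
    info_eta = -(d * (data.r * omega)[:, None]).T @ d / data.n
    nuis.delta_hat = delta
    nuis.delta_fixed = False
    nuis.eta_hat = eta
    nuis.delta_design = d
    nuis.eta_weights = omega
    nuis.score_eta = score_eta
    nuis.info_eta = info_eta
    return nuis


# ---------------------------------------------------------------------------
# working variance
# ---------------------------------------------------------------------------


def fit_working_variance(data: ObservedData, nuis: NuisanceFit, q_hat: np.ndarray,
                         variance_spec: str = "constant",
                         estimator: str = "aipw",
                         lp: Optional[np.ndarray] = None) -> NuisanceFit:
    """Estimate zeta in the working variance V(X,Z; zeta).

    For the AIPW branch the regressand is the squared per-unit AIPW residual
    S_i = {R_i/pi_i (Y_i - Q_i) - (R_i/pi_i - 1)(delta_i - Q_i)}^2 with Q_i
    from the current fit; for IPW it is S~_i = R_i/pi_i (Y_i - Q_i)^2; for
    the naive branch the complete-case squared residual.  zeta-hat solves the
    nonlinear least squares of S_i on the variance family.
    """
    q_hat = np.asarray(q_hat, dtype=float).ravel()
    rp = data.r / nuis.pi_hat
    resid = data.y_filled - q_hat
    if estimator == "aipw":
        if nuis.delta_hat is None:
            raise ValueError("AIPW working variance needs delta_hat")
        s = (rp * resid - (rp - 1.0) * (nuis.delta_hat - q_hat)) ** 2
        wts = np.ones(data.n)
    elif estimator == "ipw":
        s = rp * resid ** 2
        wts = np.ones(data.n)
    elif estimator == "naive":
        s = resid ** 2
        wts = data.r.astype(float)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")

    if variance_spec == "constant":
        zeta = np.array([float(np.sum(wts * s) / np.sum(wts))])
    elif variance_spec == "loglinear":
        if lp is None:
            lp = q_hat
        z0 = np.log(max(np.sum(wts * s) / np.sum(wts), 1e-8))
        res = least_squares(
            lambda zz: np.sqrt(wts) * (s - np.exp(np.clip(zz[0] + zz[1] * lp, -30, 30))),
            x0=np.array([z0, 0.0]), method="lm", max_nfev=2000)
        if not res.success:
            raise RuntimeError(f"working-variance NLS did not converge: {res.message}")
        zeta = res.x
    else:
        raise ValueError(f"unknown variance_spec {variance_spec!r}")

    nuis.zeta_hat = zeta
    nuis.variance_spec = variance_spec
    v = nuis.v_of(lp if lp is not None else q_hat)
    if np.any(v <= 0):
        raise RuntimeError("fitted working variance is nonpositive somewhere")
    nuis.v_values = v
    return nuis


# ---------------------------------------------------------------------------
# initial estimator
# ---------------------------------------------------------------------------


def initial_fit(data: ObservedData, nuis: NuisanceFit, config: FitConfig,
                h: float) -> tuple:
    """Root-n-consistent starting values (beta-check, theta-check at Z_i).

    Runs the inverse-probability-weighted kernel-profile loop with the
    working variance frozen at a user-specified constant (default 1) for a
    small fixed number of sweeps (default 2), no variance update.  The naive
    branch uses unweighted complete cases instead.
    """
    from . import beta_profile, theta_kernel  # local import: avoids a cycle

    est = "naive" if config.estimator == "naive" else "ipw"
    init_nuis = NuisanceFit(pi_hat=nuis.pi_hat, pi_known=True,
                            zeta_hat=np.array([float(config.init_zeta)]),
                            variance_spec="constant")
    init_cfg = FitConfig(
        estimator=est, link=config.link, kernel=config.kernel, bandwidth=h,
        variance_spec="constant", tol=config.tol, local_tol=config.local_tol,
        max_local_iter=config.max_local_iter, force_iterative=config.force_iterative,
        eta_clamp=config.eta_clamp, pi_floor=0.0)
    beta = np.zeros(data.p)
    link = config.link_obj
    for _ in range(max(1, config.init_sweeps)):
        beta_new = beta_profile.solve_beta(data, init_nuis, beta, h, init_cfg)
        if link.name == "identity":
            beta = beta_new
            break  # exact profile solve: further sweeps are identical
        if np.max(np.abs(beta_new - beta)) <= config.tol:
            beta = beta_new
            break
        beta = beta_new
    curve = theta_kernel.theta_curve(data, init_nuis, beta, data.z, h, init_cfg,
                                     compute_phi=False)
    return beta, curve.alpha0
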