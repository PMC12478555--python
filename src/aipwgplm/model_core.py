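"""Core domain types shared by every estimation stage.

The model throughout is the generalized partially linear model (GPLM)

    E(Y | X, Z) = mu(X' beta + theta(Z)),

with a known monotone link ``mu``, a parametric index ``X' beta`` and an
unknown smooth function ``theta`` of a scalar covariate ``Z``.  The outcome
``Y`` may be missing (missing at random given ``(X, Z, U)`` where ``U`` are
auxiliary covariates); ``R`` is the response indicator.

This module holds the data container, link and kernel objects and the fit
configuration.  The estimating-equation machinery lives in
:mod:`aipwgplm.theta_kernel` and :mod:`aipwgplm.beta_profile`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
from scipy.special import expit

logger = logging.getLogger("aipwgplm")

__all__ = [
    "ObservedData",
    "LinkFunction",
    "KernelFunction",
    "FitConfig",
    "get_link",
    "get_kernel",
    "eval_linear_predictor",
    "kernel_weights",
]


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------


@dataclass
class ObservedData:
    """One study's (Y, R, X, Z, U) with missing-outcome bookkeeping.

    Parameters
    ----------
    y : array of shape (n,)
        Outcome; only meaningful where ``r == 1``.  Entries with ``r == 0``
        may be NaN.
    r : array of shape (n,)
        Response indicator, 1 = outcome observed.
    x : array of shape (n, p) or (n,)
        Primary covariates entering the parametric index.
    z : array of shape (n,)
        Scalar smoothing covariate.
    u : array of shape (n, q) or (n,), optional
        Auxiliary covariates; needed for the MAR assumption and usable for
        efficiency.  May be empty.
    """

    y: np.ndarray
    r: np.ndarray
    x: np.ndarray
    z: np.ndarray
    u: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.r = np.asarray(self.r).ravel().astype(int)
        x = np.asarray(self.x, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        self.x = x
        self.z = np.asarray(self.z, dtype=float).ravel()
        if self.u is None:
            self.u = np.empty((len(self.y), 0))
        else:
            u = np.asarray(self.u, dtype=float)
            if u.ndim == 1:
                u = u[:, None]
            self.u = u
        n = len(self.y)
        if not (len(self.r) == n == self.x.shape[0] == len(self.z) == self.u.shape[0]):
            raise ValueError("y, r, x, z, u must share the same number of rows")
        if not np.isin(self.r, (0, 1)).all():
            raise ValueError("r must be binary (0/1)")
        if not np.isfinite(self.y[self.r == 1]).all():
            bad = np.nonzero((self.r == 1) & ~np.isfinite(self.y))[0]
            raise ValueError(f"y must be finite wherever r=1; offending rows {bad[:10]}")
        if n < self.x.shape[1] + 2:
            raise ValueError("need n >= p + 2 observations")
        if np.unique(self.z).size < 2:
            raise ValueError("z must take at least 2 distinct values")
        if not np.isfinite(self.x).all() or not np.isfinite(self.z).all():
            raise ValueError("x and z must be finite")

    # -- convenience -------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.x.shape[1]

    @property
    def n_complete(self) -> int:
        return int(self.r.sum())

    @property
    def missing_fraction(self) -> float:
        return 1.0 - self.r.mean()

    @property
    def y_filled(self) -> np.ndarray:
        """Outcome with missing entries replaced by 0 (always multiplied by R)."""
        return np.where(self.r == 1, np.nan_to_num(self.y), 0.0)


# ---------------------------------------------------------------------------
# link functions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LinkFunction:
    """Known monotone link mu with first/second derivatives.

    The linear predictor is clamped to ``|eta| <= clamp`` for the logit and
    log links to avoid overflow; clamping events are logged at DEBUG level.
    """

    name: str
    mu: Callable[[np.ndarray], np.ndarray]
    mu1: Callable[[np.ndarray], np.ndarray]
    mu2: Callable[[np.ndarray], np.ndarray]
    clamp: float = 30.0


def _clip_eta(eta: np.ndarray, clamp: float, name: str) -> np.ndarray:
    eta = np.asarray(eta, dtype=float)
    n_out = int(np.count_nonzero(np.abs(eta) > clamp))
    if n_out:
        logger.debug("%s link: clamped %d linear-predictor values to |eta|<=%g", name, n_out, clamp)
    return np.clip(eta, -clamp, clamp)


def get_link(name: str, clamp: float = 30.0) -> LinkFunction:
    """Return one of the shipped links: identity, logit, log."""
    if isinstance(name, LinkFunction):
        return name
    name = name.lower()
    if name == "identity":
        return LinkFunction(
            "identity",
            mu=lambda eta: np.asarray(eta, dtype=float),
            mu1=lambda eta: np.ones_like(np.asarray(eta, dtype=float)),
            mu2=lambda eta: np.zeros_like(np.asarray(eta, dtype=float)),
            clamp=np.inf,
        )
    if name == "logit":
        def mu(eta, clamp=clamp):
            return expit(_clip_eta(eta, clamp, "logit"))

        def mu1(eta, clamp=clamp):
            m = expit(_clip_eta(eta, clamp, "logit"))
            return m * (1.0 - m)

        def mu2(eta, clamp=clamp):
            m = expit(_clip_eta(eta, clamp, "logit"))
            return m * (1.0 - m) * (1.0 - 2.0 * m)

        return LinkFunction("logit", mu, mu1, mu2, clamp)
    if name == "log":
        def mu(eta, clamp=clamp):
            return np.exp(_clip_eta(eta, clamp, "log"))

        return LinkFunction("log", mu, mu, mu, clamp)
    raise ValueError(f"unsupported link {name!r}; choose identity, logit or log")


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KernelFunction:
    """Symmetric mean-zero density K with its variance constants.

    ``c0`` is c0(K^2) = int K(s)^2 ds and ``c2`` is c2(K) = int s^2 K(s) ds,
    the constants entering the asymptotic variance and bias of the local
    linear estimator.  ``support`` is the half-width of the support (inf for
    the Gaussian kernel).
    """

    name: str
    k: Callable[[np.ndarray], np.ndarray]
    c0: float
    c2: float
    support: float


def get_kernel(name: str) -> KernelFunction:
    if isinstance(name, KernelFunction):
        return name
    name = name.lower()
    if name == "epanechnikov":
        def k(s):
            s = np.asarray(s, dtype=float)
            return 0.75 * np.clip(1.0 - s * s, 0.0, None)

        return KernelFunction("epanechnikov", k, c0=0.6, c2=0.2, support=1.0)
    if name == "gaussian":
        def k(s):
            s = np.asarray(s, dtype=float)
            return np.exp(-0.5 * s * s) / np.sqrt(2.0 * np.pi)

        return KernelFunction("gaussian", k, c0=1.0 / (2.0 * np.sqrt(np.pi)), c2=1.0,
                              support=np.inf)
    raise ValueError(f"unsupported kernel {name!r}; choose epanechnikov or gaussian")


# ---------------------------------------------------------------------------
# basic operations
# ---------------------------------------------------------------------------


def eval_linear_predictor(x_row: np.ndarray, beta: np.ndarray, theta_at_z: float) -> float:
    """Linear predictor eta = x' beta + theta(z), no link applied."""
    x_row = np.asarray(x_row, dtype=float).ravel()
    beta = np.asarray(beta, dtype=float).ravel()
    if x_row.shape != beta.shape:
        raise ValueError(f"dimension mismatch: x has {x_row.size}, beta has {beta.size}")
    return float(x_row @ beta + theta_at_z)


def kernel_weights(z_obs: np.ndarray, z0: float, h: float,
                   kernel: Union[str, KernelFunction] = "epanechnikov") -> np.ndarray:
    """Local weights w_i = K_h(z_i - z0) = K((z_i - z0)/h)/h."""
    if h <= 0:
        raise ValueError("bandwidth h must be positive")
    kernel = get_kernel(kernel)
    z_obs = np.asarray(z_obs, dtype=float)
    return kernel.k((z_obs - z0) / h) / h


# ---------------------------------------------------------------------------
# fit configuration
# ---------------------------------------------------------------------------


@dataclass
class FitConfig:
    """Configuration for :func:`aipwgplm.beta_profile.fit_gplm`.

    Parameters of note
    ------------------
    estimator : {"naive", "ipw", "aipw"}
        Which estimating-equation branch to solve.  ``naive`` uses the
        unweighted complete cases, ``ipw`` weights complete cases by 1/pi,
        ``aipw`` adds the augmentation term built from delta(X,Z,U).
    bandwidth : float or "ebbs"
        Kernel bandwidth on the Z scale, or "ebbs" for empirical-bias
        bandwidth selection.
    pi_spec, delta_spec
        Nuisance model specifications (see :mod:`aipwgplm.nuisance`).
    variance_spec : {"constant", "loglinear"}
        Working-variance family V(X,Z; zeta).  Affects efficiency weighting
        only, never consistency.
    pi_floor : float
        Fitted selection probabilities below this are truncated (with a
        logged count); known-by-design probabilities are never truncated.
    """

    estimator: str = "aipw"
    link: Union[str, LinkFunction] = "identity"
    kernel: Union[str, KernelFunction] = "epanechnikov"
    bandwidth: Union[float, str] = "ebbs"
    pi_spec: object = None
    delta_spec: object = None
    variance_spec: str = "constant"
    weighted_eta: bool = False
    max_outer_iter: int = 50
    tol: float = 1e-6
    local_tol: float = 1e-8
    max_local_iter: int = 50
    pi_floor: float = 0.01
    init_sweeps: int = 2
    init_zeta: float = 1.0
    refresh_zeta: bool = False
    force_iterative: bool = False
    eta_clamp: float = 30.0
    grid_points: int = 101

    def __post_init__(self) -> None:
        if self.estimator not in ("naive", "ipw", "aipw"):
            raise ValueError("estimator must be naive, ipw or aipw")
        if self.tol <= 0 or self.local_tol <= 0:
            raise ValueError("tolerances must be positive")
        if isinstance(self.bandwidth, str):
            if self.bandwidth != "ebbs":
                raise ValueError("bandwidth must be a positive number or 'ebbs'")
        elif self.bandwidth <= 0:
            raise ValueError("bandwidth must be a positive number or 'ebbs'")
        if not (0.0 <= self.pi_floor < 0.5):
            raise ValueError("pi_floor must lie in [0, 0.5)")

    @property
    def link_obj(self) -> LinkFunction:
        return get_link(self.link, self.eta_clamp)

    @property
    def kernel_obj(self) -> KernelFunction:
        return get_kernel(self.kernel)
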