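"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from aipwgplm import ObservedData, get_kernel


def make_complete_data(n=200, seed=0, p=1, theta=None, sigma=0.5,
                       beta=None):
    """Fully observed identity-link dataset Y = X beta + theta(Z) + noise."""
    rng = np.random.default_rng(seed)
    z = rng.uniform(0.0, 1.0, n)
    x = rng.normal(0.0, 1.0, (n, p))
    if beta is None:
        beta = np.arange(1, p + 1, dtype=float)
    th = theta(z) if theta is not None else np.sin(2 * np.pi * z)
    y = x @ beta + th + sigma * rng.normal(size=n)
    return ObservedData(y=y, r=np.ones(n, dtype=int), x=x, z=z,
                        u=rng.normal(size=n)), beta


def local_linear_smoother(z_obs, z_eval, h, weights=None, kernel="epanechnikov"):
    """Brute-force local-linear smoother rows (independent oracle).

    Returns the matrix S with S[j] the weights such that the local-linear
    fit at z_eval[j] is S[j] @ y.
    """
    k = get_kernel(kernel)
    z_obs = np.asarray(z_obs, float)
    z_eval = np.atleast_1d(np.asarray(z_eval, float))
    n = z_obs.size
    if weights is None:
        weights = np.ones(n)
    rows = np.zeros((z_eval.size, n))
    for j, z0 in enumerate(z_eval):
        d = z_obs - z0
        w = k.k(d / h) / h * weights
        g = np.column_stack([np.ones(n), d])
        gtw = g.T * w
        m = gtw @ g
        sol = np.linalg.solve(m, gtw)
        rows[j] = sol[0]
    return rows


def profile_ls_oracle(data, h, weights=None, kernel="epanechnikov"):
    """Brute-force profile (partially linear) least squares.

    Smooth X and Y with the local-linear smoother at the observed Z, then
    regress the Y residual on the X residual, with optional unit weights.
    """
    n = data.n
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    s = local_linear_smoother(data.z, data.z, h, weights=w, kernel=kernel)
    xc = data.x - s @ data.x
    yc = data.y - s @ data.y
    wx = xc * w[:, None]
    beta = np.linalg.solve(wx.T @ xc, wx.T @ yc)
    return beta, xc, yc


@pytest.fixture(scope="session")
def complete_data():
    return make_complete_data(n=250, seed=42)
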