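"""Independent oracles for the test suite.

These deliberately avoid the package's analytic/exact sampling routes:
first-passage times come from discretized Euler path simulation (with a
Brownian-bridge crossing correction for the overshoot bias), convolutions
from brute-force trapezoid integration, and OLS from the raw normal
equations.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def euler_first_passage(v: float, eta: float, a: float, n_paths: int,
                        dt: float, t_max: float, seed: int) -> np.ndarray:
    """First-passage times by Euler-discretized diffusion paths.

    Each path draws its trial drift from Normal(v, eta^2), then steps
    ``x += u*dt + sqrt(dt)*N(0,1)`` until absorption at ``a`` or ``t_max``.
    Between steps, a Brownian-bridge correction absorbs paths that crossed
    and returned within the step (probability exp(-2(a-x0)(a-x1)/dt);
    conditioned on its endpoints a drifted Brownian path is a driftless
    bridge, so this is exact), removing the O(sqrt(dt)) overshoot bias.
    The crossing time is reported uniformly within the step, which both
    removes the systematic +dt/2 shift of end-of-step reporting and
    de-aliases the dt-grid against histogram bin edges.  Returns inf for
    paths not absorbed by ``t_max``.
    """
    np.random.seed(seed)
    sqdt = math.sqrt(dt)
    n_steps = int(t_max / dt)
    out = np.empty(n_paths)
    for p in range(n_paths):
        u = v + eta * np.random.standard_normal()
        x = 0.0
        t_hit = np.inf
        for k in range(n_steps):
            x_new = x + u * dt + sqdt * np.random.standard_normal()
            if x_new >= a:
                t_hit = (k + np.random.random()) * dt
                break
            # bridge: crossing within the step despite both endpoints below a
            p_cross = math.exp(-2.0 * (a - x) * (a - x_new) / dt)
            if np.random.random() < p_cross:
                t_hit = (k + np.random.random()) * dt
                break
            x = x_new
        out[p] = t_hit
    return out


def brute_force_uniform_convolution(t_grid: np.ndarray, density, ter: float,
                                    st: float, n_points: int = 100_000) -> np.ndarray:
    """Convolve ``density`` with Uniform(ter-st/2, ter+st/2) by trapezoid rule."""
    w = np.linspace(ter - st / 2, ter + st / 2, n_points)
    out = np.empty_like(t_grid, dtype=float)
    for i, t in enumerate(t_grid):
        out[i] = np.trapezoid(density(t - w), w) / st
    return out


def normal_equations_ols(X: np.ndarray, y: np.ndarray):
    """(beta, se, t, p) straight from the normal equations."""
    from scipy import stats

    n, k = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (n - k)
    se = np.sqrt(np.diag(sigma2 * xtx_inv))
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), n - k)
    return beta, se, t, p
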