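"""Numba-compiled censored log-likelihood kernel for the one-choice DDM.

This is a performance twin of the numpy route in :mod:`vigilpred.ddm`
(`rt_density` + `censored_loglik`): same densities, same Gauss-Legendre
convolution over the uniform non-decision window, same closed-form survival
term.  A test asserts agreement with the numpy implementation to 1e-8; the
optimizer in ``fit_day`` calls this kernel.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

SQRT2 = math.sqrt(2.0)
SQRT2PI = math.sqrt(2.0 * math.pi)
_NEG_INF_PENALTY = -1e12


@njit(cache=True, fastmath=True)
def _ndtr(x: float) -> float:
    return 0.5 * math.erfc(-x / SQRT2)


@njit(cache=True, fastmath=True)
def _log_ndtr(x: float) -> float:
    # asymptotic expansion for the deep lower tail, where erfc underflows
    if x < -20.0:
        z = x * x
        return -0.5 * z - math.log(-x * SQRT2PI) + math.log1p(
            -1.0 / z + 3.0 / (z * z))
    return math.log(0.5 * math.erfc(-x / SQRT2))


@njit(cache=True, fastmath=True)
def _decision_density(t: float, v: float, eta: float, a: float) -> float:
    if t <= 0.0:
        return 0.0
    s2 = t * (1.0 + eta * eta * t)
    return a / (SQRT2PI * math.sqrt(t * t * s2)) * math.exp(
        -(a - v * t) * (a - v * t) / (2.0 * s2))


@njit(cache=True, fastmath=True)
def _decision_cdf(t: float, v: float, eta: float, a: float) -> float:
    if t <= 0.0:
        return 0.0
    s = math.sqrt(t * (1.0 + eta * eta * t))
    term1 = _ndtr((v * t - a) / s)
    log_term2 = 2.0 * v * a + 2.0 * (eta * a) ** 2 + _log_ndtr(
        -(v * t + a + 2.0 * eta * eta * a * t) / s)
    out = term1 + math.exp(log_term2)
    if out < 0.0:
        return 0.0
    if out > 1.0:
        return 1.0
    return out


@njit(cache=True, fastmath=True)
def _unpack_kernel(x: np.ndarray, fix_a: float):
    """Unconstrained vector -> (v, eta, a, ter, st, p_c); fix_a <= 0 frees a."""
    j = 0
    v = math.exp(min(x[j], 50.0)); j += 1
    eta = math.exp(min(x[j], 50.0)); j += 1
    if fix_a > 0.0:
        a = fix_a
    else:
        a = math.exp(min(x[j], 50.0)); j += 1
    lo = 0.05 + math.exp(min(x[j], 50.0)); j += 1
    st = math.exp(min(x[j], 50.0)); j += 1
    z = x[j]
    if z > 50.0:
        z = 50.0
    elif z < -50.0:
        z = -50.0
    p_c = 0.10 / (1.0 + math.exp(-z))
    return v, eta, a, lo + st / 2.0, st, p_c


@njit(cache=True, fastmath=True)
def _neg_mean_loglik(x: np.ndarray, obs: np.ndarray, n_timeouts: int,
                     deadline: float, gl_x: np.ndarray, gl_w: np.ndarray,
                     fix_a: float) -> float:
    v, eta, a, ter, st, p_c = _unpack_kernel(x, fix_a)
    ll = censored_loglik_kernel(obs, n_timeouts, v, eta, a, ter, st, p_c,
                                deadline, gl_x, gl_w)
    return -ll / (obs.shape[0] + n_timeouts)


@njit(cache=True, fastmath=True)
def nelder_mead(x0: np.ndarray, obs: np.ndarray, n_timeouts: int,
                deadline: float, gl_x: np.ndarray, gl_w: np.ndarray,
                fix_a: float, xatol: float, fatol: float, maxiter: int):
    """Adaptive Nelder-Mead on the transformed censored log-likelihood.

    Mirrors the classic simplex updates (reflect / expand / contract /
    shrink) with dimension-adaptive coefficients; returns
    (x_best, f_best, converged flag).
    """
    n = x0.shape[0]
    alpha = 1.0
    gamma = 1.0 + 2.0 / n
    rho = 0.75 - 1.0 / (2.0 * n)
    sigma = 1.0 - 1.0 / n

    simplex = np.empty((n + 1, n))
    fvals = np.empty(n + 1)
    simplex[0] = x0
    fvals[0] = _neg_mean_loglik(x0, obs, n_timeouts, deadline, gl_x, gl_w, fix_a)
    for i in range(n):
        xi = x0.copy()
        if xi[i] != 0.0:
            xi[i] *= 1.05
        else:
            xi[i] = 0.00025
        simplex[i + 1] = xi
        fvals[i + 1] = _neg_mean_loglik(xi, obs, n_timeouts, deadline,
                                        gl_x, gl_w, fix_a)

    converged = False
    for _ in range(maxiter):
        order = np.argsort(fvals)
        simplex = simplex[order]
        fvals = fvals[order]
        # convergence: simplex collapsed in both x and f
        xspread = 0.0
        fspread = 0.0
        for i in range(1, n + 1):
            fs = abs(fvals[i] - fvals[0])
            if fs > fspread:
                fspread = fs
            for j in range(n):
                xs = abs(simplex[i, j] - simplex[0, j])
                if xs > xspread:
                    xspread = xs
        if xspread <= xatol and fspread <= fatol:
            converged = True
            break

        centroid = np.zeros(n)
        for i in range(n):
            centroid += simplex[i]
        centroid /= n

        xr = centroid + alpha * (centroid - simplex[n])
        fr = _neg_mean_loglik(xr, obs, n_timeouts, deadline, gl_x, gl_w, fix_a)
        if fr < fvals[0]:
            xe = centroid + gamma * (xr - centroid)
            fe = _neg_mean_loglik(xe, obs, n_timeouts, deadline, gl_x, gl_w, fix_a)
            if fe < fr:
                simplex[n] = xe
                fvals[n] = fe
            else:
                simplex[n] = xr
                fvals[n] = fr
        elif fr < fvals[n - 1]:
            simplex[n] = xr
            fvals[n] = fr
        else:
            if fr < fvals[n]:
                xc = centroid + rho * (xr - centroid)
            else:
                xc = centroid + rho * (simplex[n] - centroid)
            fc = _neg_mean_loglik(xc, obs, n_timeouts, deadline, gl_x, gl_w, fix_a)
            if fc < min(fr, fvals[n]):
                simplex[n] = xc
                fvals[n] = fc
            else:
                for i in range(1, n + 1):
                    simplex[i] = simplex[0] + sigma * (simplex[i] - simplex[0])
                    fvals[i] = _neg_mean_loglik(simplex[i], obs, n_timeouts,
                                                deadline, gl_x, gl_w, fix_a)
    best = int(np.argmin(fvals))
    return simplex[best], fvals[best], converged


@njit(cache=True, fastmath=True)
def censored_loglik_kernel(obs: np.ndarray, n_timeouts: int,
                           v: float, eta: float, a: float,
                           ter: float, st: float, p_c: float,
                           deadline: float,
                           gl_x: np.ndarray, gl_w: np.ndarray) -> float:
    """Censored log-likelihood; ``gl_x``/``gl_w`` are Gauss-Legendre nodes and
    weights on [-1, 1] (weights summing to 2)."""
    n_nodes = gl_x.shape[0]
    ll = 0.0
    contam = p_c / deadline
    for i in range(obs.shape[0]):
        t = obs[i]
        if st > 0.0:
            f = 0.0
            for k in range(n_nodes):
                w_node = ter + 0.5 * st * gl_x[k]
                f += 0.5 * gl_w[k] * _decision_density(t - w_node, v, eta, a)
        else:
            f = _decision_density(t - ter, v, eta, a)
        dens = (1.0 - p_c) * f + contam
        if dens <= 0.0:
            return _NEG_INF_PENALTY
        ll += math.log(dens)
    if n_timeouts > 0:
        if st > 0.0:
            cdf = 0.0
            for k in range(n_nodes):
                w_node = ter + 0.5 * st * gl_x[k]
                cdf += 0.5 * gl_w[k] * _decision_cdf(deadline - w_node, v, eta, a)
        else:
            cdf = _decision_cdf(deadline - ter, v, eta, a)
        surv = 1.0 - ((1.0 - p_c) * cdf + p_c)
        if surv <= 0.0:
            surv = 1e-300
        ll += n_timeouts * math.log(surv)
    if not math.isfinite(ll):
        return _NEG_INF_PENALTY
    return ll
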