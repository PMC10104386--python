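"""One-choice drift-diffusion model for PVT reaction times.

A single evidence accumulator starts at 0 and drifts toward an absorbing
boundary ``a`` with within-trial Wiener noise (diffusion coefficient fixed at
1, the scaling convention; the common sigma = 0.1 convention differs only by
the reparameterization v -> v/0.1, a -> a/0.1).  The first-passage time of a
positive-drift trial is Wald (inverse-Gaussian) distributed.  Across trials
the drift is Normal(v, eta^2), which produces the heavy slow tail — lapses —
seen in vigilance data; marginalizing the Wald density over that Normal has
the closed form implemented in :func:`decision_density`.  The observed RT
adds a non-decision time drawn uniformly from ``[ter - st/2, ter + st/2]``
(motor/encoding latency), and a small uniform contaminant with mixing weight
``p_c`` absorbs anticipations and other off-model responses.  Responses
slower than the 10-s deadline are censored (timeouts) and contribute a
survival term to the likelihood.

The two quantities of scientific interest for baseline prediction are the
mean drift rate ``v`` (speed of information accumulation) and the
non-decision time range ``st`` (within-subject variation in non-cognitive
responding); ``a``, ``eta`` and ``p_c`` are nuisance parameters.

All times inside this module are seconds; conversion from milliseconds
happens at the module boundary (:func:`baseline_ddm_table`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import log_ndtr, ndtr

__all__ = [
    "DDMParams",
    "FitOptions",
    "wald_density",
    "decision_density",
    "decision_cdf",
    "rt_density",
    "rt_cdf_model",
    "censored_loglik",
    "fit_day",
    "baseline_ddm_table",
]

DEADLINE_S = 10.0
#: hard lower bound for the earliest possible non-decision time (s)
MIN_TER_EDGE = 0.05
#: cap on the contaminant proportion, so the uniform component cannot absorb
#: the slow tail that drift variability should explain
PC_MAX = 0.10

_NEG_INF_PENALTY = -1e12


@dataclass
class DDMParams:
    """Fitted one-choice DDM parameters plus fit diagnostics."""

    v: float
    eta: float
    a: float
    ter_s: float
    st_s: float
    p_c: float
    loglik: float = float("nan")
    n_trials_fit: int = 0
    converged: bool = False
    n_restarts_used: int = 0

    def validate(self) -> None:
        if not (self.a > 0):
            raise ValueError("boundary a must be positive")
        if self.eta < 0 or self.st_s < 0:
            raise ValueError("eta and st_s must be non-negative")
        if self.ter_s - self.st_s / 2 < MIN_TER_EDGE - 1e-12:
            raise ValueError("non-decision window extends below the minimum edge")
        if not (0.0 <= self.p_c <= PC_MAX):
            raise ValueError(f"p_c must lie in [0, {PC_MAX}]")

    def as_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# densities

def wald_density(t, u, a):
    """First-passage density of a drift-``u`` diffusion at boundary ``a``.

    f(t) = a * (2 pi t^3)^(-1/2) * exp(-(a - u t)^2 / (2 t))

    Defined for any real drift (defective for u <= 0).  Returns 0 for t <= 0
    by convention.  Vectorized over ``t``.
    """
    if np.any(np.asarray(a) <= 0):
        raise ValueError("boundary a must be positive")
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    out[pos] = a / np.sqrt(2.0 * np.pi * tp**3) * np.exp(-((a - u * tp) ** 2) / (2.0 * tp))
    if out.ndim == 0:
        return float(out)
    return out


def decision_density(t, v, eta, a):
    """Wald density marginalized over across-trial Normal(v, eta^2) drift.

    f(t) = a * (2 pi t^3 (1 + eta^2 t))^(-1/2)
             * exp(-(a - v t)^2 / (2 t (1 + eta^2 t)))

    Reduces to :func:`wald_density` at eta = 0.  Defective when eta > 0 (the
    never-absorbed mass of non-positive sampled drifts); the deficit is the
    timeout probability before censoring.
    """
    if np.any(np.asarray(a) <= 0):
        raise ValueError("boundary a must be positive")
    if np.any(np.asarray(eta) < 0):
        raise ValueError("eta must be non-negative")
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    s2 = tp * (1.0 + eta * eta * tp)
    out[pos] = a / np.sqrt(2.0 * np.pi * tp * tp * s2) * np.exp(-((a - v * tp) ** 2) / (2.0 * s2))
    if out.ndim == 0:
        return float(out)
    return out


def decision_cdf(t, v, eta, a):
    """Closed-form CDF of :func:`decision_density`.

    Integrating the inverse-Gaussian CDF against the Normal drift law gives

        F(t) = Phi((v t - a)/s) + exp(2 v a + 2 eta^2 a^2)
                 * Phi(-(v t + a + 2 eta^2 a t)/s),      s^2 = t (1 + eta^2 t)

    which at eta = 0 is the familiar Wald CDF.  The exponential factor can be
    astronomically large while its Phi factor underflows, so the second term
    is evaluated on the log scale.
    """
    if np.any(np.asarray(a) <= 0):
        raise ValueError("boundary a must be positive")
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    s = np.sqrt(tp * (1.0 + eta * eta * tp))
    term1 = ndtr((v * tp - a) / s)
    log_term2 = 2.0 * v * a + 2.0 * (eta * a) ** 2 + log_ndtr(-(v * tp + a + 2.0 * eta * eta * a * tp) / s)
    out[pos] = term1 + np.exp(log_term2)
    if out.ndim == 0:
        return float(np.clip(out, 0.0, 1.0))
    return np.clip(out, 0.0, 1.0)


def _gauss_legendre_nodes(ter: float, st: float, n_nodes: int):
    """Nodes/weights for averaging over the uniform non-decision window."""
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    nodes = ter + 0.5 * st * x
    weights = 0.5 * w  # integrates to 1 over [-1, 1] scaled: mean, not sum
    return nodes, weights


def rt_density(t, params: DDMParams, deadline_s: float = DEADLINE_S,
               n_nodes: int = 11):
    """Observed-RT density: decision density convolved with the uniform
    non-decision time, mixed with a uniform contaminant on (0, deadline].

    The convolution integral (an average of ``decision_density(t - w)`` over
    w ~ Uniform(ter - st/2, ter + st/2)) is computed by ``n_nodes``-point
    Gauss-Legendre quadrature; st = 0 short-circuits to the shifted density.
    """
    params.validate()
    if not np.all(np.isfinite([params.v, params.eta, params.a,
                               params.ter_s, params.st_s, params.p_c])):
        raise ValueError("non-finite DDM parameters")
    scalar_in = np.ndim(t) == 0
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if params.st_s <= 0:
        f_model = decision_density(t - params.ter_s, params.v, params.eta, params.a)
        f_model = np.atleast_1d(f_model)
    else:
        nodes, weights = _gauss_legendre_nodes(params.ter_s, params.st_s, n_nodes)
        f_model = np.zeros_like(t)
        for w_node, w_wt in zip(nodes, weights):
            f_model += w_wt * np.atleast_1d(
                decision_density(t - w_node, params.v, params.eta, params.a))
    out = (1.0 - params.p_c) * f_model
    in_window = (t > 0) & (t <= deadline_s)
    out[in_window] += params.p_c / deadline_s
    out[t <= 0] = 0.0
    return float(out[0]) if scalar_in else out


def rt_cdf_model(t, params: DDMParams, n_nodes: int = 11):
    """CDF of the model (non-contaminant) RT component, via the closed-form
    decision CDF averaged over the non-decision window."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if params.st_s <= 0:
        return np.atleast_1d(decision_cdf(t - params.ter_s, params.v, params.eta, params.a))
    nodes, weights = _gauss_legendre_nodes(params.ter_s, params.st_s, n_nodes)
    out = np.zeros_like(t)
    for w_node, w_wt in zip(nodes, weights):
        out += w_wt * np.atleast_1d(decision_cdf(t - w_node, params.v, params.eta, params.a))
    return out


def response_prob(params: DDMParams, deadline_s: float = DEADLINE_S,
                  n_nodes: int = 11) -> float:
    """P(observed response before the deadline) under the full mixture."""
    f_cdf = float(rt_cdf_model(np.array([deadline_s]), params, n_nodes)[0])
    return (1.0 - params.p_c) * f_cdf + params.p_c


def censored_loglik(rts: Sequence[tuple[float, bool]] | np.ndarray,
                    params: DDMParams, deadline_s: float = DEADLINE_S,
                    n_nodes: int = 11) -> float:
    """Censored log-likelihood of observed RTs plus timeout survival terms.

    ``rts`` is a sequence of ``(rt_s, timeout)`` pairs (false starts must be
    excluded upstream).  Observed trials contribute ``log rt_density(rt)``;
    timeouts contribute ``log S(deadline)`` with S = 1 - P(response).
    Impossible parameter/data combinations (zero density with p_c = 0) return
    a large negative sentinel rather than -inf so optimizers can recover.
    """
    arr = np.asarray([(float(r), bool(to)) for r, to in rts], dtype=object)
    if arr.size == 0:
        raise ValueError("censored_loglik requires at least one trial")
    rt_vals = np.array([r for r, to in rts], dtype=float)
    to_mask = np.array([to for r, to in rts], dtype=bool)
    obs = rt_vals[~to_mask]
    if np.any((obs <= 0) | (obs > deadline_s)):
        raise ValueError("observed RTs must lie in (0, deadline]")
    return _loglik_arrays(obs, int(to_mask.sum()), params, deadline_s, n_nodes)


def _loglik_arrays(obs_rt_s: np.ndarray, n_timeouts: int, params: DDMParams,
                   deadline_s: float = DEADLINE_S, n_nodes: int = 11) -> float:
    dens = rt_density(obs_rt_s, params, deadline_s, n_nodes) if obs_rt_s.size else np.array([])
    if obs_rt_s.size and np.any(dens <= 0):
        return _NEG_INF_PENALTY
    ll = float(np.sum(np.log(dens))) if obs_rt_s.size else 0.0
    if n_timeouts:
        surv = 1.0 - response_prob(params, deadline_s, n_nodes)
        if surv <= 0:
            surv = 1e-300
        ll += n_timeouts * math.log(surv)
    if not np.isfinite(ll):
        return _NEG_INF_PENALTY
    return ll


# ---------------------------------------------------------------------------
# fitting

@dataclass
class FitOptions:
    """Options for :func:`fit_day`."""

    method: str = "mle"  # "mle" or "quantile_chisq"
    min_trials: int = 100
    restarts: int = 8
    seed: int = 0
    #: boundary anchoring: the (v, eta, a) scale direction of the one-choice
    #: likelihood is nearly flat at single-day sample sizes, so by default the
    #: boundary is fixed (drift in boundary units/s); None frees it.
    fix_a: float | None = 1.0
    deadline_s: float = DEADLINE_S
    n_nodes: int = 11
    xatol: float = 1e-4
    fatol: float = 1e-6
    maxiter: int = 2000
    n_quantile_bins: int = 10


def _pack(v, eta, a, lo, st, p_c, fix_a: float | None = None) -> np.ndarray:
    """Map constrained parameters to the unconstrained optimizer space.

    lo = ter - st/2 is the lower edge of the non-decision window; the
    transform keeps v, eta, a, st positive, lo > MIN_TER_EDGE and
    p_c in (0, PC_MAX).  When the boundary is anchored (``fix_a``) the vector
    has five entries, otherwise six.
    """
    eps = 1e-8
    pc_frac = min(max(p_c / PC_MAX, eps), 1 - eps)
    entries = [math.log(max(v, eps)), math.log(max(eta, eps))]
    if fix_a is None:
        entries.append(math.log(max(a, eps)))
    entries += [
        math.log(max(lo - MIN_TER_EDGE, eps)),
        math.log(max(st, eps)),
        math.log(pc_frac / (1 - pc_frac)),
    ]
    return np.array(entries)


def _unpack(x: np.ndarray, fix_a: float | None = None) -> DDMParams:
    x = [float(min(xi, 50.0)) for xi in x]
    v = math.exp(x[0])
    eta = math.exp(x[1])
    if fix_a is None:
        a, rest = math.exp(x[2]), x[3:]
    else:
        a, rest = float(fix_a), x[2:]
    lo = MIN_TER_EDGE + math.exp(rest[0])
    st = math.exp(rest[1])
    p_c = PC_MAX / (1.0 + math.exp(-max(rest[2], -50.0)))
    return DDMParams(v=v, eta=eta, a=a, ter_s=lo + st / 2, st_s=st, p_c=p_c)


def _moment_anchors(obs_rt_s: np.ndarray,
                    fix_a: float | None = None) -> list[np.ndarray]:
    """Multi-start anchors around a method-of-moments shifted-Wald fit.

    The plain MoM point (match mean, variance, fast edge) sits on the
    eta ~ 0 ridge where the contaminant can absorb the slow tail, so the
    anchor set also covers starts with substantial drift variability and a
    robust (interquartile-based) moment estimate that discounts that tail.
    """
    lo0 = max(MIN_TER_EDGE + 1e-3, 0.85 * float(np.min(obs_rt_s)))
    anchors = []
    q25, q50, q75 = np.quantile(obs_rt_s, [0.25, 0.5, 0.75])
    robust_sd = (q75 - q25) / 1.349
    for mean_d, sd_d in ((float(np.mean(obs_rt_s)) - lo0, float(np.std(obs_rt_s))),
                         (float(q50) - lo0, float(robust_sd))):
        mean_d = max(mean_d, 1e-2)
        var_d = max(sd_d * sd_d, 1e-6)
        if fix_a is None:
            # Wald: mean = a/v, var = a/v^3 => v = sqrt(mean/var), a = mean*v
            v0 = math.sqrt(mean_d / var_d)
            a0 = mean_d * v0
        else:
            a0 = fix_a
            v0 = a0 / mean_d  # Wald mean = a/v
        for eta_frac in (0.3, 0.05):
            anchors.append(_pack(v0, max(eta_frac * v0, 0.05), a0, lo0,
                                 0.08, 0.02, fix_a))
    return anchors


def _quantile_chisq_objective(obs_rt_s: np.ndarray, n_timeouts: int,
                              options: FitOptions):
    """Pearson chi-square of observed vs model counts in RT quantile bins,
    with a timeout cell.  Alternative estimator to the censored MLE."""
    n_obs = obs_rt_s.size
    n_tot = n_obs + n_timeouts
    qs = np.linspace(0, 1, options.n_quantile_bins + 1)[1:-1]
    edges = np.concatenate([[0.0], np.quantile(obs_rt_s, qs), [options.deadline_s]])
    counts, _ = np.histogram(obs_rt_s, bins=edges)
    counts = np.append(counts, n_timeouts).astype(float)

    def objective(x: np.ndarray) -> float:
        p = _unpack(x, options.fix_a)
        cdf = (1.0 - p.p_c) * rt_cdf_model(edges, p, options.n_nodes) \
            + p.p_c * np.clip(edges / options.deadline_s, 0, 1)
        probs = np.diff(cdf)
        probs = np.append(probs, max(1.0 - cdf[-1], 0.0))
        probs = np.clip(probs, 1e-10, None)
        expected = n_tot * probs
        return float(np.sum((counts - expected) ** 2 / expected))

    return objective


def fit_day(trials: pd.DataFrame | Sequence[tuple[float, bool]],
            options: FitOptions | None = None) -> DDMParams:
    """Fit the one-choice DDM to one subject-day's pooled RTs.

    ``trials`` is either a trial table slice (with ``rt_ms``/``timeout``
    columns; all sessions of the day pooled, false starts excluded upstream)
    or a sequence of ``(rt_s, timeout)`` pairs.  Maximizes the censored
    log-likelihood (or minimizes the quantile chi-square) by Nelder-Mead on
    an unconstrained transform, from a method-of-moments anchor plus seeded
    log-scale jittered restarts.  Ties across restarts (< 1e-9) go to the
    lowest restart index.
    """
    options = options or FitOptions()
    if isinstance(trials, pd.DataFrame):
        rts_s = trials["rt_ms"].to_numpy(dtype=float) / 1000.0
        to = trials["timeout"].to_numpy(dtype=bool)
    else:
        rts_s = np.array([r for r, _ in trials], dtype=float)
        to = np.array([t for _, t in trials], dtype=bool)
    obs = rts_s[~to]
    n_timeouts = int(to.sum())
    n_total = obs.size + n_timeouts
    if n_total < options.min_trials:
        raise ValueError(
            f"fit_day requires at least {options.min_trials} trials, got {n_total}")

    use_fast_nm = options.method == "mle"
    if options.method == "quantile_chisq":
        objective = _quantile_chisq_objective(obs, n_timeouts, options)
    elif not use_fast_nm:
        raise ValueError(f"unknown fit method: {options.method}")
    if use_fast_nm:
        from ._fastlik import nelder_mead
        gl_x, gl_w = np.polynomial.legendre.leggauss(options.n_nodes)
        fix_a_flag = -1.0 if options.fix_a is None else float(options.fix_a)

    anchors = _moment_anchors(obs, options.fix_a)
    ndim = anchors[0].size
    rng = np.random.default_rng(options.seed)
    best: tuple[float, DDMParams, int] | None = None
    any_converged = False
    for k in range(options.restarts):
        x0 = anchors[k % len(anchors)]
        if k >= len(anchors):
            x0 = x0 + rng.uniform(-0.4, 0.4, size=ndim)
        if use_fast_nm:
            xb, fval, ok = nelder_mead(
                np.asarray(x0, dtype=float), obs, n_timeouts,
                options.deadline_s, gl_x, gl_w, fix_a_flag,
                options.xatol, options.fatol, options.maxiter)
            res_x, fval = xb, float(fval)
        else:
            res = minimize(objective, x0, method="Nelder-Mead",
                           options={"xatol": options.xatol,
                                    "fatol": options.fatol,
                                    "maxiter": options.maxiter,
                                    "adaptive": True})
            res_x, fval, ok = res.x, float(res.fun), bool(res.success)
        any_converged = any_converged or ok
        if best is None or fval < best[0] - 1e-9:
            best = (fval, _unpack(res_x, options.fix_a), k)
    assert best is not None
    params = best[1]
    params.loglik = _loglik_arrays(obs, n_timeouts, params,
                                   options.deadline_s, options.n_nodes)
    params.n_trials_fit = n_total
    params.converged = any_converged and params.loglik > _NEG_INF_PENALTY / 2
    params.n_restarts_used = options.restarts
    return params


DDM_TABLE_COLUMNS = ("subject_id", "v", "eta", "a", "ter_s", "st_s", "p_c",
                     "loglik", "n_trials_fit", "converged")


def baseline_ddm_table(trials: pd.DataFrame, baseline_day: str = "B2",
                       options: FitOptions | None = None,
                       false_start_ms: float = 100.0) -> pd.DataFrame:
    """Fit the DDM per subject on the pooled baseline-day sessions.

    All of a subject's sessions on ``baseline_day`` are collapsed into one
    fit.  False starts (rt below ``false_start_ms``) are excluded before
    fitting.  Subjects without baseline data, with too few trials, or with
    non-converged fits get a flagged row (``converged`` False, NaN
    parameters) and are excluded downstream by complete-case analysis.
    """
    options = options or FitOptions()
    rows = []
    for sid, sub in trials.groupby("subject_id", sort=True):
        day = sub[sub["day_label"] == baseline_day]
        day = day[day["timeout"] | (day["rt_ms"] >= false_start_ms)]
        row: dict = {"subject_id": sid}
        if day.empty:
            row.update({c: np.nan for c in DDM_TABLE_COLUMNS[1:-2]})
            row.update({"n_trials_fit": 0, "converged": False})
        else:
            try:
                p = fit_day(day, options)
                row.update({"v": p.v, "eta": p.eta, "a": p.a, "ter_s": p.ter_s,
                            "st_s": p.st_s, "p_c": p.p_c, "loglik": p.loglik,
                            "n_trials_fit": p.n_trials_fit, "converged": p.converged})
            except ValueError:
                row.update({c: np.nan for c in DDM_TABLE_COLUMNS[1:-2]})
                row.update({"n_trials_fit": int(len(day)), "converged": False})
        rows.append(row)
    return pd.DataFrame(rows, columns=list(DDM_TABLE_COLUMNS))
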