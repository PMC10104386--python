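"""Inferential models: week-by-group analysis of slopes and the multiple
regressions predicting vulnerability from baseline PVT and DDM metrics.

Two stages mirror the analysis design:

* :func:`week_group_analysis` — a 2 (week, within-subject) x 2 (group,
  between-subject) repeated-measures analysis of the deterioration slopes,
  computed in closed form: with exactly two balanced within-subject levels
  the mixed-model tests reduce to t-tests on per-subject week means and week
  differences (the interaction test is algebraically a two-sample t-test on
  slope_wk2 - slope_wk1 between groups).

* :func:`predict_vulnerability` — for each PVT outcome, an OLS regression of
  a vulnerability target (slope_wk1 or slope_diff) on the subject's baseline
  (B2) summary metric for that outcome, the two baseline DDM predictors
  (drift average ``v`` and non-decision time range ``st_s``), and the group
  indicator (1 = 5-h TIB group) as a covariate.  Raw two-sided p-values are
  reported per term; an optional Benjamini-Hochberg adjustment is available
  but off by default.

Complete-case analysis throughout: subjects with non-converged baseline DDM
fits or missing slopes are dropped (and counted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GROUP_INDICATOR
from .vulnerability import OUTCOMES

__all__ = ["RegressionResult", "WeekGroupResult", "fit_ols",
           "predict_vulnerability", "week_group_analysis", "bh_adjust"]


@dataclass
class RegressionResult:
    """Coefficient table of one fitted regression."""

    outcome: str
    terms: list[dict]          # name, B, SE, t, p, df
    n: int
    r_squared: float

    def term(self, name: str) -> dict:
        for t in self.terms:
            if t["name"] == name:
                return t
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.terms)
        df.insert(0, "outcome", self.outcome)
        df["n"] = self.n
        return df


def fit_ols(y, design: pd.DataFrame) -> RegressionResult:
    """Ordinary least squares with classical (homoskedastic) inference.

    ``design`` must contain the intercept column explicitly.  Raises on rank
    deficiency, naming the collinear columns.  Two-sided p-values come from
    the t distribution with ``n - k`` degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    X = design.to_numpy(dtype=float)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more observations ({n}) than columns ({k})")
    # detect collinear columns via the QR diagonal
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    scale = max(diag.max(), 1e-300)
    bad = [design.columns[i] for i in range(k) if diag[i] < 1e-10 * scale]
    if bad:
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df_resid = n - k
    sigma2 = rss / df_resid
    cov = sigma2 * np.linalg.inv(xtx)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    terms = [{"name": c, "B": float(b), "SE": float(s), "t": float(t),
              "p": float(p), "df": df_resid}
             for c, b, s, t, p in zip(design.columns, beta, se, tvals, pvals)]
    return RegressionResult(outcome="", terms=terms, n=n, r_squared=r2)


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up FDR)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0, 1)
    return out


_BASELINE_COLUMN = {"lapses": "lapses", "median_rt": "median_rt_ms",
                    "sd_rt": "sd_rt_ms"}


def predict_vulnerability(slopes: pd.DataFrame, baseline_daily: pd.DataFrame,
                          ddm_table: pd.DataFrame, outcome: str,
                          target: str, baseline_day: str = "B2",
                          min_cases: int = 10) -> RegressionResult:
    """Regress a vulnerability target on baseline PVT + DDM predictors.

    Model:  target ~ intercept + baseline summary(outcome) + st_s + v + group

    ``slopes`` is a subject_slopes table for ``outcome``; ``baseline_daily``
    a daily-metrics table containing the baseline day; ``ddm_table`` the
    per-subject baseline DDM fits (non-converged rows are dropped).
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome: {outcome!r}")
    if target not in ("slope_wk1", "slope_diff"):
        raise ValueError(f"unknown target: {target!r}")
    sl = slopes[slopes["outcome"] == outcome][
        ["subject_id", "group", target]].copy()
    base = baseline_daily[baseline_daily["day_label"] == baseline_day][
        ["subject_id", _BASELINE_COLUMN[outcome]]].rename(
        columns={_BASELINE_COLUMN[outcome]: f"baseline_{outcome}"})
    dd = ddm_table[ddm_table["converged"].astype(bool)][
        ["subject_id", "v", "st_s"]]
    merged = sl.merge(base, on="subject_id").merge(dd, on="subject_id")
    merged["group_5h"] = merged["group"].map(GROUP_INDICATOR)
    merged = merged.dropna()
    if len(merged) < min_cases:
        raise ValueError(
            f"only {len(merged)} complete cases (need >= {min_cases})")
    design = pd.DataFrame({
        "intercept": 1.0,
        f"baseline_{outcome}": merged[f"baseline_{outcome}"],
        "st_s": merged["st_s"],
        "v": merged["v"],
        "group_5h": merged["group_5h"].astype(float),
    })
    res = fit_ols(merged[target].to_numpy(), design)
    res.outcome = f"{target}:{outcome}"
    return res


@dataclass
class WeekGroupResult:
    """Closed-form 2 x 2 repeated-measures analysis of the two weekly slopes."""

    outcome: str
    cells: dict                # (group, week) -> {"mean", "sem", "n"}
    p_week: float
    p_group: float
    p_interaction: float
    simple_effects: dict       # name -> p
    n_excluded: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (g, w), c in self.cells.items():
            rows.append({"outcome": self.outcome, "group": g, "week": w,
                         "mean": c["mean"], "sem": c["sem"], "n": c["n"],
                         "p_week": self.p_week, "p_group": self.p_group,
                         "p_interaction": self.p_interaction})
        return pd.DataFrame(rows)


def _pooled_two_sample(x1: np.ndarray, x2: np.ndarray) -> tuple[float, float]:
    """Equal-variance two-sample t-test: (t, p)."""
    n1, n2 = x1.size, x2.size
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * np.var(x1, ddof=1) + (n2 - 1) * np.var(x2, ddof=1)) / df
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    t = (x1.mean() - x2.mean()) / se
    return float(t), float(2 * stats.t.sf(abs(t), df))


def week_group_analysis(slopes: pd.DataFrame, outcome: str) -> WeekGroupResult:
    """Week (within) x group (between) analysis of deterioration slopes.

    With two within-subject levels the repeated-measures tests are exact
    t-contrasts: the between-group effect is a pooled two-sample t-test on
    per-subject means over weeks; the week effect tests the unweighted mean
    of the group means of the per-subject week differences; the interaction
    is a pooled two-sample t-test on those differences.  Simple effects are
    the corresponding paired (week within group) and two-sample (group within
    week) contrasts.
    """
    sub = slopes[slopes["outcome"] == outcome].copy()
    usable = sub.dropna(subset=["slope_wk1", "slope_wk2"])
    n_excluded = len(sub) - len(usable)
    g5 = usable[usable["group"] == "g5h"]
    g6 = usable[usable["group"] == "g6p5h"]
    if len(g5) < 2 or len(g6) < 2:
        raise ValueError("need at least 2 usable subjects per group")

    cells = {}
    for g, frame in (("g5h", g5), ("g6p5h", g6)):
        for week in ("slope_wk1", "slope_wk2"):
            vals = frame[week].to_numpy(dtype=float)
            cells[(g, week)] = {"mean": float(vals.mean()),
                                "sem": float(vals.std(ddof=1) / np.sqrt(vals.size)),
                                "n": int(vals.size)}

    m5 = g5[["slope_wk1", "slope_wk2"]].mean(axis=1).to_numpy()
    m6 = g6[["slope_wk1", "slope_wk2"]].mean(axis=1).to_numpy()
    d5 = (g5["slope_wk2"] - g5["slope_wk1"]).to_numpy()
    d6 = (g6["slope_wk2"] - g6["slope_wk1"]).to_numpy()
    n1, n2 = d5.size, d6.size
    df = n1 + n2 - 2

    _, p_group = _pooled_two_sample(m5, m6)
    t_int, p_interaction = _pooled_two_sample(d5, d6)

    # week main effect: unweighted marginal mean of the group week-differences
    sp2 = ((n1 - 1) * np.var(d5, ddof=1) + (n2 - 1) * np.var(d6, ddof=1)) / df
    est = 0.5 * (d5.mean() + d6.mean())
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2)) / 2.0
    t_week = est / se
    p_week = float(2 * stats.t.sf(abs(t_week), df))

    def paired_p(d: np.ndarray) -> float:
        t = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        return float(2 * stats.t.sf(abs(t), d.size - 1))

    simple = {
        "week_within_g5h": paired_p(d5),
        "week_within_g6p5h": paired_p(d6),
        "group_within_wk1": _pooled_two_sample(
            g5["slope_wk1"].to_numpy(), g6["slope_wk1"].to_numpy())[1],
        "group_within_wk2": _pooled_two_sample(
            g5["slope_wk2"].to_numpy(), g6["slope_wk2"].to_numpy())[1],
    }
    return WeekGroupResult(outcome=outcome, cells=cells, p_week=p_week,
                           p_group=p_group, p_interaction=p_interaction,
                           simple_effects=simple, n_excluded=n_excluded)
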