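"""PVT summary metrics: per-session lapse/RT statistics and daily averages.

The three outcomes are the ones the vulnerability analysis uses: the number
of lapses (RTs of at least 500 ms, timeouts included), the median RT, and the
within-session SD of RT.  Daily values are unweighted means over a day's
sessions.  Conventions the analysis depends on:

* False starts — anticipations faster than ``false_start_ms`` (default
  100 ms) — are excluded from all three metrics.
* Timeouts count as lapses but are excluded from median and SD by default
  (a 10-s censored value would dominate the SD); set
  ``include_timeouts_in_rt_stats=True`` to pool them at the deadline value.
* The median of an even count is the mean of the two central values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import day_index

__all__ = ["MetricRules", "SessionMetrics", "session_metrics",
           "daily_metrics", "metrics_table", "LAPSE_THRESHOLD_MS"]

LAPSE_THRESHOLD_MS = 500.0


@dataclass(frozen=True)
class MetricRules:
    false_start_ms: float = 100.0
    lapse_threshold_ms: float = LAPSE_THRESHOLD_MS
    include_timeouts_in_rt_stats: bool = False


@dataclass
class SessionMetrics:
    subject_id: str
    day_label: str
    session_index: int
    n_trials: int
    n_false_starts: int
    n_lapses: int
    median_rt_ms: float  # NaN when no usable RTs
    sd_rt_ms: float      # NaN when < 2 usable RTs
    missing: bool = False


def session_metrics(trials: pd.DataFrame,
                    rules: MetricRules | None = None) -> SessionMetrics:
    """Summary metrics of one session's trials.

    ``trials`` must all share subject, day and session.  An empty session is
    returned flagged ``missing``.
    """
    rules = rules or MetricRules()
    if trials.empty:
        raise ValueError("session_metrics requires a non-empty session; "
                         "use daily_metrics' missing handling upstream")
    keys = trials[["subject_id", "day_label", "session_index"]].drop_duplicates()
    if len(keys) != 1:
        raise ValueError("session_metrics expects trials from a single session")
    sid, day, sess = keys.iloc[0]

    rt = trials["rt_ms"].to_numpy(dtype=float)
    timeout = trials["timeout"].to_numpy(dtype=bool)
    false_start = ~timeout & (rt < rules.false_start_ms)
    valid = ~false_start
    lapse = valid & (timeout | (rt >= rules.lapse_threshold_ms))
    if rules.include_timeouts_in_rt_stats:
        rt_pool = rt[valid]
    else:
        rt_pool = rt[valid & ~timeout]

    median = float(np.median(rt_pool)) if rt_pool.size else float("nan")
    sd = float(np.std(rt_pool, ddof=1)) if rt_pool.size >= 2 else float("nan")
    return SessionMetrics(
        subject_id=str(sid), day_label=str(day), session_index=int(sess),
        n_trials=int(len(trials)), n_false_starts=int(false_start.sum()),
        n_lapses=int(lapse.sum()), median_rt_ms=median, sd_rt_ms=sd,
        missing=bool(rt_pool.size == 0),
    )


DAILY_COLUMNS = ("subject_id", "day_label", "lapses", "median_rt_ms",
                 "sd_rt_ms", "n_sessions_used")


def daily_metrics(sessions: list[SessionMetrics]) -> dict:
    """Unweighted mean of session metrics over one subject-day.

    Sessions flagged missing are dropped; with zero usable sessions the
    returned row carries NaNs and a ``reason``.
    """
    if not sessions:
        raise ValueError("daily_metrics requires at least one session")
    keys = {(s.subject_id, s.day_label) for s in sessions}
    if len(keys) != 1:
        raise ValueError("daily_metrics expects sessions from a single subject-day")
    sid, day = next(iter(keys))
    usable = [s for s in sessions if not s.missing]
    if not usable:
        return {"subject_id": sid, "day_label": day, "lapses": float("nan"),
                "median_rt_ms": float("nan"), "sd_rt_ms": float("nan"),
                "n_sessions_used": 0, "reason": "no usable sessions"}
    return {
        "subject_id": sid, "day_label": day,
        "lapses": float(np.mean([s.n_lapses for s in usable])),
        "median_rt_ms": float(np.mean([s.median_rt_ms for s in usable])),
        "sd_rt_ms": float(np.nanmean([s.sd_rt_ms for s in usable])),
        "n_sessions_used": len(usable),
        "reason": "",
    }


def metrics_table(trials: pd.DataFrame,
                  rules: MetricRules | None = None) -> pd.DataFrame:
    """Daily metrics for every subject-day present in the trial table.

    One row per subject x test day, ordered by (subject, protocol day index);
    invariant to the input row order.  Vectorized equivalent of composing
    :func:`session_metrics` and :func:`daily_metrics` over the table (the
    tests assert the equivalence).
    """
    rules = rules or MetricRules()
    t = trials[["subject_id", "day_label", "session_index", "rt_ms",
                "timeout"]].copy()
    keys = ["subject_id", "day_label", "session_index"]
    fs = ~t["timeout"] & (t["rt_ms"] < rules.false_start_ms)
    valid = ~fs
    t["_lapse"] = valid & (t["timeout"] | (t["rt_ms"] >= rules.lapse_threshold_ms))
    pool = valid if rules.include_timeouts_in_rt_stats else (valid & ~t["timeout"])

    lapses = t.groupby(keys, sort=False)["_lapse"].sum()
    pooled = t[pool].groupby(keys, sort=False)["rt_ms"]
    med = pooled.median()
    sd = pooled.std(ddof=1)
    sess = pd.DataFrame({"n_lapses": lapses})
    sess["median_rt_ms"] = med   # NaN where a session has no usable RTs
    sess["sd_rt_ms"] = sd
    usable = sess[sess["median_rt_ms"].notna()]

    day_keys = ["subject_id", "day_label"]
    g = usable.groupby(day_keys, sort=False)
    daily = pd.DataFrame({
        "lapses": g["n_lapses"].mean(),
        "median_rt_ms": g["median_rt_ms"].mean(),
        "sd_rt_ms": g["sd_rt_ms"].mean(),  # NaN sd (1-trial session) skipped
        "n_sessions_used": g.size(),
    })
    # subject-days present in the input but with zero usable sessions
    all_days = t.drop_duplicates(day_keys).set_index(day_keys).index
    daily = daily.reindex(all_days.union(daily.index, sort=False))
    daily["n_sessions_used"] = daily["n_sessions_used"].fillna(0).astype(int)
    daily["reason"] = np.where(daily["n_sessions_used"] == 0,
                               "no usable sessions", "")
    df = daily.reset_index()
    df["_order"] = df["day_label"].map(day_index)
    df = df.sort_values(["subject_id", "_order"], kind="mergesort")
    df = df.drop(columns=["_order"]).reset_index(drop=True)
    return df[list(DAILY_COLUMNS) + ["reason"]]
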