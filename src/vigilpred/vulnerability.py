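"""Per-subject deterioration slopes across the two restriction weeks.

For each subject and each PVT outcome (lapses, median RT, SD RT), an ordinary
least-squares line is fitted through the daily values over

* week 1: the last baseline day B2 through the last manipulation day of the
  first cycle, M1_5 (six days), and
* week 2: the last recovery day of the first cycle, R1_2, through the last
  manipulation day of the second cycle, M2_3 (four days).

Days are coded as consecutive integer offsets 0, 1, 2, ... within each
window, so a slope is the metric's change per day.  ``slope_diff``
(= slope_wk2 - slope_wk1) indexes vulnerability to *recurrent* restriction:
whether a subject deteriorates faster the second time around, after recovery
sleep.  Slopes are flagged missing when fewer than ``min_days`` (default 3)
usable days fall in a window.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["OUTCOMES", "window_days", "ols_slope", "subject_slopes"]

OUTCOMES = ("lapses", "median_rt", "sd_rt")

_OUTCOME_COLUMN = {"lapses": "lapses", "median_rt": "median_rt_ms",
                   "sd_rt": "sd_rt_ms"}

_WINDOWS = {
    "wk1": ("B2", "M1_1", "M1_2", "M1_3", "M1_4", "M1_5"),
    "wk2": ("R1_2", "M2_1", "M2_2", "M2_3"),
}


def window_days(window: str) -> tuple[str, ...]:
    """Ordered day labels of a slope window ('wk1' or 'wk2')."""
    try:
        return _WINDOWS[window]
    except KeyError:
        raise ValueError(f"unknown window: {window!r}") from None


def ols_slope(x, y) -> tuple[float, float]:
    """Least-squares (slope, intercept) of y on x.

    slope = sum((x - xbar)(y - ybar)) / sum((x - xbar)^2)
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size != x.size:
        raise ValueError("ols_slope requires >= 2 paired points")
    xc = x - x.mean()
    sxx = float(np.sum(xc * xc))
    if sxx == 0.0:
        raise ValueError("degenerate x: all values equal")
    slope = float(np.sum(xc * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    return slope, intercept


SLOPE_COLUMNS = ("subject_id", "group", "outcome", "slope_wk1", "slope_wk2",
                 "slope_diff", "n_days_wk1", "n_days_wk2")


def _window_slope(daily: pd.DataFrame, labels: tuple[str, ...], column: str,
                  min_days: int) -> tuple[float, int]:
    sub = daily[daily["day_label"].isin(labels)]
    x, y = [], []
    for offset, lab in enumerate(labels):
        row = sub[sub["day_label"] == lab]
        if row.empty:
            continue
        val = float(row[column].iloc[0])
        if np.isnan(val):
            continue
        x.append(offset)
        y.append(val)
    if len(x) < max(min_days, 2):
        return float("nan"), len(x)
    slope, _ = ols_slope(x, y)
    return slope, len(x)


def subject_slopes(daily: pd.DataFrame, outcome: str,
                   groups: pd.Series | dict | None = None,
                   min_days: int = 3) -> pd.DataFrame:
    """Week-1/week-2 deterioration slopes per subject for one outcome.

    ``daily`` is a metrics table (one row per subject-day).  ``groups`` maps
    subject_id to group; if omitted and ``daily`` has a ``group`` column it is
    used.  Subjects with too few usable days in a window get NaN slopes.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome: {outcome!r}")
    column = _OUTCOME_COLUMN[outcome]
    if groups is None and "group" in daily.columns:
        groups = daily.drop_duplicates("subject_id").set_index("subject_id")["group"]
    rows = []
    for sid, sub in daily.groupby("subject_id", sort=True):
        s1, n1 = _window_slope(sub, _WINDOWS["wk1"], column, min_days)
        s2, n2 = _window_slope(sub, _WINDOWS["wk2"], column, min_days)
        group = ""
        if groups is not None:
            group = groups[sid] if sid in groups else ""
        rows.append({
            "subject_id": sid, "group": group, "outcome": outcome,
            "slope_wk1": s1, "slope_wk2": s2, "slope_diff": s2 - s1,
            "n_days_wk1": n1, "n_days_wk2": n2,
        })
    return pd.DataFrame(rows, columns=list(SLOPE_COLUMNS))
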