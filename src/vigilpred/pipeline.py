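"""End-to-end analysis: trials -> metrics -> baseline DDM -> slopes -> models."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from . import ddm, prediction, pvt_metrics, vulnerability

__all__ = ["AnalysisResult", "run_analysis"]

log = logging.getLogger("vigilpred")

TARGETS = ("slope_wk1", "slope_diff")


@dataclass
class AnalysisResult:
    daily: pd.DataFrame
    ddm_table: pd.DataFrame
    slopes: pd.DataFrame                       # all outcomes stacked
    week_group: dict                           # outcome -> WeekGroupResult
    regressions: dict                          # (target, outcome) -> RegressionResult
    n_nonconverged: int = 0

    def regression_frame(self) -> pd.DataFrame:
        """Tidy term-level coefficient table across all fitted models."""
        frames = []
        for (target, outcome), res in self.regressions.items():
            df = res.to_frame()
            df.insert(0, "target", target)
            df.insert(1, "pvt_outcome", outcome)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def week_group_frame(self) -> pd.DataFrame:
        return pd.concat([r.to_frame() for r in self.week_group.values()],
                         ignore_index=True)


def run_analysis(trials: pd.DataFrame,
                 rules: pvt_metrics.MetricRules | None = None,
                 ddm_options: ddm.FitOptions | None = None,
                 baseline_day: str = "B2",
                 min_cases: int = 10) -> AnalysisResult:
    """Run the full vulnerability-prediction analysis on a trial table."""
    rules = rules or pvt_metrics.MetricRules()
    ddm_options = ddm_options or ddm.FitOptions()

    if not (trials["day_label"] == baseline_day).any():
        raise ValueError(f"no trials on baseline day {baseline_day!r}; "
                         "cannot fit baseline DDM")

    groups = trials.drop_duplicates("subject_id").set_index("subject_id")["group"]
    daily = pvt_metrics.metrics_table(trials, rules)

    ddm_table = ddm.baseline_ddm_table(trials, baseline_day, ddm_options,
                                       false_start_ms=rules.false_start_ms)
    n_bad = int((~ddm_table["converged"].astype(bool)).sum())
    if n_bad:
        log.warning("%d baseline DDM fits non-converged; excluded downstream",
                    n_bad)

    slope_frames = []
    week_group = {}
    regressions = {}
    for outcome in vulnerability.OUTCOMES:
        sl = vulnerability.subject_slopes(daily, outcome, groups=groups)
        slope_frames.append(sl)
        week_group[outcome] = prediction.week_group_analysis(sl, outcome)
        for target in TARGETS:
            regressions[(target, outcome)] = prediction.predict_vulnerability(
                sl, daily, ddm_table, outcome, target,
                baseline_day=baseline_day, min_cases=min_cases)
    slopes = pd.concat(slope_frames, ignore_index=True)
    return AnalysisResult(daily=daily, ddm_table=ddm_table, slopes=slopes,
                          week_group=week_group, regressions=regressions,
                          n_nonconverged=n_bad)
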