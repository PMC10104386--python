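"""Replicate-study harnesses: null calibration, planted-effect recovery,
and DDM parameter-recovery summaries.

These run many scaled-down simulated studies through the full pipeline
(simulate -> metrics -> baseline DDM -> slopes -> models) and tabulate
rejection rates, coefficient signs and recovery error.  Sessions are
shortened and the optimizer budget reduced for replicate studies; the daily
session structure, subject counts and population parameters are the study
conditions themselves and are never scaled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import ddm, prediction, pvt_metrics, synthetic_data, vulnerability

__all__ = ["StudyScale", "FULL_SCALE", "REPLICATE_SCALE", "run_study_once",
           "replicate_studies", "null_population", "planted_population"]

#: days the slope windows and the baseline fit actually use
ANALYSIS_DAYS = ("B2", "M1_1", "M1_2", "M1_3", "M1_4", "M1_5",
                 "R1_2", "M2_1", "M2_2", "M2_3")


@dataclass(frozen=True)
class StudyScale:
    """Problem size of one simulated study in a replicate experiment."""

    session_duration_s: float = 600.0
    restarts: int = 8
    maxiter: int = 2000
    min_trials: int = 100
    xatol: float = 1e-4
    fatol: float = 1e-6
    n_nodes: int = 11

    def fit_options(self, seed: int = 1) -> ddm.FitOptions:
        return ddm.FitOptions(restarts=self.restarts, maxiter=self.maxiter,
                              min_trials=self.min_trials, seed=seed,
                              xatol=self.xatol, fatol=self.fatol,
                              n_nodes=self.n_nodes)


FULL_SCALE = StudyScale()
#: cheap replicate studies for null calibration: ~20 trials/session
REPLICATE_SCALE = StudyScale(session_duration_s=100.0, restarts=1,
                             maxiter=1200, min_trials=30, xatol=1e-3,
                             fatol=1e-5, n_nodes=7)
#: full-length sessions, reduced optimizer budget: the planted associations
#: run through baseline drift estimates, which need the full trial counts
POWER_SCALE = StudyScale(session_duration_s=600.0, restarts=2,
                         maxiter=500, min_trials=100, xatol=1e-3,
                         fatol=1e-5, n_nodes=7)


def null_population() -> synthetic_data.PopulationConfig:
    """All vulnerability effects off: no deterioration, no heterogeneity.

    Under this generator the weekly slopes are pure measurement noise,
    independent of every baseline predictor, so each regression term and the
    week/group/interaction tests are exact nulls.
    """
    return synthetic_data.PopulationConfig(kappa_mean=0.0, kappa_sd=0.0,
                                           kappa2=0.0, corr_v_kappa=0.0)


def planted_population() -> synthetic_data.PopulationConfig:
    """Default population: vulnerability correlated with baseline drift."""
    return synthetic_data.PopulationConfig()


def run_study_once(seed: int, config: synthetic_data.PopulationConfig,
                   scale: StudyScale = REPLICATE_SCALE,
                   outcomes: tuple[str, ...] = ("lapses", "sd_rt")) -> dict:
    """Simulate and analyze one study; return the inferential summaries.

    Returns a dict with, per outcome, the week-group p-values and the two
    prediction regressions' coefficient tables.
    """
    study = synthetic_data.simulate_study(
        seed=seed, config=config, day_labels=ANALYSIS_DAYS,
        session_duration_s=scale.session_duration_s)
    daily = pvt_metrics.metrics_table(study.trials)
    ddm_tab = ddm.baseline_ddm_table(study.trials,
                                     options=scale.fit_options(seed=seed))
    groups = study.subjects.set_index("subject_id")["group"]
    out: dict = {"seed": seed}
    for outcome in outcomes:
        sl = vulnerability.subject_slopes(daily, outcome, groups=groups)
        wg = prediction.week_group_analysis(sl, outcome)
        out[outcome] = {
            "p_week": wg.p_week, "p_group": wg.p_group,
            "p_interaction": wg.p_interaction,
        }
        for target in ("slope_wk1", "slope_diff"):
            reg = prediction.predict_vulnerability(sl, daily, ddm_tab,
                                                   outcome, target)
            out[outcome][target] = {
                t["name"]: {"B": t["B"], "p": t["p"]} for t in reg.terms}
    return out


def replicate_studies(n_studies: int, config: synthetic_data.PopulationConfig,
                      base_seed: int = 1,
                      scale: StudyScale = REPLICATE_SCALE,
                      outcomes: tuple[str, ...] = ("lapses", "sd_rt")) -> list[dict]:
    """Run ``n_studies`` independent studies with seeds base_seed + i."""
    return [run_study_once(base_seed + i, config, scale, outcomes)
            for i in range(n_studies)]


def rejection_rates(results: list[dict], outcome: str, target: str,
                    alpha: float = 0.05) -> dict[str, float]:
    """Fraction of studies in which each regression term rejects at alpha."""
    terms = results[0][outcome][target].keys()
    return {name: float(np.mean(
        [r[outcome][target][name]["p"] < alpha for r in results]))
        for name in terms}


def sign_rates(results: list[dict], outcome: str, target: str,
               term: str, sign: int) -> float:
    """Fraction of studies where a term's coefficient has the given sign."""
    return float(np.mean(
        [np.sign(r[outcome][target][term]["B"]) == sign for r in results]))
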