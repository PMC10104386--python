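"""Trial-level PVT study generator with planted vulnerability traits.

The generator emulates a two-group (5-h / 6.5-h TIB) boarding-school study:
57 adolescents, 15 protocol days, three 10-minute PVT sessions per test day
(two on the arrival day B0), inter-stimulus intervals uniform on 2-10 s and a
10-s response deadline.

Each simulated subject is a one-choice diffusion process.  A night of
restricted sleep adds to a carried-over "sleep pressure" (hours-equivalent
deficit), and a subject's mean drift rate on a given day declines linearly in
that pressure at a subject-specific rate ``kappa`` — the latent vulnerability
trait.  A multiplier ``kappa2`` makes a unit of pressure more costly in the
second restriction cycle, which produces the week-by-group divergence that
the analysis stage is meant to detect.  Drawing ``kappa`` negatively
correlated with baseline drift ``v_base`` plants the association between poor
baseline vigilance and steep deterioration.

Decision times are sampled *exactly* from the single-boundary first-passage
law: inverse-Gaussian for positive per-trial drift, the reflection identity
``T | absorbed ~ IG(a/|u|, a^2)`` with absorption probability ``exp(2 u a)``
for negative drift, and the Levy law ``(a/|Z|)^2`` at zero drift.  No
discretized path simulation is involved, so the generator's RT law agrees
with :func:`vigilpred.ddm.decision_density` to machine precision.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .core import DEADLINE_MS, Group, Protocol, default_protocol, TRIAL_COLUMNS

__all__ = [
    "SubjectProfile",
    "SleepPressureModel",
    "PopulationConfig",
    "SimulatedStudy",
    "sleep_pressure",
    "day_drift",
    "sample_first_passage",
    "simulate_session",
    "simulate_study",
]


@dataclass
class SubjectProfile:
    """Latent generative parameters of one simulated subject."""

    subject_id: str
    group: str
    v_base: float     # mean drift at zero sleep pressure (evidence/s)
    eta: float        # across-trial drift SD
    a: float          # boundary separation
    ter_s: float      # non-decision time centre (s)
    st_s: float       # non-decision time range (s)
    kappa: float      # drift loss per hour-equivalent of sleep pressure
    kappa2: float     # extra week-2 vulnerability multiplier
    p_false_start: float  # per-trial anticipatory-response probability

    def __post_init__(self) -> None:
        if self.v_base <= 0 or self.a <= 0:
            raise ValueError("v_base and a must be positive")
        if self.eta < 0 or self.st_s < 0 or self.kappa < 0:
            raise ValueError("eta, st_s and kappa must be non-negative")
        if self.ter_s - self.st_s / 2 <= 0:
            raise ValueError("non-decision window must stay positive")
        if not (0.0 <= self.p_false_start <= 0.05):
            raise ValueError("p_false_start must lie in [0, 0.05]")


@dataclass
class SleepPressureModel:
    """First-order carry-over model of accumulated sleep debt.

    Pressure after night d is ``P(d) = max(0, rho * P(d-1) + (need - tib_d))``
    in hours-equivalent units, starting from 0 before the first baseline
    night.  A 9-h night adds nothing, so recovery sleep decays the deficit
    geometrically (two recovery nights leave rho^2 of the peak).
    """

    rho: float = 0.5
    need_hours: float = 9.0
    floor: float = 0.25  # minimum fraction of baseline drift retained

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must lie in [0, 1]")


def sleep_pressure(protocol: Protocol,
                   model: SleepPressureModel | None = None) -> dict[str, float]:
    """Hours-equivalent sleep pressure on each protocol day."""
    model = model or SleepPressureModel()
    pressure: dict[str, float] = {}
    p = 0.0
    for day in protocol.days:
        p = max(0.0, model.rho * p + (model.need_hours - day.tib_hours))
        pressure[day.label] = p
    return pressure


#: sleep pressure (hours-equivalent) above which the week-2 multiplier
#: engages: severe-restriction territory (the 5-h schedule exceeds it on
#: every second-cycle manipulation day, the 6.5-h schedule never does)
KAPPA2_PRESSURE_GATE = 4.9


def day_drift(profile: SubjectProfile, pressure: float, in_week2: bool,
              floor: float = 0.25,
              kappa2_gate: float = KAPPA2_PRESSURE_GATE) -> float:
    """Mean drift on a day with the given sleep pressure.

    ``v_d = max(floor * v_base, v_base - kappa * (1 + kappa2*[week2]) * P)``,
    where the week-2 vulnerability multiplier ``kappa2`` engages only when
    the pressure is at severe levels (``P >= kappa2_gate``): recurrent
    restriction compounds vulnerability only under a strong dose, which is
    what lets the high-dose group diverge in the second cycle while the
    moderate-dose group deteriorates at its week-1 rate.
    """
    if pressure < 0:
        raise ValueError("pressure must be non-negative")
    engaged = in_week2 and pressure >= kappa2_gate
    mult = 1.0 + (profile.kappa2 if engaged else 0.0)
    return max(floor * profile.v_base,
               profile.v_base - profile.kappa * mult * pressure)


def _in_week2(label: str) -> bool:
    return label.startswith("M2") or label.startswith("R2")


# ---------------------------------------------------------------------------
# exact first-passage sampling

def _invgauss_sample(mu: np.ndarray, lam: float, rng: np.random.Generator) -> np.ndarray:
    """Michael-Schucany-Haas inverse-Gaussian sampler, vectorized."""
    nu = rng.standard_normal(mu.shape)
    y = nu * nu
    x = mu + mu * mu * y / (2.0 * lam) \
        - (mu / (2.0 * lam)) * np.sqrt(4.0 * mu * lam * y + (mu * y) ** 2)
    u = rng.uniform(size=mu.shape)
    return np.where(u <= mu / (mu + x), x, mu * mu / x)


def sample_first_passage(u: np.ndarray | float, a: float,
                         rng: np.random.Generator,
                         size: int | None = None) -> np.ndarray:
    """Exact first-passage times of drift-``u`` diffusions at boundary ``a``.

    Returns ``inf`` for paths that are never absorbed (possible when the
    drift is non-positive).  ``u`` may be a scalar (with ``size``) or an
    array of per-trial drifts.
    """
    if a <= 0:
        raise ValueError("boundary a must be positive")
    u = np.asarray(u, dtype=float)
    if u.ndim == 0:
        if size is None:
            raise ValueError("scalar drift requires size")
        u = np.full(size, float(u))
    t = np.empty_like(u)
    lam = a * a

    pos = u > 0
    if pos.any():
        t[pos] = _invgauss_sample(a / u[pos], lam, rng)
    zero = u == 0
    if zero.any():
        z = rng.standard_normal(int(zero.sum()))
        z = np.where(np.abs(z) < 1e-300, 1e-300, z)
        t[zero] = (a / z) ** 2
    neg = u < 0
    if neg.any():
        # reflection identity: absorbed with prob exp(2 u a); conditional on
        # absorption the passage time is IG with the mirrored drift |u|
        p_hit = np.exp(2.0 * u[neg] * a)
        hit = rng.uniform(size=int(neg.sum())) < p_hit
        tt = np.full(int(neg.sum()), np.inf)
        if hit.any():
            tt[hit] = _invgauss_sample(a / np.abs(u[neg][hit]), lam, rng)
        t[neg] = tt
    return t


# ---------------------------------------------------------------------------
# session / study simulation

FALSE_START_RANGE_MS = (100.0, 250.0)


def session_rng(seed: int, subject_id: str, day_label: str,
                session_index: int) -> np.random.Generator:
    """Deterministic per-session RNG stream keyed by stable string hashes."""
    entropy = (int(seed) % (2**31),
               zlib.crc32(subject_id.encode()),
               zlib.crc32(day_label.encode()),
               int(session_index))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _session_arrays(profile: SubjectProfile, drift: float,
                    rng: np.random.Generator, duration_s: float):
    """Core session simulation; returns (isi_s, rt_s, timeout) arrays."""
    if not np.all(np.isfinite([drift, profile.eta, profile.a, profile.ter_s,
                               profile.st_s])):
        raise ValueError("non-finite simulation parameters")
    deadline_s = DEADLINE_MS / 1000.0
    isi_parts: list[np.ndarray] = []
    rt_parts: list[np.ndarray] = []
    to_parts: list[np.ndarray] = []
    elapsed_last = 0.0
    total = 0
    while elapsed_last < duration_s and total < 10_000:
        n = max(16, int((duration_s - elapsed_last) / 2.2) + 4)
        isi_s = rng.uniform(2.0, 10.0, size=n)
        u = rng.normal(drift, profile.eta, size=n)
        dec = sample_first_passage(u, profile.a, rng)
        ndt = rng.uniform(profile.ter_s - profile.st_s / 2,
                          profile.ter_s + profile.st_s / 2, size=n)
        rt = dec + ndt
        fs = rng.uniform(size=n) < profile.p_false_start
        fs_rt = rng.uniform(*FALSE_START_RANGE_MS, size=n) / 1000.0
        rt = np.where(fs, fs_rt, rt)
        timeout = rt >= deadline_s
        rt = np.where(timeout, deadline_s, rt)
        isi_parts.append(isi_s)
        rt_parts.append(rt)
        to_parts.append(timeout)
        elapsed_last += float(np.sum(isi_s + rt))
        total += n
    isi_s = np.concatenate(isi_parts)
    rt = np.concatenate(rt_parts)
    timeout = np.concatenate(to_parts)
    # keep trial i iff the stimulus schedule is still inside the window
    start_times = np.concatenate([[0.0], np.cumsum(isi_s + rt)[:-1]])
    keep = start_times < duration_s
    return isi_s[keep], rt[keep], timeout[keep]


def simulate_session(profile: SubjectProfile, drift: float,
                     rng: np.random.Generator, *,
                     day_label: str = "B2", session_index: int = 0,
                     duration_s: float = 600.0) -> pd.DataFrame:
    """Simulate one PVT session as a block of the canonical trial table.

    Stimuli follow ISIs uniform on 2-10 s; trials keep arriving while the
    cumulative ISI + RT is below ``duration_s`` (so a ~10-minute session at
    baseline speed yields roughly 90-95 trials).  Per trial the drift is
    Normal(drift, eta^2), the decision time comes from the exact first-
    passage law, the non-decision time is uniform on the ``ter +- st/2``
    window, and the sum is censored at the 10-s deadline (timeout).  With
    probability ``p_false_start`` the response is replaced by an anticipation
    uniform on 100-250 ms.
    """
    isi_s, rt, timeout = _session_arrays(profile, drift, rng, duration_s)
    n = isi_s.size
    return pd.DataFrame({
        "subject_id": profile.subject_id,
        "group": profile.group,
        "day_label": day_label,
        "session_index": np.int64(session_index),
        "trial_index": np.arange(n, dtype=np.int64),
        "isi_ms": isi_s * 1000.0,
        "rt_ms": np.round(rt * 1000.0, 6),
        "timeout": timeout,
    }, columns=list(TRIAL_COLUMNS))


@dataclass
class PopulationConfig:
    """Distributions of the subject profiles and the pressure model.

    Defaults were chosen once to give realistic well-rested PVT behaviour
    (median RT around 300 ms, a handful of lapses per baseline session), with
    a planted negative correlation between baseline drift and vulnerability.
    The vulnerability scale (kappa_mean, with kappa_sd keeping a coefficient
    of variation of one third) is calibrated so the group-mean deterioration
    slopes of daily lapses match the magnitudes reported for adolescents under
    5-h/6.5-h restriction: roughly +1.5-1.8 lapses/day in the first
    restriction week and ~4.5 (5-h) vs ~2 (6.5-h) lapses/day in the second.
    """

    v_base_mean: float = 8.0
    v_base_sd: float = 1.5
    eta_mean: float = 2.5
    eta_sd: float = 0.4
    a_mean: float = 1.0
    a_sd: float = 0.12
    ter_mean: float = 0.20
    ter_sd: float = 0.02
    st_mean: float = 0.12
    st_sd: float = 0.04
    kappa_mean: float = 0.25
    kappa_sd: float = 0.08
    kappa2: float = 0.5
    corr_v_kappa: float = -0.6
    p_false_start: float = 0.01
    rho: float = 0.5
    need_hours: float = 9.0
    floor: float = 0.25

    def __post_init__(self) -> None:
        if abs(self.corr_v_kappa) >= 1.0:
            raise ValueError("corr_v_kappa must satisfy |r| < 1")

    def pressure_model(self) -> SleepPressureModel:
        return SleepPressureModel(rho=self.rho, need_hours=self.need_hours,
                                  floor=self.floor)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self)))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PopulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def sample_profiles(n_per_group: tuple[int, int], config: PopulationConfig,
                    rng: np.random.Generator) -> list[SubjectProfile]:
    """Draw subject profiles; kappa is correlated with v_base via a Gaussian
    copula on the underlying normals (small truncations distort the planted
    correlation only marginally)."""
    profiles = []
    counts = {"g5h": n_per_group[0], "g6p5h": n_per_group[1]}
    r = config.corr_v_kappa
    for group, n in counts.items():
        tag = "s5h" if group == "g5h" else "s6h"
        for i in range(n):
            z1, z2 = rng.standard_normal(2)
            v_base = max(1.0, config.v_base_mean + config.v_base_sd * z1)
            kappa = max(0.0, config.kappa_mean + config.kappa_sd *
                        (r * z1 + np.sqrt(1 - r * r) * z2))
            eta = max(0.2, rng.normal(config.eta_mean, config.eta_sd))
            a = max(0.4, rng.normal(config.a_mean, config.a_sd))
            st = float(np.clip(rng.normal(config.st_mean, config.st_sd),
                               0.02, 0.30))
            ter = max(0.06 + st / 2,
                      rng.normal(config.ter_mean, config.ter_sd))
            profiles.append(SubjectProfile(
                subject_id=f"{tag}_{i + 1:02d}", group=group,
                v_base=v_base, eta=eta, a=a, ter_s=ter, st_s=st,
                kappa=kappa, kappa2=config.kappa2,
                p_false_start=config.p_false_start))
    return profiles


@dataclass
class SimulatedStudy:
    """Trial table plus the ground truth that generated it."""

    trials: pd.DataFrame
    subjects: pd.DataFrame      # one row per subject: latent profile
    day_truth: pd.DataFrame     # per subject-day: pressure and true drift
    config: PopulationConfig
    seed: int


SUBJECT_TRUTH_COLUMNS = ("subject_id", "group", "v_base", "eta", "a",
                         "ter_s", "st_s", "kappa", "kappa2", "p_false_start")


def simulate_study(n_per_group: tuple[int, int] = (28, 29),
                   config: PopulationConfig | None = None,
                   seed: int = 0, *,
                   session_duration_s: float = 600.0,
                   day_labels: Sequence[str] | None = None) -> SimulatedStudy:
    """Simulate a full two-cycle restriction study.

    ``day_labels`` restricts which days emit trials (the pressure recursion
    always runs over the whole protocol); ``session_duration_s`` scales the
    session length, for cheap replicate studies.  Deterministic given
    ``seed``: profile draws use one study-level stream and every session has
    its own stream keyed by (seed, subject, day, session).
    """
    config = config or PopulationConfig()
    prof_rng = np.random.default_rng(
        np.random.SeedSequence((int(seed) % (2**31), 0x9E3779B9)))
    profiles = sample_profiles(n_per_group, config, prof_rng)
    model = config.pressure_model()
    protocols = {g.value: default_protocol(g) for g in Group}
    pressures = {g: sleep_pressure(p, model) for g, p in protocols.items()}

    sid_parts: list[np.ndarray] = []
    blocks: list[tuple] = []   # (subject, group, day, session, isi, rt, timeout)
    truth_rows: list[dict] = []
    wanted = set(day_labels) if day_labels is not None else None
    for prof in profiles:
        protocol = protocols[prof.group]
        pres = pressures[prof.group]
        for day in protocol.days:
            wk2 = _in_week2(day.label)
            v_d = day_drift(prof, pres[day.label], wk2, floor=model.floor)
            truth_rows.append({
                "subject_id": prof.subject_id, "group": prof.group,
                "day_label": day.label, "pressure": pres[day.label],
                "in_week2": wk2, "drift": v_d,
            })
            if wanted is not None and day.label not in wanted:
                continue
            for s_idx in range(protocol.n_sessions(day.label)):
                rng = session_rng(seed, prof.subject_id, day.label, s_idx)
                isi_s, rt, timeout = _session_arrays(
                    prof, v_d, rng, session_duration_s)
                blocks.append((prof.subject_id, prof.group, day.label,
                               s_idx, isi_s, rt, timeout))
    n_per_block = [b[4].size for b in blocks]
    trials = pd.DataFrame({
        "subject_id": np.repeat([b[0] for b in blocks], n_per_block),
        "group": np.repeat([b[1] for b in blocks], n_per_block),
        "day_label": np.repeat([b[2] for b in blocks], n_per_block),
        "session_index": np.repeat(
            np.array([b[3] for b in blocks], dtype=np.int64), n_per_block),
        "trial_index": np.concatenate(
            [np.arange(n, dtype=np.int64) for n in n_per_block]),
        "isi_ms": np.concatenate([b[4] for b in blocks]) * 1000.0,
        "rt_ms": np.round(np.concatenate([b[5] for b in blocks]) * 1000.0, 6),
        "timeout": np.concatenate([b[6] for b in blocks]),
    }, columns=list(TRIAL_COLUMNS))
    subjects = pd.DataFrame(
        [{k: getattr(p, k) for k in SUBJECT_TRUTH_COLUMNS} for p in profiles],
        columns=list(SUBJECT_TRUTH_COLUMNS))
    day_truth = pd.DataFrame(truth_rows)
    return SimulatedStudy(trials=trials, subjects=subjects,
                          day_truth=day_truth, config=config, seed=seed)
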