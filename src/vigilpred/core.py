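"""Domain types, study-protocol schedule, and trial-table I/O.

The study protocol is a 15-day boarding design: two baseline nights of 9-h
time in bed (TIB), a first restriction cycle of five short nights followed by
two 9-h recovery nights, and a second cycle of three short nights followed by
two recovery nights.  The restricted groups sleep 5.0 h or 6.5 h per
manipulation night.

Day-label convention: a label names a *night*; the daytime PVT sessions on
the following day carry that night's label.  "B2 performance" therefore means
the sessions after the second baseline night — the last well-rested
measurement.  The first protocol day (B0, the arrival day before any in-lab
night) carries two PVT sessions; every other test day carries three; the
final day (after night R2_2) carries none.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Group",
    "Phase",
    "StudyDay",
    "Protocol",
    "TrialRecord",
    "DAY_LABELS",
    "GROUP_INDICATOR",
    "TRIAL_COLUMNS",
    "DEADLINE_MS",
    "default_protocol",
    "read_trials",
    "write_trials",
    "trials_frame",
    "records_from_frame",
    "day_index",
]

DEADLINE_MS = 10_000.0
ISI_RANGE_MS = (2_000.0, 10_000.0)

#: Protocol day labels in temporal order (each labels the preceding night,
#: except B0 which is the arrival day).
DAY_LABELS: tuple[str, ...] = (
    "B0", "B1", "B2",
    "M1_1", "M1_2", "M1_3", "M1_4", "M1_5",
    "R1_1", "R1_2",
    "M2_1", "M2_2", "M2_3",
    "R2_1", "R2_2",
)

_DAY_INDEX = {lab: i for i, lab in enumerate(DAY_LABELS)}


class Group(str, enum.Enum):
    """Sleep-restriction dose group (nightly TIB during manipulation)."""

    g5h = "g5h"
    g6p5h = "g6p5h"


#: Indicator coding used by all downstream models: 1 = 5-h group, 0 = 6.5-h.
GROUP_INDICATOR = {"g6p5h": 0, "g5h": 1}


class Phase(str, enum.Enum):
    baseline = "baseline"
    manipulation1 = "manipulation1"
    recovery1 = "recovery1"
    manipulation2 = "manipulation2"
    recovery2 = "recovery2"


_PHASE_BY_PREFIX = {
    "B": Phase.baseline,
    "M1": Phase.manipulation1,
    "R1": Phase.recovery1,
    "M2": Phase.manipulation2,
    "R2": Phase.recovery2,
}


def _phase_of(label: str) -> Phase:
    prefix = label.split("_")[0] if "_" in label else label[0]
    return _PHASE_BY_PREFIX[prefix]


@dataclass(frozen=True)
class StudyDay:
    """One protocol day, carrying the TIB of the preceding night."""

    label: str
    index: int
    tib_hours: float
    phase: Phase

    def __post_init__(self) -> None:
        if not (0.0 < self.tib_hours < 24.0):
            raise ValueError(f"tib_hours out of range: {self.tib_hours}")


#: Clock times of the daily cognitive battery (PVT is the last task).
SESSION_TIMES = ("10:00", "15:45", "20:00")
B0_SESSION_TIMES = ("15:45", "20:00")


@dataclass
class Protocol:
    """Ordered study days plus the per-day PVT session schedule."""

    days: list[StudyDay]
    group_label: str
    sessions_per_day: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [d.label for d in self.days]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate day labels in protocol")
        for i, d in enumerate(self.days):
            if d.index != i:
                raise ValueError("day indices must be consecutive from 0")

    @property
    def day_labels(self) -> list[str]:
        return [d.label for d in self.days]

    def day(self, label: str) -> StudyDay:
        for d in self.days:
            if d.label == label:
                return d
        raise KeyError(label)

    def test_days(self) -> list[str]:
        """Labels of days that carry at least one PVT session."""
        return [lab for lab, s in self.sessions_per_day.items() if s]

    def n_sessions(self, label: str) -> int:
        return len(self.sessions_per_day.get(label, ()))

    def to_dict(self) -> dict:
        return {
            "group_label": self.group_label,
            "days": [
                {"label": d.label, "tib_hours": d.tib_hours, "phase": d.phase.value}
                for d in self.days
            ],
            "sessions_per_day": {k: list(v) for k, v in self.sessions_per_day.items()},
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path


def default_protocol(group: Group | str) -> Protocol:
    """The 15-day two-cycle restriction protocol for one dose group.

    Manipulation nights have TIB 5.0 h (``g5h``) or 6.5 h (``g6p5h``);
    baseline and recovery nights have 9.0 h.  B0 (arrival day, preceded by a
    9-h home-schedule night) carries two PVT sessions, days B1..R2_1 carry
    three, and the final day carries none.
    """
    group = Group(group)
    man_tib = 5.0 if group is Group.g5h else 6.5
    days = []
    for i, lab in enumerate(DAY_LABELS):
        phase = _phase_of(lab)
        tib = man_tib if phase in (Phase.manipulation1, Phase.manipulation2) else 9.0
        days.append(StudyDay(label=lab, index=i, tib_hours=tib, phase=phase))
    sessions: dict[str, tuple[str, ...]] = {"B0": B0_SESSION_TIMES}
    for lab in DAY_LABELS[1:-1]:
        sessions[lab] = SESSION_TIMES
    sessions[DAY_LABELS[-1]] = ()
    return Protocol(days=days, group_label=group.value, sessions_per_day=sessions)


def day_index(label: str) -> int:
    """Position of a day label within the canonical 15-day protocol."""
    return _DAY_INDEX[label]


@dataclass
class TrialRecord:
    """One PVT stimulus-response event."""

    subject_id: str
    group: str
    day_label: str
    session_index: int
    trial_index: int
    isi_ms: float
    rt_ms: float | None
    timeout: bool

    def __post_init__(self) -> None:
        if self.timeout:
            if self.rt_ms is not None and self.rt_ms != DEADLINE_MS:
                raise ValueError("timeout trials must have rt_ms absent or 10000")
        else:
            if self.rt_ms is None or not (0.0 < self.rt_ms <= DEADLINE_MS):
                raise ValueError(f"rt_ms out of range: {self.rt_ms}")
        if not (ISI_RANGE_MS[0] <= self.isi_ms <= ISI_RANGE_MS[1]):
            raise ValueError(f"isi_ms out of range: {self.isi_ms}")


TRIAL_COLUMNS = (
    "subject_id", "group", "day_label", "session_index",
    "trial_index", "isi_ms", "rt_ms", "timeout",
)


def trials_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    """Assemble TrialRecords into the canonical trial table."""
    rows = [asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))
    return _canonicalize(df)


def records_from_frame(df: pd.DataFrame) -> list[TrialRecord]:
    out = []
    for row in df.itertuples(index=False):
        rt = None if pd.isna(row.rt_ms) else float(row.rt_ms)
        out.append(TrialRecord(
            subject_id=str(row.subject_id), group=str(row.group),
            day_label=str(row.day_label), session_index=int(row.session_index),
            trial_index=int(row.trial_index), isi_ms=float(row.isi_ms),
            rt_ms=rt, timeout=bool(row.timeout),
        ))
    return out


def _canonicalize(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["subject_id"] = df["subject_id"].astype(str)
    df["group"] = df["group"].astype(str)
    df["day_label"] = df["day_label"].astype(str)
    df["session_index"] = df["session_index"].astype(np.int64)
    df["trial_index"] = df["trial_index"].astype(np.int64)
    df["isi_ms"] = df["isi_ms"].astype(float)
    df["rt_ms"] = df["rt_ms"].astype(float)
    df["timeout"] = df["timeout"].astype(bool)
    # canonical censored representation
    df.loc[df["timeout"], "rt_ms"] = DEADLINE_MS
    return df


def _validate_trials(df: pd.DataFrame) -> pd.Series:
    """Return a Series of error messages ('' = valid) per row."""
    err = pd.Series("", index=df.index, dtype=object)
    bad_group = ~df["group"].isin([g.value for g in Group])
    err[bad_group & (err == "")] = "unknown group"
    bad_day = ~df["day_label"].isin(DAY_LABELS)
    err[bad_day & (err == "")] = "unknown day_label"
    bad_sess = (df["session_index"] < 0) | (df["session_index"] > 2)
    err[bad_sess & (err == "")] = "session_index out of range"
    bad_isi = (df["isi_ms"] < ISI_RANGE_MS[0]) | (df["isi_ms"] > ISI_RANGE_MS[1])
    err[bad_isi & (err == "")] = "isi_ms out of range"
    rt = df["rt_ms"]
    to = df["timeout"]
    over = rt.notna() & (rt > DEADLINE_MS)
    err[over & (err == "")] = "rt_ms exceeds deadline"
    nonpos = rt.notna() & (rt <= 0)
    err[nonpos & (err == "")] = "rt_ms must be positive"
    missing = ~to & rt.isna()
    err[missing & (err == "")] = "rt_ms missing on non-timeout trial"
    bad_to = to & rt.notna() & (rt != DEADLINE_MS)
    err[bad_to & (err == "")] = "timeout trial with rt_ms != 10000"
    return err


def read_trials(path: str | Path, strict: bool = True) -> pd.DataFrame:
    """Read and validate a trial CSV.

    Empty ``rt_ms`` cells are allowed only on timeout rows (read back as the
    canonical censored value 10000).  In strict mode the first malformed row
    raises ``ValueError`` naming its 1-based data-row number; otherwise bad
    rows are dropped and their count recorded in ``df.attrs['n_skipped']``.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str, "group": str, "day_label": str})
    missing_cols = set(TRIAL_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"trial CSV missing columns: {sorted(missing_cols)}")
    df = df[list(TRIAL_COLUMNS)]
    if df.empty:
        out = _canonicalize(df)
        out.attrs["n_skipped"] = 0
        return out
    err = _validate_trials(df)
    bad = err != ""
    if bad.any():
        if strict:
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"row {i + 1}: {err.iloc[i]}")
        df = df[~bad]
    out = _canonicalize(df)
    out.attrs["n_skipped"] = int(bad.sum())
    return out


def write_trials(trials: pd.DataFrame | Sequence[TrialRecord],
                 path: str | Path) -> Path:
    """Write the canonical trial CSV (UTF-8, comma, '.' decimal, header).

    Timeout rows are written with rt_ms = 10000 so the censored
    representation is unique; ``read_trials(write_trials(x))`` reproduces
    ``x`` field for field.
    """
    if not isinstance(trials, pd.DataFrame):
        trials = trials_frame(trials)
    else:
        trials = _canonicalize(trials[list(TRIAL_COLUMNS)])
    path = Path(path)
    trials.to_csv(path, index=False)
    return path
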