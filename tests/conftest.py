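import numpy as np
import pandas as pd
import pytest

from vigilpred import synthetic_data as sd
from vigilpred.core import TRIAL_COLUMNS


@pytest.fixture(scope="session")
def typical_profile() -> sd.SubjectProfile:
    """A population-typical simulated subject."""
    return sd.SubjectProfile(
        subject_id="s5h_01", group="g5h", v_base=8.0, eta=2.5, a=1.0,
        ter_s=0.20, st_s=0.12, kappa=0.25, kappa2=0.5, p_false_start=0.01)


@pytest.fixture(scope="session")
def baseline_study() -> sd.SimulatedStudy:
    """Default-population study simulated on the baseline day only."""
    return sd.simulate_study(seed=1, day_labels=["B2"])


def make_trials(rts_ms, timeouts=None, subject="s01", group="g5h",
                day="B2", session=0) -> pd.DataFrame:
    """Hand-crafted session block in the canonical trial layout."""
    rts_ms = list(rts_ms)
    if timeouts is None:
        timeouts = [False] * len(rts_ms)
    n = len(rts_ms)
    return pd.DataFrame({
        "subject_id": subject, "group": group, "day_label": day,
        "session_index": np.int64(session),
        "trial_index": np.arange(n, dtype=np.int64),
        "isi_ms": np.full(n, 4000.0),
        "rt_ms": np.asarray(rts_ms, dtype=float),
        "timeout": np.asarray(timeouts, dtype=bool),
    }, columns=list(TRIAL_COLUMNS))
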