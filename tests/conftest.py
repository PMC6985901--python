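import pandas as pd
import pytest

from betadyn import SessionConfig, detect_contraction_bounds, synthesize_session
from betadyn.synth import SCHEDULE_COLUMNS, TaskSchedule


def make_schedule(conditions, rest_s=30.0, lead_in_s=30.0, cue_lead_s=2.0,
                  jitter=None):
    """Deterministic schedule from an explicit condition sequence."""
    rows = []
    t = lead_in_s
    for i, d in enumerate(conditions):
        on = t if jitter is None else t + jitter[i][0]
        off = t + d if jitter is None else t + d + jitter[i][1]
        rows.append((i, float(d), t - cue_lead_s, on, off, t + d + rest_s))
        t = t + d + rest_s
    return TaskSchedule(pd.DataFrame(rows, columns=SCHEDULE_COLUMNS),
                        cue_lead_s=cue_lead_s)


def empty_schedule():
    return TaskSchedule(pd.DataFrame(columns=SCHEDULE_COLUMNS))


@pytest.fixture(scope="session")
def small_session():
    """16-channel, 6-source run with 3 trials per duration (seeded)."""
    cfg = SessionConfig(n_channels=16, n_sources=6, n_trials_per_condition=3,
                        lead_in_s=50.0, tail_s=50.0)
    return synthesize_session(cfg, seed=7)


@pytest.fixture(scope="session")
def small_events(small_session):
    s = small_session
    return detect_contraction_bounds(s.emg, s.schedule)
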