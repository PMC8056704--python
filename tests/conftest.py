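import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_diary():
    """Tiny hand-written raw diary table (3 participants, mixed day types)."""
    rows = [
        # pid, day, bed, lights_off, latency, wake, alarm, workday
        ("A", 1, "23:00", "23:30", 30, "07:30", 1, 1),
        ("A", 2, "23:15", "23:45", 15, "08:00", 1, 1),
        ("A", 3, "00:30", "01:00", 30, "09:30", 0, 0),
        ("A", 5, "23:00", "23:30", 30, "07:30", 1, 1),  # gap after day 3
        ("B", 1, "01:00", "01:30", 60, "10:00", 0, 0),
        ("B", 2, "02:00", "02:15", 15, "10:15", 0, 0),
        ("C", 1, "22:00", "22:30", 10, "06:30", 1, 1),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id", "day_index", "bed_time", "lights_off",
            "latency_min", "wake_time", "alarm", "workday_today",
        ],
    )


@pytest.fixture(scope="session")
def scored_small_diary(small_diary):
    from chronostab.records import score_diary

    return score_diary(small_diary)


@pytest.fixture(scope="session")
def default_diary_sim():
    """One medium synthetic diary shared across tests (seeded)."""
    from chronostab.simulate import DiarySimConfig, simulate_diary

    return simulate_diary(DiarySimConfig(seed=42))


def balanced_oneway(rng, n_groups, per_group, sigma_b, sigma_w, mu=0.0):
    """Simulate a balanced one-way random-effects layout."""
    u = rng.normal(0.0, sigma_b, n_groups)
    y = mu + u[:, None] + rng.normal(0.0, sigma_w, (n_groups, per_group))
    groups = np.repeat(np.arange(n_groups), per_group)
    return y.ravel(), groups
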