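import numpy as np
import pytest

from patd.sensor_io import AccStream, GpsStream, LabelTrack, SubjectRecord
from patd.synthetic_data import DEFAULT_SCHEDULES, default_profiles, generate_cohort

FS = 50.0


def make_acc(subject_id="s1", position="chest", duration_s=10.0, seed=0):
    rng = np.random.default_rng(seed)
    n = int(duration_s * FS)
    t = np.arange(n) / FS
    return AccStream(
        subject_id, position, t,
        rng.normal(0, 0.05, n), rng.normal(0, 0.05, n), 1.0 + rng.normal(0, 0.05, n),
    )


def make_record(subject_id="s1", duration_s=10.0, with_gps=True, seed=0):
    """Minimal hand-built record: one chest stream, flat GPS, walking labels."""
    acc = make_acc(subject_id, "chest", duration_s, seed)
    gps = None
    if with_gps:
        n = int(duration_s)
        t = np.arange(n, dtype=float)
        gps = GpsStream(subject_id, t, np.full(n, 47.4), np.full(n, 8.55), np.full(n, 420.0))
    labels = LabelTrack(subject_id, [(0.0, duration_s, "walking", "semi_structured")])
    return SubjectRecord(subject_id, "young", {"chest": acc}, gps, labels)


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def short_schedules():
    """Compressed sessions (every activity, ~1 min per protocol) for fast tests."""
    return {
        "semi_structured": (
            ("standing", 8.0), ("lying", 8.0), ("sitting", 8.0),
            ("walking", 14.0), ("nonlevel_walking", 12.0), ("running", 10.0),
        ),
        "real_life": (
            ("sitting", 8.0), ("walking", 12.0), ("standing", 8.0),
            ("nonlevel_walking", 10.0), ("running", 8.0), ("lying", 8.0),
        ),
    }


@pytest.fixture(scope="session")
def tiny_cohorts(profiles, short_schedules):
    """3 young + 3 old subjects on compressed schedules."""
    young, old = profiles
    return (
        generate_cohort(3, young, short_schedules, seed=7),
        generate_cohort(3, old, short_schedules, seed=7),
    )
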