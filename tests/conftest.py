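import numpy as np
import pandas as pd
import pytest

from sepsight import (
    StayRecord,
    SynthConfig,
    TimelineConfig,
    build_stay_timeline,
    generate_cohort,
    prepare_cohort,
)


def make_stay(
    obs_rows,
    stay_id="s1",
    age=60.0,
    length_h=6.0,
    abx=(),
    cultures=(),
):
    """StayRecord from a list of (time_h, channel, value) tuples."""
    obs = pd.DataFrame(obs_rows, columns=["time_h", "channel", "value"])
    return StayRecord(
        stay_id=stay_id,
        age_years=age,
        icu_length_h=length_h,
        observations=obs,
        antibiotic_times_h=np.asarray(abx, float),
        culture_times_h=np.asarray(cultures, float),
    )


NORMAL_VITALS = [
    ("heart_rate", 80.0),
    ("resp_rate", 14.0),
    ("temperature", 37.0),
    ("spo2", 98.0),
    ("gcs", 15.0),
    ("nisysabp", 120.0),
    ("nidiasabp", 70.0),
]


def normal_stay(length_h=12.0, **kwargs):
    """A stay with one full normal-vitals assessment every hour."""
    rows = [
        (h + 0.5, ch, val)
        for h in range(int(length_h))
        for ch, val in NORMAL_VITALS
    ]
    return make_stay(rows, length_h=length_h, **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A 150-stay synthetic cohort shared by the cheaper integration tests."""
    cohort, truth = generate_cohort(SynthConfig(n_stays=150, seed=42))
    timelines, labels, included, report = prepare_cohort(cohort)
    return dict(
        cohort=cohort,
        truth=truth,
        timelines=timelines,
        labels=labels,
        included=included,
        report=report,
    )
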