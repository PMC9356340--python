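import dataclasses

import numpy as np
import pandas as pd
import pytest

from accelharm.io_formats import MinuteSeries, ParticipantData
from accelharm.synthetic_data import SimProfile, generate_minute_cohort


@pytest.fixture(scope="session")
def _cohort_cache():
    profile = SimProfile(seed=7, n_participants=12, days_per_participant=4)
    cohort, truth = generate_minute_cohort(profile)
    return cohort, truth, profile


@pytest.fixture
def small_cohort(_cohort_cache):
    """12 participants × 4 days with known truth; fresh copies per test."""
    cohort, truth, profile = _cohort_cache
    copies = [dataclasses.replace(p, minutes=p.minutes.copy(),
                                  valid_day_flags=None) for p in cohort]
    return copies, truth, profile


def make_minute_series(ac, start="2020-03-02", participant="T1", **extra):
    """MinuteSeries from a plain count vector (padded to full days)."""
    ac = np.asarray(ac, dtype=float)
    idx = pd.date_range(start, periods=len(ac), freq="min")
    df = pd.DataFrame({"ac": ac, **extra}, index=idx)
    return MinuteSeries(participant, df)


def make_participant(ac, participant="T1", age=70.0, sex="female", bmi=27.0,
                     **extra):
    return ParticipantData(participant, age, sex, bmi,
                           make_minute_series(ac, participant=participant, **extra))
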