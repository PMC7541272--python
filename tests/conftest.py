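import numpy as np
import pytest

from ylldecomp import AgeSchedule, Instance, LifeTable, RateSchedule


@pytest.fixture
def three_bin_schedule():
    # wide bins so that bin_start + LE stays non-decreasing for the
    # steeply falling LE values used in the worked examples
    return AgeSchedule.from_starts([0.0, 30.0, 60.0])


@pytest.fixture
def three_bin_lifetable(three_bin_schedule):
    return LifeTable(three_bin_schedule, np.array([70.0, 50.0, 20.0]))


@pytest.fixture
def three_bin_instance(three_bin_schedule):
    return Instance(
        "demo",
        three_bin_schedule,
        population=np.array([200.0, 300.0, 500.0]),
        deaths=np.array([2.0, 3.0, 10.0]),
    )


def rate_schedule(schedule, dr, pw):
    return RateSchedule(schedule, np.asarray(dr, float), np.asarray(pw, float))
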