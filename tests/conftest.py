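import numpy as np
import pandas as pd
import pytest

from actiprofiles.lpa import ProfileSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_profile_separated():
    """Two well-separated profiles (5+ SD apart in every indicator)."""
    return ProfileSet(
        mu=np.array([[0.15, 0.50, 0.15, 0.50],
                     [0.05, 0.75, 0.05, 0.75]]),
        var_m=np.array([1e-4, 1e-4]),
        var_s=np.array([4e-4, 4e-4]),
        cov=np.array([-1e-5, -1e-5]),
        mixing=np.array([0.4, 0.6]),
    )


@pytest.fixture
def single_profile():
    return ProfileSet(
        mu=np.array([[0.08, 0.64, 0.08, 0.64]]),
        var_m=np.array([9e-4]),
        var_s=np.array([4.9e-3]),
        cov=np.array([-1.05e-3]),
        mixing=np.array([1.0]),
    )


def make_epoch_frame(counts, start="2022-05-03 06:00:00", epoch_s=10,
                     child_id="c1"):
    """Long epoch table from a counts array starting at a given time."""
    ts = pd.date_range(start, periods=len(counts), freq=f"{epoch_s}s")
    return pd.DataFrame({"child_id": child_id, "timestamp": ts,
                         "counts": np.asarray(counts)})
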