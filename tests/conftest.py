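import numpy as np
import pytest

from mitoabc import MeasuredSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_series(t, z1, z2, death_time=None, horizon=None):
    """Measured series with sensible defaults for summary tests."""
    t = np.asarray(t)
    if horizon is None:
        horizon = int(t[-1]) if len(t) else 0
    return MeasuredSeries(
        t=t,
        z1=np.asarray(z1),
        z2=np.asarray(z2),
        death_time=death_time,
        horizon=horizon,
    )


@pytest.fixture
def series_factory():
    return make_series
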