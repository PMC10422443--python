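import numpy as np
import pytest

from swaysense import AccelSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20230806)


def make_series(duration=6.0, rate=50.0, accel_fn=None):
    """Build an AccelSeries from a callable t -> (ax, ay, az)."""
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    if accel_fn is None:
        ax = np.zeros(n)
        ay = np.zeros(n)
        az = np.ones(n)
    else:
        ax, ay, az = accel_fn(t)
    return AccelSeries(t=t, ax=np.broadcast_to(ax, t.shape).copy(),
                       ay=np.broadcast_to(ay, t.shape).copy(),
                       az=np.broadcast_to(az, t.shape).copy())


@pytest.fixture
def static_series():
    """A motionless subject: pure 1 G gravity on the Z axis for 6 s."""
    return make_series()
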