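import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from evocgm import CGMSeries, SimParams, generate_cgm

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_series(values, interval=300.0, start="2023-01-01T00:00:00", offsets=None):
    """Regular series at the nominal grid; `offsets` adds per-reading seconds."""
    n = len(values)
    t0 = pd.Timestamp(start)
    secs = np.arange(n) * interval
    if offsets is not None:
        secs = secs + np.asarray(offsets, dtype=float)
    ts = pd.DatetimeIndex([t0 + pd.Timedelta(seconds=float(s)) for s in secs])
    return CGMSeries(ts, np.asarray(values, dtype=float), nominal_interval=interval)


@pytest.fixture
def regular_series():
    """One hour of regular 5-min readings with a mild trend."""
    vals = np.round(np.linspace(4.0, 8.0, 13), 1)
    return make_series(vals)


@pytest.fixture
def day_trace():
    """A clean synthetic day of CGM data (288 readings)."""
    return generate_cgm(SimParams(duration_days=1.0, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
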