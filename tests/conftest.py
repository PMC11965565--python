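import numpy as np
import pytest

from circapheno.preprocess import DetrendedSignal, TimeSeries

DT_H = 1.0 / 6.0  # 10-min sampling


@pytest.fixture(scope="session")
def times():
    return np.arange(0.0, 132.7, DT_H)


@pytest.fixture(scope="session")
def sine24(times):
    """Unit-amplitude 24-h sinusoid on the 10-min grid."""
    return np.sin(2 * np.pi * times / 24.0)


@pytest.fixture()
def sine24_detrended(times, sine24):
    return DetrendedSignal(times=times, detrended=sine24.copy())


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_detrended(times, values, **kw):
    return DetrendedSignal(times=np.asarray(times, float), detrended=np.asarray(values, float), **kw)


def make_timeseries(times, values, **kw):
    return TimeSeries(np.asarray(times, float), np.asarray(values, float), **kw)
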