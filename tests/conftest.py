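import numpy as np
import pytest

from sipbite.core import RunConfig, SensorStream


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def config():
    return RunConfig(seed=7)


def make_stream(n=500, fs=50.0, t0=0.0, seed=0, acc_scale=0.5, gyro_scale=20.0):
    r = np.random.default_rng(seed)
    acc = acc_scale * r.standard_normal((n, 3))
    acc[:, 2] += 9.80665
    gyro = gyro_scale * r.standard_normal((n, 3))
    return SensorStream(t0=t0, fs=fs, acc=acc, gyro=gyro)


@pytest.fixture
def small_stream():
    return make_stream()
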