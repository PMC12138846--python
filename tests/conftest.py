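import numpy as np
import pytest

from fiberglide import FiberGeometry, MotilityParams, ShutterSchedule


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def geometry():
    return FiberGeometry()  # 100 µm core, 10 µm cladding annulus


@pytest.fixture
def params():
    return MotilityParams()  # 500 nm/s, L_p 100 µm, dt 10 ms


@pytest.fixture
def schedule():
    return ShutterSchedule()  # single channel, 2.6 s / 100 ms / 10 ms / 58 s


@pytest.fixture
def schedule2():
    return ShutterSchedule(channels=("A", "B"))
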