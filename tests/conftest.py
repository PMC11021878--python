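import numpy as np
import pytest

from neuroloop.bus import BusConfig, InProcessBus, StreamServer
from neuroloop.simulator import SpikeWaveformBank, TuningModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def bus():
    return InProcessBus()


@pytest.fixture
def tuning_small():
    return TuningModel.random(n_channels=8, seed=0, velocity_scale=0.8)


@pytest.fixture
def bank_small():
    return SpikeWaveformBank.default(n_channels=8)


@pytest.fixture
def tcp_server():
    """A stream server on an ephemeral TCP port, torn down after the test."""
    server = StreamServer(BusConfig(transport="tcp", port=0)).start()
    yield server
    server.stop()
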