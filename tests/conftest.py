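import socket

import pytest

from quadpure.control import ConfigRegistry, HardwareController
from quadpure.protocol import ProtocolEngine


@pytest.fixture(scope="session")
def registry():
    return ConfigRegistry()


@pytest.fixture
def controller(registry):
    ctl = HardwareController(registry)
    ctl.set_seed(0)
    return ctl


@pytest.fixture
def histrap_engine(controller):
    """Controller with the 1 mL IMAC config loaded, plus its engine."""
    controller.load_configuration("histrap_1ml")
    return ProtocolEngine(controller)


@pytest.fixture
def free_udp_port():
    s = socket.socket(socket.AF_INET, socket.SOCK_DGRAM)
    s.bind(("127.0.0.1", 0))
    port = s.getsockname()[1]
    s.close()
    return port
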