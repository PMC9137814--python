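import pytest

from capchip import ElectrodeGeometry, MaterialStack, ReadoutConfig


@pytest.fixture
def geom() -> ElectrodeGeometry:
    return ElectrodeGeometry()


@pytest.fixture
def stack() -> MaterialStack:
    return MaterialStack()


@pytest.fixture
def readout() -> ReadoutConfig:
    return ReadoutConfig()


@pytest.fixture
def quiet_readout() -> ReadoutConfig:
    """Noise-free readout for exact-arithmetic checks."""
    return ReadoutConfig(noise_sd=0.0)
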