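import pytest

from celldose.stopping import load_water_model
from celldose.transport import CellPhantom


@pytest.fixture(scope="session")
def water_model():
    return load_water_model()


@pytest.fixture(scope="session")
def phantom():
    return CellPhantom()
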