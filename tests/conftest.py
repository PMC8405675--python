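import pytest

from thermoreg import SaturationShape, ThermoParams


@pytest.fixture
def params() -> ThermoParams:
    """Reference physical parameters (equal exchange rates, 300 K air)."""
    return ThermoParams()


@pytest.fixture
def shape() -> SaturationShape:
    """Reference saturating-function shape (p=2, v=0.5, set point 310.15 K)."""
    return SaturationShape()
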