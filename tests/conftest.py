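import numpy as np
import pytest

from oligotherm import OligomerSystem
from oligotherm.thermo import celsius_to_kelvin


@pytest.fixture
def hexadecamer():
    """Hexadecamer with the published wild-type-like dissociation parameters."""
    return OligomerSystem(kd=0.31e-6, n=16, delta_h_d=-350.0)


@pytest.fixture
def dimer():
    return OligomerSystem(kd=1.0e-6, n=2)


@pytest.fixture
def wide_grid_k():
    """Kelvin grid wide enough to capture the slow low-T tail at n = 16."""
    return celsius_to_kelvin(np.arange(-10.0, 140.001, 0.1))


@pytest.fixture
def scan_grid_k():
    """Default instrument-like scan window, kelvin."""
    return celsius_to_kelvin(np.arange(20.0, 125.001, 0.1))
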