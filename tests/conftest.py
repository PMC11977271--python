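import numpy as np
import pytest

from discsense import (
    ChannelGeometry,
    LdrModel,
    LedSource,
    OpticalMedium,
    WaveguideArray,
)
from discsense.dynamics import DropletSpec, PhaseSpec


@pytest.fixture
def array3():
    """Three 1 mm apertures, 0.3 mm gaps, first center at 15 mm."""
    return WaveguideArray(n_apertures=3, aperture_diameter_D1=1.0, gap=0.3, first_center=15.0)


@pytest.fixture
def led():
    return LedSource(voltage=3.5)


@pytest.fixture
def ldr():
    return LdrModel()


@pytest.fixture
def channel():
    return ChannelGeometry(41.0, 1.0, 2.0)


@pytest.fixture
def water_drop():
    return DropletSpec(diameter_d=1.0, specific_gravity=1.0, viscosity=1.0,
                       medium=OpticalMedium("water", 0.0))


@pytest.fixture
def oil_phase():
    return PhaseSpec(viscosity_mu=75.0, specific_gravity=0.85,
                     medium=OpticalMedium("blue oil", 0.1265))


def constant_velocity_positions(time, v_mm_s, x0):
    """Shadow positions for an exactly constant-velocity pass."""
    return x0 + v_mm_s * np.asarray(time)
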