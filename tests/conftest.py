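import numpy as np
import pytest

from ppgkit.photochem_kinetics import IrradiationSetup


@pytest.fixture
def setup_760nm() -> IrradiationSetup:
    """NIR LED: 5 mW at 760 nm into a 3 mL cuvette, 1 cm path."""
    return IrradiationSetup(
        wavelength_nm=760.0,
        incident_power_W=5e-3,
        volume_L=3e-3,
        path_length_cm=1.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20261001)
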