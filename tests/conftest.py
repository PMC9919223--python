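import numpy as np
import pytest

from qcmfilm import (BulkMedium, Layer, PowerLawMaterial, Resonator)

OVERTONES = np.array([3, 5, 7, 9, 11])


@pytest.fixture(scope="session")
def res():
    """Standard 5 MHz AT-cut resonator."""
    return Resonator(5e6, 8.8e6)


@pytest.fixture(scope="session")
def water():
    return BulkMedium.water()


@pytest.fixture(scope="session")
def soft_material():
    """The polymer-brush compliance set (J' = 0.29 MPa^-1, J'' = 1.68 MPa^-1,
    beta' = -1.61, beta'' = -0.91 at f_cen = 30 MHz, rho = 1 g/cm^3)."""
    return PowerLawMaterial.from_compliance(0.29e-6, 1.68e-6, -1.61, -0.91,
                                            f_cen=30e6, rho=1000.0)


@pytest.fixture(scope="session")
def overtones():
    return OVERTONES.copy()
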