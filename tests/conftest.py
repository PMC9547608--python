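import numpy as np
import pytest

from oaflux.acoustic import desk2d_preset


@pytest.fixture(scope="session")
def desk():
    return desk2d_preset()


@pytest.fixture(scope="session")
def disc_p0():
    """Smooth compactly supported disc on the desk phantom grid."""
    yy, xx = np.mgrid[0:64, 0:64]
    return np.clip(1 - ((yy - 32) ** 2 + (xx - 32) ** 2) / 14 ** 2, 0, None) ** 2


@pytest.fixture(scope="session")
def desk_sinogram(desk, disc_p0):
    """Noiseless unfiltered full-view sinogram of the disc phantom."""
    from oaflux.acoustic import forward_propagate
    from oaflux.optical import AbsorbedEnergyMap
    p0 = AbsorbedEnergyMap(H=disc_p0, gamma=1.0, spacing_mm=0.2)
    return forward_propagate(p0, desk.c, desk.forward_grid, desk.detectors)
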