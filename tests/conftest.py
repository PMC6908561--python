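import numpy as np
import pytest

from attenquant import CZT, VENTRI, LVGeometry, build_ac_volume
from attenquant.fixtures import phantom_czt, phantom_ventri
from attenquant.sectorization import N_SECTORS


@pytest.fixture(scope="session")
def czt_study():
    """Pinned noiseless CZT reference study."""
    return phantom_czt()


@pytest.fixture(scope="session")
def ventri_study():
    """Pinned noiseless conventional-camera reference study."""
    return phantom_ventri()


@pytest.fixture(scope="session")
def czt_shell():
    """Noiseless AC shell on the CZT grid with the default geometry."""
    return build_ac_volume(LVGeometry(), CZT)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def oracle_sector_sums(volume, slice_indices, centers, offset_deg=0.0):
    """Brute-force per-voxel angular binning, independent of the package.

    Loops over every voxel of every analyzed slice, computes its angle
    about the slice centre with plain trigonometry (0 deg at +y,
    increasing toward +x) and accumulates counts into half-open
    30-degree bins.
    """
    import math

    sums = np.zeros((len(slice_indices), N_SECTORS))
    for row, z in enumerate(slice_indices):
        cx, cy = centers[row]
        sl = volume[:, :, z]
        for i in range(sl.shape[0]):
            for j in range(sl.shape[1]):
                dx, dy = i + 0.5 - cx, j + 0.5 - cy
                ang = (math.degrees(math.atan2(dx, dy)) - offset_deg) % 360.0
                sums[row, min(int(ang // 30.0), N_SECTORS - 1)] += sl[i, j]
    return sums
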