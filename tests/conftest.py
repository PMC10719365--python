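import numpy as np
import pytest

from chromascope.io import AcquisitionSpec
from chromascope.synthetic import SyntheticSpec


@pytest.fixture
def acq():
    """Default acquisition geometry: 0.09 um lateral, 0.5 um axial."""
    return AcquisitionSpec(channel_map={"DAPI": 0, "gH2AX": 1, "CD3": 2})


@pytest.fixture
def px_spec():
    """Unit-voxel geometry, handy when oracles are stated in pixel units."""
    return AcquisitionSpec(dx_um=1.0, dy_um=1.0, dz_um=1.0, channel_map={"DAPI": 0})


@pytest.fixture
def small_synth():
    """A compact, noise-reduced synthetic field spec for fast image tests."""
    return SyntheticSpec(shape_zyx=(17, 120, 120), noise_sd=0.01)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def disc_mask(shape, center, radius):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def ellipsoid_mask(shape_zyx, center, semi_axes):
    zz, yy, xx = np.mgrid[: shape_zyx[0], : shape_zyx[1], : shape_zyx[2]]
    cz, cy, cx = center
    az, ay, ax = semi_axes
    return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
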