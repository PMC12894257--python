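import numpy as np
import pytest

from imtx import synth
from imtx.volumes import StatMap, VolumeGrid


@pytest.fixture(scope="session")
def gm_grid_6mm() -> VolumeGrid:
    """Coarse MNI-box grid with the ellipsoidal gray-matter stand-in mask."""
    return synth.synthetic_gm_mask(6.0)


@pytest.fixture(scope="session")
def smooth_map_6mm(gm_grid_6mm) -> StatMap:
    """A stationary smooth alteration map on the coarse grid."""
    field = synth.smooth_field(gm_grid_6mm, 15.0, np.random.default_rng(7))
    return StatMap(gm_grid_6mm, np.where(gm_grid_6mm.mask, field, 0.0), "z")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
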