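import numpy as np
import pytest

from emphyhet import LabeledVolume


def make_volume(image, lobes, spacing=(0.7, 0.7, 0.625)):
    """Build a LabeledVolume from (possibly 2D) arrays, promoting to 3D."""
    image = np.asarray(image, dtype=float)
    lobes = np.asarray(lobes, dtype=np.int16)
    if image.ndim == 2:
        image = image[:, :, None]
        lobes = lobes[:, :, None]
    return LabeledVolume(image=image, lobes=lobes, spacing=spacing)


@pytest.fixture
def toy_volume():
    """Two-slice volume with hand-placed LAA voxels in lobes 1 and 5.

    Slice 0: a 3x3 block of -980 HU in lobe 1 (LUL); slice 1: one voxel
    of -960 HU in lobe 5 (RLL).  Everything else is -850 HU parenchyma.
    """
    shape = (10, 10, 2)
    image = np.full(shape, -850.0)
    lobes = np.zeros(shape, dtype=np.int16)
    lobes[1:6, 1:6, :] = 1      # LUL
    lobes[6:9, 1:4, :] = 2      # LLL
    lobes[1:4, 6:9, :] = 3      # RUL
    lobes[4:6, 6:9, :] = 4      # RML
    lobes[6:9, 6:9, :] = 5      # RLL
    image[2:5, 2:5, 0] = -980.0  # 9-voxel cluster in LUL, slice 0
    image[7, 7, 1] = -960.0      # single voxel in RLL, slice 1
    return make_volume(image, lobes)
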