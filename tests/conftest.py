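import numpy as np
import pytest

import calcimorph as cm
from calcimorph.segment import LabeledMask


@pytest.fixture
def voxel_sphere():
    """Factory: labeled mask holding one voxelized sphere of radius r voxels,
    centred on a voxel centre (lattice-aligned, the best-behaved case)."""

    def make(r_vox: float, voxel_size: float = 0.035, pad: int = 6) -> LabeledMask:
        n = int(2 * np.ceil(r_vox)) + 2 * pad
        c = (n // 2 + 0.5) * voxel_size
        spec = cm.ShapeSpec("sphere", (c, c, c), {"radius": r_vox * voxel_size})
        mask = cm.voxelize(spec, voxel_size, (n, n, n))
        return LabeledMask(mask.data.astype(np.int32), voxel_size)

    return make


@pytest.fixture
def labeled_mask():
    """Factory: wrap any boolean array as a single-object labeled mask."""

    def make(mask: np.ndarray, voxel_size: float = 0.035) -> LabeledMask:
        return LabeledMask(np.asarray(mask, bool).astype(np.int32), voxel_size)

    return make


@pytest.fixture
def two_sphere_core():
    """Noise-free three-intensity core phantom with two spheres, plus the
    ground-truth foreground union."""
    vs = 0.07
    s1 = cm.ShapeSpec("sphere", (1.0, 1.0, 1.0), {"radius": 0.3})
    s2 = cm.ShapeSpec("sphere", (2.5, 1.0, 1.0), {"radius": 0.2})
    vol, truth = cm.make_core_phantom(
        [s1, s2], vs, core_diameter_mm=2.0, core_length_mm=3.2
    )
    union = np.zeros(vol.shape, dtype=bool)
    for s in (s1, s2):
        union |= cm.voxelize(s, vs, vol.shape).data
    return vol, union, (s1, s2)
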