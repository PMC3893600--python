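"""Fixed analysis constants of the reference acquisition protocol.

The scanner delivered isotropic 35 μm voxels.  An object qualifies as a
microcalcification only below 1 mm maximum diameter; objects of two image
voxels or fewer are sub-resolution (counted but not measured); and the
mammographic visibility cut-off is the volume of a 0.2 mm-diameter sphere
(two 0.1 mm mammography pixels across), ≈ 0.0042 mm³.
"""

from __future__ import annotations

import math

#: isotropic voxel edge length of the reference scans, mm
VOXEL_SIZE_MM = 0.035

#: objects with <= this many voxels are sub-resolution
MIN_OBJECT_VOXELS = 2

#: objects with max Feret diameter above this are macrocalcifications, mm
MAX_DIAMETER_MM = 1.0

#: significance level used throughout the cohort statistics
ALPHA = 0.05


def visibility_threshold_mm3(diameter_mm: float = 0.2) -> float:
    """Volume of a sphere of the given diameter: the smallest object that
    might be visible on mammography (default 0.2 mm → ≈ 0.0042 mm³)."""
    r = diameter_mm / 2.0
    return (4.0 / 3.0) * math.pi * r**3


def min_measurable_volume_mm3(
    voxel_size_mm: float = VOXEL_SIZE_MM, n_voxels: int = MIN_OBJECT_VOXELS
) -> float:
    """Volume of ``n_voxels`` voxels: the sub-resolution bound
    (2 voxels at 35 μm → ≈ 0.000086 mm³)."""
    return n_voxels * voxel_size_mm**3


#: mammographic visibility threshold, mm^3 (rounded as conventionally quoted)
VISIBILITY_THRESHOLD_MM3 = round(visibility_threshold_mm3(), 4)
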