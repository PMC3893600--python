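"""Measure the six structural parameters of analytically known objects.

Builds voxelized archetypes (sphere, rod, plate) at 35 um resolution,
runs the per-object morphometry and prints measured vs analytic values.
SMI sits near 4 for the sphere, near 3 for the rod and below 1 for the
thin plate; structure thickness recovers the diameter / thickness within
about one voxel.
"""

import math

import calcimorph as cm
from calcimorph.segment import LabeledMask

VS = 0.035  # mm, the reference scanner resolution

shapes = {
    "sphere (r = 0.35 mm)": (
        cm.ShapeSpec("sphere", (1.0, 1.0, 1.0), {"radius": 0.35}),
        (60, 60, 60),
    ),
    "rod (r = 0.15, L = 1.5 mm)": (
        cm.ShapeSpec("rod", (1.05, 0.5, 0.5), {"radius": 0.15, "length": 1.5}),
        (62, 30, 30),
    ),
    "plate (0.07 x 1.4 x 1.4 mm)": (
        cm.ShapeSpec("plate", (0.14, 0.8, 0.8), {"thickness": 0.07,
                                                 "width": 1.4, "height": 1.4}),
        (8, 46, 46),
    ),
}

for label, (spec, grid) in shapes.items():
    mask = cm.voxelize(spec, VS, grid)
    labels = LabeledMask(mask.data.astype(int), VS)
    m = cm.measure_object(labels, 1)
    print(f"\n{label}")
    print(f"  Obj.V    {m.volume_mm3:8.5f} mm^3   (analytic {spec.analytic_volume():.5f})")
    print(f"  Obj.S    {m.surface_mm2:8.5f} mm^2   (analytic {spec.analytic_surface():.5f})")
    print(f"  Obj.S/V  {m.sv_ratio_per_mm:8.3f} 1/mm")
    print(f"  St.Th    {m.thickness_mm:8.4f} mm     (analytic {spec.analytic_thickness():.4f})")
    print(f"  SMI      {m.smi:8.3f}        (ideal {spec.smi_class():.0f})")
    print(f"  voxels   {m.voxel_count}, max Feret {m.feret_mm:.3f} mm")

print(
    "\nSMI orders the archetypes (plate < rod < sphere); finite extents and"
    "\nvoxelization keep measured values off the ideal limits 0 / 3 / 4."
)
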