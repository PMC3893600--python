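"""Per-object 3D structural parameters.

For every segmented calcification the pipeline reports:

* ``Obj.V`` — volume (mm³) enclosed by the marching-cubes isosurface,
  via the divergence theorem over the closed triangle mesh;
* ``Obj.S`` — surface area (mm²) of the same mesh;
* ``Obj.S/Obj.V`` — surface-to-volume ratio (mm⁻¹), a smoothness measure;
* ``St.Th`` — structure thickness (mm): the volume-weighted mean, over
  object voxels, of the diameter of the largest inscribed sphere covering
  each voxel (Hildebrand–Rüegsegger local thickness, computed from the
  Euclidean distance transform by sphere painting);
* ``SMI`` — structure model index ``6·V·S′/S²`` with ``S′ = dS/dr``
  estimated by displacing each mesh vertex a small step along its outward
  normal: 0 for an ideal plate, 3 for an ideal rod, 4 for an ideal sphere;
  convex mixtures fall in between, concave structures may go negative and
  are reported unclamped;
* maximum Feret diameter (mm) and voxel count.

Meshes come from marching cubes at iso-level 0.5 on the object's binary
subgrid padded by one background voxel, so objects touching the volume
border can never produce an open surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh
from scipy import ndimage
from skimage.measure import marching_cubes

from .segment import LabeledMask, max_feret_diameter_mm

__all__ = [
    "ObjectMorphometry",
    "mesh_object",
    "mesh_volume",
    "mesh_surface",
    "structure_thickness",
    "local_thickness_map",
    "smi",
    "smi_from_rates",
    "measure_object",
    "measure_all",
    "export_mesh",
]


@dataclass
class ObjectMorphometry:
    """One object's structural parameters (units in field names)."""

    object_id: int
    volume_mm3: float
    surface_mm2: float
    sv_ratio_per_mm: float
    thickness_mm: float
    smi: float
    voxel_count: int
    feret_mm: float
    centroid_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not (self.volume_mm3 > 0 and self.surface_mm2 > 0):
            raise ValueError("volume and surface must be positive")
        if not np.isfinite(self.smi):
            raise ValueError("SMI must be finite")


#: pre-mesh smoothing of the binary indicator, in voxels.  Marching cubes on
#: raw binary data overestimates surface area by ~8-9% (staircase bias); a
#: light Gaussian brings the sphere-surface error under 5% while moving the
#: enclosed volume by ~0.1%.
MESH_SMOOTHING_SIGMA_VOX = 0.5


def mesh_object(labels: LabeledMask, object_id: int) -> trimesh.Trimesh:
    """Marching-cubes surface of one object, vertices in mm world coordinates.

    The object's bounding subgrid is padded by two background voxels, the
    binary indicator is lightly smoothed (see
    :data:`MESH_SMOOTHING_SIGMA_VOX`) and the isosurface is taken at 0.5 —
    guaranteeing a closed, consistently oriented surface.  Structures so
    thin that smoothing would erode them (the smoothed field drops below
    the iso-level over a substantial part of the object) are meshed from
    the raw binary grid instead.  Objects of fewer than 3 voxels are too
    small to mesh.
    """
    mask = labels.object_mask(object_id)
    nvox = int(mask.sum())
    if nvox < 3:
        raise ValueError(
            f"object {object_id} has {nvox} voxels: too small to mesh"
        )
    idx = np.argwhere(mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    pad = 2
    sub = np.zeros(tuple(hi - lo + 2 * pad), dtype=np.float32)
    core = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    sub[pad:-pad, pad:-pad, pad:-pad] = core
    field = ndimage.gaussian_filter(sub, MESH_SMOOTHING_SIGMA_VOX)
    # thin structures: smoothing must not swallow the object
    kept = field[pad:-pad, pad:-pad, pad:-pad][core] > 0.5
    if kept.mean() < 0.7:
        field = sub
    vs = labels.voxel_size
    verts, faces, _, _ = marching_cubes(field, level=0.5, spacing=(vs, vs, vs))
    # local index j maps to global index lo - pad + j; voxel centre world
    # coordinate is (i + 0.5)*vs, so the subgrid origin is (lo - pad + 0.5)*vs
    verts = verts + (lo - pad + 0.5) * vs
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def _require_closed(mesh: trimesh.Trimesh) -> None:
    if len(mesh.faces) == 0 or not mesh.is_watertight:
        raise ValueError("mesh is not a closed surface")


def mesh_volume(mesh: trimesh.Trimesh) -> float:
    """Enclosed volume (mm³) by the divergence theorem; mesh must be closed.

    A mirror-oriented (inside-out) mesh is sign-corrected with a warning.
    """
    _require_closed(mesh)
    vol = float(mesh.volume)
    if vol < 0:
        import warnings

        warnings.warn("mesh was inside-out; volume sign corrected", stacklevel=2)
        vol = -vol
    if vol == 0:
        raise ValueError("mesh encloses zero volume")
    return vol


def mesh_surface(mesh: trimesh.Trimesh) -> float:
    """Total triangle area (mm²); degenerate zero-area triangles are ignored."""
    if len(mesh.faces) == 0:
        raise ValueError("mesh has no triangles")
    return float(mesh.area)


def _triangle_area(vertices: np.ndarray, faces: np.ndarray) -> float:
    tri = vertices[faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    return float(0.5 * np.linalg.norm(cross, axis=1).sum())


def smi_from_rates(volume: float, surface: float, surface_derivative: float) -> float:
    """Structure model index from volume, surface and dS/dr: ``6·V·S′/S²``.

    Closed-form checks: a sphere (S = 4πr², V = 4πr³/3, S′ = 8πr) gives 4,
    an infinite rod per unit length (S = 2πr, V = πr², S′ = 2π) gives 3,
    an infinite plate (S′ = 0) gives 0.
    """
    if not (volume > 0 and surface > 0):
        raise ValueError("volume and surface must be positive")
    return 6.0 * volume * surface_derivative / surface**2


def smi(
    mesh: trimesh.Trimesh,
    volume: float | None = None,
    surface: float | None = None,
    epsilon_fraction: float = 1e-3,
) -> float:
    """SMI by differential analysis of the triangulated surface.

    Each vertex is displaced by ``ε`` along its outward normal
    (``ε = epsilon_fraction × mean edge length``, keeping the estimate
    scale-invariant) and the area derivative ``S′ ≈ (S(ε) − S)/ε`` is fed
    into ``6·V·S′/S²``.  The value is reported unclamped.
    """
    _require_closed(mesh)
    v = mesh_volume(mesh) if volume is None else volume
    s = mesh_surface(mesh) if surface is None else surface
    eps = epsilon_fraction * float(mesh.edges_unique_length.mean())
    displaced = mesh.vertices + eps * mesh.vertex_normals
    s_eps = _triangle_area(np.asarray(displaced), np.asarray(mesh.faces))
    s_prime = (s_eps - s) / eps
    return smi_from_rates(v, s, s_prime)


def local_thickness_map(object_mask: np.ndarray, voxel_size: float = 1.0) -> np.ndarray:
    """Local thickness τ(p) for every voxel of a binary object, in mm.

    Let ``EDT(c)`` be the distance from object voxel c to the nearest
    background voxel centre (the grid border counts as background).  The
    maximal inscribed sphere centred at c has continuum radius
    ``ρ_c = EDT(c) − 0.5`` (the object boundary lies halfway between
    foreground and background centres), and a voxel p is covered by that
    sphere when ``|p − c| ≤ EDT(c)`` (its cube intersects the sphere).
    Then ``τ(p) = 2·max{ρ_c : |p − c| ≤ EDT(c)}``, computed by painting
    spheres in decreasing radius order.  Consequences of the convention:
    a 1-voxel object has τ = 1 voxel, a radius-r rod τ ≈ 2r, a t-voxel
    plate τ ≈ t, a d-voxel sphere τ within ~1 voxel of d.
    """
    mask = np.asarray(object_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty object")
    padded = np.pad(mask, 1)
    edt = ndimage.distance_transform_edt(padded)

    tau = np.zeros_like(edt)
    coords = np.argwhere(padded)
    dists = edt[padded]
    order = np.argsort(-dists)  # paint the biggest spheres first
    shape = np.array(padded.shape)
    for k in order:
        c = coords[k]
        e = dists[k]
        diam = 2.0 * (e - 0.5)
        if e <= 1.0 and tau[tuple(c)] >= diam:
            # a boundary voxel's sphere only covers itself and its face
            # neighbours; skipping it once covered cannot change any τ
            # that the exhaustive definition would produce
            continue
        r_int = int(np.floor(e))
        lo = np.maximum(c - r_int, 0)
        hi = np.minimum(c + r_int + 1, shape)
        zz, yy, xx = np.meshgrid(
            *(np.arange(l, h) for l, h in zip(lo, hi)), indexing="ij"
        )
        d2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
        ball = np.sqrt(d2) <= e
        region = tau[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        np.maximum(region, np.where(ball, diam, 0.0), out=region)
    return tau[1:-1, 1:-1, 1:-1][mask] * voxel_size


def structure_thickness(labels: LabeledMask, object_id: int) -> float:
    """St.Th: mean local thickness over the object's voxels, in mm."""
    tau = local_thickness_map(labels.object_mask(object_id), labels.voxel_size)
    return float(tau.mean())


def measure_object(labels: LabeledMask, object_id: int) -> ObjectMorphometry:
    """Assemble all structural parameters for one object."""
    mask = labels.object_mask(object_id)
    mesh = mesh_object(labels, object_id)
    v = mesh_volume(mesh)
    s = mesh_surface(mesh)
    centroid = (np.argwhere(mask).mean(axis=0) + 0.5) * labels.voxel_size
    return ObjectMorphometry(
        object_id=object_id,
        volume_mm3=v,
        surface_mm2=s,
        sv_ratio_per_mm=s / v,
        thickness_mm=structure_thickness(labels, object_id),
        smi=smi(mesh, volume=v, surface=s),
        voxel_count=int(mask.sum()),
        feret_mm=max_feret_diameter_mm(mask, labels.voxel_size),
        centroid_mm=tuple(float(c) for c in centroid),
    )


def measure_all(
    labels: LabeledMask, min_voxels: int = 2
) -> list[ObjectMorphometry]:
    """Measure every object above the sub-resolution bound (> ``min_voxels``)."""
    counts = labels.voxel_counts()
    return [
        measure_object(labels, oid)
        for oid in range(1, labels.n_objects + 1)
        if counts[oid - 1] > min_voxels
    ]


def export_mesh(mesh: trimesh.Trimesh, path: str | Path) -> None:
    """Write a mesh as binary PLY or STL (by file extension)."""
    if len(mesh.faces) == 0:
        raise ValueError("refusing to export a mesh with no triangles")
    path = Path(path)
    if path.suffix.lower() not in (".ply", ".stl"):
        raise ValueError(f"unsupported mesh format {path.suffix!r} (use .ply or .stl)")
    path.parent.mkdir(parents=True, exist_ok=True)
    mesh.export(path)
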