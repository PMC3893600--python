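"""Synthetic biopsy-core phantoms with analytically known calcifications.

Real vacuum-assisted biopsy cores are 3 mm × 23 mm tissue cylinders scanned
in formalin.  The generator emulates a reconstructed core: a soft-tissue
cylinder against a formalin background, carrying high-intensity calcified
objects of controlled geometry, followed by an isotropic Gaussian blur
(point-spread stand-in) and additive Gaussian intensity noise.

Every primitive has a closed-form ground truth where one exists (sphere,
finite cylinder "rod", box "plate", ellipsoid volume), so the whole
segmentation → morphometry → statistics pipeline can be validated without
real scans.  Voxelization uses the voxel-centre inclusion rule: a voxel is
foreground iff its centre lies inside the analytic solid; partial volume is
produced by the blur stage, not by the voxelizer.

Shape stand-ins for morphologies seen in breast disease:

* ``teacup_shell`` — a spherical-cap shell (milk-of-calcium / fibrocystic
  "teacup" sediment);
* ``popcorn`` — a union of overlapping spheres (fibroadenoma-associated
  coarse calcification);
* ``v_branch`` — two capsules sharing an endpoint (branching casting-type
  calcification of ductal carcinoma in situ).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .io import BinaryMask, VoxelVolume, load_reference_morphometry

__all__ = [
    "ShapeSpec",
    "PhantomGroundTruth",
    "CohortSpec",
    "voxelize",
    "make_core_phantom",
    "make_cohort",
    "sample_subject_summaries",
    "DEFAULT_INTENSITIES",
]

KINDS = ("sphere", "ellipsoid", "rod", "plate", "teacup_shell", "v_branch", "popcorn")

#: 8-bit-scale phantom intensities: formalin background, soft tissue,
#: calcification (calcium is by far the most radiodense constituent).
DEFAULT_INTENSITIES = {"background": 50.0, "tissue": 90.0, "calcification": 200.0}

# ideal structure-model-index values by archetype
SMI_SPHERE, SMI_ROD, SMI_PLATE = 4.0, 3.0, 0.0


@dataclass
class ShapeSpec:
    """One analytic calcification primitive.

    ``center`` is in mm, (z, y, x) world order.  ``params`` are in mm (see
    module docstring); ``euler_deg`` rotates the local frame (intrinsic
    z-y-x Euler angles, degrees).
    """

    kind: str
    center: tuple[float, float, float]
    params: dict[str, float] = field(default_factory=dict)
    euler_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown shape kind {self.kind!r}; expected one of {KINDS}")
        for key, val in self.params.items():
            if key in ("n_lobes", "seed"):
                continue
            if not (val > 0):
                raise ValueError(f"{self.kind}.{key} must be > 0, got {val}")
        p = self.params
        if self.kind == "sphere":
            self._need(p, "radius")
        elif self.kind == "ellipsoid":
            self._need(p, "a", "b", "c")
        elif self.kind == "rod":
            self._need(p, "radius", "length")
        elif self.kind == "plate":
            self._need(p, "thickness", "width", "height")
        elif self.kind == "teacup_shell":
            self._need(p, "radius", "thickness", "cap_angle_deg")
            if not (0 < p["cap_angle_deg"] <= 180):
                raise ValueError("cap_angle_deg must be in (0, 180]")
        elif self.kind == "v_branch":
            self._need(p, "radius", "length", "angle_deg")
            if not (0 < p["angle_deg"] < 180):
                raise ValueError("v_branch angle must be in (0, 180) degrees")
        elif self.kind == "popcorn":
            self._need(p, "n_lobes", "lobe_radius_min", "lobe_radius_max")
            if int(p["n_lobes"]) < 1:
                raise ValueError("popcorn needs at least one lobe")
            if p["lobe_radius_max"] < p["lobe_radius_min"]:
                raise ValueError("lobe_radius_max < lobe_radius_min")
            rng = np.random.default_rng(int(p.get("seed", 0)))
            n = int(p["n_lobes"])
            self._lobe_r = rng.uniform(p["lobe_radius_min"], p["lobe_radius_max"], n)
            # lobe centres packed within ~0.8 of the largest radius
            self._lobe_c = rng.uniform(-0.8, 0.8, (n, 3)) * self._lobe_r.max()
            self._lobe_c[0] = 0.0

    @staticmethod
    def _need(p: dict, *keys: str) -> None:
        missing = [k for k in keys if k not in p]
        if missing:
            raise ValueError(f"missing shape parameters: {missing}")

    # -- geometry ---------------------------------------------------------

    @property
    def _rotation(self) -> Rotation:
        return Rotation.from_euler("zyx", self.euler_deg, degrees=True)

    @property
    def bounding_radius(self) -> float:
        """Radius of a ball around ``center`` guaranteed to contain the shape."""
        p = self.params
        if self.kind == "sphere":
            return p["radius"]
        if self.kind == "ellipsoid":
            return max(p["a"], p["b"], p["c"])
        if self.kind == "rod":
            return math.hypot(p["length"] / 2, p["radius"])
        if self.kind == "plate":
            return 0.5 * math.sqrt(p["thickness"] ** 2 + p["width"] ** 2 + p["height"] ** 2)
        if self.kind == "teacup_shell":
            return p["radius"] + p["thickness"]
        if self.kind == "v_branch":
            return p["length"] + p["radius"]
        if self.kind == "popcorn":
            return float(np.max(np.linalg.norm(self._lobe_c, axis=1) + self._lobe_r))
        raise AssertionError(self.kind)

    def contains(self, points_mm: np.ndarray) -> np.ndarray:
        """Vectorized membership test for world points, shape (N, 3) in (z,y,x) mm."""
        q = np.asarray(points_mm, dtype=float) - np.asarray(self.center)
        q = self._rotation.inv().apply(q)
        p = self.params
        if self.kind == "sphere":
            return np.einsum("ij,ij->i", q, q) <= p["radius"] ** 2
        if self.kind == "ellipsoid":
            axes = np.array([p["a"], p["b"], p["c"]])
            s = q / axes
            return np.einsum("ij,ij->i", s, s) <= 1.0
        if self.kind == "rod":
            half = p["length"] / 2
            return (np.abs(q[:, 0]) <= half) & (q[:, 1] ** 2 + q[:, 2] ** 2 <= p["radius"] ** 2)
        if self.kind == "plate":
            half = np.array([p["thickness"], p["width"], p["height"]]) / 2
            return np.all(np.abs(q) <= half, axis=1)
        if self.kind == "teacup_shell":
            r = np.linalg.norm(q, axis=1)
            with np.errstate(invalid="ignore"):
                # polar angle from the local -z axis (cup opens upward)
                cos_theta = np.where(r > 0, -q[:, 0] / np.maximum(r, 1e-300), 1.0)
            in_shell = (r >= p["radius"]) & (r <= p["radius"] + p["thickness"])
            return in_shell & (cos_theta >= math.cos(math.radians(p["cap_angle_deg"])))
        if self.kind == "v_branch":
            half_angle = math.radians(p["angle_deg"]) / 2
            d1 = np.array([math.cos(half_angle), math.sin(half_angle), 0.0])
            d2 = np.array([math.cos(half_angle), -math.sin(half_angle), 0.0])
            out = np.zeros(len(q), dtype=bool)
            for d in (d1, d2):
                t = np.clip(q @ d, 0.0, p["length"])
                closest = t[:, None] * d
                out |= np.einsum("ij,ij->i", q - closest, q - closest) <= p["radius"] ** 2
            return out
        if self.kind == "popcorn":
            out = np.zeros(len(q), dtype=bool)
            for c, r in zip(self._lobe_c, self._lobe_r):
                d = q - c
                out |= np.einsum("ij,ij->i", d, d) <= r**2
            return out
        raise AssertionError(self.kind)

    # -- closed forms -----------------------------------------------------

    def analytic_volume(self) -> float | None:
        p = self.params
        if self.kind == "sphere":
            return (4 / 3) * math.pi * p["radius"] ** 3
        if self.kind == "ellipsoid":
            return (4 / 3) * math.pi * p["a"] * p["b"] * p["c"]
        if self.kind == "rod":
            return math.pi * p["radius"] ** 2 * p["length"]
        if self.kind == "plate":
            return p["thickness"] * p["width"] * p["height"]
        return None

    def analytic_surface(self) -> float | None:
        p = self.params
        if self.kind == "sphere":
            return 4 * math.pi * p["radius"] ** 2
        if self.kind == "rod":
            return 2 * math.pi * p["radius"] * p["length"] + 2 * math.pi * p["radius"] ** 2
        if self.kind == "plate":
            t, w, h = p["thickness"], p["width"], p["height"]
            return 2 * (t * w + t * h + w * h)
        return None

    def analytic_thickness(self) -> float | None:
        """Mean local thickness of the ideal solid (sphere: diameter; rod:
        diameter; plate: plate thickness)."""
        p = self.params
        if self.kind == "sphere":
            return 2 * p["radius"]
        if self.kind == "rod":
            return 2 * p["radius"]
        if self.kind == "plate":
            return p["thickness"]
        return None

    def smi_class(self) -> float | None:
        if self.kind == "sphere":
            return SMI_SPHERE
        if self.kind in ("rod", "v_branch"):
            return SMI_ROD
        if self.kind == "plate":
            return SMI_PLATE
        return None


@dataclass
class PhantomGroundTruth:
    """Per-object analytic truth for one phantom volume."""

    shapes: list[ShapeSpec]
    table: pd.DataFrame  # one row per object

    @property
    def n_objects(self) -> int:
        return len(self.shapes)


def voxelize(shape: ShapeSpec, voxel_size: float, grid_shape: tuple[int, int, int]) -> BinaryMask:
    """Rasterize a shape: foreground iff the voxel centre is inside the solid.

    The shape must keep a >= 2-voxel clear margin to the grid boundary so
    that downstream morphometry never sees a clipped object.
    """
    if not (voxel_size > 0):
        raise ValueError("voxel_size must be > 0")
    grid_shape = tuple(int(s) for s in grid_shape)
    mask = np.zeros(grid_shape, dtype=bool)
    # evaluate only within the shape's bounding box (plus one voxel slack)
    c_vox = np.asarray(shape.center) / voxel_size - 0.5
    r_vox = shape.bounding_radius / voxel_size + 1.0
    lo = np.maximum(np.floor(c_vox - r_vox).astype(int), 0)
    hi = np.minimum(np.ceil(c_vox + r_vox).astype(int) + 1, grid_shape)
    if np.any(lo >= hi):
        raise ValueError("shape lies outside the grid")
    zz, yy, xx = np.meshgrid(*(np.arange(l, h) for l, h in zip(lo, hi)), indexing="ij")
    centers = (np.stack([zz, yy, xx], axis=-1).reshape(-1, 3) + 0.5) * voxel_size
    inside = shape.contains(centers).reshape(zz.shape)
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = inside
    if not mask.any():
        # sub-voxel shape: rasterize to the voxel containing its centre so
        # that sub-resolution calcifications remain countable objects
        ctr = np.floor(np.asarray(shape.center) / voxel_size).astype(int)
        if np.any(ctr < 0) or np.any(ctr >= grid_shape):
            raise ValueError(f"{shape.kind} at {shape.center} lies outside the grid")
        mask[tuple(ctr)] = True
    idx = np.argwhere(mask)
    if (idx.min(axis=0) < 2).any() or (idx.max(axis=0) >= np.array(grid_shape) - 2).any():
        raise ValueError(
            f"{shape.kind} at {shape.center} violates the 2-voxel boundary margin"
        )
    return BinaryMask(mask, voxel_size)


_TRUTH_COLUMNS = [
    "object_id", "kind", "center_z_mm", "center_y_mm", "center_x_mm",
    "true_volume_mm3", "true_surface_mm2", "true_thickness_mm",
    "ideal_smi", "voxel_count",
]


def _ground_truth_table(shapes: list[ShapeSpec], counts: list[int]) -> pd.DataFrame:
    if not shapes:
        return pd.DataFrame(columns=_TRUTH_COLUMNS)
    rows = []
    for i, (s, n) in enumerate(zip(shapes, counts), start=1):
        rows.append(
            {
                "object_id": i,
                "kind": s.kind,
                "center_z_mm": s.center[0],
                "center_y_mm": s.center[1],
                "center_x_mm": s.center[2],
                "true_volume_mm3": s.analytic_volume(),
                "true_surface_mm2": s.analytic_surface(),
                "true_thickness_mm": s.analytic_thickness(),
                "ideal_smi": s.smi_class(),
                "voxel_count": n,
            }
        )
    return pd.DataFrame(rows)


def make_core_phantom(
    shapes: list[ShapeSpec],
    voxel_size: float,
    intensities: dict[str, float] | None = None,
    blur_sigma_mm: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    core_diameter_mm: float = 3.0,
    core_length_mm: float = 23.0,
    name: str = "phantom",
) -> tuple[VoxelVolume, PhantomGroundTruth]:
    """Build a blurred, noisy grayscale biopsy-core volume plus ground truth.

    The tissue cylinder (``core_diameter_mm`` × ``core_length_mm``, axis
    along z) sits in a formalin background; calcifications must be pairwise
    disjoint after voxelization.  With ``blur_sigma_mm = noise_sigma = 0``
    a mid-intensity threshold recovers the union of voxelized shapes
    exactly.
    """
    inten = dict(DEFAULT_INTENSITIES)
    if intensities:
        inten.update(intensities)
    if not (inten["calcification"] > inten["tissue"] > inten["background"]):
        raise ValueError("need calcification > tissue > background intensity")

    margin = 4  # voxels of formalin padding around the core
    ny = nx = int(math.ceil(core_diameter_mm / voxel_size)) + 2 * margin
    nz = int(math.ceil(core_length_mm / voxel_size)) + 2 * margin
    grid_shape = (nz, ny, nx)

    # soft-tissue cylinder along z, centred in the xy plane
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    cy = cx = (ny - 1) / 2.0
    tissue_2d = ((yy - cy) ** 2 + (xx - cx) ** 2) <= (core_diameter_mm / 2 / voxel_size) ** 2
    vol = np.full(grid_shape, inten["background"], dtype=np.float32)
    vol[margin : nz - margin, tissue_2d] = inten["tissue"]

    masks = [voxelize(s, voxel_size, grid_shape) for s in shapes]
    occupancy = np.zeros(grid_shape, dtype=np.uint16)
    for m in masks:
        occupancy += m.data
    if occupancy.max() > 1:  # identify the colliding pair for the error
        for i in range(len(masks)):
            for j in range(i + 1, len(masks)):
                if np.any(masks[i].data & masks[j].data):
                    raise ValueError(
                        f"shapes {i + 1} ({shapes[i].kind}) and {j + 1} "
                        f"({shapes[j].kind}) overlap after voxelization"
                    )
    calc = occupancy > 0
    vol[calc] = inten["calcification"]

    if blur_sigma_mm > 0:
        vol = ndimage.gaussian_filter(vol, sigma=blur_sigma_mm / voxel_size)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        vol = vol + rng.normal(0.0, noise_sigma, size=vol.shape).astype(np.float32)

    truth = PhantomGroundTruth(
        shapes=list(shapes),
        table=_ground_truth_table(shapes, [int(m.data.sum()) for m in masks]),
    )
    return VoxelVolume(np.asarray(vol, dtype=np.float32), voxel_size, name=name), truth


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortSpec:
    """Group-structured phantom cohort mirroring the benign/malignant
    contrast of the reference study: benign cores carry fewer, larger
    calcifications; malignant cores more numerous, smaller ones.

    Counts are gamma-Poisson (negative binomial) with the reference
    per-subject means (benign 36.6, malignant 69.0); object volumes are
    log-normal in mm³ with group means matching the reference per-subject
    averages (benign 0.0159 mm³, malignant 0.0078 mm³ at sigma_log 1.5).
    """

    n_benign: int = 5
    n_malignant: int = 6
    count_mean: dict[str, float] = field(
        default_factory=lambda: {"benign": 36.6, "malignant": 69.0}
    )
    count_dispersion: float = 3.0  # NB shape k; var = m + m^2/k
    volume_log_mean: dict[str, float] = field(
        default_factory=lambda: {
            "benign": math.log(0.0159) - 1.125,   # lognormal mean 0.0159 mm^3
            "malignant": math.log(0.0078) - 1.125,  # lognormal mean 0.0078 mm^3
        }
    )
    volume_log_sigma: float = 1.5
    shape_mix: dict[str, float] = field(
        default_factory=lambda: {"rod": 0.5, "sphere": 0.2, "ellipsoid": 0.15, "plate": 0.15}
    )
    blur_sigma_mm: float = 0.0
    noise_sigma: float = 0.0
    voxel_size: float = 0.035
    core_diameter_mm: float = 3.0
    core_length_mm: float = 23.0
    max_volume_mm3: float = 0.05  # rejection cap so objects fit the core
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.shape_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"shape_mix proportions must sum to 1, got {total}")
        unknown = set(self.shape_mix) - set(KINDS)
        if unknown:
            raise ValueError(f"unknown shapes in mix: {sorted(unknown)}")


def _shape_from_volume(kind: str, volume: float, center, rng: np.random.Generator) -> ShapeSpec:
    """Construct a randomly oriented primitive of the given analytic volume."""
    euler = tuple(rng.uniform(0, 360, 3))
    if kind == "sphere":
        params = {"radius": (3 * volume / (4 * math.pi)) ** (1 / 3)}
        euler = (0.0, 0.0, 0.0)
    elif kind == "rod":
        r = (volume / (6 * math.pi)) ** (1 / 3)  # aspect ratio L = 6 r
        params = {"radius": r, "length": 6 * r}
    elif kind == "ellipsoid":
        base = (3 * volume / (4 * math.pi * 1.0 * 1.5 * 2.5)) ** (1 / 3)
        params = {"a": base, "b": 1.5 * base, "c": 2.5 * base}
    elif kind == "plate":
        t = (volume / 36.0) ** (1 / 3)  # aspect ratio t : 6t : 6t
        params = {"thickness": t, "width": 6 * t, "height": 6 * t}
    else:
        raise ValueError(f"cohort sampling does not support kind {kind!r}")
    return ShapeSpec(kind, center, params, euler)


def _place_shapes(spec: CohortSpec, n_objects: int, group: str, rng: np.random.Generator) -> list[ShapeSpec]:
    """Rejection-sample non-overlapping object placements inside the core.

    Disjointness is enforced on bounding spheres (conservative; the
    rasterizer re-checks exactly).  If a drawn object cannot be placed,
    its volume and kind are periodically redrawn — size/shape draws are
    thereby conditioned on feasibility within the remaining space — and a
    bounded total attempt budget turns a genuinely full core into an error.
    """
    margin_mm = 2 * spec.voxel_size
    core_r = spec.core_diameter_mm / 2
    kinds = list(spec.shape_mix)
    probs = np.array([spec.shape_mix[k] for k in kinds])
    shapes: list[ShapeSpec] = []
    bounds: list[tuple[np.ndarray, float]] = []
    # world origin of the tissue cylinder (see make_core_phantom margins)
    pad = 4 * spec.voxel_size
    cxy = pad + core_r

    def draw_kind_volume():
        vol = float(
            np.clip(
                rng.lognormal(spec.volume_log_mean[group], spec.volume_log_sigma),
                1e-7,
                spec.max_volume_mm3,
            )
        )
        return kinds[rng.choice(len(kinds), p=probs)], vol

    for _ in range(n_objects):
        kind, vol = draw_kind_volume()
        for attempt in range(400):
            if attempt and attempt % 80 == 0:
                kind, vol = draw_kind_volume()  # redraw: conditioned on feasibility
            probe = _shape_from_volume(kind, vol, (0, 0, 0), rng)
            br = probe.bounding_radius
            if br + margin_mm >= core_r:
                vol *= 0.6  # shrink until it can fit the core cross-section
                continue
            rho = rng.uniform(0, core_r - br - margin_mm)
            phi = rng.uniform(0, 2 * math.pi)
            z = rng.uniform(pad + br + margin_mm, pad + spec.core_length_mm - br - margin_mm)
            center = np.array([z, cxy + rho * math.sin(phi), cxy + rho * math.cos(phi)])
            ok = all(
                np.linalg.norm(center - c0) > br + r0 + 2 * spec.voxel_size
                for c0, r0 in bounds
            )
            if ok:
                shapes.append(
                    ShapeSpec(kind, tuple(center), probe.params, probe.euler_deg)
                )
                bounds.append((center, br))
                break
        else:
            raise RuntimeError(
                f"infeasible packing: could not place object {len(shapes) + 1} "
                f"of {n_objects} after 400 attempts"
            )
    return shapes


def make_cohort(spec: CohortSpec) -> list[tuple[VoxelVolume, PhantomGroundTruth, str]]:
    """Generate per-subject phantom volumes with ground truth and group labels."""
    rng = np.random.default_rng(spec.seed)
    out = []
    subject = 0
    for group, n_subj in (("benign", spec.n_benign), ("malignant", spec.n_malignant)):
        for _ in range(n_subj):
            subject += 1
            m = spec.count_mean[group]
            lam = rng.gamma(spec.count_dispersion, m / spec.count_dispersion)
            n_obj = int(rng.poisson(lam))
            shapes = _place_shapes(spec, n_obj, group, rng)
            vol, truth = make_core_phantom(
                shapes,
                spec.voxel_size,
                blur_sigma_mm=spec.blur_sigma_mm,
                noise_sigma=spec.noise_sigma,
                seed=int(rng.integers(0, 2**31 - 1)),
                core_diameter_mm=spec.core_diameter_mm,
                core_length_mm=spec.core_length_mm,
                name=f"{group}_{subject:03d}",
            )
            out.append((vol, truth, group))
    return out


def sample_subject_summaries(
    n_benign: int,
    n_malignant: int,
    seed: int,
    params: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Draw per-subject mean parameters from the reference group distributions.

    Each subject's parameter vector is sampled from independent normals with
    the reference cohort's per-group mean and SD (truncated below at a tenth
    of the group mean, all parameters being positive).  This is the
    subject-level view of the cohort generator, used for statistical power
    studies where rendering full volumes would add nothing.
    """
    ref = params if params is not None else load_reference_morphometry()
    cols = ["obj_v_mm3", "obj_s_mm2", "sv_per_mm", "st_th_mm", "smi", "obj_n"]
    rng = np.random.default_rng(seed)
    rows = []
    for group, n in (("benign", n_benign), ("malignant", n_malignant)):
        sub = ref[ref["group"] == group]
        mu = sub[cols].mean()
        sd = sub[cols].std(ddof=1)
        for i in range(n):
            draw = rng.normal(mu.to_numpy(), sd.to_numpy())
            draw = np.maximum(draw, 0.1 * mu.to_numpy())
            rows.append({"subject": f"{group}_{i + 1:03d}", "group": group, **dict(zip(cols, draw))})
    return pd.DataFrame(rows)
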