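import math

import numpy as np
import pytest
import trimesh

import calcimorph as cm
from calcimorph.morphometry import (
    export_mesh,
    local_thickness_map,
    measure_object,
    mesh_object,
    mesh_surface,
    mesh_volume,
    smi,
    smi_from_rates,
    structure_thickness,
)


def brute_force_thickness(mask: np.ndarray) -> np.ndarray:
    """Exhaustive sphere-fitting oracle (voxel units).

    Same convention as the implementation — inscribed radius EDT(c) − 0.5,
    coverage |p − c| <= EDT(c) — but every quantity is computed by direct
    enumeration: the distance transform as a minimum over all background
    voxel centres (grid border padded as background), and τ as a maximum
    over all candidate sphere centres.
    """
    padded = np.pad(np.asarray(mask, bool), 1)
    obj = np.argwhere(padded).astype(float)
    bg = np.argwhere(~padded).astype(float)
    d2 = ((obj[:, None, :] - bg[None, :, :]) ** 2).sum(-1)
    edt = np.sqrt(d2.min(axis=1))
    sep = np.sqrt(((obj[:, None, :] - obj[None, :, :]) ** 2).sum(-1))
    covered = sep <= edt[None, :]  # p covered by the sphere centred at c
    tau = np.max(np.where(covered, 2 * (edt[None, :] - 0.5), -np.inf), axis=1)
    return tau


class TestMesh:
    def test_voxel_ball_is_closed_with_euler_two(self, voxel_sphere):
        mesh = mesh_object(voxel_sphere(10), 1)
        assert mesh.is_watertight
        assert mesh.euler_number == 2

    def test_too_small_to_mesh(self, labeled_mask):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        with pytest.raises(ValueError, match="too small"):
            mesh_object(labeled_mask(mask), 1)

    def test_icosphere_closed_forms(self):
        ico = trimesh.creation.icosphere(subdivisions=5, radius=1.0)
        assert mesh_volume(ico) == pytest.approx(4 * math.pi / 3, rel=1e-3)
        assert mesh_surface(ico) == pytest.approx(4 * math.pi, rel=1e-3)

    def test_unit_cube_surface(self):
        box = trimesh.creation.box(extents=(1, 1, 1))
        assert mesh_surface(box) == pytest.approx(6.0)

    def test_open_mesh_rejected(self):
        ico = trimesh.creation.icosphere(subdivisions=2)
        open_mesh = trimesh.Trimesh(ico.vertices, ico.faces[:-1], process=False)
        with pytest.raises(ValueError, match="closed"):
            mesh_volume(open_mesh)

    def test_inverted_mesh_sign_corrected(self):
        ico = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
        ico.invert()
        with pytest.warns(UserWarning, match="inside-out"):
            v = mesh_volume(ico)
        assert v > 0

    def test_voxelized_sphere_volume_and_surface(self, voxel_sphere):
        labels = voxel_sphere(10)
        r = 10 * labels.voxel_size
        mesh = mesh_object(labels, 1)
        assert mesh_volume(mesh) == pytest.approx((4 / 3) * math.pi * r**3, rel=0.02)
        assert mesh_surface(mesh) == pytest.approx(4 * math.pi * r**2, rel=0.05)


class TestStructureThickness:
    def test_sphere_thickness_is_diameter(self, voxel_sphere):
        labels = voxel_sphere(15)  # diameter 30 voxels
        d = 30 * labels.voxel_size
        assert abs(structure_thickness(labels, 1) - d) <= labels.voxel_size + 1e-9

    def test_rod_thickness_is_twice_radius(self, labeled_mask):
        vs = 0.035
        n = 64
        c = (n // 2 + 0.5) * vs
        mask = cm.voxelize(
            cm.ShapeSpec("rod", (c, c, c), {"radius": 4.5 * vs, "length": 50 * vs}),
            vs, (n, n, n),
        )
        labels = labeled_mask(mask.data, vs)
        assert abs(structure_thickness(labels, 1) - 9 * vs) <= vs + 1e-9

    def test_single_voxel_convention(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        assert local_thickness_map(mask, 0.035) == pytest.approx([0.035])

    def test_plate_thickness(self, labeled_mask):
        mask = np.zeros((30, 30, 10), bool)
        mask[4:26, 4:26, 4:7] = True  # 3-voxel slab
        labels = labeled_mask(mask, 1.0)
        assert structure_thickness(labels, 1) == pytest.approx(3.0, abs=1.0)

    def test_brute_force_oracle_equality_random_masks(self):
        rng = np.random.default_rng(2024)
        for _ in range(20):
            mask = rng.random((12, 12, 12)) < 0.3
            if not mask.any():
                continue
            got = local_thickness_map(mask, 1.0)
            want = brute_force_thickness(mask)
            assert np.allclose(got, want, atol=1e-9)


class TestSMI:
    def test_ideal_sphere_rod_plate(self):
        r = 0.73
        assert smi_from_rates((4 / 3) * math.pi * r**3, 4 * math.pi * r**2,
                              8 * math.pi * r) == pytest.approx(4.0, rel=1e-12)
        assert smi_from_rates(math.pi * r**2, 2 * math.pi * r,
                              2 * math.pi) == pytest.approx(3.0, rel=1e-12)
        assert smi_from_rates(1.0, 2.0, 0.0) == 0.0

    def test_voxelized_sphere_near_four(self, voxel_sphere):
        m = measure_object(voxel_sphere(10), 1)
        assert 3.5 <= m.smi <= 4.5

    def test_shape_ordering(self, labeled_mask):
        vs = 0.035

        def measure(kind, params, grid):
            c = tuple(((g // 2) + 0.5) * vs for g in grid)
            mask = cm.voxelize(cm.ShapeSpec(kind, c, params), vs, grid)
            return measure_object(labeled_mask(mask.data, vs), 1)

        plate = measure("plate", {"thickness": 2 * vs, "width": 40 * vs,
                                  "height": 40 * vs}, (8, 46, 46))
        rod = measure("rod", {"radius": 4 * vs, "length": 40 * vs}, (46, 14, 14))
        sphere = measure("sphere", {"radius": 10 * vs}, (26, 26, 26))
        assert plate.smi < rod.smi < sphere.smi

    def test_sphere_sv_ratio_close_to_3_over_r(self, labeled_mask):
        vs, r = 0.035, 0.15
        n = 24
        c = (n // 2 + 0.5) * vs
        mask = cm.voxelize(cm.ShapeSpec("sphere", (c, c, c), {"radius": r}),
                           vs, (n, n, n))
        m = measure_object(labeled_mask(mask.data, vs), 1)
        assert m.sv_ratio_per_mm == pytest.approx(3 / r, rel=0.10)


class TestInvariants:
    def test_scale_equivariance(self, voxel_sphere):
        a = measure_object(voxel_sphere(8, voxel_size=0.035), 1)
        b = measure_object(voxel_sphere(8, voxel_size=0.070), 1)
        assert b.volume_mm3 == pytest.approx(8 * a.volume_mm3, rel=1e-9)
        assert b.surface_mm2 == pytest.approx(4 * a.surface_mm2, rel=1e-9)
        assert b.thickness_mm == pytest.approx(2 * a.thickness_mm, rel=1e-9)
        assert b.sv_ratio_per_mm == pytest.approx(a.sv_ratio_per_mm / 2, rel=1e-9)
        assert b.smi == pytest.approx(a.smi, rel=1e-6)

    def test_rotation_robustness_of_rod(self, labeled_mask):
        vs = 0.035
        c = (45 + 0.5) * vs
        grid = (92, 92, 92)
        params = {"radius": 5 * vs, "length": 40 * vs}
        axis = cm.voxelize(cm.ShapeSpec("rod", (c, c, c), params), vs, grid)
        tilted = cm.voxelize(
            cm.ShapeSpec("rod", (c, c, c), params, euler_deg=(0, 45, 0)), vs, grid
        )
        a = measure_object(labeled_mask(axis.data, vs), 1)
        b = measure_object(labeled_mask(tilted.data, vs), 1)
        assert b.volume_mm3 == pytest.approx(a.volume_mm3, rel=0.10)
        assert b.surface_mm2 == pytest.approx(a.surface_mm2, rel=0.10)
        assert b.thickness_mm == pytest.approx(a.thickness_mm, rel=0.10)
        assert abs(a.smi - b.smi) < 0.5

    def test_sphere_convergence_with_resolution(self, voxel_sphere):
        v_err, t_err, s_err = [], [], []
        for rv in (5, 10, 20):
            labels = voxel_sphere(rv)
            r = rv * labels.voxel_size
            m = measure_object(labels, 1)
            v_err.append(abs(m.volume_mm3 - (4 / 3) * math.pi * r**3)
                         / ((4 / 3) * math.pi * r**3))
            s_err.append(abs(m.surface_mm2 - 4 * math.pi * r**2) / (4 * math.pi * r**2))
            t_err.append(abs(m.thickness_mm - 2 * r) / labels.voxel_size)
        assert v_err[0] > v_err[1] > v_err[2]
        assert t_err[0] >= t_err[1] - 1e-9 >= t_err[2] - 1e-9
        # surface error is bias-dominated rather than monotone; it must stay
        # bounded at the working resolutions
        assert all(e < 0.05 for e in s_err[1:])

    def test_sv_ratio_is_exact_quotient(self, voxel_sphere):
        m = measure_object(voxel_sphere(6), 1)
        assert m.sv_ratio_per_mm == m.surface_mm2 / m.volume_mm3


class TestExport:
    def test_ply_round_trip_vertex_count(self, tmp_path):
        ico = trimesh.creation.icosphere(subdivisions=3)
        export_mesh(ico, tmp_path / "m.ply")
        back = trimesh.load(tmp_path / "m.ply")
        assert len(back.vertices) == len(ico.vertices)

    def test_stl_area_preserved(self, tmp_path):
        ico = trimesh.creation.icosphere(subdivisions=3)
        export_mesh(ico, tmp_path / "m.stl")
        back = trimesh.load(tmp_path / "m.stl")
        assert back.area == pytest.approx(mesh_surface(ico), rel=1e-6)

    def test_empty_mesh_rejected(self, tmp_path):
        empty = trimesh.Trimesh()
        with pytest.raises(ValueError):
            export_mesh(empty, tmp_path / "m.ply")

    def test_unknown_format_rejected(self, tmp_path):
        ico = trimesh.creation.icosphere(subdivisions=1)
        with pytest.raises(ValueError, match="format"):
            export_mesh(ico, tmp_path / "m.obj")


def test_smi_open_mesh_rejected():
    ico = trimesh.creation.icosphere(subdivisions=2)
    open_mesh = trimesh.Trimesh(ico.vertices, ico.faces[:-1], process=False)
    with pytest.raises(ValueError, match="closed"):
        smi(open_mesh)
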