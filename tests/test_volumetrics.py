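"""Mesh and voxel volumetry against analytic and hand-counted oracles."""

import math

import numpy as np
import pytest
import trimesh

from phragmovol import volumetrics as vol
from phragmovol.volumetrics import (
    BuoyancyInputs,
    MeshError,
    VolumeStack,
    label_chambers,
    measure_width,
    mesh_volume,
    neutral_fill_fraction,
    shell_volume_bounds,
    subsample_slices,
    voxel_volumes,
)


class TestMeshVolume:
    def test_unit_cube_exact(self):
        assert mesh_volume(trimesh.creation.box(extents=(1, 1, 1))) == pytest.approx(1.0)

    def test_icosphere_within_1_percent_of_analytic(self):
        sphere = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
        assert abs(mesh_volume(sphere) - 4 * math.pi / 3) / (4 * math.pi / 3) < 0.01

    def test_disjoint_components_sum(self):
        a = trimesh.creation.box(extents=(1, 1, 1))
        b = trimesh.creation.box(extents=(2, 1, 1))
        b.apply_translation([5.0, 0.0, 0.0])
        assert mesh_volume(trimesh.util.concatenate([a, b])) == pytest.approx(3.0)

    def test_rigid_motion_invariance(self):
        box = trimesh.creation.box(extents=(1, 2, 3))
        v0 = mesh_volume(box)
        moved = box.copy()
        moved.apply_transform(
            trimesh.transformations.rotation_matrix(0.7, [1, 2, 0.5], point=[0.3, 0.1, 0])
        )
        moved.apply_translation([5, -3, 2])
        assert abs(mesh_volume(moved) - v0) / v0 < 1e-9

    def test_orientation_independent(self):
        box = trimesh.creation.box(extents=(1, 1, 2))
        inverted = box.copy()
        inverted.invert()
        assert mesh_volume(inverted) == pytest.approx(mesh_volume(box))

    def test_open_mesh_rejected_naming_open_edges(self):
        open_mesh = trimesh.Trimesh(
            vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0]], faces=[[0, 1, 2]], process=False
        )
        with pytest.raises(MeshError, match="3 edges"):
            mesh_volume(open_mesh)

    def test_agrees_with_independent_mesh_library(self):
        # trimesh's own divergence-theorem volume as the cross-check
        shape = trimesh.creation.icosphere(subdivisions=2, radius=1.7)
        assert mesh_volume(shape) == pytest.approx(abs(shape.volume), rel=1e-12)


class TestVoxelVolumes:
    def test_count_times_voxel_volume(self):
        labels = np.zeros((20, 10, 10), dtype=np.int32)
        labels[:10, :10, :10] = 1  # 1000 voxels
        stack = VolumeStack(labels=labels, voxel_dims=(0.24, 0.025, 0.025))
        assert voxel_volumes(stack)[1] == pytest.approx(1000 * 0.24 * 0.025 * 0.025)

    def test_hand_counted_tiny_stack(self):
        labels = np.array([[[1, 0], [2, 2]], [[1, 0], [0, 2]]], dtype=np.int32)
        stack = VolumeStack(labels=labels, voxel_dims=(1.0, 2.0, 0.5))
        vols = voxel_volumes(stack)
        assert vols == {1: 2 * 1.0, 2: 3 * 1.0}

    def test_empty_label_is_zero(self):
        labels = np.ones((2, 2, 2), dtype=np.int32)
        stack = VolumeStack(labels=labels, voxel_dims=(1, 1, 1))
        assert voxel_volumes(stack, labels=[1, 2])[2] == 0.0

    def test_label_sum_equals_binary_mask_volume(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 4, size=(8, 8, 8)).astype(np.int32)
        stack = VolumeStack(labels=labels, voxel_dims=(0.3, 0.2, 0.1))
        per_label = sum(voxel_volumes(stack).values())
        merged = float((labels > 0).sum()) * stack.voxel_volume
        assert per_label == pytest.approx(merged, abs=0.0)

    def test_cross_oracle_voxelized_cube_vs_mesh(self):
        from phragmovol.synth import voxelize

        cube = trimesh.creation.box(extents=(1.0, 2.0, 1.5))
        stack = voxelize([cube], (0.05, 0.05, 0.05))
        assert abs(voxel_volumes(stack)[1] - mesh_volume(cube)) / 3.0 < 0.02


class TestLabelChambers:
    def test_two_separated_boxes(self):
        grid = np.zeros((4, 10, 10), dtype=bool)
        grid[1:3, 1:4, 1:4] = True
        grid[1:3, 6:9, 6:9] = True
        stack = label_chambers(grid, (1.0, 1.0, 1.0))
        assert stack.n_labels == 2
        assert np.all(stack.labels[~grid] == 0)

    def test_six_connectivity_keeps_corner_touching_blocks_apart(self):
        grid = np.zeros((1, 4, 4), dtype=bool)
        grid[0, :2, :2] = True
        grid[0, 2:, 2:] = True  # touches only at a corner
        stack = label_chambers(grid, (1.0, 1.0, 1.0))
        assert stack.n_labels == 2

    @pytest.mark.parametrize("handedness", [+1.0, -1.0])
    def test_spiral_phantom_labeled_in_ontogenetic_order(self, handedness):
        grid = np.zeros((8, 64, 64), dtype=bool)
        true_rho = []
        for k in range(7):
            th = handedness * 0.9 * k
            rho = 6 + 2.4 * k
            cy = 32 + rho * math.sin(th)
            cx = 32 + rho * math.cos(th)
            grid[2:6, int(cy) - 1 : int(cy) + 2, int(cx) - 1 : int(cx) + 2] = True
            true_rho.append(rho)
        stack = label_chambers(grid, (0.5, 0.5, 0.5))
        import scipy.ndimage as ndi

        got_rho = []
        for ell in range(1, 8):
            com = ndi.center_of_mass(stack.labels == ell)
            got_rho.append(math.hypot(com[1] - 32, com[2] - 32))
        # labels must walk outward along the spiral, whichever way it coils
        assert np.all(np.diff(got_rho) > 0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="no chamber"):
            label_chambers(np.zeros((3, 3, 3), dtype=bool), (1, 1, 1))


class TestSubsampleSlices:
    @pytest.fixture()
    def sphere_stack(self):
        zz, yy, xx = np.mgrid[:48, :40, :40]
        mask = ((zz - 24) / 20.0) ** 2 + ((yy - 20) / 17.0) ** 2 + (
            (xx - 20) / 17.0
        ) ** 2 <= 1
        return VolumeStack(labels=mask.astype(np.int32), voxel_dims=(0.25, 0.25, 0.25))

    def test_k1_is_identity(self, sphere_stack):
        reduced, est = subsample_slices(sphere_stack, 1)
        np.testing.assert_array_equal(reduced.labels, sphere_stack.labels)
        assert est[1] == pytest.approx(voxel_volumes(sphere_stack)[1])

    def test_error_nondecreasing_in_k_for_convex_phantom(self, sphere_stack):
        full = voxel_volumes(sphere_stack)[1]
        mean_abs_err = []
        for k in (1, 2, 4, 8):
            errs = [
                abs(subsample_slices(sphere_stack, k, offset)[1][1] - full) / full
                for offset in range(k)
            ]
            mean_abs_err.append(np.mean(errs))
        assert all(a <= b + 1e-12 for a, b in zip(mean_abs_err, mean_abs_err[1:]))

    def test_every_fourth_slice_on_synthetic_shell(self):
        from phragmovol.synth import ShellParams, generate_shell, voxelize

        model = generate_shell(ShellParams(n_chambers=6))
        stack = voxelize(model.meshes, (0.15, 0.25, 0.25))
        full = voxel_volumes(stack)
        _, est = subsample_slices(stack, 4)
        for ell in range(1, 7):
            n_slices = int(np.any(stack.labels == ell, axis=(1, 2)).sum())
            if n_slices >= 12:
                assert abs(est[ell] - full[ell]) / full[ell] < 0.05

    def test_k_beyond_slice_count_rejected(self, sphere_stack):
        with pytest.raises(ValueError, match="exceeds"):
            subsample_slices(sphere_stack, 1000)


class TestMeasureWidth:
    def test_box_extent_in_physical_units(self):
        labels = np.zeros((20, 20, 20), dtype=np.int32)
        labels[3:13, 2:8, 5:6] = 1
        stack = VolumeStack(labels=labels, voxel_dims=(0.5, 0.025, 0.1))
        assert measure_width(stack, 1, axis=0) == pytest.approx(10 * 0.5)
        assert measure_width(stack, 1, axis=1) == pytest.approx(6 * 0.025)

    def test_ellipsoid_extent_within_one_voxel(self):
        zz, yy, xx = np.mgrid[:40, :30, :30]
        b_vox = 15.0  # semi-axis along z in voxels
        mask = ((zz - 20) / b_vox) ** 2 + ((yy - 15) / 9.0) ** 2 + (
            (xx - 15) / 9.0
        ) ** 2 <= 1
        dz = 0.3
        stack = VolumeStack(labels=mask.astype(np.int32), voxel_dims=(dz, 0.2, 0.2))
        width = measure_width(stack, 1, axis=0)
        assert abs(width - 2 * b_vox * dz) <= dz

    def test_absent_label_rejected(self):
        stack = VolumeStack(labels=np.ones((2, 2, 2), dtype=np.int32), voxel_dims=(1, 1, 1))
        with pytest.raises(ValueError, match="label 9"):
            measure_width(stack, 9)


class TestShellVolumeBounds:
    def test_printed_density_range_arithmetic(self):
        v_min, v_max = shell_volume_bounds(262.0)
        assert v_min == pytest.approx(262.0 / 2.62)
        assert v_max == pytest.approx(262.0 / 2.54)
        assert v_min == pytest.approx(100.0)
        assert v_max == pytest.approx(103.15, abs=0.005)

    def test_zero_mass(self):
        assert shell_volume_bounds(0.0) == (0.0, 0.0)

    def test_ordering_and_negative_mass(self):
        v_min, v_max = shell_volume_bounds(10.0, density_range=(2.0, 3.0))
        assert v_min <= v_max
        with pytest.raises(ValueError):
            shell_volume_bounds(-1.0)


class TestNeutralFillFraction:
    def test_already_neutral_with_empty_chambers(self):
        rho_sw = (10 * 2.5 + 50 * 1.0) / 80.0  # balances dry mass exactly
        b = BuoyancyInputs(
            shell_volume=10, soft_body_volume=50, cameral_volume=20,
            shell_density=2.5, soft_density=1.0, liquid_density=1.0,
            seawater_density=rho_sw,
        )
        res = neutral_fill_fraction(b)
        assert res.fraction == pytest.approx(0.0)
        assert res.status == "ok"

    def test_constructed_half_fill(self):
        # displaced mass exceeds dry mass by exactly half the full-chamber
        # liquid mass, so f = 1/2; checked by direct mass balance
        V_s, V_b, V_c = 10.0, 50.0, 20.0
        rho_s, rho_b, rho_l = 2.5, 1.0, 1.0
        rho_sw = (V_s * rho_s + V_b * rho_b + 0.5 * V_c * rho_l) / (V_s + V_b + V_c)
        res = neutral_fill_fraction(
            BuoyancyInputs(V_s, V_b, V_c, rho_s, rho_b, rho_l, rho_sw)
        )
        assert res.fraction == pytest.approx(0.5, rel=1e-12)
        assert res.residual < 1e-9

    def test_no_cameral_volume_reports_out_of_range(self):
        b = BuoyancyInputs(
            shell_volume=10, soft_body_volume=50, cameral_volume=0.0,
            shell_density=2.5, soft_density=1.0,
        )
        res = neutral_fill_fraction(b)
        assert res.status == "undefined"

    def test_sinking_body_reports_negative(self):
        b = BuoyancyInputs(
            shell_volume=50, soft_body_volume=10, cameral_volume=5,
            shell_density=2.6, soft_density=1.2, seawater_density=1.025,
        )
        res = neutral_fill_fraction(b)
        assert res.status == "negative" and res.fraction < 0

    def test_mass_balance_residual_tiny(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            vs, vb, vc = rng.uniform(1, 100, 3)
            b = BuoyancyInputs(vs, vb, vc, 2.58, 1.06, 1.025, 1.025)
            res = neutral_fill_fraction(b)
            assert res.residual < 1e-9


class TestStackIO:
    def test_tiff_sidecar_round_trip(self, tmp_path):
        labels = np.arange(24, dtype=np.int32).reshape(2, 3, 4) % 3
        stack = VolumeStack(labels=labels, voxel_dims=(0.24, 0.025, 0.025))
        path = tmp_path / "stack.tif"
        vol.save_stack(stack, path)
        back = vol.load_stack(path)
        np.testing.assert_array_equal(back.labels, labels)
        assert back.voxel_dims == stack.voxel_dims

    def test_missing_sidecar_rejected(self, tmp_path):
        import tifffile

        path = tmp_path / "naked.tif"
        tifffile.imwrite(str(path), np.zeros((2, 2, 2), dtype=np.uint16))
        with pytest.raises(FileNotFoundError):
            vol.load_stack(path)

    def test_stl_round_trip(self, tmp_path):
        mesh = trimesh.creation.icosphere(subdivisions=1, radius=2.0)
        path = tmp_path / "chamber.stl"
        vol.save_mesh(mesh, path)
        back = vol.load_mesh(path)
        assert mesh_volume(back) == pytest.approx(mesh_volume(mesh), rel=1e-6)
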