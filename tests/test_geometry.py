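import numpy as np
import pytest

from avcalc.geometry import (
    CylinderParams,
    DiskAnnotation,
    ExpansionConfig,
    GeometryError,
    GridCrop,
    cylinder_origin_from_mask,
    disk_radius,
    expand_disk_to_cylinder,
    fit_local_frame,
    map_params_between_spaces,
    parameterize_cylinder_mask,
    reconstruct_cylinder_mask,
)
from avcalc.volume import ImageVolume

from oracles import voxelize_scalar


def flat_disk(radius_vox: float, z: int = 10, center=(20, 20)) -> np.ndarray:
    ii, jj = np.mgrid[0:41, 0:41]
    m = (ii - center[0]) ** 2 + (jj - center[1]) ** 2 < radius_vox**2
    vox = np.argwhere(m)
    return np.column_stack([vox, np.full(len(vox), z)])


class TestLocalFrame:
    def test_axis_aligned_disk_normal_and_centroid(self):
        vox = flat_disk(8.0)
        disk = DiskAnnotation(vox, center_point=(20, 20, 10))
        frame = fit_local_frame(disk, (1.0, 1.0, 1.0))
        np.testing.assert_allclose(np.abs(frame.pc3), [0, 0, 1], atol=1e-9)
        assert frame.pc3[2] > 0  # sign fixed toward superior
        np.testing.assert_allclose(frame.centroid_mm, vox.mean(axis=0), atol=1e-9)

    def test_mm_rescaling_invariance(self):
        vox = flat_disk(8.0)
        disk = DiskAnnotation(vox, center_point=(20, 20, 10))
        f1 = fit_local_frame(disk, (1.0, 1.0, 1.0))
        f2 = fit_local_frame(disk, (0.5, 0.5, 3.0))
        np.testing.assert_allclose(f2.pc3, f1.pc3, atol=1e-9)

    def test_tilted_disk_matches_analytic_normal(self):
        # exact in-plane lattice of a disk tilted 30 degrees about x
        c, s = np.cos(np.pi / 6), np.sin(np.pi / 6)
        u = np.array([1.0, 0.0, 0.0])
        v = np.array([0.0, c, s])
        pts = []
        for m in range(-9, 10):
            for n in range(-9, 10):
                if m * m + n * n < 81:
                    pts.append(50 + m * u + n * v)
        disk = DiskAnnotation(np.array(pts), center_point=(50, 50, 50))
        frame = fit_local_frame(disk, (1.0, 1.0, 1.0))
        np.testing.assert_allclose(frame.pc3, [0.0, -s, c], atol=1e-6)

    def test_orthonormality(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            n = rng.normal(size=3)
            n /= np.linalg.norm(n)
            basis = np.linalg.svd(np.outer(n, n))[0][:, 1:]
            pts = [30 + m * basis[:, 0] + k * basis[:, 1]
                   for m in range(-6, 7) for k in range(-6, 7) if m * m + k * k < 36]
            frame = fit_local_frame(
                DiskAnnotation(np.array(pts), center_point=(30, 30, 30)), (1, 1, 1)
            )
            g = np.stack([frame.pc1, frame.pc2, frame.pc3])
            np.testing.assert_allclose(g @ g.T, np.eye(3), atol=1e-8)

    def test_degenerate_collinear_raises(self):
        vox = np.column_stack([np.arange(10), np.zeros(10), np.zeros(10)]).astype(int)
        with pytest.raises(GeometryError):
            fit_local_frame(DiskAnnotation(vox, center_point=(0, 0, 0)), (1, 1, 1))


class TestDiskRadius:
    def test_circular_disk_half_mm_spacing(self):
        # mm radius 10 at 0.5 mm spacing = 20 voxel radius
        ii, jj = np.mgrid[0:81, 0:81]
        m = (ii - 40) ** 2 + (jj - 40) ** 2 <= 20**2
        vox = np.column_stack([np.argwhere(m), np.full(int(m.sum()), 5)])
        disk = DiskAnnotation(vox, center_point=(40, 40, 5))
        frame = fit_local_frame(disk, (0.5, 0.5, 3.0))
        r = disk_radius(disk, frame, (0.5, 0.5, 3.0))
        # brute-force oracle: max mm distance over the voxel set
        d = np.sqrt(((vox[:, :2] - 40) ** 2).sum(axis=1)) * 0.5
        assert r == pytest.approx(d.max())
        assert abs(r - 10.0) <= 0.5

    def test_ellipse_major_axis(self):
        ii, jj = np.mgrid[0:61, 0:61]
        m = ((ii - 30) / 8.0) ** 2 + ((jj - 30) / 11.0) ** 2 <= 1.0
        vox = np.column_stack([np.argwhere(m), np.full(int(m.sum()), 3)])
        disk = DiskAnnotation(vox, center_point=(30, 30, 3))
        frame = fit_local_frame(disk, (1.0, 1.0, 1.0))
        assert disk_radius(disk, frame, (1.0, 1.0, 1.0)) == pytest.approx(11.0, abs=0.5)

    def test_measured_from_annotated_center_not_centroid(self):
        # asymmetric disk: radius from the off-center annotated point differs
        vox = flat_disk(8.0)
        disk_c = DiskAnnotation(vox, center_point=(20, 20, 10))
        disk_o = DiskAnnotation(vox, center_point=(16, 20, 10))
        frame = fit_local_frame(disk_c, (1, 1, 1))
        r_c = disk_radius(disk_c, frame, (1, 1, 1))
        r_o = disk_radius(disk_o, frame, (1, 1, 1))
        assert r_o > r_c


class TestExpansion:
    def _disk(self):
        vox = flat_disk(10.0, z=30, center=(32, 32))
        return DiskAnnotation(vox, center_point=(32, 32, 30))

    def test_degenerate_zero_height_is_empty(self, iso_grid):
        disk = self._disk()
        frame = fit_local_frame(disk, iso_grid.spacing)
        cfg = ExpansionConfig(delta_r_mm=0.0, dA_mm=0.0, dB_mm=1e-9)
        mask = expand_disk_to_cylinder(disk, frame, cfg, iso_grid)
        assert mask.sum() == 0  # strict inequalities leave nothing

    def test_voxel_count_matches_analytic_volume(self, iso_grid):
        # measured disk radius ~9.95, dr -> r = 10 + eps; use dr to hit r ~ 10
        disk = self._disk()
        frame = fit_local_frame(disk, iso_grid.spacing)
        r_meas = disk_radius(disk, frame, iso_grid.spacing)
        cfg = ExpansionConfig(delta_r_mm=10.0 - r_meas, dA_mm=10.0, dB_mm=30.0)
        mask = expand_disk_to_cylinder(disk, frame, cfg, iso_grid)
        assert mask.sum() == pytest.approx(np.pi * 100 * 40, rel=0.02)

    def test_membership_matches_scalar_oracle(self, iso_grid):
        disk = self._disk()
        frame = fit_local_frame(disk, iso_grid.spacing)
        cfg = ExpansionConfig()
        mask = expand_disk_to_cylinder(disk, frame, cfg, iso_grid)
        r = disk_radius(disk, frame, iso_grid.spacing) + cfg.delta_r_mm
        oracle = voxelize_scalar(
            iso_grid.shape, iso_grid.spacing, iso_grid.origin_mm,
            frame.centroid_mm, frame.pc3, r, cfg.dA_mm, cfg.dB_mm,
        )
        assert np.array_equal(mask, oracle)


class TestReconstruct:
    def test_roundtrip_dice(self, iso_grid):
        rng = np.random.default_rng(3)
        for _ in range(5):
            n = rng.normal(size=3) * np.array([0.2, 0.2, 1.0])
            n /= np.linalg.norm(n)
            n *= np.sign(n[2])
            p = CylinderParams(normal=n, origin_mm=rng.uniform(28, 36, 3),
                               radius_mm=rng.uniform(8, 18), height_mm=40.0)
            m = reconstruct_cylinder_mask(p, iso_grid)
            p2 = parameterize_cylinder_mask(m, iso_grid)
            m2 = reconstruct_cylinder_mask(p2, iso_grid)
            dice = 2 * np.logical_and(m, m2).sum() / (m.sum() + m2.sum())
            assert dice >= 0.99

    def test_translation_equivariance(self, iso_grid):
        p = CylinderParams(normal=(0, 0, 1), origin_mm=(30, 30, 28), radius_mm=10, height_mm=24)
        m1 = reconstruct_cylinder_mask(p, iso_grid)
        p5 = CylinderParams(normal=(0, 0, 1), origin_mm=(30, 30, 33), radius_mm=10, height_mm=24)
        m2 = reconstruct_cylinder_mask(p5, iso_grid)
        c1 = cylinder_origin_from_mask(m1, iso_grid)
        c2 = cylinder_origin_from_mask(m2, iso_grid)
        np.testing.assert_allclose(c2 - c1, [0, 0, 5], atol=0.5)

    def test_subvoxel_radius_empty_with_warning(self, iso_grid):
        p = CylinderParams(normal=(0, 0, 1), origin_mm=(30, 30, 30), radius_mm=0.3, height_mm=10)
        with pytest.warns(UserWarning):
            m = reconstruct_cylinder_mask(p, iso_grid)
        assert m.sum() == 0

    def test_near_unit_normal_normalized_else_error(self, iso_grid):
        p = CylinderParams(normal=(0, 0, 1.0005), origin_mm=(30, 30, 30),
                           radius_mm=10, height_mm=20)
        assert np.linalg.norm(p.normal) == pytest.approx(1.0, abs=1e-9)
        with pytest.raises(GeometryError):
            CylinderParams(normal=(0, 0, 1.1), origin_mm=(30, 30, 30),
                           radius_mm=10, height_mm=20)


class TestOriginFromMask:
    def test_two_voxel_mask(self):
        grid = ImageVolume(np.zeros((8, 8, 4), dtype=np.float32), (1.0, 1.0, 1.0))
        m = np.zeros((8, 8, 4), dtype=bool)
        m[0, 0, 0] = m[2, 0, 0] = True
        np.testing.assert_allclose(cylinder_origin_from_mask(m, grid), [1, 0, 0])

    def test_symmetric_cylinder_center(self, iso_grid):
        p = CylinderParams(normal=(0, 0, 1), origin_mm=(32, 32, 32), radius_mm=12, height_mm=30)
        m = reconstruct_cylinder_mask(p, iso_grid)
        np.testing.assert_allclose(cylinder_origin_from_mask(m, iso_grid), [32, 32, 32], atol=0.5)

    def test_empty_mask_raises(self, iso_grid):
        with pytest.raises(GeometryError):
            cylinder_origin_from_mask(np.zeros(iso_grid.shape, bool), iso_grid)

    def test_oblique_phantom_truth(self, plain_phantom):
        t = plain_phantom
        c = cylinder_origin_from_mask(t.cylinder_mask, t.image)
        diag = np.linalg.norm(t.image.spacing)
        assert np.linalg.norm(c - t.params.origin_mm) <= diag


class TestParameterRecovery:
    def test_cohort_range_recovery(self, iso_grid):
        """parameterize(reconstruct(p)) recovers p for valve-sized cylinders."""
        rng = np.random.default_rng(42)
        half_diag = np.linalg.norm(iso_grid.spacing) / 2
        for _ in range(10):
            tilt = np.deg2rad(rng.uniform(0, 15))
            phi = rng.uniform(0, 2 * np.pi)
            n = np.array([np.sin(tilt) * np.cos(phi), np.sin(tilt) * np.sin(phi), np.cos(tilt)])
            p = CylinderParams(normal=n, origin_mm=rng.uniform(30, 34, 3),
                               radius_mm=rng.uniform(16, 22), height_mm=40.0)
            m = reconstruct_cylinder_mask(p, iso_grid)
            p2 = parameterize_cylinder_mask(m, iso_grid)
            assert np.linalg.norm(p2.origin_mm - p.origin_mm) <= half_diag
            assert abs(p2.radius_mm - p.radius_mm) <= iso_grid.spacing[0]
            assert abs(np.dot(p2.normal, p.normal)) >= 0.999


class TestSpaceMapping:
    def _crop(self, offset=(0, 0, 0)):
        return GridCrop(crop_offset=offset, crop_shape=(64, 64, 64),
                        orig_shape=(96, 96, 26), orig_spacing=(0.7, 0.7, 2.5))

    def test_identity_crop(self):
        p = CylinderParams(normal=(0, 0, 1), origin_mm=(30, 30, 30), radius_mm=18, height_mm=40)
        q = map_params_between_spaces(p, self._crop(), "to_crop")
        np.testing.assert_allclose(q.origin_mm, p.origin_mm)
        assert q.space == "iso_crop"

    def test_offset_shifts_origin(self):
        p = CylinderParams(normal=(0, 0, 1), origin_mm=(30, 30, 30), radius_mm=18, height_mm=40)
        q = map_params_between_spaces(p, self._crop((10, 20, 5)), "to_crop")
        np.testing.assert_allclose(q.origin_mm, [20, 10, 25])
        assert q.radius_mm == p.radius_mm and q.height_mm == p.height_mm

    def test_random_roundtrip_identity(self, rng):
        for _ in range(20):
            offset = tuple(int(v) for v in rng.integers(-10, 11, 3))
            crop = self._crop(offset)
            p = CylinderParams(normal=(0, 0, 1), origin_mm=rng.uniform(15, 45, 3),
                               radius_mm=float(rng.uniform(10, 22)), height_mm=40)
            q = map_params_between_spaces(p, crop, "to_crop")
            back = map_params_between_spaces(q, crop, "to_acquisition")
            np.testing.assert_allclose(back.origin_mm, p.origin_mm, atol=1e-6)
            assert back.radius_mm == p.radius_mm

    def test_center_outside_fov_raises(self):
        crop = self._crop((-300, 0, 0))
        p = CylinderParams(normal=(0, 0, 1), origin_mm=(30, 30, 30), radius_mm=18,
                           height_mm=40, space="iso_crop")
        with pytest.raises(GeometryError):
            map_params_between_spaces(p, crop, "to_acquisition")


def test_anisotropic_spacing_same_physical_object():
    """The same mm-space cylinder voxelized on different anisotropic grids
    recovers the same physical parameters within half-voxel effects."""
    p = CylinderParams(normal=(0, 0, 1), origin_mm=(30.2, 29.7, 30.3), radius_mm=12.3,
                       height_mm=24.4)
    g1 = ImageVolume(np.zeros((120, 120, 60), dtype=np.float32), (0.5, 0.5, 1.0))
    g2 = ImageVolume(np.zeros((60, 60, 24), dtype=np.float32), (1.0, 1.0, 2.5))
    r1 = parameterize_cylinder_mask(reconstruct_cylinder_mask(p, g1), g1)
    r2 = parameterize_cylinder_mask(reconstruct_cylinder_mask(p, g2), g2)
    half_diag = np.linalg.norm(g2.spacing) / 2
    assert np.linalg.norm(r1.origin_mm - r2.origin_mm) <= half_diag
    assert abs(r1.radius_mm - r2.radius_mm) <= 0.5 * max(g2.spacing[:2])
    assert abs(r1.height_mm - r2.height_mm) <= g2.spacing[2]
    assert abs(np.dot(r1.normal, r2.normal)) >= 0.999
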