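"""Image-to-print chain and particle morphology checks."""

import math

import numpy as np
import pytest

from coralight import oct_pipeline as oct
from coralight import phantoms
from coralight.oct_pipeline import ImageVolume, SurfaceMesh
from coralight.phantoms import PhantomConfig


def digital_ball(r_vox=20, spacing=10.0, pad=3):
    n = 2 * r_vox + 2 * pad
    zz, yy, xx = np.mgrid[:n, :n, :n]
    mask = ((zz - n / 2) ** 2 + (yy - n / 2) ** 2 + (xx - n / 2) ** 2) <= r_vox**2
    return ImageVolume(data=mask, spacing_um=(spacing, spacing, spacing))


@pytest.fixture(scope="module")
def ball_mesh():
    return oct.extract_surface(digital_ball())


class TestMedianFilter:
    def test_constant_volume_unchanged(self):
        vol = ImageVolume(np.full((8, 8, 8), 42, dtype=np.uint16), (1.0, 1.0, 1.0))
        assert np.array_equal(oct.denoise_median3d(vol).data, vol.data)

    def test_single_impulse_removed(self):
        data = np.full((9, 9, 9), 100, dtype=np.uint16)
        data[4, 4, 4] = 60000
        vol = ImageVolume(data, (1.0, 1.0, 1.0))
        assert np.all(oct.denoise_median3d(vol).data == 100)

    def test_oversized_radius_rejected(self):
        vol = ImageVolume(np.zeros((5, 20, 20), dtype=np.uint16), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            oct.denoise_median3d(vol, radius=3)

    def test_denoising_reduces_segmentation_errors(self):
        cfg = PhantomConfig(seed=30, noise_rel=0.25, grid_spacing=(15.0, 15.0, 15.0))
        vol = phantoms.make_corallite_volume(cfg)
        raw_seg, _ = oct.segment_surface(vol, n_classes=2)
        den_seg, _ = oct.segment_surface(oct.denoise_median3d(vol), n_classes=2)
        truth = vol.foreground_mask
        raw_err = int((raw_seg.data.astype(bool) ^ truth).sum())
        den_err = int((den_seg.data.astype(bool) ^ truth).sum())
        assert den_err < raw_err


class TestSegmentSurface:
    def test_noiseless_two_level_phantom_is_exact(self):
        cfg = PhantomConfig(seed=31, noise_rel=0.0, grid_spacing=(10.0, 10.0, 10.0))
        vol = phantoms.make_corallite_volume(cfg)
        seg, thresholds = oct.segment_surface(vol)
        assert int((seg.data.astype(bool) ^ vol.foreground_mask).sum()) == 0
        assert all(t is not None for t in thresholds)

    def test_bimodal_threshold_lies_between_modes(self):
        rng = np.random.default_rng(0)
        lo = rng.normal(1000, 30, 4000)
        hi = rng.normal(3000, 30, 4000)
        img = np.concatenate([lo, hi]).reshape(1, 80, 100).astype(np.uint16)
        _, thresholds = oct.segment_surface(ImageVolume(img, (1, 1, 1)), n_classes=2)
        # strictly between the modes (outside each mode's 3 sigma range)
        assert 1000 + 3 * 30 < thresholds[0] < 3000 - 3 * 30

    def test_noisy_corallite_misclassification_below_two_percent(self):
        cfg = PhantomConfig(seed=32, noise_rel=0.05, grid_spacing=(10.0, 10.0, 10.0))
        vol = phantoms.make_corallite_volume(cfg)
        # the phantom is a two-level image; use the matching class count
        seg, _ = oct.segment_surface(vol, n_classes=2)
        frac = (seg.data.astype(bool) ^ vol.foreground_mask).mean()
        assert frac < 0.02

    def test_constant_slices_inherit_neighbour_threshold(self):
        data = np.full((3, 20, 20), 100, dtype=np.uint16)
        data[1, 5:15, 5:15] = 3000
        _, thresholds = oct.segment_surface(ImageVolume(data, (1, 1, 1)), n_classes=2)
        assert thresholds[0] == thresholds[1] == thresholds[2]


class TestExtractSurface:
    def test_ball_area_and_volume_within_three_percent(self, ball_mesh):
        r_um = 200.0
        assert ball_mesh.area() == pytest.approx(4 * math.pi * r_um**2, rel=0.03)
        assert ball_mesh.volume() == pytest.approx(4 / 3 * math.pi * r_um**3, rel=0.03)

    def test_ball_mesh_is_watertight(self, ball_mesh):
        assert ball_mesh.is_watertight

    def test_single_voxel_gives_closed_mesh(self):
        data = np.zeros((5, 5, 5), dtype=bool)
        data[2, 2, 2] = True
        mesh = oct.extract_surface(ImageVolume(data, (1.0, 1.0, 1.0)))
        assert mesh.is_watertight
        assert mesh.volume() > 0

    def test_empty_foreground_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            oct.extract_surface(ImageVolume(np.zeros((4, 4, 4), dtype=bool), (1, 1, 1)))

    def test_cup_only_phantom_mesh_depth_matches_one_mm(self):
        cfg = PhantomConfig(seed=33, noise_rel=0.0, grid_spacing=(10.0, 10.0, 10.0))
        vol = phantoms.make_corallite_volume(cfg, tentacle_length_um=0.0, n_tentacles=0)
        mesh = oct.extract_surface(
            ImageVolume(vol.foreground_mask, vol.spacing_um)
        )
        assert mesh.z_extent == pytest.approx(1000.0, abs=10.0)

    def test_volumes_agree_across_voxel_spacings(self):
        fine = oct.extract_surface(digital_ball(r_vox=30, spacing=5.0))
        coarse = oct.extract_surface(digital_ball(r_vox=15, spacing=10.0))
        assert fine.volume() == pytest.approx(coarse.volume(), rel=0.03)


class TestFillHoles:
    def test_watertight_mesh_unchanged(self, ball_mesh):
        out, skipped = oct.fill_holes(ball_mesh)
        assert out.faces.shape == ball_mesh.faces.shape
        assert skipped == []

    def test_single_missing_face_refilled(self, ball_mesh):
        broken = SurfaceMesh(ball_mesh.vertices.copy(), ball_mesh.faces[:-1].copy())
        assert not broken.is_watertight
        fixed, skipped = oct.fill_holes(broken)
        assert fixed.is_watertight and skipped == []
        assert fixed.volume() == pytest.approx(ball_mesh.volume(), rel=1e-6)

    def test_oversized_hole_reported_untouched(self, ball_mesh):
        broken = SurfaceMesh(ball_mesh.vertices.copy(), ball_mesh.faces[:-1].copy())
        out, skipped = oct.fill_holes(broken, max_hole_edges=2)
        assert skipped == [3]
        assert not out.is_watertight


class TestSliceMasks:
    def test_mid_layer_is_disc_of_ball_radius(self, ball_mesh):
        stack = oct.slice_masks(ball_mesh, layer_um=10.0, pixel_um=10.0)
        mid = stack.masks[stack.n_layers // 2]
        r_px = math.sqrt(mid.sum() / math.pi)
        assert r_px == pytest.approx(20.0, abs=1.0)

    def test_stacked_volume_matches_mesh_volume(self, ball_mesh):
        stack = oct.slice_masks(ball_mesh, layer_um=10.0, pixel_um=10.0)
        assert stack.volume() == pytest.approx(ball_mesh.volume(), rel=0.03)

    def test_layer_count_is_ceiling_of_extent(self, ball_mesh):
        stack = oct.slice_masks(ball_mesh, layer_um=27.0, pixel_um=10.0)
        assert stack.n_layers == math.ceil(ball_mesh.z_extent / 27.0)

    def test_open_mesh_rejected_with_pointer_to_fill_holes(self, ball_mesh):
        broken = SurfaceMesh(ball_mesh.vertices.copy(), ball_mesh.faces[:-1].copy())
        with pytest.raises(ValueError, match="fill_holes"):
            oct.slice_masks(broken, layer_um=10.0)


class TestParticles:
    def test_noiseless_spheres_recovered_exactly_with_unit_sphericity(self):
        cfg = PhantomConfig(seed=34, noise_rel=0.0, grid_spacing=(2.0, 2.0, 2.0))
        vol = phantoms.make_aggregate_stack(
            cfg, n_particles=10, target_sphericity=1.0, sphericity_sd=0.0
        )
        stats = oct.segment_particles(vol)
        assert stats.n_particles == 10
        assert np.all(stats.sphericity > 0.97)
        d = stats.equivalent_diameter_um
        assert d.min() > 25.0 and d.max() < 55.0

    def test_tuned_ellipsoids_hit_target_mean_sphericity(self):
        cfg = PhantomConfig(seed=35, noise_rel=0.0, grid_spacing=(2.5, 2.5, 2.5))
        vol = phantoms.make_aggregate_stack(cfg, n_particles=20)
        stats = oct.segment_particles(vol)
        assert stats.n_particles == 20
        assert stats.sphericity.mean() == pytest.approx(0.75, abs=0.07)

    def test_touching_spheres_merge_below_smoothing_scale(self):
        data = np.full((40, 40, 80), 100, dtype=np.uint16)
        zz, yy, xx = np.mgrid[:40, :40, :80]
        r = 10
        s1 = ((zz - 20) ** 2 + (yy - 20) ** 2 + (xx - 25) ** 2) <= r**2
        s2 = ((zz - 20) ** 2 + (yy - 20) ** 2 + (xx - 46) ** 2) <= r**2
        data[s1 | s2] = 3000
        stats = oct.segment_particles(ImageVolume(data, (2.0, 2.0, 2.0)))
        assert stats.n_particles == 1  # gap of ~1 voxel closes at radius 2

    def test_empty_segmentation_warns_and_returns_no_particles(self):
        vol = ImageVolume(np.full((10, 10, 10), 50, dtype=np.uint16), (1, 1, 1))
        with pytest.warns(UserWarning, match="empty"):
            stats = oct.segment_particles(vol)
        assert stats.n_particles == 0

    def test_invalid_window_rejected(self):
        vol = ImageVolume(np.zeros((4, 4, 4), dtype=np.uint16), (1, 1, 1))
        with pytest.raises(ValueError):
            oct.segment_particles(vol, lo=300, hi=100)


class TestFullChain:
    def test_corallite_roundtrip_conserves_volume(self):
        """phantom -> segment -> mesh -> masks keeps volume within 5%."""
        cfg = PhantomConfig(seed=36, noise_rel=0.05, grid_spacing=(10.0, 10.0, 10.0))
        vol = phantoms.make_corallite_volume(cfg)
        seg, _ = oct.segment_surface(vol, n_classes=2)
        mesh, _ = oct.fill_holes(oct.extract_surface(seg), max_hole_edges=10_000)
        assert mesh.is_watertight
        stack = oct.slice_masks(mesh, layer_um=10.0, pixel_um=10.0)
        assert stack.volume() == pytest.approx(mesh.volume(), rel=0.05)
        truth_vol = vol.foreground_mask.sum() * 1000.0  # 10 um voxels
        assert mesh.volume() == pytest.approx(truth_vol, rel=0.05)

    def test_stl_roundtrip_preserves_geometry(self, tmp_path, ball_mesh):
        path = tmp_path / "ball.stl"
        ball_mesh.to_stl(path)
        text = path.read_text()
        assert text.startswith("solid") and text.rstrip().endswith("endsolid coralight")
        assert text.count("facet normal") == ball_mesh.faces.shape[0]
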