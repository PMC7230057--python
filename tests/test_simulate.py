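import numpy as np
import pytest

from gridwarp import (
    AnalyticDistortion,
    build_grid_geometry,
    make_distortion_field,
    random_smooth_field,
    true_cp_positions,
    voxelize_phantom,
    warp_volume,
)
from gridwarp.simulate import DistortionTooLargeError


@pytest.fixture(scope="module")
def small_geometry():
    return build_grid_geometry(15.0, 3.0, (30.0, 30.0, 30.0))


class TestVoxelize:
    def test_vertex_and_background_intensities(self, small_geometry):
        vol = voxelize_phantom(small_geometry, 0.5, "observed")
        v = small_geometry.vertices[0]
        assert vol.sample(v[None, :], order=0)[0] == 50.0  # grid (hyposignal)
        mid = np.array([[7.5, 7.5, 7.5]])  # cell center, >= 6 mm from any bar
        assert vol.sample(mid, order=0)[0] == 1000.0
        ref = voxelize_phantom(small_geometry, 0.5, "reference")
        assert ref.sample(v[None, :], order=0)[0] == 120.0  # grid (hyperdense)

    def test_resolution_error(self, small_geometry):
        with pytest.raises(ValueError, match="resolvable"):
            voxelize_phantom(small_geometry, 4.0)

    def test_grid_fraction_matches_monte_carlo_oracle(self, small_geometry):
        """Voxel-counted bar fraction agrees with a dense-point volume oracle."""
        vol = voxelize_phantom(small_geometry, 0.5, "observed")
        axes = vol.axis_coordinates()
        idx = [np.flatnonzero((a >= -15) & (a <= 15)) for a in axes]
        frac = (vol.intensities[np.ix_(*idx)] == 50.0).mean()

        rng = np.random.default_rng(0)
        pts = rng.uniform(-15, 15, size=(200_000, 3))
        lat = np.array([-15.0, 0.0, 15.0])
        inside = np.zeros(len(pts), dtype=bool)
        for axis in range(3):
            others = [a for a in range(3) if a != axis]
            d1 = np.min(np.abs(pts[:, others[0]][:, None] - lat), axis=1)
            d2 = np.min(np.abs(pts[:, others[1]][:, None] - lat), axis=1)
            inside |= (d1 <= 1.5) & (d2 <= 1.5)
        mc = inside.mean()
        assert abs(frac - mc) / mc < 0.02

    def test_fraction_error_shrinks_with_voxel_size(self, small_geometry):
        """Rendering error decreases on a voxel-halving sequence."""
        analytic = None
        errs = []
        for spacing in (2.0, 1.0, 0.5):
            vol = voxelize_phantom(small_geometry, spacing, "observed")
            axes = vol.axis_coordinates()
            idx = [np.flatnonzero((a >= -15) & (a <= 15)) for a in axes]
            frac = (vol.intensities[np.ix_(*idx)] == 50.0).mean()
            if analytic is None:
                # fine-sampled oracle once
                rng = np.random.default_rng(1)
                pts = rng.uniform(-15, 15, size=(200_000, 3))
                lat = np.array([-15.0, 0.0, 15.0])
                inside = np.zeros(len(pts), dtype=bool)
                for axis in range(3):
                    others = [a for a in range(3) if a != axis]
                    d1 = np.min(np.abs(pts[:, others[0]][:, None] - lat), axis=1)
                    d2 = np.min(np.abs(pts[:, others[1]][:, None] - lat), axis=1)
                    inside |= (d1 <= 1.5) & (d2 <= 1.5)
                analytic = inside.mean()
            errs.append(abs(frac - analytic))
        assert errs[2] <= errs[0]


class TestDistortionFields:
    def test_zero_and_constant_fields(self):
        f0 = make_distortion_field("polynomial", {"const": np.zeros(3)}, 90.0)
        pts = np.random.default_rng(0).normal(0, 30, (50, 3))
        assert np.allclose(f0(pts), 0.0)
        fc = make_distortion_field("polynomial", {"const": np.array([1.0, 0, 0])}, 90.0)
        assert np.allclose(fc(pts), [1.0, 0, 0])

    def test_radial_quadratic_closed_form(self):
        c = 2.0 / 90.0**2  # |d| = 2 mm at r = 90 mm
        f = make_distortion_field("radial-harmonic", {2: c}, 90.0)
        rng = np.random.default_rng(3)
        pts = rng.normal(0, 30, (100, 3))
        r = np.linalg.norm(pts, axis=1)
        mags = np.linalg.norm(f(pts), axis=1)
        assert np.max(np.abs(mags - c * r**2)) < 1e-9
        assert abs(f.meta["max_magnitude_mm"] - 2.0) < 0.02

    def test_random_field_scaled_to_peak(self):
        f = random_smooth_field(4, max_magnitude=2.0, domain_radius=52.0)
        assert abs(f.meta["max_magnitude_mm"] - 2.0) < 1e-6

    def test_nonfinite_coefficients_rejected(self):
        with pytest.raises(ValueError):
            make_distortion_field("polynomial", {"const": np.array([np.nan, 0, 0])}, 90.0)

    def test_manifest_roundtrip(self, tmp_path):
        f = random_smooth_field(5, 1.5, 40.0)
        f.save(tmp_path / "field.json")
        import json

        f2 = AnalyticDistortion.from_manifest(json.loads((tmp_path / "field.json").read_text()))
        pts = np.random.default_rng(0).normal(0, 20, (50, 3))
        assert np.allclose(f(pts), f2(pts))


class TestWarp:
    def test_zero_field_zero_noise_is_identity(self, small_geometry):
        vol = voxelize_phantom(small_geometry, 1.0)
        f = make_distortion_field("polynomial", {}, 60.0)
        out = warp_volume(vol, f, noise_sigma=0.0, seed=0)
        assert np.array_equal(out.intensities, vol.intensities)

    def test_integer_voxel_translation_matches_shift_oracle(self, small_geometry):
        vol = voxelize_phantom(small_geometry, 1.0)
        f = make_distortion_field("polynomial", {"const": np.array([2.0, 0.0, 0.0])}, 60.0)
        out = warp_volume(vol, f, noise_sigma=0.0, seed=0)
        # T shifts content +2 voxels along axis 0: out[i] == in[i-2] (interior)
        assert np.allclose(out.intensities[5:-5], vol.intensities[3:-7])

    def test_inverse_self_consistency(self, small_geometry):
        """T(T^-1(x)) returns x to within the inversion tolerance."""
        f = random_smooth_field(2, 2.0, 60.0)
        rng = np.random.default_rng(0)
        x = rng.uniform(-20, 20, (1000, 3))
        y = x - f(x)
        for _ in range(60):
            y = y - (y + f(y) - x)
        assert np.max(np.linalg.norm(y + f(y) - x, axis=1)) < 0.01

    def test_fixed_seed_bit_reproducible(self, small_geometry):
        vol = voxelize_phantom(small_geometry, 1.0)
        f = random_smooth_field(2, 1.0, 60.0)
        a = warp_volume(vol, f, noise_sigma=20.0, seed=9)
        b = warp_volume(vol, f, noise_sigma=20.0, seed=9)
        assert np.array_equal(a.intensities, b.intensities)

    def test_too_large_distortion_raises(self, small_geometry):
        vol = voxelize_phantom(small_geometry, 1.0)
        # expansive linear field: fixed-point iteration cannot converge
        f = AnalyticDistortion("polynomial", {"linear": -1.5 * np.eye(3)}, 60.0)
        with pytest.raises(DistortionTooLargeError):
            warp_volume(vol, f, noise_sigma=0.0, seed=0)


class TestTruePositions:
    def test_zero_and_constant_fields(self, small_geometry):
        assert np.array_equal(
            true_cp_positions(small_geometry, None), small_geometry.vertices
        )
        f = make_distortion_field("polynomial", {"const": np.array([0, 0, 1.0])}, 60.0)
        shifted = true_cp_positions(small_geometry, f)
        assert np.allclose(shifted - small_geometry.vertices, [0, 0, 1.0])

    def test_radial_field_matches_per_point_evaluation(self, small_geometry):
        f = make_distortion_field("radial-harmonic", {2: 1e-4}, 60.0)
        pos = true_cp_positions(small_geometry, f)
        for i in (0, 7, 13):
            v = small_geometry.vertices[i]
            assert np.allclose(pos[i], v + f(v[None, :])[0], atol=1e-12)

    def test_affine_field_midpoint_linearity(self, small_geometry):
        """For affine fields, warped cell midpoints equal warped-corner means."""
        f = AnalyticDistortion(
            "polynomial",
            {"const": np.array([0.5, -0.2, 0.1]), "linear": 0.01 * np.eye(3)},
            60.0,
        )
        warped_corners = true_cp_positions(small_geometry, f)
        warped_mids = true_cp_positions(small_geometry, f, midpoints=True)
        corner_means = warped_corners[small_geometry.cells].mean(axis=1)
        assert np.max(np.abs(warped_mids - corner_means)) < 1e-9
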