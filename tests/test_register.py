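import numpy as np
import pytest

from gridwarp import (
    AnalyticDistortion,
    ImageVolume,
    RegistrationParams,
    bspline_register,
    build_grid_geometry,
    make_grid_mask,
    resample_to_reference,
    rigid_register,
    voxelize_phantom,
    warp_volume,
)
from gridwarp.register import InsufficientROIError, RigidTransform


def make_rigidly_moved(volume, transform, noise_sigma=10.0, noise_seed=42):
    """Analytically warp a clean volume through a rigid transform (cubic
    interpolation), then add independent noise — an unbiased fixture."""
    field = AnalyticDistortion(
        "polynomial",
        {
            "const": np.asarray(transform.translation, dtype=float),
            "linear": transform.matrix() - np.eye(3),
        },
        1000.0,
    )
    moved = warp_volume(volume, field, noise_sigma=0.0, seed=0, order=3)
    rng = np.random.default_rng(noise_seed)
    return moved.copy_with(moved.intensities + rng.normal(0, noise_sigma, moved.shape))


class TestRigidTransform:
    def test_inverse_composes_to_identity(self):
        t = RigidTransform((0.1, -0.2, 0.3), (4.0, -5.0, 6.0), (1.0, 2.0, 3.0))
        pts = np.random.default_rng(0).normal(0, 30, (100, 3))
        back = t.inverse()._apply_full(t.apply(pts))
        assert np.max(np.abs(back - pts)) < 1e-9

    def test_preserves_pairwise_distances(self):
        t = RigidTransform((0.3, 0.2, -0.4), (10.0, 0.0, -3.0), (0.0, 0.0, 0.0))
        pts = np.random.default_rng(1).normal(0, 20, (50, 3))
        d0 = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        mapped = t.apply(pts)
        d1 = np.linalg.norm(mapped[:, None] - mapped[None, :], axis=-1)
        assert np.max(np.abs(d1 - d0)) < 1e-9


@pytest.fixture(scope="module")
def rigid_geometry():
    return build_grid_geometry(15.0, 3.0, (90.0, 90.0, 90.0))


@pytest.fixture(scope="module")
def rigid_fixed(rigid_geometry):
    clean = voxelize_phantom(rigid_geometry, 1.0, "reference")
    noisy = clean.copy_with(
        clean.intensities + np.random.default_rng(0).normal(0, 10, clean.shape)
    )
    return clean, noisy


class TestRigidRegister:
    def test_self_registration_is_identity(self, rigid_fixed):
        _, fixed = rigid_fixed
        t = rigid_register(fixed, fixed, 27.0, np.zeros(3), "mean-squares")
        assert np.max(np.abs(t.translation)) < 0.05
        assert np.max(np.abs(t.rotation)) < np.deg2rad(0.05)

    def test_known_pose_recovered_within_roi(self, rigid_fixed):
        """(3, -2, 5) mm translation + 2 deg rotation from the 27 mm ROI."""
        clean, fixed = rigid_fixed
        deg = np.pi / 180
        t_true = RigidTransform((2 * deg, 0.0, 0.0), (3.0, -2.0, 5.0), (0.0, 0.0, 0.0))
        moving = make_rigidly_moved(clean, t_true)
        t = rigid_register(moving, fixed, roi_radius=27.0, roi_center=np.zeros(3))
        assert np.max(np.abs(np.array(t.translation) - np.array(t_true.translation))) < 0.1
        assert np.max(np.abs(np.array(t.rotation) - np.array(t_true.rotation))) < np.deg2rad(0.1)

    def test_cross_contrast_pose_with_correlation_metric(self, rigid_geometry, rigid_fixed):
        _, fixed = rigid_fixed
        obs_clean = voxelize_phantom(rigid_geometry, 1.0, "observed")
        deg = np.pi / 180
        t_true = RigidTransform((0.0, -1.5 * deg, 0.0), (2.0, 1.0, -3.0), (0.0, 0.0, 0.0))
        moving = make_rigidly_moved(obs_clean, t_true, noise_sigma=20.0)
        t = rigid_register(moving, fixed, 27.0, np.zeros(3), metric="correlation")
        pts = np.random.default_rng(1).normal(0, 15, (200, 3))
        assert np.max(np.abs(t.apply(pts) - t_true.apply(pts))) < 0.15

    def test_tiny_roi_rejected(self, rigid_fixed):
        _, fixed = rigid_fixed
        with pytest.raises(InsufficientROIError):
            rigid_register(fixed, fixed, roi_radius=4.0, roi_center=np.zeros(3))


class TestResample:
    def test_identity_on_same_grid_is_unchanged(self, rigid_fixed):
        _, fixed = rigid_fixed
        out = resample_to_reference(fixed, fixed, None)
        assert np.allclose(out.intensities, fixed.intensities)

    def test_constant_volume_stays_constant_in_field(self):
        vol = ImageVolume(np.full((20, 20, 20), 7.0), (1, 1, 1), (-9.5, -9.5, -9.5))
        t = RigidTransform((0.02, 0, 0), (1.0, 0.5, -0.5), (0, 0, 0))
        out = resample_to_reference(vol, vol, t)
        assert np.allclose(out.intensities[5:-5, 5:-5, 5:-5], 7.0)

    def test_integer_translation_moves_delta_by_voxel_offset(self):
        arr = np.zeros((21, 21, 21))
        arr[10, 10, 10] = 1.0
        vol = ImageVolume(arr, (1, 1, 1), (-10, -10, -10))
        # T(x) = x + (2, 0, -3): output(x) = volume(x + offset)
        t = RigidTransform((0, 0, 0), (2.0, 0.0, -3.0), (0, 0, 0))
        out = resample_to_reference(vol, vol, t)
        assert out.intensities[8, 10, 13] == pytest.approx(1.0)


class TestBSplineRegister:
    def test_identity_recovery(self, geometry, identity_pair):
        ref, obs = identity_pair
        t = bspline_register(ref, obs, RegistrationParams(seed=1))
        d = np.linalg.norm(t.apply(geometry.vertices) - geometry.vertices, axis=1)
        assert d.mean() <= 0.1
        assert d.max() <= 0.5

    def test_known_field_recovery_mutual_information(
        self, geometry, smooth_field, field_registration
    ):
        true = geometry.vertices + smooth_field(geometry.vertices)
        errs = field_registration.apply(geometry.vertices) - true
        rmse = np.sqrt((errs**2).sum(axis=1).mean())
        assert rmse <= 0.25
        assert np.linalg.norm(errs, axis=1).mean() <= 0.2

    def test_known_field_recovery_mean_squares_same_contrast(self, geometry, smooth_field):
        ref = voxelize_phantom(geometry, 1.0, "reference")
        obs = warp_volume(ref, smooth_field, noise_sigma=10.0, seed=3)
        t = bspline_register(ref, obs, RegistrationParams(metric="mean-squares", seed=1))
        true = geometry.vertices + smooth_field(geometry.vertices)
        errs = t.apply(geometry.vertices) - true
        assert np.sqrt((errs**2).sum(axis=1).mean()) <= 0.25

    def test_overfitting_at_small_final_grid_spacing(
        self, geometry, smooth_field, field_registration, fgs5_registration
    ):
        """Fig-4-style shape: FGS below the vertex spacing inflates both the
        CP error and, more strongly, the midpoint error."""
        true_cp = geometry.vertices + smooth_field(geometry.vertices)
        mids = geometry.cell_midpoints()
        true_mid = mids + smooth_field(mids)

        def errors(t):
            cp = np.linalg.norm(t.apply(geometry.vertices) - true_cp, axis=1).mean()
            mid = np.linalg.norm(t.apply(mids) - true_mid, axis=1).mean()
            return cp, mid

        cp5, mid5 = errors(fgs5_registration)
        cp30, mid30 = errors(field_registration)
        assert cp5 > cp30
        assert mid5 > cp5
        assert mid30 <= cp30 + 0.05

    def test_deterministic_given_seed(self, identity_pair):
        ref, obs = identity_pair
        p = RegistrationParams(nss=1000, mni=30, nr=2, seed=11)
        t1 = bspline_register(ref, obs, p)
        t2 = bspline_register(ref, obs, p)
        assert np.array_equal(t1.coefficients, t2.coefficients)

    def test_best_so_far_metric_non_increasing(self, field_registration):
        for trace in field_registration.meta["metric_trace"].values():
            best = np.minimum.accumulate(trace)
            assert np.all(np.diff(best) <= 0)

    def test_mismatched_grids_rejected(self, identity_pair):
        ref, obs = identity_pair
        shrunk = ImageVolume(
            obs.intensities[:-2], obs.voxel_spacing, obs.origin, obs.modality_tag
        )
        with pytest.raises(ValueError, match="common grid"):
            bspline_register(ref, shrunk, RegistrationParams())

    def test_out_of_range_params_warn(self):
        with pytest.warns(UserWarning):
            RegistrationParams(fgs=3.0)

    def test_grid_mask_covers_bars(self, identity_pair, geometry):
        ref, _ = identity_pair
        mask = make_grid_mask(ref)
        idx = np.round(ref.voxel_indices(geometry.vertices)).astype(int)
        assert mask[idx[:, 0], idx[:, 1], idx[:, 2]].all()
        assert 0 < mask.mean() < 0.9
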