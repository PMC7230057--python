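import itertools

import numpy as np
import pytest

from gridwarp import (
    ControlPointSet,
    ImageVolume,
    build_vertex_template,
    extract_cp_candidates,
    ncc_match,
    pair_control_points,
)
from gridwarp.localize import DegenerateTemplateError


def brute_force_ncc(volume: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Direct sliding-window zero-normalized cross-correlation (valid region)."""
    t = template - template.mean()
    tnorm = np.sqrt((t**2).sum())
    out_shape = tuple(v - s + 1 for v, s in zip(volume.shape, template.shape))
    out = np.zeros(out_shape)
    for i in range(out_shape[0]):
        for j in range(out_shape[1]):
            for k in range(out_shape[2]):
                w = volume[
                    i : i + template.shape[0],
                    j : j + template.shape[1],
                    k : k + template.shape[2],
                ]
                wc = w - w.mean()
                denom = np.sqrt((wc**2).sum()) * tnorm
                out[i, j, k] = (wc * t).sum() / denom if denom > 0 else 0.0
    return out


class TestTemplate:
    def test_printed_size_at_half_mm_voxels(self):
        tpl = build_vertex_template(3.0, 7.5, 0.5)
        assert tpl.shape == (15, 15, 15)

    def test_symmetry_under_axis_permutations_and_flips(self):
        tpl = build_vertex_template(3.0, 7.5, 0.5)
        for perm in itertools.permutations(range(3)):
            assert np.array_equal(tpl, np.transpose(tpl, perm))
        for axis in range(3):
            assert np.array_equal(tpl, np.flip(tpl, axis))

    def test_foreground_fraction_matches_inclusion_exclusion(self):
        # voxel size chosen so bar surfaces fall midway between voxel
        # centers: the rendered fraction then equals the closed form
        # (3 a^2 s - 2 a^3) / s^3 at the template's realized dimensions
        spacing = 0.6
        tpl = build_vertex_template(3.0, 7.5, spacing, polarity="grid-bright")
        a = 3.0
        s = tpl.shape[0] * spacing
        analytic = (3 * a * a * s - 2 * a**3) / s**3
        assert abs(tpl.mean() - analytic) / analytic < 0.02

    def test_even_count_adjusted_to_odd(self):
        tpl = build_vertex_template(3.0, 8.0, 1.0)  # 8 voxels -> bumped to 9
        assert all(n % 2 == 1 for n in tpl.shape)

    def test_polarities_are_complementary(self):
        dark = build_vertex_template(3.0, 7.5, 0.5, "grid-dark")
        bright = build_vertex_template(3.0, 7.5, 0.5, "grid-bright")
        assert np.array_equal(dark + bright, np.ones_like(dark))


class TestNCC:
    def test_exact_copy_peaks_at_one(self):
        rng = np.random.default_rng(0)
        tpl = rng.random((5, 5, 5))
        vol_arr = rng.random((20, 20, 20))
        vol_arr[7:12, 3:8, 10:15] = tpl
        vol = ImageVolume(vol_arr, (1, 1, 1), (0, 0, 0))
        corr = ncc_match(vol, tpl)
        assert corr.intensities[9, 5, 12] == pytest.approx(1.0, abs=1e-9)

    def test_bounded_and_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        arr = rng.normal(0, 1, (16, 16, 16))
        tpl = rng.normal(0, 1, (5, 5, 5))
        vol = ImageVolume(arr, (1, 1, 1), (0, 0, 0))
        corr = ncc_match(vol, tpl).intensities
        assert corr.min() >= -1.0 - 1e-9 and corr.max() <= 1.0 + 1e-9
        oracle = brute_force_ncc(arr, tpl)
        inner = corr[2:14, 2:14, 2:14]
        assert np.max(np.abs(inner - oracle)) < 1e-6

    def test_invariant_to_affine_intensity_rescaling(self):
        rng = np.random.default_rng(2)
        arr = rng.normal(0, 1, (20, 20, 20))
        tpl = build_vertex_template(2.0, 5.0, 1.0)
        vol = ImageVolume(arr, (1, 1, 1), (0, 0, 0))
        scaled = ImageVolume(3.7 * arr + 120.0, (1, 1, 1), (0, 0, 0))
        c1 = ncc_match(vol, tpl).intensities
        c2 = ncc_match(scaled, tpl).intensities
        assert np.max(np.abs(c1 - c2)) < 1e-6

    def test_degenerate_template_rejected(self):
        vol = ImageVolume(np.random.default_rng(0).random((10, 10, 10)), (1, 1, 1), (0, 0, 0))
        with pytest.raises(DegenerateTemplateError):
            ncc_match(vol, np.ones((3, 3, 3)))


class TestExtract:
    def _corr_volume(self, arr):
        return ImageVolume(arr, (1, 1, 1), (0, 0, 0))

    def test_symmetric_blob_localizes_at_center(self):
        arr = np.zeros((15, 15, 15))
        arr[6:9, 6:9, 6:9] = 0.8
        arr[7, 7, 7] = 0.95
        cps = extract_cp_candidates(self._corr_volume(arr), threshold=0.5)
        assert len(cps) == 1
        assert np.allclose(cps.points[0], [7, 7, 7], atol=1e-9)

    def test_two_separated_blobs(self):
        arr = np.zeros((20, 20, 20))
        arr[3:6, 3:6, 3:6] = 0.9
        arr[14:17, 14:17, 14:17] = 0.9
        cps = extract_cp_candidates(self._corr_volume(arr), threshold=0.5)
        assert len(cps) == 2

    def test_small_components_dropped(self):
        arr = np.zeros((15, 15, 15))
        arr[7, 7, 7] = 0.9  # single voxel: below min size
        arr[2:5, 2:5, 2:5] = 0.9
        cps = extract_cp_candidates(self._corr_volume(arr), threshold=0.5, min_voxels=3)
        assert len(cps) == 1

    def test_empty_suprathreshold_warns_not_raises(self):
        arr = np.zeros((10, 10, 10))
        with pytest.warns(UserWarning):
            cps = extract_cp_candidates(self._corr_volume(arr), threshold=0.5)
        assert len(cps) == 0

    def test_nonmax_suppression_keeps_strongest(self):
        arr = np.zeros((20, 20, 20))
        arr[4:7, 4:7, 4:7] = 0.9
        arr[9:12, 4:7, 4:7] = 0.6  # 5 voxels away: suppressed at 6 mm separation
        cps = extract_cp_candidates(self._corr_volume(arr), threshold=0.5, min_separation=6.0)
        assert len(cps) == 1
        assert np.allclose(cps.points[0], [5, 5, 5])


class TestPairing:
    def test_identical_sets_pair_with_zero_displacement(self):
        pts = np.random.default_rng(0).uniform(-20, 20, (30, 3))
        a = ControlPointSet.from_points(pts, "reference")
        b = ControlPointSet.from_points(pts.copy(), "detected")
        pairs = pair_control_points(a, b, 7.5)
        assert len(pairs) == 30
        assert np.allclose(pairs.displacements, 0)

    def test_uniform_shift_recovered(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(-20, 20, (25, 3))
        a = ControlPointSet.from_points(pts, "reference")
        b = ControlPointSet.from_points(pts + [1.0, 0, 0], "detected")
        pairs = pair_control_points(a, b, 7.5)
        assert len(pairs) == 25
        assert np.allclose(pairs.magnitudes, 1.0)

    def test_distant_point_left_unmatched(self):
        a = ControlPointSet.from_points(np.array([[0.0, 0, 0], [30, 0, 0]]), "reference")
        b = ControlPointSet.from_points(np.array([[0.0, 0, 0], [39, 0, 0]]), "detected")
        pairs = pair_control_points(a, b, max_distance=7.5)
        assert len(pairs) == 1
        assert 1 in pairs.unmatched_reference_ids
        assert 1 in pairs.unmatched_detected_ids

    def test_pairing_symmetric_under_role_swap(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(-20, 20, (40, 3))
        jitter = rng.normal(0, 0.5, (40, 3))
        a = ControlPointSet.from_points(pts, "reference")
        b = ControlPointSet.from_points(pts + jitter, "detected")
        ab = pair_control_points(a, b, 7.5)
        ba = pair_control_points(b, a, 7.5)
        fwd = {(r, d) for r, d in zip(ab.reference_ids, ab.detected_ids)}
        rev = {(d, r) for r, d in zip(ba.reference_ids, ba.detected_ids)}
        assert fwd == rev
        # displacements negate under the swap
        order = np.argsort(ab.reference_ids)
        order2 = np.argsort(ba.detected_ids)
        assert np.allclose(
            ab.displacements[order], -ba.displacements[order2]
        )

    def test_tsv_roundtrip(self, tmp_path):
        pts = np.random.default_rng(3).uniform(-10, 10, (8, 3))
        cps = ControlPointSet.from_points(pts, "detected")
        cps.save_tsv(tmp_path / "cps.tsv")
        back = ControlPointSet.load_tsv(tmp_path / "cps.tsv")
        assert np.allclose(back.points, pts, atol=1e-6)
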