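"""Fiducial-based similarity registration and label-mask resampling."""

import numpy as np
import pytest

from nanoxrf.registration import (
    FiducialSet,
    RegionMask,
    SimilarityTransform,
    apply_transform,
    check_alignment,
    estimate_similarity,
)


def grid_search_similarity(src, dst, scales, rotations):
    """Brute-force oracle: best (scale, rotation) on a grid, translation
    closed-form from the centroids, scored by summed squared residuals."""
    best = None
    for s in scales:
        for th in rotations:
            rot = s * np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            moved = src @ rot.T
            t = dst.mean(axis=0) - moved.mean(axis=0)
            ssd = np.sum((moved + t - dst) ** 2)
            if best is None or ssd < best[0]:
                best = (ssd, s, th, t)
    return best


@pytest.fixture
def disk_mask():
    rr, cc = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
    labels = ((rr - 32) ** 2 + (cc - 32) ** 2 <= 10**2).astype(np.uint8)
    return RegionMask(labels, {1: "nucleus"}, 50.0)


class TestEstimateSimilarity:
    def test_identical_points_give_identity(self):
        pts = np.array([[1.0, 2.0], [5.0, 7.0], [9.0, 3.0]])
        tf = estimate_similarity(FiducialSet(pts, pts))
        assert tf.scale == pytest.approx(1.0)
        assert tf.rotation == pytest.approx(0.0)
        assert np.allclose(tf.translation, 0.0)
        assert tf.rms_residual == pytest.approx(0.0, abs=1e-12)

    def test_rotation_and_shift_recovered_exactly(self):
        src = np.array([[0, 0], [10, 0], [0, 10], [7, 3]], float)
        dst = np.column_stack([-src[:, 1] + 10, src[:, 0] - 5])  # 90 deg + (10, -5)
        tf = estimate_similarity(FiducialSet(src, dst))
        assert tf.rotation == pytest.approx(np.pi / 2)
        assert tf.scale == pytest.approx(1.0)
        assert tf.translation == pytest.approx((10.0, -5.0))
        assert tf.rms_residual < 1e-9

    def test_jittered_fiducials_match_grid_search_oracle(self):
        rng = np.random.default_rng(12)
        src = rng.uniform(0, 100, size=(6, 2))
        true = SimilarityTransform(scale=1.1, rotation=0.3, translation=(12.0, -4.0))
        dst = true.apply(src) + rng.normal(0, 0.5, size=(6, 2))
        tf = estimate_similarity(FiducialSet(src, dst))
        _, s_o, th_o, t_o = grid_search_similarity(
            src, dst,
            scales=np.linspace(1.0, 1.2, 81),
            rotations=np.linspace(0.2, 0.4, 81),
        )
        assert tf.scale == pytest.approx(s_o, abs=0.005)
        assert tf.rotation == pytest.approx(th_o, abs=0.005)
        assert np.allclose(tf.translation, t_o, atol=0.6)
        assert tf.rms_residual <= 1.0

    def test_pair_order_invariance(self):
        rng = np.random.default_rng(5)
        src = rng.uniform(0, 50, size=(8, 2))
        dst = SimilarityTransform(0.9, -0.2, (3.0, 8.0)).apply(src)
        perm = rng.permutation(8)
        tf_a = estimate_similarity(FiducialSet(src, dst))
        tf_b = estimate_similarity(FiducialSet(src[perm], dst[perm]))
        assert tf_a.scale == pytest.approx(tf_b.scale)
        assert tf_a.rotation == pytest.approx(tf_b.rotation)
        assert np.allclose(tf_a.translation, tf_b.translation)

    def test_inverse_returns_points(self):
        rng = np.random.default_rng(8)
        src = rng.uniform(0, 50, size=(5, 2))
        dst = SimilarityTransform(1.3, 0.7, (-5.0, 2.0)).apply(src)
        tf = estimate_similarity(FiducialSet(src, dst))
        back = tf.inverse().apply(tf.apply(src))
        assert np.allclose(back, src, atol=1e-9)

    def test_degenerate_fiducials_rejected(self):
        pts = np.array([[2.0, 2.0], [2.0, 2.0 + 1e-9]])
        with pytest.raises(ValueError, match="duplicate|degenerate"):
            fid = FiducialSet(np.array([[2.0, 2.0], [2.0, 2.0]]), pts)
        with pytest.raises(ValueError, match="degenerate"):
            estimate_similarity(FiducialSet(pts, pts))


class TestApplyTransform:
    def test_identity_leaves_raster_unchanged(self, disk_mask):
        out = apply_transform(
            disk_mask, SimilarityTransform(1.0, 0.0, (0.0, 0.0)), disk_mask.shape
        )
        np.testing.assert_array_equal(out.labels, disk_mask.labels)

    def test_integer_translation_shifts_and_conserves_area(self, disk_mask):
        out = apply_transform(
            disk_mask, SimilarityTransform(1.0, 0.0, (5.0, -3.0)), disk_mask.shape
        )
        assert out.labels.sum() == disk_mask.labels.sum()
        np.testing.assert_array_equal(
            out.labels[29 - 10 : 29 + 11, 37 - 10 : 37 + 11],
            disk_mask.labels[32 - 10 : 32 + 11, 32 - 10 : 32 + 11],
        )

    def test_scale_two_quadruples_disk_area_within_boundary_tolerance(self, disk_mask):
        small = RegionMask(disk_mask.labels.copy(), {1: "nucleus"}, 50.0)
        out = apply_transform(
            small, SimilarityTransform(2.0, 0.0, (-32.0, -32.0)), (128, 128)
        )
        area_in = small.labels.sum()
        area_out = out.labels.sum()
        perimeter = 2 * np.pi * 20  # scaled disk radius in pixels
        assert abs(area_out - 4 * area_in) <= perimeter + 4

    def test_resampling_introduces_no_new_labels(self, disk_mask):
        out = apply_transform(
            disk_mask, SimilarityTransform(1.7, 0.4, (3.0, 1.0)), (64, 64)
        )
        assert set(np.unique(out.labels)) <= set(np.unique(disk_mask.labels)) | {0}

    def test_out_of_bounds_becomes_background(self, disk_mask):
        out = apply_transform(
            disk_mask, SimilarityTransform(1.0, 0.0, (200.0, 200.0)), (64, 64)
        )
        assert not out.labels.any()


class TestCheckAlignment:
    def test_zero_rms_passes(self):
        assert check_alignment(SimilarityTransform(1, 0, (0, 0), rms_residual=0.0)).passed

    def test_two_pixel_rms_fails_default_threshold(self):
        report = check_alignment(SimilarityTransform(1, 0, (0, 0), rms_residual=2.0))
        assert not report.passed
        assert report.max_rms == 1.0

    def test_half_pixel_jitter_passes_default_threshold(self):
        rng = np.random.default_rng(2)
        src = rng.uniform(0, 100, size=(6, 2))
        dst = SimilarityTransform(1.0, 0.1, (4.0, 4.0)).apply(src)
        dst = dst + rng.normal(0, 0.4, size=dst.shape)
        tf = estimate_similarity(FiducialSet(src, dst))
        report = check_alignment(tf)
        assert report.passed
        assert len(report.per_fiducial) == 6


def test_region_mask_round_trip(tmp_path, disk_mask):
    path = disk_mask.write(tmp_path / "mask.tif")
    back = RegionMask.read(path)
    np.testing.assert_array_equal(back.labels, disk_mask.labels)
    assert back.class_table == disk_mask.class_table
    assert back.pixel_size_nm == disk_mask.pixel_size_nm


def test_fiducial_csv_round_trip(tmp_path):
    fid = FiducialSet(np.array([[0.0, 1.0], [5.0, 2.0]]), np.array([[1.0, 1.5], [6.0, 2.5]]))
    fid.write_csv(tmp_path / "fid.csv")
    back = FiducialSet.read_csv(tmp_path / "fid.csv")
    np.testing.assert_allclose(back.src, fid.src)
    np.testing.assert_allclose(back.dst, fid.dst)
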