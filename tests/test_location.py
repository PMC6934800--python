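import numpy as np
import pytest

import behavtrack as bt
from behavtrack import fixtures as fx
from behavtrack.video_io import array_stream


def brute_percentile(values, q):
    """Independent linear-interpolation percentile (sort + interpolate)."""
    v = np.sort(np.asarray(values).ravel())
    h = (v.size - 1) * q / 100.0
    lo, hi = int(np.floor(h)), int(np.ceil(h))
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def brute_com(mat):
    """Double-loop intensity-weighted mean coordinate."""
    total = sx = sy = 0.0
    for y in range(mat.shape[0]):
        for x in range(mat.shape[1]):
            v = mat[y, x]
            total += v
            sx += v * x
            sy += v * y
    return sx / total, sy / total


class TestReference:
    def test_constant_video_reference_is_constant(self):
        stack = np.full((7, 8, 8), 42.0)
        ref = bt.make_reference(array_stream(stack), bt.LocationParams())
        np.testing.assert_array_equal(ref.image, 42.0)

    def test_median_ignores_transient_animal(self):
        """A pixel occluded on a minority of frames keeps its background value."""
        stack = np.full((5, 2, 2), 10.0)
        stack[3, 0, 0] = 200.0
        ref = bt.make_reference(array_stream(stack), bt.LocationParams())
        assert ref.image[0, 0] == 10.0

    def test_median_matches_brute_force_oracle(self, rng):
        stack = rng.integers(0, 256, size=(9, 20, 20)).astype(float)
        ref = bt.make_reference(
            array_stream(stack), bt.LocationParams(reference_sample_n=9)
        )
        oracle = np.empty((20, 20))
        for y in range(20):
            for x in range(20):
                v = sorted(stack[:, y, x])
                oracle[y, x] = v[len(v) // 2]
        np.testing.assert_array_equal(ref.image, oracle)

    def test_default_sample_count_is_100(self, rng):
        stack = rng.integers(0, 256, size=(250, 4, 4)).astype(float)
        ref = bt.make_reference(array_stream(stack), bt.LocationParams())
        assert len(ref.sample_indices) == 100
        assert ref.source == "same_video"

    def test_sampling_respects_frame_range(self, rng):
        stack = rng.integers(0, 256, size=(50, 4, 4)).astype(float)
        stream = array_stream(stack, frame_range=bt.FrameRange(10, 30))
        ref = bt.make_reference(stream, bt.LocationParams())
        assert all(10 <= i < 30 for i in ref.sample_indices)

    def test_seeded_sampling_is_reproducible(self, rng):
        stack = rng.integers(0, 256, size=(200, 4, 4)).astype(float)
        p = bt.LocationParams(rng_seed=7)
        a = bt.make_reference(array_stream(stack), p)
        b = bt.make_reference(array_stream(stack), p)
        assert a.sample_indices == b.sample_indices
        np.testing.assert_array_equal(a.image, b.image)

    def test_external_stream_dimension_mismatch(self, rng):
        main = array_stream(rng.integers(0, 256, size=(5, 8, 8)).astype(float))
        ext = array_stream(rng.integers(0, 256, size=(5, 6, 8)).astype(float))
        with pytest.raises(ValueError, match="dimensions"):
            bt.make_reference(main, bt.LocationParams(), external_stream=ext)

    def test_external_stream_used_when_given(self):
        main = array_stream(np.full((5, 4, 4), 99.0))
        ext = array_stream(np.full((5, 4, 4), 10.0))
        ref = bt.make_reference(main, bt.LocationParams(), external_stream=ext)
        np.testing.assert_array_equal(ref.image, 10.0)
        assert ref.source == "external_video"


class TestFrameDifference:
    REF = np.array([[20.0, 20.0], [20.0, 20.0]])
    FRAME = np.array([[10.0, 20.0], [30.0, 40.0]])

    @pytest.mark.parametrize(
        "mode,expected",
        [
            ("absolute", [[10, 0], [10, 20]]),
            ("animal_darker", [[10, 0], [0, 0]]),
            ("animal_lighter", [[0, 0], [10, 20]]),
        ],
    )
    def test_modes_hand_checked(self, mode, expected):
        out = bt.frame_difference(self.FRAME, self.REF, mode)
        np.testing.assert_array_equal(out, expected)

    def test_identical_frames_give_zero(self):
        out = bt.frame_difference(self.REF, self.REF, "absolute")
        np.testing.assert_array_equal(out, 0.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bt.frame_difference(np.zeros((2, 3)), self.REF, "absolute")


class TestThreshold:
    def test_top_percentile_survives(self):
        mat = np.arange(1, 101, dtype=float).reshape(10, 10)
        out = bt.threshold_by_percentile(mat, 99)
        assert set(out[out > 0]) == {100.0}

    def test_cutoff_from_sort_oracle(self, rng):
        mat = rng.uniform(0, 50, size=(10, 10))
        out = bt.threshold_by_percentile(mat, 99)
        c = brute_percentile(mat, 99)
        np.testing.assert_array_equal(out, np.where(mat > c, mat, 0.0))

    def test_all_equal_all_zeroed(self):
        out = bt.threshold_by_percentile(np.full((5, 5), 3.0), 99)
        np.testing.assert_array_equal(out, 0.0)

    def test_survivors_keep_magnitudes(self, rng):
        mat = rng.uniform(0, 50, size=(20, 20))
        out = bt.threshold_by_percentile(mat, 90)
        nz = out > 0
        np.testing.assert_array_equal(out[nz], mat[nz])


class TestWindowWeight:
    def test_zero_weight_is_identity(self, rng):
        mat = rng.uniform(0, 10, size=(9, 9))
        out = bt.apply_location_weight(mat, (4, 4), 3, 0.0)
        np.testing.assert_array_equal(out, mat)

    def test_full_weight_zeroes_outside(self):
        mat = np.full((9, 9), 5.0)
        out = bt.apply_location_weight(mat, (4, 4), 3, 1.0)
        assert out[4, 4] == 5.0 and out[3, 3] == 5.0
        assert out[0, 0] == 0.0 and out[8, 8] == 0.0
        assert (out > 0).sum() == 9

    def test_partial_weight_arithmetic(self):
        mat = np.full((9, 9), 50.0)
        out = bt.apply_location_weight(mat, (4, 4), 3, 0.8)
        assert out[4, 4] == 50.0
        np.testing.assert_allclose(out[0, 0], 10.0)

    def test_window_clipped_at_border(self):
        mat = np.full((9, 9), 1.0)
        out = bt.apply_location_weight(mat, (0, 0), 5, 1.0)
        assert (out > 0).sum() == 9  # 3x3 corner remnant of a 5x5 window


class TestCenterOfMass:
    def test_single_pixel(self):
        mat = np.zeros((8, 8))
        mat[5, 3] = 7.0
        assert bt.center_of_mass(mat, (0, 0)) == (3.0, 5.0)

    def test_symmetric_pair(self):
        mat = np.zeros((4, 4))
        mat[0, 0] = mat[0, 2] = 3.0
        assert bt.center_of_mass(mat, (0, 0)) == (1.0, 0.0)

    def test_weighted_mean(self):
        mat = np.zeros((2, 5))
        mat[0, 0], mat[0, 4] = 1.0, 3.0
        x, y = bt.center_of_mass(mat, (0, 0))
        assert (x, y) == (3.0, 0.0)

    def test_all_zero_falls_back(self, caplog):
        with caplog.at_level("WARNING", logger="behavtrack.location"):
            pos = bt.center_of_mass(np.zeros((4, 4)), (1.5, 2.5))
        assert pos == (1.5, 2.5)
        assert any("all-zero" in r.message for r in caplog.records)

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(20):
            mat = rng.uniform(0, 10, size=(20, 20))
            ox, oy = brute_com(mat)
            x, y = bt.center_of_mass(mat, (0, 0))
            np.testing.assert_allclose((x, y), (ox, oy), atol=1e-10)


class TestROI:
    SQUARE = bt.ROI("sq", [(0, 0), (10, 0), (10, 10), (0, 10)])

    def test_centroid_inside(self):
        assert bt.point_in_roi((5, 5), self.SQUARE)

    def test_far_point_outside(self):
        assert not bt.point_in_roi((20, 20), self.SQUARE)

    def test_boundary_counts_as_inside(self):
        assert bt.point_in_roi((5, 0), self.SQUARE)
        assert bt.point_in_roi((10, 10), self.SQUARE)

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError):
            bt.ROI("line", [(0, 0), (5, 5), (10, 10)])
        with pytest.raises(ValueError):
            bt.ROI("two", [(0, 0), (1, 1)])


class TestScale:
    def test_factor_arithmetic(self):
        cal = bt.calibrate_scale((0, 0), (100, 0), 200, "cm")
        assert cal.factor == 2.0

    def test_345_triangle(self):
        assert bt.calibrate_scale((0, 0), (3, 4), 5).factor == 1.0

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            bt.calibrate_scale((1, 1), (1, 1), 10)


class TestTrackSession:
    def test_recovers_moving_disk(self, tracking_bundle, tracking_stream):
        params = bt.LocationParams(rng_seed=0)
        ref = bt.make_reference(tracking_stream, params)
        res = bt.track_session(tracking_stream, ref, params)
        truth = tracking_bundle.trajectory.as_array()
        err = np.hypot(res.data["x"] - truth[:, 0], res.data["y"] - truth[:, 1])
        assert err.max() < 0.5
        true_len = tracking_bundle.true_path_length
        assert abs(res.total_distance_px - true_len) / true_len < 0.02

    def test_stationary_disk_zero_distance(self):
        """Noise-free stationary scene tracked against an external reference."""
        bundle = fx.render_scene(
            fx.SceneSpec(height=60, width=60, n_frames=50, disk_radius=5,
                         disk_intensity=30, background=200, noise_amp=0, seed=0,
                         trajectory=fx.stationary_trajectory(50, 30, 25))
        )
        ext = array_stream(np.full((3, 60, 60), 200.0))
        params = bt.LocationParams()
        ref = bt.make_reference(bundle.stream(), params, external_stream=ext)
        res = bt.track_session(bundle.stream(), ref, params)
        assert res.total_distance_px == 0.0

    def test_scaled_distance_is_factor_times_pixels(self, tracking_stream):
        params = bt.LocationParams(rng_seed=0)
        ref = bt.make_reference(tracking_stream, params)
        cal = bt.calibrate_scale((0, 0), (0, 100), 200, "cm")
        res = bt.track_session(tracking_stream, ref, params, cal=cal)
        np.testing.assert_allclose(
            res.data["distance_cm"], 2.0 * res.data["distance_px"]
        )

    def test_roi_flags_recorded(self, tracking_bundle, tracking_stream):
        params = bt.LocationParams(rng_seed=0)
        ref = bt.make_reference(tracking_stream, params)
        left = bt.ROI("left", [(0, 0), (60, 0), (60, 100), (0, 100)])
        res = bt.track_session(tracking_stream, ref, params, rois=[left])
        truth = tracking_bundle.trajectory.as_array()
        np.testing.assert_array_equal(res.data["left"], (truth[:, 0] <= 60).astype(int))

    def test_contrast_polarity_symmetry(self, tracking_bundle):
        """absolute mode tracks the inverted video identically (within 0.5 px)."""
        stack = tracking_bundle.stack
        inv = 255.0 - stack
        out = []
        for data in (stack, inv):
            stream = array_stream(data)
            params = bt.LocationParams(rng_seed=0)
            ref = bt.make_reference(stream, params)
            res = bt.track_session(stream, ref, params)
            out.append(res.data[["x", "y"]].to_numpy())
        assert np.hypot(*(out[0] - out[1]).T).max() < 0.5

    def test_illumination_invariance(self, tracking_bundle):
        """Halving all pixel values leaves the trajectory within 0.5 px."""
        stack = tracking_bundle.stack
        out = []
        for data in (stack, stack * 0.5):
            stream = array_stream(data)
            params = bt.LocationParams(rng_seed=0)
            ref = bt.make_reference(stream, params)
            res = bt.track_session(stream, ref, params)
            out.append(res.data[["x", "y"]].to_numpy())
        assert np.hypot(*(out[0] - out[1]).T).max() < 0.5

    def test_distance_rigid_motion_invariance(self):
        """Per-frame distances are preserved under translation + rotation."""
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 50, size=(30, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = pts @ rot.T + [100, -40]
        d0 = np.hypot(*np.diff(pts, axis=0).T)
        d1 = np.hypot(*np.diff(moved, axis=0).T)
        np.testing.assert_allclose(d0, d1, atol=1e-9)

    def test_reference_shape_mismatch_rejected(self, tracking_stream):
        bad = bt.ReferenceFrame(np.zeros((10, 10)), (), "same_video")
        with pytest.raises(ValueError):
            bt.track_session(tracking_stream, bad)
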