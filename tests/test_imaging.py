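"""Segmentation front-end: channel extraction through centroid recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epimesh import SegmentationConfig, segment_nuclei
from epimesh.imaging import (
    apply_overrides,
    clean_mask,
    compute_centroid,
    denoise,
    extract_channel,
    fill_contour,
    otsu_threshold,
    saturate_stretch,
    sharpen,
    trace_contours,
)
from epimesh.synthetic import (
    SyntheticImageConfig,
    random_disk_layout,
    render_nuclei_image,
)


class TestExtractChannel:
    def test_constant_blue_plane_normalizes_to_one(self):
        img = np.zeros((4, 4, 3))
        img[..., 2] = 0.4
        assert np.array_equal(extract_channel(img, "blue"), np.ones((4, 4)))

    def test_grayscale_identity_up_to_scaling(self):
        img = np.array([[0, 128], [255, 64]], dtype=np.uint8)
        out = extract_channel(img)
        assert out.max() == 1.0
        assert np.allclose(out, img / 255.0)

    def test_all_zero_channel_no_division_by_zero(self):
        img = np.zeros((4, 4, 3))
        img[..., 0] = 1.0  # bright red, dark blue
        assert np.array_equal(extract_channel(img, "blue"), np.zeros((4, 4)))

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError):
            extract_channel(np.zeros((4, 4, 3)), "ultraviolet")

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            extract_channel(np.empty((0, 0)))


class TestDenoise:
    @pytest.mark.parametrize("method", ["none", "median", "gaussian", "tv"])
    def test_constant_image_is_fixed_point(self, method):
        img = np.full((8, 8), 0.6)
        assert np.allclose(denoise(img, method), img, atol=1e-8)

    def test_none_is_bit_identical(self, rng):
        img = rng.random((16, 16))
        assert np.array_equal(denoise(img, "none"), img)

    def test_median_removes_salt_spike(self):
        # 5x5 toy grid: one bright pixel in a dark field; 3x3 median of any
        # window contains at most one spike, so the output is all zeros
        img = np.zeros((5, 5))
        img[2, 2] = 1.0
        assert np.array_equal(denoise(img, "median", 3), np.zeros((5, 5)))

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            denoise(np.zeros((4, 4)), "wavelet")


class TestSharpen:
    def test_constant_invariant(self):
        img = np.full((8, 8), 0.3)
        assert np.allclose(sharpen(img), img)

    def test_amount_zero_identity(self, rng):
        img = rng.random((8, 8))
        assert np.array_equal(sharpen(img, amount=0.0), img)

    def test_step_edge_overshoot_clipped(self):
        # 1-D step profile 0|1: unsharp mask overshoots on both sides of the
        # edge; clipping maps the overshoot back onto [0, 1], so the binary
        # step is a fixed point of the clipped filter
        img = np.tile(np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0]), (6, 1))
        out = sharpen(img, amount=1.0, radius=1.0)
        assert out.min() >= 0.0 and out.max() <= 1.0
        assert out[0, 3] == 1.0  # overshoot at bright side, clipped
        assert out[0, 2] == 0.0  # undershoot at dark side, clipped

    def test_ramp_edge_steepened(self):
        # on a gentle ramp nothing clips: sharpening pushes the convex foot
        # of the ramp down and the concave shoulder up, steepening the edge
        row = np.array([0.2, 0.2, 0.2, 0.35, 0.5, 0.65, 0.8, 0.8, 0.8])
        img = np.tile(row, (9, 1))
        out = sharpen(img, amount=1.0, radius=1.0)
        assert out[0, 2] < img[0, 2]
        assert out[0, 6] > img[0, 6]

    def test_negative_params_rejected(self):
        with pytest.raises(ValueError):
            sharpen(np.zeros((4, 4)), amount=-1.0)
        with pytest.raises(ValueError):
            sharpen(np.zeros((4, 4)), radius=-1.0)


class TestSaturateStretch:
    @pytest.mark.parametrize(
        ("value", "expected"),
        [(0.7, 1.0), (0.05, 0.0), (0.3, 0.5), (0.1, 0.0), (0.5, 1.0)],
    )
    def test_threshold_mapping(self, value, expected):
        out = saturate_stretch(np.array([[value]]), low=0.1, high=0.5)
        assert out[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            saturate_stretch(np.zeros((2, 2)), low=0.5, high=0.5)

    @settings(max_examples=50, derandomize=True)
    @given(
        a=st.floats(min_value=0, max_value=1),
        b=st.floats(min_value=0, max_value=1),
    )
    def test_monotone_nondecreasing(self, a, b):
        lo, hi = min(a, b), max(a, b)
        out = saturate_stretch(np.array([[lo, hi]]))
        assert out[0, 0] <= out[0, 1]


class TestOtsu:
    def test_bimodal_toy_image(self):
        """Oracle: exhaustive search of between-class variance over all
        candidate thresholds for a 10-dark / 6-bright image."""
        values = np.array([0.2] * 10 + [0.8] * 6)
        img = values.reshape(4, 4)

        def between_class_variance(t):
            lo, hi = values[values <= t], values[values > t]
            if len(lo) == 0 or len(hi) == 0:
                return -np.inf
            w0, w1 = len(lo) / len(values), len(hi) / len(values)
            return w0 * w1 * (lo.mean() - hi.mean()) ** 2

        candidates = np.linspace(0, 1, 257)
        best = candidates[np.argmax([between_class_variance(t) for t in candidates])]
        assert 0.2 < best < 0.8
        mask = otsu_threshold(img)
        assert mask.sum() == 6
        assert np.array_equal(mask, img > 0.5)  # the 6 bright pixels

    def test_binary_image_foreground_is_ones(self):
        img = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert np.array_equal(otsu_threshold(img), img == 1.0)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.full((4, 4), 0.5))


class TestCleanMask:
    def _mask_with_components(self, sizes):
        mask = np.zeros((40, 200), dtype=bool)
        col = 2
        for size in sizes:
            h = 5
            w = size // h
            rem = size - h * w
            mask[2 : 2 + h, col : col + w] = True
            if rem:
                mask[2, col + w] = True
                mask[3 : 3 + rem - 1, col + w] = True if rem > 1 else mask[3:3, col + w]
            col += w + 4
        return mask

    def test_size_rule_is_strict(self):
        # 59-pixel component removed, 60-pixel component kept
        mask = np.zeros((30, 60), dtype=bool)
        mask[2:7, 2:14] = True  # 5*12 = 60
        mask[12:17, 2:14] = True
        mask[16, 13] = False  # 59
        out = clean_mask(mask, min_size=60)
        assert out[2:7, 2:14].all()
        assert not out[12:17, 2:14].any()

    def test_small_hole_filled(self):
        mask = np.ones((20, 20), dtype=bool)
        mask[8:10, 8:13] = False  # 10-pixel hole
        out = clean_mask(mask)
        assert out.all()

    def test_large_hole_left_open(self):
        mask = np.ones((30, 30), dtype=bool)
        mask[5:15, 5:15] = False  # 100-pixel hole >= 60
        out = clean_mask(mask)
        assert not out[10, 10]

    def test_empty_mask_unchanged(self):
        mask = np.zeros((10, 10), dtype=bool)
        assert np.array_equal(clean_mask(mask), mask)

    def test_idempotent(self, rng):
        for _ in range(10):
            mask = rng.random((50, 50)) > 0.6
            once = clean_mask(mask)
            assert np.array_equal(clean_mask(once), once)


class TestContours:
    def test_3x3_square_hand_trace(self):
        """Frozen hand-derived clockwise Moore walk of a solid 3x3 square."""
        mask = np.zeros((5, 5), dtype=bool)
        mask[0:3, 0:3] = True
        (contour,) = trace_contours(mask)
        expected = [(0, 0), (0, 1), (0, 2), (1, 2), (2, 2), (2, 1), (2, 0), (1, 0)]
        assert contour.points.tolist() == [list(p) for p in expected]

    def test_two_disjoint_squares(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[1:4, 1:4] = True
        mask[6:9, 6:9] = True
        assert len(trace_contours(mask)) == 2

    def test_isolated_pixel(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 3] = True
        (contour,) = trace_contours(mask)
        assert contour.points.tolist() == [[2, 3]]

    def test_border_component_flagged(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[0:2, 0:2] = True
        (contour,) = trace_contours(mask)
        assert contour.touches_border

    def test_contour_points_lie_on_boundary(self, rng):
        mask = np.zeros((30, 30), dtype=bool)
        rr, cc = np.mgrid[0:30, 0:30]
        mask[(rr - 14) ** 2 + (cc - 15) ** 2 <= 64] = True
        (contour,) = trace_contours(mask)
        import scipy.ndimage as ndi

        interior = ndi.binary_erosion(mask)
        boundary = mask & ~interior
        assert all(boundary[r, c] for r, c in contour.points)

    def test_consecutive_points_8_adjacent_and_closed(self):
        mask = np.zeros((20, 20), dtype=bool)
        rr, cc = np.mgrid[0:20, 0:20]
        mask[(rr - 10) ** 2 + (cc - 10) ** 2 <= 36] = True
        (contour,) = trace_contours(mask)
        pts = contour.points
        steps = np.abs(np.diff(np.vstack([pts, pts[:1]]), axis=0))
        assert steps.max() <= 1


class TestFillContour:
    def test_square_boundary_fills_interior(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[0:3, 0:3] = True
        (contour,) = trace_contours(mask)
        assert np.array_equal(fill_contour(contour, (5, 5)), mask)

    def test_triangle_contour_matches_point_in_polygon(self):
        """Oracle: shapely inside-or-on-boundary test per pixel."""
        from shapely.geometry import Point, Polygon

        pts = np.array([[0, 0], [0, 4], [4, 0]])
        out = fill_contour(pts, (6, 6))
        poly = Polygon([(c, r) for r, c in pts])
        for r in range(6):
            for c in range(6):
                expected = poly.covers(Point(c, r))
                assert out[r, c] == expected, (r, c)
        assert out[1, 1]

    def test_short_contour_sets_listed_pixels_only(self):
        out = fill_contour(np.array([[1, 1], [2, 2]]), (4, 4))
        assert out.sum() == 2 and out[1, 1] and out[2, 2]

    def test_contour_on_image_border_fills_in_bounds(self):
        pts = np.array([[0, 0], [0, 3], [3, 3], [3, 0]])
        out = fill_contour(pts, (4, 4))
        assert out.shape == (4, 4)
        assert out.all()

    def test_out_of_bounds_points_dropped(self):
        pts = np.array([[0, 0], [0, 5], [5, 5], [5, 0]])
        out = fill_contour(pts, (3, 3))  # polygon extends past the image
        assert out.shape == (3, 3)

    def test_roundtrip_on_convex_components(self, rng):
        """fill(trace(mask)) reproduces solid convex components exactly."""
        for _ in range(20):
            mask = np.zeros((40, 40), dtype=bool)
            r0 = rng.integers(8, 32)
            c0 = rng.integers(8, 32)
            rad = rng.integers(3, 7)
            rr, cc = np.mgrid[0:40, 0:40]
            mask[(rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2] = True
            (contour,) = trace_contours(mask)
            assert np.array_equal(fill_contour(contour, mask.shape), mask)


class TestCentroid:
    @pytest.mark.parametrize(
        ("slices", "expected"),
        [
            ((slice(0, 3), slice(0, 3)), (1.0, 1.0)),
            ((slice(0, 2), slice(0, 2)), (0.5, 0.5)),
            ((slice(5, 6), slice(7, 8)), (7.0, 5.0)),
        ],
    )
    def test_examples(self, slices, expected):
        mask = np.zeros((10, 10), dtype=bool)
        mask[slices] = True
        assert compute_centroid(mask) == pytest.approx(expected)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            compute_centroid(np.zeros((4, 4), dtype=bool))


class TestSegmentNuclei:
    def test_recovers_rendered_disks(self, rng):
        pts = random_disk_layout(8, (256, 256), 10, rng)
        img, truth = render_nuclei_image(
            pts, SyntheticImageConfig(shape=(256, 256), seed=5)
        )
        result = segment_nuclei(img)
        assert len(result) == 8
        rec = result.centroids
        true = truth[["x_true", "y_true"]].to_numpy()
        for t in true:
            assert np.min(np.linalg.norm(rec - t, axis=1)) < 1.0

    def test_blank_image_empty_result(self, caplog):
        result = segment_nuclei(np.zeros((64, 64)))
        assert len(result) == 0

    def test_small_disk_excluded_by_size_rule(self):
        # radius-4 disk rasterizes to 49 px < 60 -> removed; radius-10 kept
        img, _ = render_nuclei_image(
            np.array([[40.0, 40.0], [120.0, 120.0]]),
            SyntheticImageConfig(shape=(180, 180), nucleus_radius=10, noise_level=0),
        )
        small, _ = render_nuclei_image(
            np.array([[90.0, 40.0]]),
            SyntheticImageConfig(shape=(180, 180), nucleus_radius=4, noise_level=0),
        )
        combined = np.maximum(img, small)
        result = segment_nuclei(combined)
        assert len(result) == 2

    def test_deterministic(self, rng):
        pts = random_disk_layout(5, (128, 128), 10, rng)
        img, _ = render_nuclei_image(pts, SyntheticImageConfig(shape=(128, 128), seed=9))
        a = segment_nuclei(img)
        b = segment_nuclei(img)
        assert np.array_equal(a.centroids, b.centroids)

    def test_override_csv(self, tmp_path, rng):
        pts = random_disk_layout(4, (128, 128), 10, rng)
        img, _ = render_nuclei_image(pts, SyntheticImageConfig(shape=(128, 128), seed=2))
        base = segment_nuclei(img)
        override = tmp_path / "fix.csv"
        cx, cy = base.nuclei[0].centroid
        override.write_text(
            "action,x,y\n" f"remove,{cx},{cy}\n" "add,100.5,10.5\n"
        )
        fixed = apply_overrides(base, override)
        assert len(fixed) == len(base)  # one removed, one added
        assert (100.5, 10.5) in [n.centroid for n in fixed.nuclei]

    def test_border_disk_flagged(self):
        img, _ = render_nuclei_image(
            np.array([[5.0, 64.0], [64.0, 64.0]]),
            SyntheticImageConfig(shape=(128, 128), noise_level=0),
        )
        result = segment_nuclei(img)
        flags = sorted(n.touches_border for n in result.nuclei)
        assert flags == [False, True]
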