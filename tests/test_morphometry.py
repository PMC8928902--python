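import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage as ndi

import fishsizer as fs
from fishsizer.errors import MeasurementError, ValidationError
from fishsizer.morphometry import MidlinePolynomial

from conftest import SMALL_RANGES


def band(coeffs, x0, x1, half_depth, shape):
    """Rasterize a band of given vertical half-depth around y = p(x)."""
    H, W = shape
    xs = np.arange(W, dtype=float)
    f = np.polyval(coeffs, xs)
    ygrid = np.arange(H, dtype=float)[:, None]
    return ((xs >= x0) & (xs <= x1))[None, :] & (np.abs(ygrid - f[None, :]) <= half_depth)


def rect_mask(shape=(60, 100), y0=25, y1=35, x0=20, x1=80):
    arr = np.zeros(shape, bool)
    arr[y0:y1, x0:x1] = True
    return arr


class TestRotateMask:
    def test_zero_orientation_is_unchanged_up_to_padding(self):
        pixels = rect_mask()
        mask = fs.select_largest(pixels)
        rotated = fs.rotate_mask(mask)
        assert rotated.sum() == pixels.sum()
        assert np.array_equal(rotated[np.ix_(*map(np.flatnonzero, (rotated.any(1), rotated.any(0))))],
                              pixels[25:35, 20:80])

    def test_45_degree_rectangle_comes_back_horizontal(self):
        arr = np.zeros((400, 400), np.uint8)
        arr[170:230, 50:350] = 1
        tilted = ndi.rotate(arr, 45, order=0, reshape=False) > 0
        mask = fs.select_largest(tilted)
        rotated = fs.rotate_mask(mask)
        _, theta = fs.region_orientation(rotated)
        assert abs(theta) <= 3.0

    def test_pixel_count_preserved_within_5_percent(self):
        arr = np.zeros((400, 400), np.uint8)
        arr[170:230, 50:350] = 1
        tilted = ndi.rotate(arr, 33, order=0, reshape=False) > 0
        mask = fs.select_largest(tilted)
        rotated = fs.rotate_mask(mask)
        assert abs(rotated.sum() / mask.area - 1.0) <= 0.05


class TestFindHeadEnd:
    def test_heavier_left_half(self):
        arr = np.zeros((40, 100), bool)
        arr[10:30, 10:50] = True   # 800 px left
        arr[18:22, 50:90] = True   # 160 px right
        assert fs.find_head_end(arr) == "left"

    def test_mirror_flips_to_right(self):
        arr = np.zeros((40, 100), bool)
        arr[10:30, 10:50] = True
        arr[18:22, 50:90] = True
        assert fs.find_head_end(arr[:, ::-1]) == "right"

    def test_symmetric_mask_ties_to_left(self):
        assert fs.find_head_end(rect_mask()) == "left"


class TestSelectPolyOrder:
    def test_curved_tail_band_selects_order_3(self):
        # tail half around y = 0.2 * t^2: fitted a2 ~ 0.2 > 0.1
        coeffs = (0.2, 0.0, 30.0)
        xs = np.arange(0, 40, dtype=float)
        H = 400
        arr = np.zeros((H, 80), bool)
        for x in range(40, 80):
            t = float(x - 40)
            y = 0.2 * t * t + 30.0
            lo, hi = int(y) - 3, int(y) + 3
            arr[max(lo, 0) : min(hi, H), x] = True
        arr[27:34, 0:40] = True  # head half, flat and heavy
        assert fs.find_head_end(arr) == "left"
        assert fs.select_poly_order(arr, "left") == 3

    def test_straight_tail_selects_order_2(self):
        assert fs.select_poly_order(rect_mask(), "left") == 2

    def test_boundary_coefficients_keep_order_2(self):
        """Thresholds are strict: coefficients equal to them select order 2."""
        arr = np.zeros((200, 100), bool)
        for x in range(50, 100):
            t = x - 50
            y = 0.05 * t * t * 0.5 + 0.3 * t + 20  # a2=0.025, a1=0.3
            arr[int(y) - 2 : int(y) + 3, x] = True
        arr[15:26, 0:50] = True
        # compute the exact fitted tail coefficients, then use them as the
        # thresholds: strict inequality must keep order 2
        ys, xs = np.nonzero(arr)
        keep = xs >= (xs.min() + xs.max()) / 2.0
        t = xs[keep] - xs[keep].min()
        a2, a1, _ = np.polyfit(t, ys[keep], 2)
        params = fs.MorphometryParams(
            order_threshold_a2=abs(a2), order_threshold_a1=abs(a1)
        )
        assert fs.select_poly_order(arr, "left", params) == 2

    def test_tiny_tail_raises(self):
        arr = np.zeros((20, 40), bool)
        arr[8:12, 0:14] = True
        arr[10, 30] = True
        with pytest.raises(MeasurementError):
            fs.select_poly_order(arr, "left")


class TestFitMidline:
    def test_horizontal_bar_fits_constant(self):
        mid = fs.fit_midline(rect_mask(y0=15, y1=26), 2)
        a2, a1, a0 = mid.coefficients
        assert abs(a2) < 0.01 and abs(a1) < 0.01
        assert a0 == pytest.approx(20.0, abs=0.5)

    def test_quadratic_band_recovers_curvature(self):
        arr = band((0.001, 0.0, 30.0), 0, 300, 4, (200, 301))
        mid = fs.fit_midline(arr, 2)
        assert mid.coefficients[0] == pytest.approx(0.001, rel=0.2)

    def test_column_centroid_variant_matches_on_symmetric_band(self):
        arr = band((0.001, 0.0, 30.0), 0, 300, 4, (200, 301))
        a = fs.fit_midline(arr, 2, "pixels")
        b = fs.fit_midline(arr, 2, "column_centroids")
        assert a.coefficients[0] == pytest.approx(b.coefficients[0], rel=0.05)

    def test_underdetermined_fit_raises(self):
        arr = np.zeros((20, 20), bool)
        arr[5, 5] = arr[9, 9] = True
        with pytest.raises(MeasurementError):
            fs.fit_midline(arr, 2)


class TestArcLength:
    def test_straight_horizontal_line(self):
        mid = MidlinePolynomial((0.0, 0.0, 5.0), 2, 0.0, 100.0)
        assert fs.arc_length(mid) == pytest.approx(100.0, rel=1e-9)

    def test_diagonal_unit_line(self):
        mid = MidlinePolynomial((0.0, 1.0, 0.0), 2, 0.0, 1.0)
        assert fs.arc_length(mid) == pytest.approx(math.sqrt(2.0), rel=1e-6)

    def test_parabola_closed_form(self):
        # int_0^1 sqrt(1+4x^2) dx = sqrt(5)/2 + asinh(2)/4 = 1.4789428...
        mid = MidlinePolynomial((1.0, 0.0, 0.0), 2, 0.0, 1.0)
        exact = math.sqrt(5) / 2 + math.asinh(2.0) / 4
        assert exact == pytest.approx(1.478943, abs=1e-6)
        assert fs.arc_length(mid) == pytest.approx(exact, rel=1e-6)

    def test_arc_length_dominates_chord(self):
        for a2 in (0.0, 1e-4, 1e-3, 5e-3):
            mid = MidlinePolynomial((a2, 0.0, 50.0), 2, 0.0, 400.0)
            assert fs.arc_length(mid) >= mid.x_max - mid.x_min - 1e-9


class TestMeasureDepth:
    def test_uniform_rectangle_depth(self):
        depth, x = fs.measure_depth(rect_mask(), "left")
        assert depth == 10.0
        assert x == pytest.approx((20 + 79) / 2.0, abs=0.5)

    def test_stepped_band_median_matches_column_oracle(self):
        arr = np.zeros((60, 120), bool)
        arr[20:30, 10:60] = True    # depth 10
        arr[18:32, 60:110] = True   # depth 14
        params = fs.MorphometryParams(depth_offset_percent=50, depth_window_percent=5)
        depth, target = fs.measure_depth(arr, "left", params)
        # oracle: direct scan of every column in the window
        ys, xs = np.nonzero(arr)
        x_min, x_max = xs.min(), xs.max()
        t = x_min + 0.5 * (x_max - x_min)
        w = 0.05 * (x_max - x_min)
        cols = [c for c in range(math.ceil(t - w), math.floor(t + w) + 1)]
        oracle = np.median(
            [ys[xs == c].max() - ys[xs == c].min() + 1 for c in cols if (xs == c).any()]
        )
        assert depth == oracle
        assert target == pytest.approx(t)

    def test_offset_zero_clips_window_to_head(self):
        params = fs.MorphometryParams(depth_offset_percent=0)
        depth, target = fs.measure_depth(rect_mask(), "left", params)
        assert target == 20.0
        assert depth == 10.0

    def test_exclusive_depth_variant(self):
        params = fs.MorphometryParams(inclusive_depth=False)
        depth, _ = fs.measure_depth(rect_mask(), "left", params)
        assert depth == 9.0

    def test_one_pixel_thick_band_has_depth_one(self):
        arr = np.zeros((20, 60), bool)
        arr[10, 5:55] = True
        depth, _ = fs.measure_depth(arr, "left")
        assert depth == 1.0


class TestMeasure:
    def test_straight_larva_length_within_5_percent(self):
        spec = replace(
            fs.make_spec(31, SMALL_RANGES),
            midline=(0.0, 0.0, 120.0),
            x_span=(60.0, 260.0),
            rotation_deg=0.0,
            noise_sigma=0.0,
        )
        image, truth = fs.render(spec)
        result = fs.measure(fs.segment_larva(image))
        assert truth.length_px == pytest.approx(200.0)
        assert result.length_px == pytest.approx(truth.length_px, rel=0.05)

    def test_curved_larva_length_within_5_percent_of_polyline_oracle(self):
        spec = fs.make_spec(37)  # full-size canvas for measurement accuracy
        image, truth = fs.render(spec)
        result = fs.measure(fs.segment_larva(image))
        # oracle: dense polyline arc length of the generating curve
        xs = np.linspace(spec.x_span[0], spec.x_span[1], 20001)
        ys = np.polyval(spec.midline, xs)
        oracle = np.hypot(np.diff(xs), np.diff(ys)).sum()
        assert result.length_px == pytest.approx(oracle, rel=0.05)

    def test_yolk_sac_with_straight_tail_selects_order_2(self):
        spec = replace(
            fs.make_spec(41),
            midline=(0.0, 0.0, 599.5),
            x_span=(350.0, 1250.0),
            profile="yolk_bulge",
            rotation_deg=0.0,
            noise_sigma=0.0,
        )
        image, _ = fs.render(spec)
        result = fs.measure(fs.segment_larva(image))
        assert result.midline.order == 2

    def test_length_at_least_x_extent(self, small_larva):
        image, _ = small_larva
        result = fs.measure(fs.segment_larva(image))
        assert result.length_px >= result.midline.x_max - result.midline.x_min

    def test_curvature_monotonically_increases_length(self):
        lengths = []
        for curv in (0.0, 0.25, 0.5):
            spec = fs.make_spec(
                53, {**SMALL_RANGES, "curvature": (curv, curv), "noise_sigma": (0.0, 0.0),
                     "rotation_deg": (0.0, 0.0)}
            )
            image, _ = fs.render(spec)
            lengths.append(fs.measure(fs.segment_larva(image)).length_px)
        assert lengths[0] <= lengths[1] <= lengths[2]

    def test_depth_invariant_under_mirroring_at_midpoint(self):
        spec = replace(fs.make_spec(59, SMALL_RANGES), noise_sigma=0.0)
        image, _ = fs.render(spec)
        mirrored, _ = fs.render(fs.mirror_spec(spec))
        r0 = fs.measure(fs.segment_larva(image))
        r1 = fs.measure(fs.segment_larva(mirrored))
        assert abs(r0.depth_px - r1.depth_px) <= 1.0


class TestPolylineLength:
    def test_3_4_5_triangle(self):
        assert fs.polyline_length([(0, 0), (3, 4)]) == 5.0

    def test_collinear_sum(self):
        assert fs.polyline_length([(0, 0), (3, 4), (6, 8)]) == 10.0

    def test_single_point_rejected(self):
        with pytest.raises(ValidationError):
            fs.polyline_length([(0, 0)])

    @settings(max_examples=50, derandomize=True)
    @given(
        pts=st.lists(
            st.tuples(
                st.floats(-1e3, 1e3, allow_nan=False),
                st.floats(-1e3, 1e3, allow_nan=False),
            ),
            min_size=2,
            max_size=8,
        ),
        shift=st.tuples(st.floats(-100, 100), st.floats(-100, 100)),
    )
    def test_dominates_chord_and_translation_invariant(self, pts, shift):
        total = fs.polyline_length(pts)
        chord = math.hypot(pts[-1][0] - pts[0][0], pts[-1][1] - pts[0][1])
        assert total >= chord - 1e-6
        moved = [(x + shift[0], y + shift[1]) for x, y in pts]
        assert fs.polyline_length(moved) == pytest.approx(total, rel=1e-9, abs=1e-6)
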