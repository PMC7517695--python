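"""Point selection, distances, scale-bar detection, and thickness report."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from echowall.phantom import PhantomParams, generate_phantom
from echowall.quantify import (PointSelectionParams, ScaleDetectParams,
                               SelectedPoint, classify_lvh, detect_scale,
                               filter_degenerate_points, lvpwt,
                               nearest_distance, relative_error,
                               select_lower_points, trimmed_mean_distance)
from echowall.types import ContourPoint, ParameterError, StageError


class TestSelectLowerPoints:
    def test_horizontal_contour_intersections(self):
        lower = [ContourPoint(150, c) for c in range(200)]
        params = PointSelectionParams(intercept_start=160, n_points=3,
                                      intercept_step=5)
        pts = select_lower_points(lower, params)
        assert [(p.row, p.col) for p in pts] == [(150, 10), (150, 15), (150, 20)]
        # oracle: every returned point satisfies r + c = b
        assert all(p.row + p.col == p.intercept for p in pts)

    def test_diagonal_contour(self):
        lower = [ContourPoint(c, c) for c in range(200)]
        pts = select_lower_points(lower, PointSelectionParams(
            intercept_start=160, n_points=1))
        assert [(p.row, p.col) for p in pts] == [(80, 80)]

    def test_unreachable_intercepts_yield_no_points(self):
        lower = [ContourPoint(150, c) for c in range(200)]
        pts = select_lower_points(lower, PointSelectionParams(
            intercept_start=10, n_points=5, intercept_step=5))
        assert pts == []

    def test_empty_contour_errors(self):
        with pytest.raises(ParameterError):
            select_lower_points([], PointSelectionParams())

    def test_diff_orientation(self):
        lower = [ContourPoint(150, c) for c in range(200)]
        pts = select_lower_points(lower, PointSelectionParams(
            intercept_start=100, n_points=1, orientation="diff"))
        assert [(p.row, p.col) for p in pts] == [(150, 50)]


class TestFilterDegeneratePoints:
    def test_pixel_on_line_kept(self):
        lower = [ContourPoint(150, c) for c in range(200)]
        pts = [SelectedPoint(150, 10, 160)]
        assert filter_degenerate_points(pts, lower) == pts

    def test_diagonal_pair_with_line_between_filtered(self):
        # contour pixels only at (r, c) and (r+1, c+1); a line of intercept
        # r + c + 1 threads between them without landing on either
        lower = [ContourPoint(100, 50), ContourPoint(101, 51)]
        pts = [SelectedPoint(100, 50, 151)]
        assert filter_degenerate_points(pts, lower) == []

    def test_full_block_kept(self):
        lower = [ContourPoint(100, 50), ContourPoint(100, 51),
                 ContourPoint(101, 50), ContourPoint(101, 51)]
        pts = [SelectedPoint(100, 50, 151)]
        assert filter_degenerate_points(pts, lower) == pts


class TestNearestDistance:
    def test_vertical_gap(self):
        upper = [ContourPoint(130, c) for c in range(200)]
        assert nearest_distance((150, 10), upper) == pytest.approx(20.0)

    def test_diagonal_neighbor(self):
        assert nearest_distance((150, 10), [ContourPoint(149, 9)]) == \
            pytest.approx(np.sqrt(2))

    def test_point_on_contour(self):
        upper = [ContourPoint(150, 10)]
        assert nearest_distance((150, 10), upper) == 0.0

    def test_empty_upper_errors(self):
        with pytest.raises(ParameterError):
            nearest_distance((0, 0), [])


class TestTrimmedMean:
    @pytest.mark.parametrize("group,expected", [
        ([5, 7, 9], 7.0),
        ([3, 5, 7, 9, 11], 7.0),        # mean of {5, 7, 9}
        ([4, 4], 4.0),                  # degenerate: plain mean
        ([8], 8.0),
    ])
    def test_values(self, group, expected):
        assert trimmed_mean_distance(group) == pytest.approx(expected)

    def test_empty_errors(self):
        with pytest.raises(StageError, match="no valid measurement points"):
            trimmed_mean_distance([])

    @given(st.lists(st.floats(0, 1e3), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariant_and_bounded(self, group):
        d = trimmed_mean_distance(group)
        rng = np.random.default_rng(0)
        shuffled = list(rng.permutation(group))
        assert trimmed_mean_distance(shuffled) == pytest.approx(d)
        assert min(group) - 1e-9 <= d <= max(group) + 1e-9


class TestDetectScale:
    def test_phantom_ruler_pitch(self):
        p = PhantomParams(ruler_pitch_px=25, speckle_sigma=0.0)
        img, _ = generate_phantom(p)
        scale = detect_scale(img)
        assert scale.l == pytest.approx(25.0)
        assert scale.k == pytest.approx(0.4)

    def test_long_streak_excluded(self):
        p = PhantomParams(ruler_pitch_px=25, speckle_sigma=0.0)
        img, _ = generate_phantom(p)
        img[100:400, 700] = 255               # sector-boundary-like streak
        scale = detect_scale(img)
        assert scale.l == pytest.approx(25.0)

    def test_no_ruler_errors(self):
        img = np.zeros((300, 300), np.uint8)
        with pytest.raises(StageError, match="scale not found"):
            detect_scale(img)

    def test_invariant_to_vertical_position(self):
        def ticks(start):
            img = np.zeros((400, 200), np.uint8)
            for r in range(start, 380, 30):
                img[r, 99:102] = 255
            return img
        assert detect_scale(ticks(40)).l == detect_scale(ticks(90)).l == 30.0

    def test_invariant_to_subthreshold_noise(self):
        img = np.zeros((400, 200), np.uint8)
        for r in range(40, 380, 30):
            img[r, 99:102] = 255
        noisy = img.copy()
        rng = np.random.default_rng(0)
        noise = rng.integers(0, 100, img.shape).astype(np.uint8)
        noisy = np.maximum(noisy, noise)      # below low_gray=140 everywhere
        assert detect_scale(noisy).l == detect_scale(img).l

    def test_inconsistent_thresholds(self):
        with pytest.raises(ParameterError):
            ScaleDetectParams(length_min=10, length_max=5)


class TestReportArithmetic:
    def test_lvpwt_product(self):
        assert lvpwt(0.4, 22) == pytest.approx(8.80)
        assert lvpwt(1.0, 8.43) == pytest.approx(8.43)

    def test_lvpwt_nonpositive_errors(self):
        with pytest.raises(ParameterError):
            lvpwt(0.4, 0)
        with pytest.raises(ParameterError):
            lvpwt(-1, 5)

    @pytest.mark.parametrize("measured,reference,expected", [
        (8.90, 8.43, 5.58),
        (8.90, 10.45, 14.83),
        (5.0, 5.0, 0.00),
    ])
    def test_relative_error(self, measured, reference, expected):
        assert relative_error(measured, reference) == pytest.approx(expected)

    def test_relative_error_bad_reference(self):
        with pytest.raises(ParameterError):
            relative_error(5.0, 0.0)

    @pytest.mark.parametrize("value,cutoff,expected", [
        (12.0, 11.0, True),
        (9.0, 11.0, False),
        (11.0, 11.0, False),                 # strict inequality
    ])
    def test_classify_lvh(self, value, cutoff, expected):
        assert classify_lvh(value, cutoff) is expected

    def test_classify_lvh_needs_cutoff(self):
        with pytest.raises(ParameterError):
            classify_lvh(10.0, 0)
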