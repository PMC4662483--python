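"""Measurement-line placement and perpendicular width measurement."""

import numpy as np
import pytest

from woundquant import (
    SyntheticSpec,
    WoundAxis,
    WoundContour,
    estimate_axis,
    extract_contours,
    generate_scratch_image,
    measure_widths,
    place_measurement_lines,
)
from woundquant.types import RegionMask


def axis_with_extent(lo, hi):
    return WoundAxis(direction=np.array([1.0, 0.0]), centroid=((lo + hi) / 2, 0.0),
                     extent=(lo, hi))


class TestPlacement:
    def test_five_lines_over_600px_extent(self):
        pos = place_measurement_lines(axis_with_extent(0.0, 600.0), 5)
        assert pos == pytest.approx([100.0, 200.0, 300.0, 400.0, 500.0])

    def test_single_line_sits_at_midpoint(self):
        pos = place_measurement_lines(axis_with_extent(0.0, 600.0), 1)
        assert pos == pytest.approx([300.0])

    def test_zero_lines_rejected(self):
        with pytest.raises(ValueError):
            place_measurement_lines(axis_with_extent(0.0, 600.0), 0)

    @pytest.mark.parametrize("n", [2, 5, 9])
    def test_spacing_is_exactly_equal(self, n):
        pos = place_measurement_lines(axis_with_extent(13.25, 587.5), n)
        gaps = np.diff(pos)
        assert gaps.max() - gaps.min() <= 1e-9
        assert pos[0] > 13.25 and pos[-1] < 587.5  # interior placement


def rect_contour_and_axis():
    m = np.zeros((400, 400), dtype=bool)
    m[:, 150:250] = True
    mask = RegionMask(m)
    axis = estimate_axis(mask)
    return extract_contours(mask, axis), axis


class TestMeasureWidths:
    def test_rectangular_band_measures_constant_width(self):
        contour, axis = rect_contour_and_axis()
        profile = measure_widths(contour, axis, place_measurement_lines(axis, 5))
        assert profile.widths_px == pytest.approx([100.0] * 5)
        assert profile.mean_width_px == pytest.approx(100.0)

    def test_mean_is_arithmetic_mean_of_lines(self):
        spec = SyntheticSpec(wound_width=60, width_profile="linear_taper",
                             end_width=140, seed=8)
        _, gt = generate_scratch_image(spec)
        axis = estimate_axis(gt.wound_mask)
        contour = extract_contours(gt.wound_mask, axis)
        profile = measure_widths(contour, axis, place_measurement_lines(axis, 5))
        assert profile.mean_width_px == pytest.approx(np.mean(profile.widths_px), abs=1e-9)

    def test_taper_width_at_axial_midpoint(self):
        """Linear 50->150 px taper: the width at the midpoint is 100 px."""
        spec = SyntheticSpec(wound_width=50, width_profile="linear_taper",
                             end_width=150, seed=3, noise_sigma=0.0)
        _, gt = generate_scratch_image(spec)
        axis = estimate_axis(gt.wound_mask)
        contour = extract_contours(gt.wound_mask, axis)
        mid = (axis.extent[0] + axis.extent[1]) / 2
        profile = measure_widths(contour, axis, [mid])
        assert profile.lines[0].width_px == pytest.approx(100.0, abs=1.0)

    def test_width_equals_endpoint_distance_and_perpendicularity(self):
        _, gt = generate_scratch_image(SyntheticSpec(wound_width=110, wound_angle=25, seed=4))
        axis = estimate_axis(gt.wound_mask)
        contour = extract_contours(gt.wound_mask, axis)
        profile = measure_widths(contour, axis, place_measurement_lines(axis, 5))
        for ln in profile.lines:
            pa, pb = np.array(ln.endpoint_a), np.array(ln.endpoint_b)
            assert ln.width_px == pytest.approx(np.linalg.norm(pa - pb), abs=1e-6)
            # both endpoints project onto the axis at the line position
            assert pa @ axis.direction == pytest.approx(ln.position, abs=0.5)
            assert pb @ axis.direction == pytest.approx(ln.position, abs=0.5)

    def test_coinciding_sides_report_closed_zero_width(self):
        side = np.stack([np.arange(10.0), np.full(10, 50.0)], axis=1)
        contour = WoundContour(side_a=side.copy(), side_b=side.copy())
        axis = axis_with_extent(0.0, 9.0)
        profile = measure_widths(contour, axis, [4.5])
        assert profile.lines[0].width_px == 0.0
        assert profile.lines[0].closed

    def test_position_beyond_interior_side_end_is_closed_not_dropped(self):
        contour, axis = rect_contour_and_axis()
        profile = measure_widths(contour, axis, [-50.0, 200.0])
        assert profile.n_lines == 2
        assert profile.lines[0].closed and profile.lines[0].width_px == 0.0
        assert not profile.lines[1].closed

    def test_micron_widths_scale_exactly(self):
        contour, axis = rect_contour_and_axis()
        profile = measure_widths(contour, axis, [200.0], scale=1.3)
        ln = profile.lines[0]
        assert ln.width_um == ln.width_px * 1.3

    def test_no_scale_leaves_micron_width_absent(self):
        contour, axis = rect_contour_and_axis()
        ln = measure_widths(contour, axis, [200.0]).lines[0]
        assert ln.width_um is None
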