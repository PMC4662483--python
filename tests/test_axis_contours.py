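"""Main-axis estimation and boundary-contour extraction."""

import numpy as np
import pytest

from woundquant import (
    ContourError,
    EmptyWoundError,
    IsotropyError,
    SyntheticSpec,
    estimate_axis,
    extract_contours,
    generate_scratch_image,
)
from woundquant.types import RegionMask, WoundAxis


def vertical_band_mask(shape=(400, 400), cols=(100, 200)):
    m = np.zeros(shape, dtype=bool)
    m[:, cols[0]:cols[1]] = True
    return RegionMask(m)


class TestEstimateAxis:
    def test_vertical_band_gives_row_direction(self):
        axis = estimate_axis(vertical_band_mask())
        assert axis.direction == pytest.approx([1.0, 0.0])
        assert axis.extent == (0.0, 399.0)

    def test_direction_is_unit_and_sign_normalized(self):
        _, gt = generate_scratch_image(SyntheticSpec(wound_width=100, wound_angle=-35, seed=2))
        axis = estimate_axis(gt.wound_mask)
        assert np.linalg.norm(axis.direction) == pytest.approx(1.0, abs=1e-9)
        assert axis.direction[0] > 0

    def test_rotated_band_angle_matches_centerline_regression(self):
        """Moment-based axis vs an independent least-squares centerline fit."""
        _, gt = generate_scratch_image(SyntheticSpec(wound_width=100, wound_angle=30, seed=1))
        axis = estimate_axis(gt.wound_mask)
        wound = gt.wound_mask.wound
        rows = [r for r in range(wound.shape[0]) if wound[r].any()]
        centers = [np.mean(np.nonzero(wound[r])[0]) for r in rows]
        oracle_deg = np.degrees(np.arctan(np.polyfit(rows, centers, 1)[0]))
        assert axis.angle_deg == pytest.approx(oracle_deg, abs=1.0)

    def test_square_mask_raises_isotropy_error(self):
        m = np.zeros((400, 400), dtype=bool)
        m[100:300, 100:300] = True
        with pytest.raises(IsotropyError):
            estimate_axis(RegionMask(m))

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyWoundError):
            estimate_axis(RegionMask(np.zeros((100, 100), dtype=bool)))


class TestExtractContours:
    def test_rectangle_sides_sit_at_half_integer_boundaries(self):
        mask = vertical_band_mask()
        axis = estimate_axis(mask)
        contour = extract_contours(mask, axis)
        # pixels 100..199 are wound, so boundaries sit at 99.5 and 199.5
        assert contour.side_a[:, 1] == pytest.approx(99.5)
        assert contour.side_b[:, 1] == pytest.approx(199.5)

    @pytest.mark.parametrize("angle,seed", [(0, 11), (33, 12), (-27, 13)])
    def test_sides_strictly_monotone_in_axial_projection(self, angle, seed):
        _, gt = generate_scratch_image(
            SyntheticSpec(wound_width=90, wound_angle=angle, seed=seed)
        )
        axis = estimate_axis(gt.wound_mask)
        contour = extract_contours(gt.wound_mask, axis)
        for side in (contour.side_a, contour.side_b):
            proj = side @ axis.direction
            assert (np.diff(proj) > 0).all()

    def test_contour_points_lie_on_mask_boundary(self):
        """Every contour vertex is within 1 px of a wound/cell edge pixel."""
        _, gt = generate_scratch_image(SyntheticSpec(wound_width=90, wound_angle=20, seed=5))
        mask = gt.wound_mask
        axis = estimate_axis(mask)
        contour = extract_contours(mask, axis)
        wound = mask.wound
        for side in (contour.side_a, contour.side_b):
            rr = np.clip(np.round(side[:, 0]).astype(int), 0, wound.shape[0] - 1)
            cc = np.clip(np.round(side[:, 1]).astype(int), 0, wound.shape[1] - 1)
            # nearest pixel is wound or cell adjacent to the opposite class
            for r, c in zip(rr, cc):
                patch = wound[max(r - 1, 0):r + 2, max(c - 1, 0):c + 2]
                assert patch.any() and not patch.all()

    def test_empty_wound_raises(self):
        axis = WoundAxis(direction=np.array([1.0, 0.0]), centroid=(0, 0), extent=(0, 1))
        with pytest.raises(EmptyWoundError):
            extract_contours(RegionMask(np.zeros((64, 64), dtype=bool)), axis)

    def test_frame_filling_wound_is_not_separable(self):
        m = np.ones((200, 200), dtype=bool)
        m[90:110, 90:110] = False  # only an island of cells in the middle
        axis = WoundAxis(direction=np.array([1.0, 0.0]), centroid=(99.5, 99.5),
                         extent=(0.0, 199.0))
        with pytest.raises(ContourError):
            extract_contours(RegionMask(m), axis)
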