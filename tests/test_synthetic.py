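"""Generator contracts: determinism, analytic ground truth, texture separation."""

import numpy as np
import pytest

from woundquant import (
    BandGeometryError,
    SyntheticSpec,
    generate_scratch_image,
    generate_timecourse_pair,
)
from woundquant.quantify import DEFAULT_WINDOW, local_variance
from woundquant.types import axis_basis


def test_fixed_seed_generation_is_bit_identical():
    spec = SyntheticSpec(wound_width=100.0, seed=42)
    img1, gt1 = generate_scratch_image(spec)
    img2, gt2 = generate_scratch_image(spec)
    assert np.array_equal(img1.pixels, img2.pixels)
    assert np.array_equal(gt1.wound_mask.wound, gt2.wound_mask.wound)


def test_different_seed_changes_pixels():
    img1, _ = generate_scratch_image(SyntheticSpec(seed=1))
    img2, _ = generate_scratch_image(SyntheticSpec(seed=2))
    assert not np.array_equal(img1.pixels, img2.pixels)


def test_zero_width_band_has_empty_mask(closed_monolayer):
    _, gt = closed_monolayer
    assert not gt.wound_mask.wound.any()


@pytest.mark.parametrize(
    "spec_kwargs",
    [
        dict(wound_width=900.0),  # wider than the frame
        dict(wound_width=100.0, wound_center_offset=500.0),  # pushed out of frame
        dict(wound_width=100.0, width_profile="linear_taper", end_width=900.0),
    ],
)
def test_band_outside_frame_is_rejected(spec_kwargs):
    with pytest.raises(BandGeometryError):
        generate_scratch_image(SyntheticSpec(**spec_kwargs))


def test_nonpositive_dimensions_rejected():
    with pytest.raises(ValueError):
        SyntheticSpec(image_height=0)


@pytest.mark.parametrize("angle,offset", [(0.0, 0.0), (25.0, 40.0), (-40.0, -30.0)])
def test_ground_truth_mask_matches_analytic_band(angle, offset):
    """No wound pixel center lies farther than width/2 from the centerline."""
    spec = SyntheticSpec(wound_width=120.0, wound_angle=angle,
                         wound_center_offset=offset, seed=3)
    _, gt = generate_scratch_image(spec)
    h, w = gt.wound_mask.shape
    direction, perp = axis_basis(angle)
    center = np.array([(h - 1) / 2, (w - 1) / 2]) + offset * perp
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    dist = np.abs((rr - center[0]) * perp[0] + (cc - center[1]) * perp[1])
    assert (dist[gt.wound_mask.wound] < spec.wound_width / 2).all()
    # and, conversely, every interior pixel of the band is in the mask
    assert gt.wound_mask.wound[dist < spec.wound_width / 2 - 1e-9].all()


def test_width_at_uses_pipeline_axial_coordinate():
    spec = SyntheticSpec(wound_width=50.0, width_profile="linear_taper",
                         end_width=150.0, seed=3)
    _, gt = generate_scratch_image(spec)
    lo, hi = gt.axial_extent
    assert gt.width_at(lo) == pytest.approx(50.0)
    assert gt.width_at(hi) == pytest.approx(150.0)
    assert gt.width_at((lo + hi) / 2) == pytest.approx(100.0)


def test_texture_separation_between_cell_and_wound(default_scratch):
    """Mean local std in the monolayer exceeds that in the wound >= 3-fold."""
    _, img, gt = default_scratch
    sd = np.sqrt(local_variance(img.as_float(), DEFAULT_WINDOW))
    wound = gt.wound_mask.wound
    ratio = sd[~wound].mean() / sd[wound].mean()
    assert ratio >= 3.0


class TestTimecoursePair:
    def test_zero_closure_gives_identical_frames_and_truths(self):
        spec = SyntheticSpec(wound_width=120.0, seed=9)
        img0, img1, gt0, gt1 = generate_timecourse_pair(spec, 0.0)
        assert np.array_equal(img0.pixels, img1.pixels)
        s = np.linspace(*gt0.axial_extent, 7)
        assert [gt0.width_at(v) for v in s] == [gt1.width_at(v) for v in s]

    def test_full_closure_empties_the_t1_mask(self):
        spec = SyntheticSpec(wound_width=120.0, seed=9)
        _, _, _, gt1 = generate_timecourse_pair(spec, 120.0)
        assert not gt1.wound_mask.wound.any()

    def test_frames_differ_only_inside_the_band(self):
        spec = SyntheticSpec(wound_width=120.0, seed=9)
        img0, img1, gt0, _ = generate_timecourse_pair(spec, 40.0)
        outside = ~gt0.wound_mask.wound
        assert np.array_equal(img0.pixels[outside], img1.pixels[outside])
        assert not np.array_equal(img0.pixels, img1.pixels)

    def test_excess_closure_rejected(self):
        with pytest.raises(ValueError):
            generate_timecourse_pair(SyntheticSpec(wound_width=50.0, seed=1), 60.0)
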