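"""Synthetic phase-contrast-like scratch images with exact ground truth.

The generator draws a straight wound band (optionally linearly tapered) through
a textured "cell monolayer".  Cell-covered regions receive a granular
blob-plus-speckle texture — Gaussian-filtered noise soft-thresholded into
cell-like granules over a fine speckle floor — reproducing the high local
variance that phase-contrast monolayers show, while the denuded band is left
near-uniform.  Additive Gaussian sensor noise covers the whole frame.

Everything is driven by a single integer seed through one documented
pseudo-random stream (draw order: blob field, speckle field, sensor noise), so
generation is bit-identical for equal specs.  A timecourse pair reuses the
texture and noise fields of t0, so the two frames differ only in the band.

The analytic band is the ground truth: the wound mask is exactly the set of
pixels whose centers lie strictly inside the band, and the true width at any
axial position is available as a function.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Optional

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import BandGeometryError
from .types import Micrograph, RegionMask, axis_basis

#: Generator defaults.  The assay the generator emulates gives no resolution,
#: pixel scale or bit depth for its micrographs; these are this package's own
#: choices, documented in docs/methods.md, typical of a 10x phase-contrast
#: field stored as 16-bit TIFF.
DEFAULT_HEIGHT = 600
DEFAULT_WIDTH = 800
DEFAULT_TEXTURE_CONTRAST = 0.12
DEFAULT_NOISE_SIGMA = 0.02

_BACKGROUND = 0.5
_BLOB_SIGMA = 3.0  # px; granule correlation length
_SPECKLE_SIGMA = 0.8  # px; fine speckle floor


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic scratch image.

    Parameters
    ----------
    image_height, image_width
        Frame size in pixels.
    wound_width
        Band width in pixels at the start of the axial extent; 0 gives a fully
        closed (empty) wound.
    wound_angle
        Band main-axis angle, degrees from vertical, in [-90, 90).
    wound_center_offset
        Offset of the band centerline from the image center, in pixels,
        measured along the perpendicular to the band axis.
    width_profile
        "constant", or "linear_taper" with ``end_width`` giving the band width
        at the far end of the axial extent.
    texture_contrast
        Standard deviation of the cell-region texture, in normalized intensity
        units (image background is 0.5 on a [0, 1] scale).
    noise_sigma
        Additive Gaussian sensor-noise sigma, same units.
    seed
        Integer seed of the single pseudo-random stream.
    """

    image_height: int = DEFAULT_HEIGHT
    image_width: int = DEFAULT_WIDTH
    wound_width: float = 150.0
    wound_angle: float = 0.0
    wound_center_offset: float = 0.0
    width_profile: str = "constant"
    end_width: Optional[float] = None
    texture_contrast: float = DEFAULT_TEXTURE_CONTRAST
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")
        if self.wound_width < 0:
            raise ValueError("wound_width must be >= 0")
        if not (-90.0 <= self.wound_angle < 90.0):
            raise ValueError("wound_angle must lie in [-90, 90) degrees from vertical")
        if self.width_profile not in ("constant", "linear_taper"):
            raise ValueError(f"unknown width_profile {self.width_profile!r}")
        if self.width_profile == "linear_taper":
            if self.end_width is None or self.end_width < 0:
                raise ValueError("linear_taper requires end_width >= 0")
        if self.texture_contrast < 0:
            raise ValueError("texture_contrast must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class GroundTruth:
    """Exact ground truth of a generated image.

    ``width_at(s)`` returns the true band width at scalar axial position ``s``
    (projection onto the axis direction, same coordinate used by the
    measurement pipeline).
    """

    wound_mask: RegionMask
    axis_angle: float
    width_at: Callable[[float], float]
    mean_width: float
    axial_extent: tuple[float, float]


def _band_frame(spec: SyntheticSpec):
    """Axial/perpendicular coordinate fields and the analytic width function."""
    h, w = spec.image_height, spec.image_width
    direction, perpendicular = axis_basis(spec.wound_angle)
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    origin = center + spec.wound_center_offset * perpendicular

    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    dr, dc = rr - origin[0], cc - origin[1]
    s_field = dr * direction[0] + dc * direction[1]
    d_field = dr * perpendicular[0] + dc * perpendicular[1]

    corners = np.array([[0.0, 0.0], [0.0, w - 1.0], [h - 1.0, 0.0], [h - 1.0, w - 1.0]])
    rel = corners - origin
    s_corners = rel @ direction
    d_corners = rel @ perpendicular
    s_min, s_max = float(s_corners.min()), float(s_corners.max())
    d_min, d_max = float(d_corners.min()), float(d_corners.max())

    if spec.width_profile == "constant":
        w0 = float(spec.wound_width)

        def width_at(s):
            return w0 + 0.0 * np.asarray(s, dtype=float)

        max_width = w0
    else:
        w0, w1 = float(spec.wound_width), float(spec.end_width)

        def width_at(s):
            frac = (np.asarray(s, dtype=float) - s_min) / (s_max - s_min)
            return w0 + (w1 - w0) * frac

        max_width = max(w0, w1)

    # Both band edges must cross the frame's perpendicular range, so the band
    # (and both of its boundaries) lies inside the image.
    if not (d_min < -max_width / 2.0 and max_width / 2.0 < d_max):
        raise BandGeometryError(
            f"wound band (max width {max_width} px, offset {spec.wound_center_offset} px, "
            f"angle {spec.wound_angle} deg) does not fit inside a "
            f"{h}x{w} frame (perpendicular range [{d_min:.1f}, {d_max:.1f}] px)"
        )

    s_origin = float(origin @ direction)
    return s_field, d_field, width_at, (s_min, s_max), s_origin


def _band_mask(spec: SyntheticSpec) -> tuple[np.ndarray, GroundTruth]:
    s_field, d_field, width_at, extent, s_origin = _band_frame(spec)
    mask = np.abs(d_field) < np.asarray(width_at(s_field)) / 2.0
    s_line = np.linspace(extent[0], extent[1], 512)
    mean_width = float(np.mean(np.maximum(width_at(s_line), 0.0)))
    # width_at is exposed in the measurement pipeline's axial coordinate:
    # the absolute projection of (row, col) onto the axis direction.
    gt = GroundTruth(
        wound_mask=RegionMask(mask),
        axis_angle=spec.wound_angle,
        width_at=lambda s: float(np.maximum(width_at(np.asarray(s) - s_origin), 0.0)),
        mean_width=mean_width,
        axial_extent=(extent[0] + s_origin, extent[1] + s_origin),
    )
    return mask, gt


def _random_fields(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Texture and sensor-noise fields from the documented stream order."""
    h, w = spec.image_height, spec.image_width
    rng = np.random.default_rng(spec.seed)
    blob_raw = rng.standard_normal((h, w))
    speckle_raw = rng.standard_normal((h, w))
    sensor = rng.standard_normal((h, w))

    blobs = gaussian_filter(blob_raw, _BLOB_SIGMA)
    blobs /= blobs.std()
    granules = np.maximum(blobs - 0.2, 0.0)  # soft-threshold into granules
    # High-pass so the granule field is locally zero-mean: phase-contrast
    # granularity modulates intensity around the background level rather than
    # shifting the local mean (and a mean offset at the wound edge would bias
    # any variance-based split).
    granules -= gaussian_filter(granules, 3.0 * _BLOB_SIGMA)
    granules /= granules.std()
    speckle = gaussian_filter(speckle_raw, _SPECKLE_SIGMA)
    speckle /= speckle.std()

    # Speckle carries most of the variance so the monolayer's local texture is
    # spatially homogeneous; granules sit on top for the blobby look.
    texture = 0.5 * granules + 0.85 * speckle
    texture -= texture.mean()
    texture /= texture.std()
    return spec.texture_contrast * texture, spec.noise_sigma * sensor


def _render(spec: SyntheticSpec, wound_mask: np.ndarray, texture: np.ndarray, noise: np.ndarray,
            timepoint: str = "t0") -> Micrograph:
    img = _BACKGROUND + np.where(wound_mask, 0.0, texture) + noise
    pixels = np.clip(np.round(img * 65535.0), 0, 65535).astype(np.uint16)
    return Micrograph(pixels, condition="synthetic", timepoint=timepoint)


def generate_scratch_image(spec: SyntheticSpec) -> tuple[Micrograph, GroundTruth]:
    """Generate one synthetic scratch image and its exact ground truth.

    Returns a 16-bit micrograph whose wound band is near-uniform (low local
    texture) and whose cell regions carry granular texture of amplitude
    ``spec.texture_contrast``, plus the analytic ground truth.

    Raises
    ------
    BandGeometryError
        If the requested band does not fit inside the frame.
    """
    mask, gt = _band_mask(spec)
    texture, noise = _random_fields(spec)
    return _render(spec, mask, texture, noise), gt


def generate_timecourse_pair(
    spec_t0: SyntheticSpec, closure_px: float
) -> tuple[Micrograph, Micrograph, GroundTruth, GroundTruth]:
    """Generate a t0/t1 pair in which the wound has closed by ``closure_px``.

    The t1 frame reuses the t0 texture and noise fields (same seed stream), so
    the two images differ only in the wound band, whose width is reduced by
    ``closure_px`` everywhere along the axis.

    Raises
    ------
    ValueError
        If ``closure_px`` is negative or exceeds the narrowest t0 band width.
    """
    min_width = spec_t0.wound_width
    if spec_t0.width_profile == "linear_taper":
        min_width = min(min_width, float(spec_t0.end_width))
    if closure_px < 0:
        raise ValueError("closure_px must be >= 0")
    if closure_px > min_width:
        raise ValueError(
            f"closure_px={closure_px} exceeds the narrowest initial band width {min_width}"
        )

    spec_t1 = replace(
        spec_t0,
        wound_width=spec_t0.wound_width - closure_px,
        end_width=(None if spec_t0.end_width is None else spec_t0.end_width - closure_px),
    )
    mask0, gt0 = _band_mask(spec_t0)
    mask1, gt1 = _band_mask(spec_t1)
    texture, noise = _random_fields(spec_t0)
    img0 = _render(spec_t0, mask0, texture, noise, timepoint="t0")
    img1 = _render(spec_t0, mask1, texture, noise, timepoint="t1")
    return img0, img1, gt0, gt1


def save_synthetic(out_dir, spec: SyntheticSpec, img: Micrograph, gt: GroundTruth,
                   stem: str = "scratch") -> dict:
    """Write image, ground-truth mask and a JSON sidecar to ``out_dir``.

    The image is a 16-bit grayscale TIFF, the mask an 8-bit (0/255) TIFF, and
    the sidecar records the band parameters.  Returns the paths written.
    """
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img_path = out / f"{stem}.tif"
    mask_path = out / f"{stem}_mask.tif"
    meta_path = out / f"{stem}.json"
    tifffile.imwrite(img_path, img.pixels)
    tifffile.imwrite(mask_path, gt.wound_mask.wound.astype(np.uint8) * 255)
    meta = {
        "axis_angle": gt.axis_angle,
        "wound_width": spec.wound_width,
        "width_profile": spec.width_profile,
        "end_width": spec.end_width,
        "wound_center_offset": spec.wound_center_offset,
        "texture_contrast": spec.texture_contrast,
        "noise_sigma": spec.noise_sigma,
        "seed": spec.seed,
    }
    meta_path.write_text(json.dumps(meta, indent=2) + "\n")
    return {"image": img_path, "mask": mask_path, "meta": meta_path}
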