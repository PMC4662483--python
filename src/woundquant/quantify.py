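"""Appearance-based wound segmentation and perpendicular width measurement.

The pipeline follows the three-step scheme of automated scratch-assay readers:

a) split the image into cell and wounded areas from appearance differences —
   cell monolayers are high local texture under phase contrast, the denuded
   band is smooth, so a moving-window local-variance map separates the two;
b) extract the detailed boundary contours between the compacted cell layer and
   the wounded area at subpixel precision;
c) place N equally-spaced measurement lines perpendicular to the wound main
   axis and report the gap width on each line.

Segmentation details: the local variance map (window ``DEFAULT_WINDOW`` px) is
first split by Otsu's threshold to identify the two appearance classes; the
final split level is then re-placed at the midpoint of the two class levels.
Local variance mixes linearly with the cell-area fraction of the window, so
the midpoint level crosses exactly where a window straddles the true boundary
half-and-half — placing the mask edge on the boundary without the inward bias
a direct Otsu cut on a texture map produces.  Morphological opening/closing
(disk radius 5 px) removes speckle and the largest low-texture connected
component is kept as the wound (the assay has one scratch).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, uniform_filter
from skimage.filters import threshold_otsu
from skimage.measure import find_contours, label, regionprops
from skimage.morphology import closing, disk, erosion, opening

from .errors import ContourError, DegenerateImageError, EmptyWoundError, IsotropyError
from .types import (
    MeasurementLine,
    Micrograph,
    RegionMask,
    WidthProfile,
    WoundAxis,
    WoundContour,
)

DEFAULT_WINDOW = 15  # px, moving-window side for the local texture map
DEFAULT_MIN_WOUND_AREA_FRAC = 0.02  # smallest credible wound, fraction of frame
DEFAULT_MIN_TEXTURE_RATIO = 4.0  # class contrast below which "no wound" is declared
_MORPH_RADIUS = 5  # px, disk radius for opening/closing
_ISOTROPY_TOL = 0.05  # relative eigenvalue gap below which no main axis exists
_VAR_SMOOTH_SIGMA = 2.0  # px, isotropic Gaussian smoothing of the variance map
_ALONG_SMOOTH_SIGMA = 20.0  # px, along-axis smoothing in the refinement pass
_CONTOUR_SMOOTH = 9  # points, moving-average window for boundary polylines


def local_variance(image: np.ndarray, window: int) -> np.ndarray:
    """Moving-window population variance of ``image`` (reflect boundary)."""
    x = np.asarray(image, dtype=np.float64)
    mu = uniform_filter(x, window)
    mu2 = uniform_filter(x * x, window)
    return np.maximum(mu2 - mu * mu, 0.0)


def _class_level(var: np.ndarray, cls: np.ndarray, window: int) -> float:
    """Representative local-variance level of one appearance class.

    The class mask is eroded by a full window so pixels whose windows straddle
    the cell/wound boundary (mixed variance) do not drag the level.
    """
    core = erosion(cls, disk(window))
    if not core.any():
        core = cls
    return float(var[core].mean())


def segment_wound(
    img: Micrograph,
    window: int = DEFAULT_WINDOW,
    min_wound_area_frac: float = DEFAULT_MIN_WOUND_AREA_FRAC,
    min_texture_ratio: float = DEFAULT_MIN_TEXTURE_RATIO,
) -> RegionMask:
    """Split a micrograph into cell and wounded areas by local texture.

    Returns the wound/cell partition.  An image with no credible low-texture
    region (fully closed wound, or appearance classes not separable by at
    least ``min_texture_ratio``) yields an *empty* wound mask — "no wound
    detected" is a distinguishable outcome, not an exception.

    Raises
    ------
    DegenerateImageError
        If the texture map is uniformly zero (e.g. a constant image), where
        the cell/wound split is undefined.
    ValueError
        If ``window`` is even, < 3, or too large for the frame.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if window >= min(img.height, img.width) / 2:
        raise ValueError(f"window {window} too large for a {img.height}x{img.width} image")

    x = img.as_float()
    var = local_variance(x, window)
    # Symmetric smoothing suppresses speckle-induced wiggle of the level set
    # without moving it: the variance transition across the boundary is linear
    # in position, so its midpoint crossing is preserved.
    var = gaussian_filter(var, _VAR_SMOOTH_SIGMA)
    if float(var.max()) < 1e-9:
        raise DegenerateImageError(
            "degenerate appearance: cannot split (texture map uniformly zero)"
        )

    # Otsu in the log domain: local variance is spread multiplicatively, and a
    # (near-)zero wound mode sits decades below the cell mode.
    log_var = np.log10(var + 1e-6 * float(var.max()))
    t_log = threshold_otsu(log_var)
    hi, lo = log_var > t_log, log_var <= t_log
    if not hi.any() or not lo.any():
        raise DegenerateImageError("degenerate appearance: cannot split (one-class texture map)")
    v_hi = _class_level(var, hi, window)
    v_lo = _class_level(var, lo, window)

    empty = RegionMask(np.zeros(img.pixels.shape, dtype=bool))
    # Appearance classes must be genuinely distinct; otherwise the low-variance
    # class is just the lower tail of the monolayer texture, not a wound.
    if v_hi < min_texture_ratio * max(v_lo, 1e-300):
        return empty

    t_star = 0.5 * (v_lo + v_hi)
    mask = _threshold_and_clean(var, t_star, min_wound_area_frac)
    if mask is None:
        return empty

    # Second pass: the wound boundary runs along the main axis, so smoothing
    # the variance map *along* that direction averages out the estimator noise
    # that makes the level set wiggle, without blurring the cross-boundary
    # transition (whose midpoint crossing therefore stays put).
    try:
        axis = estimate_axis(RegionMask(mask))
    except IsotropyError:
        return RegionMask(mask)
    var_along = _smooth_along(var, axis.direction, _ALONG_SMOOTH_SIGMA)
    refined = _threshold_and_clean(var_along, t_star, min_wound_area_frac)
    if refined is None:
        return RegionMask(mask)
    return RegionMask(refined)


def _threshold_and_clean(
    var: np.ndarray, t_star: float, min_wound_area_frac: float
) -> Optional[np.ndarray]:
    """Threshold a variance map, clean morphologically, keep the largest blob."""
    candidate = var < t_star
    selem = disk(_MORPH_RADIUS)
    cleaned = closing(opening(candidate, selem), selem).astype(bool)
    if not cleaned.any():
        return None
    labels = label(cleaned)
    largest = max(regionprops(labels), key=lambda r: r.area)
    if largest.area < min_wound_area_frac * var.size:
        return None
    return labels == largest.label


def _smooth_along(field: np.ndarray, direction: np.ndarray, sigma: float) -> np.ndarray:
    """Convolve with a thin Gaussian line kernel oriented along ``direction``."""
    from scipy.signal import fftconvolve

    half = int(np.ceil(2.5 * sigma))
    ax = np.arange(-half, half + 1, dtype=float)
    rr, cc = np.meshgrid(ax, ax, indexing="ij")
    t = rr * direction[0] + cc * direction[1]
    u = -rr * direction[1] + cc * direction[0]
    kernel = np.exp(-0.5 * (t / sigma) ** 2 - 0.5 * (u / 0.6) ** 2)
    kernel /= kernel.sum()
    padded = np.pad(field, half, mode="edge")
    return fftconvolve(padded, kernel, mode="same")[half:-half, half:-half]


def estimate_axis(mask: RegionMask) -> WoundAxis:
    """Estimate the wound main axis from the second central moments of the mask.

    The direction is the principal eigenvector of the covariance of wound
    pixel coordinates, sign-normalized so its first nonzero component is
    positive; the extent is the [min, max] projection of wound pixels onto it.

    Raises
    ------
    EmptyWoundError
        If the wound mask is empty.
    IsotropyError
        If the two moment eigenvalues differ by less than 5% (no well-defined
        main axis, e.g. a square or circular region).
    """
    if mask.is_empty:
        raise EmptyWoundError("cannot estimate an axis for an empty wound")
    coords = np.argwhere(mask.wound).astype(float)
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    cov = centered.T @ centered / len(coords)
    eigvals, eigvecs = np.linalg.eigh(cov)  # ascending
    lam_min, lam_max = float(eigvals[0]), float(eigvals[1])
    if lam_max <= 0 or (lam_max - lam_min) / lam_max < _ISOTROPY_TOL:
        raise IsotropyError(
            f"wound mask is isotropic (moment eigenvalues {lam_min:.4g}, {lam_max:.4g}): "
            "no well-defined main axis"
        )
    direction = eigvecs[:, 1]
    if direction[0] < 0 or (direction[0] == 0 and direction[1] < 0):
        direction = -direction
    proj = coords @ direction
    return WoundAxis(
        direction=direction,
        centroid=(float(centroid[0]), float(centroid[1])),
        extent=(float(proj.min()), float(proj.max())),
    )


def _monotone_side(points: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Order boundary points by axial projection, enforcing strict monotonicity."""
    s = points @ direction
    order = np.argsort(s, kind="stable")
    pts, s = points[order], s[order]
    keep = np.empty(len(s), dtype=bool)
    keep[0] = True
    last = s[0]
    for i in range(1, len(s)):
        keep[i] = s[i] > last + 1e-9
        if keep[i]:
            last = s[i]
    return pts[keep]


def _smooth_side(points: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Moving-average smoothing of an ordered boundary polyline.

    Marching squares quantizes the boundary to half-pixel steps; averaging a
    few consecutive vertices recovers a smoother subpixel trace while staying
    within a pixel of the mask boundary.
    """
    if len(points) <= _CONTOUR_SMOOTH:
        return points
    from scipy.ndimage import uniform_filter1d

    smoothed = uniform_filter1d(points, _CONTOUR_SMOOTH, axis=0, mode="nearest")
    return _monotone_side(smoothed, direction)


def extract_contours(mask: RegionMask, axis: WoundAxis) -> WoundContour:
    """Trace the two cell/wound boundary contours at subpixel precision.

    Marching squares on the binary mask places the boundary halfway between
    wound and cell pixel centers (half-integer offsets, per the package's
    pixel-center convention).  Contour segments are assigned to the two sides
    by the sign of their perpendicular offset from the axis and ordered by
    axial projection.

    Raises
    ------
    EmptyWoundError
        If the wound is empty.
    ContourError
        If the wound touches all four image borders (no two separable sides)
        or one side has no boundary points.
    """
    if mask.is_empty:
        raise EmptyWoundError("cannot trace contours of an empty wound")
    m = mask.wound

    segments = find_contours(m.astype(float), 0.5)
    if not segments:
        raise ContourError("no boundary found between wound and cell regions")
    centroid = np.asarray(axis.centroid)
    perp = axis.perpendicular
    a_parts, b_parts = [], []
    for seg in segments:
        offset = float(np.mean((seg - centroid) @ perp))
        (a_parts if offset < 0 else b_parts).append(seg)
    if not a_parts or not b_parts:
        four_borders = m[0, :].any() and m[-1, :].any() and m[:, 0].any() and m[:, -1].any()
        if four_borders:
            raise ContourError("wound touches all four image borders: sides not separable")
        raise ContourError("boundary lies entirely on one side of the axis")

    side_a = _smooth_side(_monotone_side(np.vstack(a_parts), axis.direction), axis.direction)
    side_b = _smooth_side(_monotone_side(np.vstack(b_parts), axis.direction), axis.direction)
    return WoundContour(side_a=side_a, side_b=side_b)


def place_measurement_lines(axis: WoundAxis, n_lines: int = 5) -> np.ndarray:
    """Axial positions of N equally-spaced interior measurement lines.

    Lines sit at interior fractions k/(N+1) of the wound's axial extent for
    k = 1..N, so none falls on the wound's axial tips.
    """
    if n_lines < 1:
        raise ValueError(f"n_lines must be >= 1, got {n_lines}")
    lo, hi = axis.extent
    k = np.arange(1, n_lines + 1, dtype=float)
    return lo + k * (hi - lo) / (n_lines + 1)


def _on_border(point: np.ndarray, frame_shape: tuple[int, int]) -> bool:
    # Contour smoothing can pull a terminal vertex a few px off the frame
    # border; the tolerance covers half a smoothing window.
    tol = _CONTOUR_SMOOTH / 2 + 1.0
    r, c = point
    h, w = frame_shape
    return r <= tol or r >= h - 1 - tol or c <= tol or c >= w - 1 - tol


def _end_line(s: np.ndarray, d: np.ndarray, at_start: bool) -> tuple[float, float]:
    """Least-squares line (slope, intercept) of a side near one of its ends.

    The vertices closest to the end are skipped: morphological cleanup rounds
    the boundary where it meets the frame corner, and including those points
    tilts the fit.
    """
    n = len(s)
    skip = min(15, n // 4)
    n_fit = min(60, n - skip)
    if at_start:
        s_fit, d_fit = s[skip:skip + n_fit], d[skip:skip + n_fit]
    else:
        hi = n - skip
        s_fit, d_fit = s[hi - n_fit:hi], d[hi - n_fit:hi]
    if len(s_fit) < 2 or s_fit.max() - s_fit.min() < 1e-9:
        return 0.0, float(d_fit.mean()) if len(d_fit) else float(d.mean())
    slope, intercept = np.polyfit(s_fit, d_fit, 1)
    return float(slope), float(intercept)


def measure_widths(
    contour: WoundContour,
    axis: WoundAxis,
    positions: Sequence[float],
    scale: Optional[float] = None,
    frame_shape: Optional[tuple[int, int]] = None,
) -> WidthProfile:
    """Measure the wound width on a perpendicular line at each axial position.

    Each boundary side is parametrized by (axial projection s, perpendicular
    projection d); the intersection of the side with the perpendicular line at
    position p is found by linear interpolation of d at s = p, and the width
    is the distance between the two intersections.  A position outside a
    side's axial span, or one where the sides coincide, is reported as a
    closed line with width 0, not dropped — a closed gap is a zero width, not
    missing data.

    ``frame_shape`` (height, width) distinguishes frame clipping from genuine
    closure: a side that terminates *at the image border* (the scratch
    boundary leaves the field of view, as happens in the frame corners of a
    strongly angled band) is extended beyond its span by linear extrapolation
    of its end segment instead of being treated as closed.
    """
    positions = np.asarray(positions, dtype=float)
    d_axis, perp = axis.direction, axis.perpendicular
    sides = []
    for pts in (contour.side_a, contour.side_b):
        sides.append((pts @ d_axis, pts @ perp, pts))

    lines = []
    for i, p in enumerate(positions, start=1):
        d_vals, closed_here = [], False
        for s, d, pts in sides:
            if s[0] <= p <= s[-1]:
                d_vals.append(float(np.interp(p, s, d)))
                continue
            at_start = p < s[0]
            end_pt = pts[0] if at_start else pts[-1]
            if frame_shape is not None and _on_border(end_pt, frame_shape):
                slope, intercept = _end_line(s, d, at_start)
                d_vals.append(slope * p + intercept)
            else:
                closed_here = True
                break
        if closed_here:
            lines.append(
                MeasurementLine(
                    index=i, position=float(p), endpoint_a=None, endpoint_b=None,
                    width_px=0.0, width_um=(0.0 if scale else None), closed=True,
                )
            )
            continue
        width = abs(d_vals[0] - d_vals[1])
        endpoints = [tuple(p * d_axis + dv * perp) for dv in d_vals]
        closed = width <= 1e-9
        lines.append(
            MeasurementLine(
                index=i,
                position=float(p),
                endpoint_a=endpoints[0],
                endpoint_b=endpoints[1],
                width_px=float(width),
                width_um=(float(width) * scale if scale else None),
                closed=closed,
            )
        )
    return WidthProfile(lines=lines)


def _closed_profile(img: Micrograph, n_lines: int) -> WidthProfile:
    """All-closed profile for an image with no detectable wound."""
    k = np.arange(1, n_lines + 1, dtype=float)
    positions = k * (img.height - 1) / (n_lines + 1)
    lines = [
        MeasurementLine(
            index=i + 1, position=float(p), endpoint_a=None, endpoint_b=None,
            width_px=0.0, width_um=(0.0 if img.scale else None), closed=True,
        )
        for i, p in enumerate(positions)
    ]
    return WidthProfile(lines=lines)


def quantify_image_full(
    img: Micrograph,
    n_lines: int = 5,
    window: int = DEFAULT_WINDOW,
    min_wound_area_frac: float = DEFAULT_MIN_WOUND_AREA_FRAC,
    positions: Optional[Sequence[float]] = None,
):
    """Run the full pipeline and return (profile, mask, axis, contour).

    ``positions`` overrides automatic equally-spaced placement with explicit
    axial positions (the "user-defined lines" reading).  For an image with no
    detectable wound the profile has all lines closed at width 0 and mask is
    empty (axis and contour are None).
    """
    mask = segment_wound(img, window=window, min_wound_area_frac=min_wound_area_frac)
    if mask.is_empty:
        n = n_lines if positions is None else len(positions)
        return _closed_profile(img, n), mask, None, None
    axis = estimate_axis(mask)
    contour = extract_contours(mask, axis)
    if positions is None:
        positions = place_measurement_lines(axis, n_lines)
    profile = measure_widths(
        contour, axis, positions, scale=img.scale, frame_shape=img.pixels.shape
    )
    return profile, mask, axis, contour


def quantify_image(
    img: Micrograph,
    n_lines: int = 5,
    window: int = DEFAULT_WINDOW,
    min_wound_area_frac: float = DEFAULT_MIN_WOUND_AREA_FRAC,
    positions: Optional[Sequence[float]] = None,
) -> WidthProfile:
    """Segment, trace and measure one micrograph; return its width profile."""
    profile, _, _, _ = quantify_image_full(
        img, n_lines=n_lines, window=window,
        min_wound_area_frac=min_wound_area_frac, positions=positions,
    )
    return profile
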