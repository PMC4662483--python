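"""Core domain types for scratch-assay quantification.

Coordinate convention used throughout the package: (row, col), 0-based, with
pixel centers at integer coordinates.  A mask pixel at (r, c) occupies the
half-open square [r-0.5, r+0.5) x [c-0.5, c+0.5); boundary contours between a
wound pixel and a cell pixel therefore sit at half-integer offsets.

Angles are measured in degrees from the vertical (row) axis, so a wound whose
long axis runs top-to-bottom has angle 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

MIN_IMAGE_SIDE = 64


@dataclass
class Micrograph:
    """A 2D grayscale intensity image with optional physical scale and metadata.

    Parameters
    ----------
    pixels
        2D array of intensities; 8/16-bit integer or real-valued.
    scale
        Physical scale in micrometres per pixel, if known (must be > 0).
    condition, timepoint
        Free-text assay metadata (e.g. "siMCT1", "t24").
    """

    pixels: np.ndarray
    scale: Optional[float] = None
    condition: str = ""
    timepoint: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"Micrograph requires a 2D array, got ndim={self.pixels.ndim}")
        h, w = self.pixels.shape
        if h < MIN_IMAGE_SIDE or w < MIN_IMAGE_SIDE:
            raise ValueError(
                f"image {h}x{w} too small: both sides must be >= {MIN_IMAGE_SIDE} px "
                "(texture windows undefined below this)"
            )
        if np.issubdtype(self.pixels.dtype, np.floating) and not np.all(np.isfinite(self.pixels)):
            raise ValueError("Micrograph intensities must be finite")
        if self.scale is not None and not self.scale > 0:
            raise ValueError(f"scale must be > 0 um/px, got {self.scale}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def as_float(self) -> np.ndarray:
        """Intensities as float64 normalized to [0, 1] for integer dtypes."""
        if np.issubdtype(self.pixels.dtype, np.integer):
            info = np.iinfo(self.pixels.dtype)
            return self.pixels.astype(np.float64) / float(info.max)
        return self.pixels.astype(np.float64)


@dataclass
class RegionMask:
    """Binary wound/cell partition of a micrograph.

    ``wound`` marks the wounded (denuded) area; the cell region is exactly its
    complement, so the split is a partition by construction.
    """

    wound: np.ndarray

    def __post_init__(self) -> None:
        self.wound = np.asarray(self.wound, dtype=bool)
        if self.wound.ndim != 2:
            raise ValueError("RegionMask requires a 2D boolean array")

    @property
    def cell(self) -> np.ndarray:
        return ~self.wound

    @property
    def is_empty(self) -> bool:
        return not bool(self.wound.any())

    @property
    def shape(self) -> tuple[int, int]:
        return self.wound.shape


@dataclass
class WoundAxis:
    """Main axis of the wound band.

    ``direction`` is a unit 2-vector in (row, col) coordinates, sign-normalized
    so its first nonzero component is positive.  ``extent`` is the [min, max]
    range of wound-pixel projections onto the direction (absolute pixel
    coordinates projected, not centroid-relative).
    """

    direction: np.ndarray
    centroid: tuple[float, float]
    extent: tuple[float, float]

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        n = float(np.linalg.norm(self.direction))
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"axis direction must be unit length, |d|={n}")

    @property
    def perpendicular(self) -> np.ndarray:
        """Unit vector perpendicular to the axis: rot90 of direction."""
        d = self.direction
        return np.array([-d[1], d[0]])

    @property
    def angle_deg(self) -> float:
        """Axis angle in degrees from vertical (the row axis), in [-90, 90)."""
        ang = float(np.degrees(np.arctan2(self.direction[1], self.direction[0])))
        if ang >= 90.0:
            ang -= 180.0
        elif ang < -90.0:
            ang += 180.0
        return ang


@dataclass
class WoundContour:
    """The two cell/wound boundary contours, split by side of the main axis.

    Each side is an (M, 2) array of subpixel (row, col) points, ordered and
    strictly monotone in their projection onto the wound axis.  ``side_a`` lies
    at negative perpendicular offset from the axis, ``side_b`` at positive.
    """

    side_a: np.ndarray
    side_b: np.ndarray

    def __post_init__(self) -> None:
        self.side_a = np.asarray(self.side_a, dtype=float)
        self.side_b = np.asarray(self.side_b, dtype=float)
        for name, side in (("side_a", self.side_a), ("side_b", self.side_b)):
            if side.ndim != 2 or side.shape[1] != 2 or len(side) < 2:
                raise ValueError(f"{name} must be an (M>=2, 2) array of points")


@dataclass
class MeasurementLine:
    """One perpendicular wound-width measurement.

    ``position`` is the scalar projection of the line onto the wound axis;
    ``endpoint_a``/``endpoint_b`` are the subpixel intersections with the two
    boundary contours.  A line over a locally closed gap carries ``closed=True``
    and width 0 (a closed gap is a zero width, not missing data).
    """

    index: int
    position: float
    endpoint_a: Optional[tuple[float, float]]
    endpoint_b: Optional[tuple[float, float]]
    width_px: float
    width_um: Optional[float] = None
    closed: bool = False


@dataclass
class WidthProfile:
    """Per-image wound-width profile: N measurement lines plus their mean."""

    lines: list[MeasurementLine]
    mean_width_px: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.lines:
            raise ValueError("WidthProfile requires at least one measurement line")
        self.mean_width_px = float(np.mean([ln.width_px for ln in self.lines]))

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def widths_px(self) -> np.ndarray:
        return np.array([ln.width_px for ln in self.lines])

    @property
    def mean_width_um(self) -> Optional[float]:
        ums = [ln.width_um for ln in self.lines]
        if any(u is None for u in ums):
            return None
        return float(np.mean(ums))


def axis_basis(angle_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal (direction, perpendicular) basis for an axis angle.

    Angle is degrees from vertical; direction is in (row, col) coordinates, so
    angle 0 gives direction (1, 0) (down the rows) and perpendicular (0, 1).
    """
    t = np.radians(angle_deg)
    direction = np.array([np.cos(t), np.sin(t)])
    perpendicular = np.array([-np.sin(t), np.cos(t)])
    return direction, perpendicular
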