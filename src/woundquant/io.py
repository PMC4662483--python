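"""Image and configuration IO.

Reads 8/16-bit grayscale TIFF and PNG micrographs (RGB accepted and converted
by luminance, with a warning), writes results, and loads/validates the batch
run configuration (YAML, of which JSON is a subset).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .errors import ConfigError
from .quantify import DEFAULT_WINDOW
from .types import Micrograph

_LUMA = np.array([0.2125, 0.7154, 0.0721])

PAIR_ROLES = ("treated_t0", "treated_t1", "control_t0", "control_t1")


def read_image(
    path,
    scale: Optional[float] = None,
    condition: str = "",
    timepoint: str = "",
) -> Micrograph:
    """Read a TIFF or PNG micrograph into a :class:`Micrograph`.

    RGB(A) input is converted to grayscale by luminance with a warning; the
    alpha channel, if any, is dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        if arr.shape[2] == 3:
            warnings.warn(f"{path.name}: RGB image converted to grayscale by luminance")
            arr = arr.astype(np.float64) @ _LUMA
        else:
            raise ValueError(f"{path.name}: unsupported channel count {arr.shape[2]}")
    elif arr.ndim != 2:
        raise ValueError(f"{path.name}: expected a 2D grayscale image, got ndim={arr.ndim}")
    return Micrograph(arr, scale=scale, condition=condition, timepoint=timepoint)


def write_image(path, img: Micrograph | np.ndarray) -> Path:
    """Write a micrograph (or bare array) as TIFF or PNG, by extension."""
    path = Path(path)
    arr = img.pixels if isinstance(img, Micrograph) else np.asarray(img)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)
    return path


@dataclass
class RunConfig:
    """Validated configuration of one batch run.

    ``pairs`` holds one mapping per treated/control quadruple with keys
    treated_t0, treated_t1, control_t0, control_t1 (image paths) and an
    optional ``name``.
    """

    pairs: list[dict]
    output_dir: Path
    n_lines: int = 5
    window: int = DEFAULT_WINDOW
    scale_um_per_px: Optional[float] = None
    seed: int = 0
    overlay: bool = False

    def __post_init__(self) -> None:
        if self.n_lines < 1:
            raise ConfigError(f"n_lines must be >= 1, got {self.n_lines}")
        if self.window < 3 or self.window % 2 == 0:
            raise ConfigError(f"window must be odd and >= 3, got {self.window}")
        if self.scale_um_per_px is not None and not self.scale_um_per_px > 0:
            raise ConfigError(f"scale_um_per_px must be > 0, got {self.scale_um_per_px}")
        if not self.pairs:
            raise ConfigError("config must list at least one image pair")
        self.output_dir = Path(self.output_dir)


_TOP_KEYS = {"pairs", "n_lines", "window", "scale_um_per_px", "output_dir", "seed", "overlay"}
_PAIR_KEYS = set(PAIR_ROLES) | {"name"}


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    Unknown keys are rejected (not ignored) to catch typos; every referenced
    image path must exist at load time.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")

    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key in ("pairs", "output_dir"):
        if key not in raw:
            raise ConfigError(f"missing required config key: {key}")

    pairs = raw["pairs"]
    if not isinstance(pairs, list):
        raise ConfigError("'pairs' must be a list")
    base = path.parent
    resolved_pairs = []
    for i, pair in enumerate(pairs):
        if not isinstance(pair, dict):
            raise ConfigError(f"pair {i} must be a mapping")
        unknown = set(pair) - _PAIR_KEYS
        if unknown:
            raise ConfigError(f"pair {i}: unknown keys {sorted(unknown)}")
        missing = [r for r in PAIR_ROLES if r not in pair]
        if missing:
            raise ConfigError(f"pair {i}: missing keys {missing}")
        resolved = {"name": str(pair.get("name", f"pair{i}"))}
        for role in PAIR_ROLES:
            p = Path(pair[role])
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                raise ConfigError(f"pair {i}: image does not exist: {p}")
            resolved[role] = p
        resolved_pairs.append(resolved)

    out_dir = Path(raw["output_dir"])
    if not out_dir.is_absolute():
        out_dir = base / out_dir
    return RunConfig(
        pairs=resolved_pairs,
        output_dir=out_dir,
        n_lines=int(raw.get("n_lines", 5)),
        window=int(raw.get("window", DEFAULT_WINDOW)),
        scale_um_per_px=(
            None if raw.get("scale_um_per_px") is None else float(raw["scale_um_per_px"])
        ),
        seed=int(raw.get("seed", 0)),
        overlay=bool(raw.get("overlay", False)),
    )


def render_overlay(img: Micrograph, mask, axis, contour, profile, out_path) -> Path:
    """Render a QC overlay (contours + measurement lines on the image) as PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 6))
    ax.imshow(img.pixels, cmap="gray")
    if contour is not None:
        ax.plot(contour.side_a[:, 1], contour.side_a[:, 0], "-", color="cyan", lw=1)
        ax.plot(contour.side_b[:, 1], contour.side_b[:, 0], "-", color="orange", lw=1)
    for ln in profile.lines:
        if ln.endpoint_a is not None and ln.endpoint_b is not None:
            ax.plot(
                [ln.endpoint_a[1], ln.endpoint_b[1]],
                [ln.endpoint_a[0], ln.endpoint_b[0]],
                "-o", color="red", ms=3, lw=1,
            )
    ax.set_title(f"mean width {profile.mean_width_px:.1f} px ({profile.n_lines} lines)")
    ax.set_axis_off()
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=110, bbox_inches="tight")
    plt.close(fig)
    return out_path
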