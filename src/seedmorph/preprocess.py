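"""Board pre-processing: tag cropping, scale calibration, color correction.

The imaging protocol places two reference objects on every top view: a
square tag of known physical side (default 16 mm) from which the
pixel-to-millimeter scale is derived, and a strip of color patches with
known reference RGB values from which a per-channel affine color
correction can be fitted.  Both tags are removed (filled with the board
background) before seeds are segmented.

Tag locations are supplied as pixel boxes in the run configuration
(0-based, row-major, half-open), mirroring the operator-selected regions
of a manual workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

__all__ = [
    "BoardImage",
    "ScaleCalibration",
    "ColorCorrection",
    "CalibrationError",
    "crop_tags",
    "calibrate_scale",
    "fit_color_correction",
    "apply_color_correction",
    "load_board_image",
]

Box = tuple[int, int, int, int]  # (r0, c0, r1, c1), half-open


class CalibrationError(ValueError):
    """Scale or color tag missing, malformed, or unusable."""


@dataclass
class BoardImage:
    """One raster view of a board plus its tag geometry.

    ``view`` is ``"top"`` or ``"side"``; side views carry the index of
    the seed row they depict and need no tag boxes.
    """

    pixels: np.ndarray  # H x W x 3, uint8
    view: str = "top"
    row_index: int | None = None
    tag_boxes: dict[str, Box] = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("BoardImage requires an H x W x 3 raster")
        self.pixels = px
        if self.view not in ("top", "side"):
            raise ValueError("view must be 'top' or 'side'")
        h, w = px.shape[:2]
        for name, (r0, c0, r1, c1) in self.tag_boxes.items():
            if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
                raise ValueError(f"tag box {name!r} exceeds image bounds")
        if self.view == "top" and self.tag_boxes:
            missing = {"scale", "color"} - set(self.tag_boxes)
            if missing:
                raise ValueError(f"top view missing tag boxes: {sorted(missing)}")


def load_board_image(path, view: str = "top", row_index: int | None = None,
                     tag_boxes: dict[str, Box] | None = None) -> BoardImage:
    """Read a PNG/TIFF board view from disk."""
    px = iio.imread(Path(path))
    if px.ndim == 3 and px.shape[2] == 4:
        px = px[:, :, :3]
    return BoardImage(px, view=view, row_index=row_index, tag_boxes=tag_boxes or {})


@dataclass(frozen=True)
class ScaleCalibration:
    """Pixel-to-mm scale from the square reference tag."""

    mm_per_pixel: float
    tag_pixel_length: float
    tag_mm: float = 16.0

    def __post_init__(self) -> None:
        if self.mm_per_pixel <= 0:
            raise ValueError("mm_per_pixel must be positive")


@dataclass(frozen=True)
class ColorCorrection:
    """Per-channel affine map: corrected = gain * observed + offset."""

    gain: tuple[float, float, float]
    offset: tuple[float, float, float]

    @classmethod
    def identity(cls) -> "ColorCorrection":
        return cls(gain=(1.0, 1.0, 1.0), offset=(0.0, 0.0, 0.0))


def _border_background(pixels: np.ndarray, width: int = 10) -> np.ndarray:
    """Median color of a border ring — a robust background estimate."""
    h, w = pixels.shape[:2]
    ring = np.concatenate(
        [
            pixels[:width].reshape(-1, 3),
            pixels[-width:].reshape(-1, 3),
            pixels[:, :width].reshape(-1, 3),
            pixels[:, -width:].reshape(-1, 3),
        ]
    )
    return np.median(ring, axis=0).astype(np.uint8)


def crop_tags(image: BoardImage) -> tuple[BoardImage, dict[str, np.ndarray]]:
    """Remove the tag regions, returning the cleaned view and tag crops.

    Tag pixels are replaced by the background color estimated from the
    image border; the extracted sub-images are kept for calibration.
    Side views without tag boxes pass through unchanged.
    """
    if not image.tag_boxes:
        if image.view == "top":
            raise CalibrationError("top view requires scale and color tag boxes")
        return image, {}
    pixels = image.pixels.copy()
    fill = _border_background(pixels)
    crops: dict[str, np.ndarray] = {}
    for name, (r0, c0, r1, c1) in image.tag_boxes.items():
        crops[name] = image.pixels[r0:r1, c0:c1].copy()
        pixels[r0:r1, c0:c1] = fill
    cleaned = BoardImage(pixels, view=image.view, row_index=image.row_index, tag_boxes={})
    return cleaned, crops


def calibrate_scale(scale_tag: np.ndarray, tag_mm: float = 16.0) -> ScaleCalibration:
    """Measure the square tag and derive mm per pixel.

    The tag sub-image must contain one high-contrast square; the tag
    side in pixels is the mean of the largest dark component's
    axis-aligned extents, and ``mm_per_pixel = tag_mm / side``.
    """
    if tag_mm <= 0:
        raise CalibrationError("tag_mm must be positive")
    tag = np.asarray(scale_tag)
    gray = tag.mean(axis=2) if tag.ndim == 3 else tag.astype(float)
    if np.ptp(gray) < 10:
        raise CalibrationError("scale tag sub-image has no contrast")
    thr = threshold_otsu(gray)
    fg = gray < thr  # tag ink is dark on a light board
    lab = label(fg, connectivity=2)
    props = regionprops(lab)
    if not props:
        raise CalibrationError("no component found in scale tag sub-image")
    biggest = max(props, key=lambda p: p.area)
    r0, c0, r1, c1 = biggest.bbox
    dy, dx = r1 - r0, c1 - c0
    if abs(dy - dx) / max(dy, dx) > 0.10:
        raise CalibrationError(
            f"scale tag is not square: extents {dy} x {dx} px differ by > 10%"
        )
    side = (dy + dx) / 2.0
    return ScaleCalibration(mm_per_pixel=tag_mm / side, tag_pixel_length=side, tag_mm=tag_mm)


def _patch_means(color_tag: np.ndarray, n_patches: int) -> np.ndarray:
    """Mean RGB of each patch in a horizontal strip of equal patches.

    Each patch mean is taken over the central half of its segment so
    margins and patch borders do not bleed in.
    """
    tag = np.asarray(color_tag, dtype=float)
    # trim surrounding board background so segments align with patches
    bg = np.median(
        np.concatenate([tag[0], tag[-1], tag[:, 0], tag[:, -1]]), axis=0
    )
    fg = (np.abs(tag - bg).max(axis=2) > 12)
    rows = np.flatnonzero(fg.any(axis=1))
    cols = np.flatnonzero(fg.any(axis=0))
    if rows.size and cols.size:
        tag = tag[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    h, w = tag.shape[:2]
    seg = w / n_patches
    means = np.empty((n_patches, 3))
    for i in range(n_patches):
        c0 = int(i * seg + seg * 0.25)
        c1 = int(i * seg + seg * 0.75)
        r0, r1 = int(h * 0.25), int(h * 0.75)
        means[i] = tag[r0:r1, c0:c1].reshape(-1, 3).mean(axis=0)
    return means


def fit_color_correction(
    color_tag: np.ndarray, reference_rgb, observed_means: np.ndarray | None = None
) -> ColorCorrection:
    """Least-squares per-channel affine map from observed to reference.

    The color tag is split into ``len(reference_rgb)`` equal horizontal
    patches whose central means are regressed onto the reference values.
    At least two patches are required to identify gain and offset.
    """
    ref = np.asarray(reference_rgb, dtype=float)
    if ref.ndim != 2 or ref.shape[1] != 3:
        raise CalibrationError("reference_rgb must be a list of RGB triples")
    if len(ref) < 2:
        raise CalibrationError("need at least 2 patches to fit gain and offset")
    obs = _patch_means(color_tag, len(ref)) if observed_means is None else np.asarray(
        observed_means, dtype=float
    )
    if obs.shape != ref.shape:
        raise CalibrationError("patch count does not match reference list")
    gain, offset = [], []
    for ch in range(3):
        A = np.column_stack([obs[:, ch], np.ones(len(ref))])
        (g, o), *_ = np.linalg.lstsq(A, ref[:, ch], rcond=None)
        gain.append(float(g))
        offset.append(float(o))
    return ColorCorrection(gain=tuple(gain), offset=tuple(offset))


def apply_color_correction(image: BoardImage | np.ndarray, correction: ColorCorrection):
    """Apply the per-channel affine map, clipped to [0, 255]."""
    pixels = image.pixels if isinstance(image, BoardImage) else np.asarray(image)
    out = pixels.astype(float) * np.asarray(correction.gain) + np.asarray(correction.offset)
    out = np.clip(np.round(out), 0, 255).astype(np.uint8)
    if isinstance(image, BoardImage):
        return BoardImage(out, view=image.view, row_index=image.row_index,
                          tag_boxes=dict(image.tag_boxes))
    return out
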