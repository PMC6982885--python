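"""Synthetic seed-board generator with exact ground truth.

Renders the board layout used by high-throughput seed phenotyping rigs:
one top view plus one side view per seed row, a square scale tag of known
physical size, a strip of reference color patches, seeds on a regular
grid, and (optionally) sub-threshold noise specks.  Every generated seed
is recorded in a ground-truth table so that segmentation, calibration,
morphometry and color analysis can be validated end to end without any
external dataset.

Seed outlines are superellipses |x/a|^n + |y/b|^n = 1 with exponent
``squareness`` n; n = 2 is an exact ellipse (analytic area pi*a*b), and
n in [1.8, 2.5] spans realistic seed shapes while keeping closed-form
area/axis oracles.  Side views show each seed as a flat-bottomed profile
whose vertical extent equals the seed's thickness at the board
resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "BoardSpec",
    "SeedSpec",
    "GroundTruthRecord",
    "LayoutError",
    "generate_board",
    "render_seed_mask",
    "sample_seed_specs",
    "write_board",
    "DEFAULT_COLOR_PATCHES",
]


class LayoutError(ValueError):
    """Seed footprints overlap or do not fit the board grid."""


DEFAULT_COLOR_PATCHES: tuple[tuple[int, int, int], ...] = (
    (40, 40, 40),
    (120, 120, 120),
    (200, 200, 200),
    (200, 40, 40),
    (40, 160, 40),
    (40, 40, 200),
)

# dark neutral ink for the scale tag and noise specks
_TAG_RGB = (25, 25, 25)
_SPECK_RGB = (60, 60, 60)


@dataclass(frozen=True)
class BoardSpec:
    """Physical board geometry and imaging resolution.

    Defaults follow an A4-sized field of view (210 x 297 mm) holding
    100 seeds in 4 rows of 25, with a 16 mm square scale tag.
    """

    board_width_mm: float = 210.0
    board_height_mm: float = 297.0
    mm_per_pixel: float = 0.1
    n_rows: int = 4
    n_cols: int = 25
    scale_tag_mm: float = 16.0
    color_tag_patches: tuple[tuple[int, int, int], ...] = DEFAULT_COLOR_PATCHES
    color_patch_mm: float = 8.0
    background_rgb: tuple[int, int, int] = (235, 235, 235)
    tag_band_mm: float = 24.0  # top band reserved for the two tags
    side_view_height_mm: float = 20.0
    coat_noise_sigma: float = 0.0  # per-pixel Gaussian color jitter on seeds
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.mm_per_pixel <= 0:
            raise ValueError("mm_per_pixel must be positive")
        if self.scale_tag_mm <= 0:
            raise ValueError("scale_tag_mm must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one cell")

    @property
    def shape_px(self) -> tuple[int, int]:
        return (
            int(round(self.board_height_mm / self.mm_per_pixel)),
            int(round(self.board_width_mm / self.mm_per_pixel)),
        )

    def px(self, mm: float) -> int:
        return int(round(mm / self.mm_per_pixel))


@dataclass(frozen=True)
class SeedSpec:
    """One seed: geometry in mm, coat/hilum color, defects, grid slot."""

    major_mm: float
    minor_mm: float
    thickness_mm: float
    base_rgb: tuple[int, int, int]
    row: int
    col: int
    squareness: float = 2.0
    angle_deg: float = 0.0  # rotation of the major axis away from vertical
    hilum_rgb: tuple[int, int, int] | None = None
    hilum_fraction: float = 0.0
    bite_defects: int = 0
    bite_radius_mm: float = 1.0
    is_color_outlier: bool = False

    def __post_init__(self) -> None:
        if self.major_mm <= 0 or self.minor_mm <= 0 or self.thickness_mm <= 0:
            raise ValueError("seed dimensions must be positive")
        if self.minor_mm > self.major_mm:
            raise ValueError("minor_mm must not exceed major_mm")
        if not 0 <= self.hilum_fraction < 0.5:
            raise ValueError("hilum_fraction must lie in [0, 0.5)")
        if self.bite_defects and self.bite_radius_mm >= self.minor_mm / 2:
            raise ValueError("bite radius must be < minor_mm / 2")

    @property
    def is_defective(self) -> bool:
        return self.bite_defects > 0


@dataclass(frozen=True)
class GroundTruthRecord:
    seed_id: int
    row: int
    col: int
    major_mm: float
    minor_mm: float
    thickness_mm: float
    base_rgb: tuple[int, int, int]
    hilum_rgb: tuple[int, int, int] | None
    is_defective: bool
    is_color_outlier: bool


def _superellipse_inside(
    shape: tuple[int, int],
    center: tuple[float, float],
    a_px: float,
    b_px: float,
    n: float,
    angle_deg: float,
) -> np.ndarray:
    """Boolean mask of |u/b|^n + |v/a|^n <= 1 on a pixel grid.

    ``a_px`` is the semi-major (vertical at angle 0), ``b_px`` the
    semi-minor half-axis, both in pixels; pixel centers at integer
    coordinates.
    """
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    dy = yy - center[0]
    dx = xx - center[1]
    t = math.radians(angle_deg)
    # v runs along the major axis (vertical when angle 0), u along minor
    v = dy * math.cos(t) - dx * math.sin(t)
    u = dy * math.sin(t) + dx * math.cos(t)
    with np.errstate(divide="ignore"):
        return (
            np.abs(u / b_px) ** n + np.abs(v / a_px) ** n <= 1.0
        )


def render_seed_mask(seed: SeedSpec, mm_per_pixel: float, rng=None) -> np.ndarray:
    """Rasterize one seed's top-view mask (bite defects subtracted).

    The mask is tight: a small margin around the superellipse bounding
    box.  For ``squareness == 2`` the mask area matches the analytic
    ellipse area pi * (major/2) * (minor/2) / mm_per_pixel**2 within
    discretization error.
    """
    if mm_per_pixel <= 0:
        raise ValueError("mm_per_pixel must be positive")
    a = seed.major_mm / 2.0 / mm_per_pixel
    b = seed.minor_mm / 2.0 / mm_per_pixel
    if a < 1 or b < 1:
        raise ValueError("seed axes degenerate at this resolution")
    margin = 3
    half = max(a, b) + margin
    size = int(math.ceil(2 * half)) + 1
    c = (size - 1) / 2.0
    mask = _superellipse_inside((size, size), (c, c), a, b, seed.squareness, seed.angle_deg)

    if seed.bite_defects:
        rng = np.random.default_rng(0) if rng is None else rng
        r_bite = seed.bite_radius_mm / mm_per_pixel
        yy, xx = np.mgrid[0:size, 0:size].astype(float)
        for _ in range(seed.bite_defects):
            phi = rng.uniform(0, 2 * math.pi)
            # boundary point of the superellipse at parameter phi
            cphi, sphi = math.cos(phi), math.sin(phi)
            n = seed.squareness
            denom = (abs(cphi) ** n + abs(sphi) ** n) ** (1.0 / n)
            u = b * cphi / denom
            v = a * sphi / denom
            # inset the bite center by 0.7 of its radius: feeding damage is
            # a crater, not a graze, so the notch reaches ~1.7 r deep
            shrink = 1.0 - 0.7 * r_bite / math.hypot(u, v)
            u *= shrink
            v *= shrink
            t = math.radians(seed.angle_deg)
            by = c + v * math.cos(t) + u * math.sin(t)
            bx = c - v * math.sin(t) + u * math.cos(t)
            mask &= (yy - by) ** 2 + (xx - bx) ** 2 > r_bite**2
    return _trim(mask)


def _trim(mask: np.ndarray, margin: int = 2) -> np.ndarray:
    """Crop a mask to its tight bounding box plus a small margin."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0 = max(0, rows[0] - margin)
    r1 = min(mask.shape[0], rows[-1] + 1 + margin)
    c0 = max(0, cols[0] - margin)
    c1 = min(mask.shape[1], cols[-1] + 1 + margin)
    return mask[r0:r1, c0:c1]


def _hilum_mask(seed: SeedSpec, mask: np.ndarray, mm_per_pixel: float) -> np.ndarray:
    """Elliptic hilum patch, centered mid-way out along the major axis."""
    if seed.hilum_rgb is None or seed.hilum_fraction <= 0:
        return np.zeros_like(mask)
    a = seed.major_mm / 2.0 / mm_per_pixel
    b = seed.minor_mm / 2.0 / mm_per_pixel
    # patch with the seed's aspect, scaled to the requested area fraction
    s = math.sqrt(seed.hilum_fraction)
    c = (mask.shape[0] - 1) / 2.0
    t = math.radians(seed.angle_deg)
    off = 0.45 * a
    cy = c + off * math.cos(t)
    cx = c - off * math.sin(t)
    patch = _superellipse_inside(mask.shape, (cy, cx), s * a, s * b, 2.0, seed.angle_deg)
    return patch & mask


def _profile_mask(seed: SeedSpec, mm_per_pixel: float,
                  max_width_px: int | None = None) -> np.ndarray:
    """Side-view profile: rectangle with a semi-elliptic top.

    Vertical extent is exactly round(thickness / mm_per_pixel) pixels;
    horizontal extent follows the seed's length (major axis) but is
    capped below the grid pitch so neighboring profiles never touch —
    only the vertical extent carries information (thickness).
    """
    t_px = max(1, int(round(seed.thickness_mm / mm_per_pixel)))
    w_px = max(3, int(round(seed.major_mm / mm_per_pixel)))
    if max_width_px is not None:
        w_px = min(w_px, max_width_px)
    half_w = w_px / 2.0
    split = t_px / 2.0
    mask = np.zeros((t_px, w_px), dtype=bool)
    xs = np.arange(w_px) - (w_px - 1) / 2.0
    for j in range(t_px):  # j = 0 is the top row
        height_above_split = split - j
        if height_above_split <= 0:
            hw = half_w
        else:
            hw = half_w * math.sqrt(max(0.0, 1.0 - (height_above_split / split) ** 2))
        hw = max(hw, 0.6)  # every row keeps >= 1 px so extent is exact
        mask[j] = np.abs(xs) <= hw
    return mask


def _paint(
    canvas: np.ndarray, mask: np.ndarray, top: int, left: int, rgb, rng=None, sigma=0.0
) -> None:
    h, w = mask.shape
    region = canvas[top : top + h, left : left + w]
    if sigma > 0 and rng is not None:
        vals = rng.normal(np.asarray(rgb, float), sigma, size=(int(mask.sum()), 3))
        region[mask] = np.clip(np.round(vals), 0, 255).astype(np.uint8)
    else:
        region[mask] = np.asarray(rgb, dtype=np.uint8)


def _tag_boxes(spec: BoardSpec) -> dict[str, tuple[int, int, int, int]]:
    """Pixel boxes (r0, c0, r1, c1), half-open, for the two tags."""
    tag_px = spec.px(spec.scale_tag_mm)
    m = spec.px(4.0)  # 4 mm margin
    scale_box = (m, m, m + tag_px + 2 * m, m + tag_px + 2 * m)
    patch_px = spec.px(spec.color_patch_mm)
    strip_w = patch_px * len(spec.color_tag_patches)
    c0 = spec.shape_px[1] // 2 - strip_w // 2 - m
    color_box = (m, c0, m + patch_px + 2 * m, c0 + strip_w + 2 * m)
    return {"scale": scale_box, "color": color_box}


def _draw_tags(canvas: np.ndarray, spec: BoardSpec) -> None:
    boxes = _tag_boxes(spec)
    tag_px = spec.px(spec.scale_tag_mm)
    m = spec.px(4.0)
    r0, c0, _, _ = boxes["scale"]
    canvas[r0 + m : r0 + m + tag_px, c0 + m : c0 + m + tag_px] = _TAG_RGB
    patch_px = spec.px(spec.color_patch_mm)
    r0, c0, _, _ = boxes["color"]
    for i, rgb in enumerate(spec.color_tag_patches):
        left = c0 + m + i * patch_px
        canvas[r0 + m : r0 + m + patch_px, left : left + patch_px] = np.asarray(
            rgb, dtype=np.uint8
        )


def _grid_center(spec: BoardSpec, row: int, col: int) -> tuple[float, float]:
    h_px, w_px = spec.shape_px
    band = spec.px(spec.tag_band_mm)
    cell_h = (h_px - band) / spec.n_rows
    cell_w = w_px / spec.n_cols
    cy = band + (row + 0.5) * cell_h
    cx = (col + 0.5) * cell_w
    return cy, cx


def generate_board(
    board_spec: BoardSpec,
    seeds: list[SeedSpec],
    noise_speck_count: int = 0,
    noise_speck_max_px: int = 99,
):
    """Render the top view, one side view per row, and the truth table.

    Returns ``(top, sides, truth)`` where ``top`` is an H x W x 3 uint8
    array, ``sides`` a list of ``n_rows`` side-view arrays and ``truth``
    a list of :class:`GroundTruthRecord` (one per seed, id = list
    order).  Deterministic for a fixed ``board_spec.rng_seed``.

    Raises :class:`LayoutError` when two seed footprints overlap or a
    seed does not fit the board.
    """
    if noise_speck_max_px >= 100:
        raise ValueError("noise specks must stay below the 100 px seed filter")
    rng = np.random.default_rng(board_spec.rng_seed)
    h_px, w_px = board_spec.shape_px
    top = np.empty((h_px, w_px, 3), dtype=np.uint8)
    top[:] = board_spec.background_rgb
    _draw_tags(top, board_spec)

    occupancy = np.zeros((h_px, w_px), dtype=bool)
    for key, (r0, c0, r1, c1) in _tag_boxes(board_spec).items():
        occupancy[r0:r1, c0:c1] = True

    truth: list[GroundTruthRecord] = []
    row_members: dict[int, list[tuple[SeedSpec, float]]] = {}
    for sid, seed in enumerate(seeds):
        if not (0 <= seed.row < board_spec.n_rows and 0 <= seed.col < board_spec.n_cols):
            raise LayoutError(f"seed {sid} position ({seed.row},{seed.col}) off-grid")
        mask = render_seed_mask(seed, board_spec.mm_per_pixel, rng=rng)
        cy, cx = _grid_center(board_spec, seed.row, seed.col)
        mh, mw = mask.shape
        top_r = int(round(cy - mh / 2))
        left_c = int(round(cx - mw / 2))
        if top_r < 0 or left_c < 0 or top_r + mh > h_px or left_c + mw > w_px:
            raise LayoutError(f"seed {sid} does not fit the board")
        window = occupancy[top_r : top_r + mh, left_c : left_c + mw]
        if (window & mask).any():
            raise LayoutError(f"seed {sid} overlaps another footprint")
        window |= mask
        _paint(top, mask, top_r, left_c, seed.base_rgb, rng, board_spec.coat_noise_sigma)
        hil = _hilum_mask(seed, mask, board_spec.mm_per_pixel)
        if hil.any():
            _paint(top, hil, top_r, left_c, seed.hilum_rgb, rng, board_spec.coat_noise_sigma)
        truth.append(
            GroundTruthRecord(
                seed_id=sid,
                row=seed.row,
                col=seed.col,
                major_mm=seed.major_mm,
                minor_mm=seed.minor_mm,
                thickness_mm=seed.thickness_mm,
                base_rgb=seed.base_rgb,
                hilum_rgb=seed.hilum_rgb,
                is_defective=seed.is_defective,
                is_color_outlier=seed.is_color_outlier,
            )
        )
        row_members.setdefault(seed.row, []).append((seed, cx))

    _add_specks(top, occupancy, board_spec, rng, noise_speck_count, noise_speck_max_px)

    sides = []
    side_h = board_spec.px(board_spec.side_view_height_mm)
    baseline = side_h - board_spec.px(2.0)
    for row in range(board_spec.n_rows):
        img = np.empty((side_h, w_px, 3), dtype=np.uint8)
        img[:] = board_spec.background_rgb
        cell_w = w_px // board_spec.n_cols
        for seed, cx in row_members.get(row, []):
            prof = _profile_mask(seed, board_spec.mm_per_pixel,
                                 max_width_px=max(3, cell_w - 6))
            ph, pw = prof.shape
            left_c = int(round(cx - pw / 2))
            _paint(img, prof, baseline - ph, left_c, seed.base_rgb, rng,
                   board_spec.coat_noise_sigma)
        sides.append(img)
    return top, sides, truth


def _add_specks(top, occupancy, spec, rng, count, max_px):
    """Scatter small disk specks disjoint from seeds and tags."""
    h_px, w_px = occupancy.shape
    band = spec.px(spec.tag_band_mm)
    placed = 0
    attempts = 0
    while placed < count:
        attempts += 1
        if attempts > 50 * max(count, 1):
            raise LayoutError("could not place noise specks without contact")
        area = int(rng.integers(8, max(9, max_px)))
        r = max(1.0, math.sqrt(area / math.pi))
        size = int(math.ceil(2 * r)) + 3
        c = (size - 1) / 2.0
        yy, xx = np.mgrid[0:size, 0:size].astype(float)
        d2 = (yy - c) ** 2 + (xx - c) ** 2
        blob = d2 <= r * r
        while blob.sum() >= max_px:  # digital disks can overshoot the target
            r *= 0.95
            blob = d2 <= r * r
        top_r = int(rng.integers(band, h_px - size))
        left_c = int(rng.integers(0, w_px - size))
        # 2 px clearance so specks never merge with a seed component
        rr0 = max(0, top_r - 2)
        cc0 = max(0, left_c - 2)
        window = occupancy[rr0 : top_r + size + 2, cc0 : left_c + size + 2]
        if window.any():
            continue
        occupancy[top_r : top_r + size, left_c : left_c + size] |= blob
        _paint(top, blob, top_r, left_c, _SPECK_RGB)
        placed += 1


def sample_seed_specs(
    board_spec: BoardSpec,
    n: int,
    rng: np.random.Generator,
    major_range=(5.7, 11.7),
    minor_range=(3.4, 8.5),
    thickness_range=(5.0, 9.9),
    squareness_range=(1.8, 2.5),
    base_rgb=(150, 110, 60),
) -> list[SeedSpec]:
    """Draw ``n`` seeds with dimensions uniform over the given mm ranges.

    Defaults reproduce the observed range of cultivated soybean lines
    (width 3.4-8.5, height 5.7-11.7, thickness 5.0-9.9 mm).  Minor axes
    are redrawn until minor <= major.  Seeds fill the grid row-major.
    """
    if n > board_spec.n_rows * board_spec.n_cols:
        raise LayoutError("more seeds than grid cells")
    seeds = []
    for i in range(n):
        major = rng.uniform(*major_range)
        minor = rng.uniform(*minor_range)
        while minor > major:
            minor = rng.uniform(*minor_range)
        seeds.append(
            SeedSpec(
                major_mm=major,
                minor_mm=minor,
                thickness_mm=rng.uniform(*thickness_range),
                base_rgb=base_rgb,
                row=i // board_spec.n_cols,
                col=i % board_spec.n_cols,
                squareness=rng.uniform(*squareness_range),
            )
        )
    return seeds


def truth_to_frame(truth: list[GroundTruthRecord]) -> pd.DataFrame:
    rows = []
    for t in truth:
        hr, hg, hb = t.hilum_rgb if t.hilum_rgb is not None else ("", "", "")
        rows.append(
            dict(
                id=t.seed_id, row=t.row, col=t.col,
                major_mm=t.major_mm, minor_mm=t.minor_mm, thickness_mm=t.thickness_mm,
                base_r=t.base_rgb[0], base_g=t.base_rgb[1], base_b=t.base_rgb[2],
                hilum_r=hr, hilum_g=hg, hilum_b=hb,
                is_defective=t.is_defective, is_color_outlier=t.is_color_outlier,
            )
        )
    return pd.DataFrame(rows)


def write_board(out_dir, prefix, top, sides, truth) -> None:
    """Write PNG views and the ground-truth CSV for one board."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out / f"{prefix}_top.png", top)
    for i, img in enumerate(sides):
        iio.imwrite(out / f"{prefix}_side{i}.png", img)
    truth_to_frame(truth).to_csv(out / f"{prefix}_truth.csv", index=False)


def tag_boxes_for(spec: BoardSpec) -> dict[str, tuple[int, int, int, int]]:
    """Public accessor for the generated tag boxes (pixel, half-open)."""
    return _tag_boxes(spec)
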