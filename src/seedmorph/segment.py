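"""Seed segmentation: channel split, thresholding, labeling, ROI store.

Seeds are separated from the board background by picking the most
separable color channel, thresholding it (Otsu by default), labeling
8-connected components, and discarding components smaller than a
minimum pixel area (default 100 px — smaller than any seed, larger than
residual noise).  Surviving regions are sorted into board order and
assigned (row, column) grid positions.

Regions persist in a plain-text archive (``rois.zip``: a JSON index plus
one run-length-encoded mask per region) so measurements can be repeated
without re-segmentation.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import find_contours, label as sk_label, regionprops

__all__ = [
    "SeedRegion",
    "SegmentationParams",
    "SegmentationError",
    "RoiArchiveError",
    "split_channels",
    "select_channel",
    "binarize",
    "label_and_filter",
    "save_rois",
    "load_rois",
]


class SegmentationError(ValueError):
    pass


class RoiArchiveError(ValueError):
    """ROI archive unreadable; the message names the offending record."""


@dataclass(frozen=True)
class SegmentationParams:
    channel_strategy: str = "auto"  # red | green | blue | gray | auto
    threshold_method: str = "otsu"  # otsu | fixed
    fixed_threshold: int | None = None
    min_area_px: int = 100
    polarity: str = "auto"  # darker | brighter | auto
    n_rows: int = 4

    def __post_init__(self) -> None:
        if self.min_area_px < 1:
            raise ValueError("min_area_px must be >= 1")
        if self.threshold_method == "fixed":
            if self.fixed_threshold is None or not 0 <= self.fixed_threshold <= 255:
                raise ValueError("fixed threshold must lie in [0, 255]")
        if self.channel_strategy not in ("red", "green", "blue", "gray", "auto"):
            raise ValueError(f"unknown channel strategy {self.channel_strategy!r}")
        if self.polarity not in ("darker", "brighter", "auto"):
            raise ValueError(f"unknown polarity {self.polarity!r}")


@dataclass
class SeedRegion:
    """One labeled seed: mask, outline, centroid and board position."""

    label: int
    mask: np.ndarray          # bool, cropped to bbox
    bbox: tuple[int, int, int, int]  # (r0, c0, r1, c1) half-open, image coords
    centroid: tuple[float, float]    # (row, col) in image coords
    area_px: int
    outline: np.ndarray       # N x 2 sub-pixel contour, image coords
    view: str = "top"
    row: int | None = None
    col: int | None = None


def split_channels(image: np.ndarray):
    """Split an RGB raster into red, green, blue and luma-gray planes.

    Gray is the Rec. 601 luma, rounded: 0.299 R + 0.587 G + 0.114 B.
    """
    px = np.asarray(image)
    if px.ndim != 3 or px.shape[2] != 3:
        raise SegmentationError("expected an H x W x 3 RGB image")
    r, g, b = px[:, :, 0], px[:, :, 1], px[:, :, 2]
    gray = np.round(
        0.299 * r.astype(float) + 0.587 * g.astype(float) + 0.114 * b.astype(float)
    ).astype(np.uint8)
    return r, g, b, gray


def _otsu_criterion(channel: np.ndarray) -> float:
    """Between-class variance at the Otsu threshold (0 when inseparable)."""
    vals = channel.ravel().astype(float)
    if np.ptp(vals) == 0:
        return 0.0
    thr = threshold_otsu(channel)
    lo, hi = vals[vals <= thr], vals[vals > thr]
    if lo.size == 0 or hi.size == 0:
        return 0.0
    w0, w1 = lo.size / vals.size, hi.size / vals.size
    return w0 * w1 * (lo.mean() - hi.mean()) ** 2


def select_channel(channels, strategy: str = "auto") -> np.ndarray:
    """Pick the channel to threshold.

    ``auto`` maximizes the Otsu between-class variance — the channel on
    which seeds and background are most separable.
    """
    r, g, b, gray = channels
    named = {"red": r, "green": g, "blue": b, "gray": gray}
    if strategy in named:
        return named[strategy]
    if strategy != "auto":
        raise SegmentationError(f"unknown channel strategy {strategy!r}")
    scores = {k: _otsu_criterion(v) for k, v in named.items()}
    best = max(scores, key=scores.get)
    if scores[best] == 0.0:
        raise SegmentationError("no channel separates foreground from background")
    return named[best]


def binarize(channel: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Threshold a single-channel image; foreground = seeds (True)."""
    ch = np.asarray(channel)
    if ch.ndim != 2:
        raise SegmentationError("binarize expects a single-channel image")
    if np.ptp(ch) == 0:
        raise SegmentationError("degenerate histogram: single-valued image")
    if params.threshold_method == "fixed":
        thr = params.fixed_threshold
        darker = ch < thr
        brighter = ch > thr
    else:
        # skimage's Otsu puts the threshold at the top of the lower class,
        # so the darker side is inclusive
        thr = threshold_otsu(ch)
        darker = ch <= thr
        brighter = ch > thr
    if params.polarity == "darker":
        return darker
    if params.polarity == "brighter":
        return brighter
    # auto: seeds cover less of the board than background
    return darker if darker.sum() <= brighter.sum() else brighter


def _assign_grid(regions: list[SeedRegion], n_rows: int) -> list[SeedRegion]:
    """Sort regions into board order and assign (row, col).

    Rows are found by splitting sorted centroid-y values at up to
    ``n_rows - 1`` of the largest gaps, counting only gaps wider than a
    typical region height (so partially filled boards do not have real
    rows fragmented); within a row, columns follow centroid x.
    """
    if not regions:
        return regions
    n_rows = min(n_rows, len(regions))
    order = sorted(regions, key=lambda r: r.centroid[0])
    ys = np.array([r.centroid[0] for r in order])
    if n_rows > 1 and len(order) > 1:
        gaps = np.diff(ys)
        mean_h = float(np.mean([r.bbox[2] - r.bbox[0] for r in order]))
        candidates = np.flatnonzero(gaps > 0.8 * mean_h)
        if len(candidates) > n_rows - 1:
            keep = np.argsort(gaps[candidates])[-(n_rows - 1):]
            candidates = candidates[np.sort(keep)]
        bounds = [0, *(c + 1 for c in candidates), len(order)]
    else:
        bounds = [0, len(order)]
    out: list[SeedRegion] = []
    for row, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        members = sorted(order[a:b], key=lambda r: r.centroid[1])
        for col, reg in enumerate(members):
            reg.row, reg.col = row, col
            out.append(reg)
    return out


def _region_outline(mask: np.ndarray, bbox) -> np.ndarray:
    """Longest sub-pixel contour of the mask, shifted to image coords."""
    padded = np.pad(mask.astype(float), 1)
    contours = find_contours(padded, 0.5)
    contour = max(contours, key=len)
    return contour - 1.0 + np.array([bbox[0], bbox[1]])


def label_and_filter(
    mask: np.ndarray, params: SegmentationParams, view: str = "top"
) -> list[SeedRegion]:
    """8-connected components with strict minimum-area noise removal.

    Components with ``area < min_area_px`` are discarded (strictly: a
    component of exactly ``min_area_px`` pixels survives).  Survivors
    are assigned board (row, col) positions.  An empty result is a valid
    outcome, not an error.
    """
    lab = sk_label(np.asarray(mask, dtype=bool), connectivity=2)
    regions: list[SeedRegion] = []
    for prop in regionprops(lab):
        if prop.area < params.min_area_px:
            continue
        crop = prop.image.copy()
        regions.append(
            SeedRegion(
                label=int(prop.label),
                mask=crop,
                bbox=tuple(int(v) for v in prop.bbox),
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                area_px=int(prop.area),
                outline=_region_outline(crop, prop.bbox),
                view=view,
            )
        )
    n_rows = params.n_rows if view == "top" else 1
    return _assign_grid(regions, n_rows)


# --- ROI persistence -------------------------------------------------------

def _rle_encode(mask: np.ndarray) -> str:
    flat = np.asarray(mask, dtype=bool).ravel()
    if not flat.any():
        return ""
    diffs = np.flatnonzero(np.diff(np.concatenate([[False], flat, [False]])))
    starts, ends = diffs[::2], diffs[1::2]
    return ",".join(f"{s}:{e - s}" for s, e in zip(starts, ends))


def _rle_decode(runs: str, shape: tuple[int, int]) -> np.ndarray:
    flat = np.zeros(shape[0] * shape[1], dtype=bool)
    if runs:
        for token in runs.split(","):
            s, n = token.split(":")
            flat[int(s) : int(s) + int(n)] = True
    return flat.reshape(shape)


def save_rois(regions: list[SeedRegion], path) -> None:
    """Write regions to a zip archive (JSON index + RLE masks)."""
    path = Path(path)
    index = []
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for i, reg in enumerate(regions):
            name = f"mask_{i:04d}.rle"
            h, w = reg.mask.shape
            zf.writestr(name, f"{h} {w};{_rle_encode(reg.mask)}")
            index.append(
                dict(
                    label=reg.label, mask=name, bbox=list(reg.bbox),
                    centroid=list(reg.centroid), area_px=reg.area_px,
                    view=reg.view, row=reg.row, col=reg.col,
                )
            )
        zf.writestr("index.json", json.dumps(index, indent=1))


def load_rois(path) -> list[SeedRegion]:
    """Read a ROI archive back; the round trip is lossless."""
    path = Path(path)
    if not path.exists():
        raise RoiArchiveError(f"no ROI archive at {path}")
    regions: list[SeedRegion] = []
    try:
        with zipfile.ZipFile(path) as zf:
            index = json.loads(zf.read("index.json"))
            for entry in index:
                try:
                    raw = zf.read(entry["mask"]).decode()
                    header, runs = raw.split(";", 1)
                    h, w = (int(v) for v in header.split())
                    mask = _rle_decode(runs, (h, w))
                except Exception as exc:
                    raise RoiArchiveError(
                        f"corrupt ROI record {entry.get('mask')!r}: {exc}"
                    ) from exc
                bbox = tuple(entry["bbox"])
                regions.append(
                    SeedRegion(
                        label=entry["label"], mask=mask, bbox=bbox,
                        centroid=tuple(entry["centroid"]), area_px=entry["area_px"],
                        outline=_region_outline(mask, bbox),
                        view=entry["view"], row=entry["row"], col=entry["col"],
                    )
                )
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError) as exc:
        raise RoiArchiveError(f"unreadable ROI archive {path}: {exc}") from exc
    return regions
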