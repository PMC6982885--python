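import numpy as np
import pytest

from seedmorph import boards
from seedmorph import morphometry as mo
from seedmorph import preprocess as pp
from seedmorph import segment as seg


def small_spec(**overrides) -> boards.BoardSpec:
    """A compact 2 x 5 board (~1000 x 900 px) that segments in well under
    a second; tag geometry shrunk so both tags fit the narrow top band."""
    kw = dict(
        board_width_mm=100.0,
        board_height_mm=90.0,
        n_rows=2,
        n_cols=5,
        # patch levels <= 190 so a 1.3x illumination gain cannot clip at 255
        color_tag_patches=((40, 40, 40), (120, 120, 120), (190, 40, 40), (40, 40, 190)),
        color_patch_mm=4.0,
        tag_band_mm=30.0,
        rng_seed=0,
    )
    kw.update(overrides)
    return boards.BoardSpec(**kw)


def uniform_seeds(spec, n, major=8.4, minor=6.0, thickness=6.8, rgb=(150, 110, 60),
                  **seed_overrides):
    return [
        boards.SeedSpec(major, minor, thickness, rgb,
                        row=i // spec.n_cols, col=i % spec.n_cols, **seed_overrides)
        for i in range(n)
    ]


def segment_top(top, spec, params=None):
    """Crop tags, calibrate, and segment a generated top view."""
    params = params or seg.SegmentationParams(n_rows=spec.n_rows)
    image = pp.BoardImage(top, view="top", tag_boxes=boards.tag_boxes_for(spec))
    cleaned, crops = pp.crop_tags(image)
    calib = pp.calibrate_scale(crops["scale"], tag_mm=spec.scale_tag_mm)
    channel = seg.select_channel(seg.split_channels(cleaned.pixels), params.channel_strategy)
    regions = seg.label_and_filter(seg.binarize(channel, params), params, view="top")
    return cleaned, regions, calib


def segment_side(img, params=None):
    params = params or seg.SegmentationParams()
    channel = seg.select_channel(seg.split_channels(img), params.channel_strategy)
    return seg.label_and_filter(seg.binarize(channel, params), params, view="side")


def measure_board(top, sides, spec):
    """Full measurement chain on one generated board."""
    cleaned, regions, calib = segment_top(top, spec)
    records = [mo.measure_region(r, calib, seed_id=i) for i, r in enumerate(regions)]
    side_by_row = {row: segment_side(img) for row, img in enumerate(sides)}
    return cleaned, regions, calib, mo.match_top_side(records, side_by_row, calib)


def region_from_mask(mask) -> seg.SeedRegion:
    """Wrap a standalone boolean mask as a single SeedRegion."""
    params = seg.SegmentationParams(min_area_px=1, n_rows=1)
    regions = seg.label_and_filter(mask, params, view="top")
    assert len(regions) == 1
    return regions[0]


def disk_mask(radius_px: int, pad: int = 5) -> np.ndarray:
    n = 2 * (radius_px + pad) + 1
    yy, xx = np.mgrid[:n, :n]
    c = radius_px + pad
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius_px**2


CALIB_01 = pp.ScaleCalibration(mm_per_pixel=0.1, tag_pixel_length=160.0)


@pytest.fixture(scope="session")
def default_board():
    """The reference layout: 100 identical seeds in 4 x 25 plus 20 specks."""
    spec = boards.BoardSpec(rng_seed=42)
    seeds = [
        boards.SeedSpec(8.4, 6.0, 6.8, (150, 110, 60), row=i // 25, col=i % 25)
        for i in range(100)
    ]
    top, sides, truth = boards.generate_board(spec, seeds, noise_speck_count=20)
    return spec, seeds, top, sides, truth
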