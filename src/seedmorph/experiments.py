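"""Reference experiments on synthetic boards with known ground truth.

These reproduce, at desk scale, the validation a physical rig would
undergo: counting seeds against noise, recovering caliper dimensions
from images, and separating smooth from damaged seeds by solidity.
Every experiment generates its own boards, runs the full preprocessing,
segmentation and morphometry chain, and compares against the generator's
ground truth.
"""

from __future__ import annotations

import numpy as np

from . import boards
from . import morphometry as mo
from . import preprocess as pp
from . import segment as seg

__all__ = [
    "seed_count_experiment",
    "dimension_recovery_experiment",
    "solidity_experiment",
    "measure_synthetic_board",
]

# Observed cultivated-soybean trait ranges (mm) used as sampling defaults
MAJOR_RANGE = (5.7, 11.7)
MINOR_RANGE = (3.4, 8.5)
THICKNESS_RANGE = (5.0, 9.9)


def landscape_spec(rng_seed: int = 0, **overrides) -> boards.BoardSpec:
    """A 297 x 210 mm board: the wide grid pitch (~11.9 mm) leaves room
    for seeds spanning the full observed size range without contact."""
    kw = dict(board_width_mm=297.0, board_height_mm=210.0, rng_seed=rng_seed)
    kw.update(overrides)
    return boards.BoardSpec(**kw)


def measure_synthetic_board(spec, seeds, noise_speck_count=0, params=None):
    """Generate one board and run the full measurement chain on it.

    Returns ``(records, truth, regions)`` with records in board order
    (row-major), aligned index-for-index with the ground truth.
    """
    top, sides, truth = boards.generate_board(spec, seeds,
                                              noise_speck_count=noise_speck_count)
    params = params or seg.SegmentationParams(n_rows=spec.n_rows)
    image = pp.BoardImage(top, view="top", tag_boxes=boards.tag_boxes_for(spec))
    cleaned, crops = pp.crop_tags(image)
    calib = pp.calibrate_scale(crops["scale"], tag_mm=spec.scale_tag_mm)
    channel = seg.select_channel(seg.split_channels(cleaned.pixels),
                                 params.channel_strategy)
    regions = seg.label_and_filter(seg.binarize(channel, params), params, view="top")
    records = [mo.measure_region(r, calib, seed_id=i) for i, r in enumerate(regions)]
    side_by_row = {}
    for row, img in enumerate(sides):
        try:
            ch = seg.select_channel(seg.split_channels(img), params.channel_strategy)
        except seg.SegmentationError:
            side_by_row[row] = []  # empty row: uniform background
            continue
        side_by_row[row] = seg.label_and_filter(seg.binarize(ch, params), params,
                                                view="side")
    records = mo.match_top_side(records, side_by_row, calib)
    return records, truth, regions


def seed_count_experiment(rng_seed: int = 42, n_specks: int = 20) -> int:
    """Count detected regions on the reference 4 x 25 board plus specks.

    100 identical seeds are laid out in 4 rows of 25 on the default
    210 x 297 mm board at 0.1 mm/px, with ``n_specks`` noise specks each
    under 100 px; the minimum-area filter must leave exactly the seeds.
    """
    spec = boards.BoardSpec(rng_seed=rng_seed)
    seeds = [
        boards.SeedSpec(8.4, 6.0, 6.8, (150, 110, 60), row=i // 25, col=i % 25)
        for i in range(100)
    ]
    records, truth, regions = measure_synthetic_board(spec, seeds,
                                                      noise_speck_count=n_specks)
    return len(regions)


def dimension_recovery_experiment(rng_seed: int = 0, n_seeds: int = 200) -> dict:
    """Image-vs-truth correlation for width, height and thickness.

    ``n_seeds`` seeds with dimensions uniform over the observed ranges
    are rendered across as many 100-seed boards as needed; the Pearson
    correlation between ground-truth and measured values is returned per
    dimension together with the minimum of the three.
    """
    rng = np.random.default_rng(rng_seed)
    pairs = {"width_mm": [], "height_mm": [], "thickness_mm": []}
    remaining = n_seeds
    board_i = 0
    while remaining > 0:
        spec = landscape_spec(rng_seed=rng_seed + board_i)
        n = min(remaining, spec.n_rows * spec.n_cols)
        seeds = boards.sample_seed_specs(spec, n, rng, major_range=MAJOR_RANGE,
                                         minor_range=MINOR_RANGE,
                                         thickness_range=THICKNESS_RANGE)
        records, truth, _ = measure_synthetic_board(spec, seeds)
        if len(records) != len(truth):
            raise RuntimeError("segmentation lost seeds; recovery undefined")
        for rec, t in zip(records, truth):
            pairs["width_mm"].append((t.minor_mm, rec.width_mm))
            pairs["height_mm"].append((t.major_mm, rec.height_mm))
            pairs["thickness_mm"].append((t.thickness_mm, rec.thickness_mm))
        remaining -= n
        board_i += 1
    out = {}
    for dim, xy in pairs.items():
        a = np.asarray(xy)
        out[dim] = float(np.corrcoef(a[:, 0], a[:, 1])[0, 1])
    out["min"] = min(out["width_mm"], out["height_mm"], out["thickness_mm"])
    out["n"] = n_seeds
    return out


def solidity_experiment(rng_seed: int = 0, n_seeds: int = 100,
                        bite: bool = False) -> dict:
    """Solidity of smooth (or uniformly bitten) superellipse seeds.

    Seeds span the observed dimension ranges with superellipse exponents
    in [1.8, 2.5].  Returns the minimum, maximum and mean measured
    solidity over the full segmentation + morphometry chain.
    """
    rng = np.random.default_rng(rng_seed)
    spec = landscape_spec(rng_seed=rng_seed)
    seeds = boards.sample_seed_specs(spec, n_seeds, rng, major_range=MAJOR_RANGE,
                                     minor_range=MINOR_RANGE,
                                     thickness_range=THICKNESS_RANGE)
    if bite:
        from dataclasses import replace

        seeds = [replace(s, bite_defects=1, bite_radius_mm=1.0) for s in seeds]
    records, truth, _ = measure_synthetic_board(spec, seeds)
    if len(records) != n_seeds:
        raise RuntimeError("segmentation lost seeds; solidity floor undefined")
    sol = np.array([r.solidity for r in records])
    return {"min": float(sol.min()), "max": float(sol.max()),
            "mean": float(sol.mean()), "n": n_seeds}
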