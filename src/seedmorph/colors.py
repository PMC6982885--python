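"""Per-seed color analysis: histograms, envelope outliers, hilum search,
and quantitative HTML color codes.

For each seed, 256-bin histograms of the red, green, blue and luma-gray
values over the seed's mask are collected.  Within a line (one board of
sibling seeds) two detectors run on the gray histograms:

* **Envelope analysis** — per-bin mean and sample standard deviation
  across the line's seeds form a band ``mean +/- k*sd``; a seed whose
  histogram strays outside the band in too large a fraction of its
  occupied bins is color-atypical for the line.
* **Log micro-analysis** — histograms are compressed bin-wise with
  ``log(1 + count)`` so that small, distinctly-colored areas (such as a
  contrasting hilum) become visible against the bulk coat color.  A seed
  is flagged when its log-space deviation concentrates in bins where the
  line as a whole has almost no mass.  Seeds with an overall dark coat
  are excluded: their histograms pile up in the same low bins the
  detector inspects, which makes the micro signal unreliable.

Each seed finally receives one or two named web colors: the
representative RGB (histogram mode per channel) is snapped to the
nearest CSS named color, and seeds whose gray histogram is strongly
bimodal are split at the valley into two pixel clusters, each coded
separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .css_colors import nearest_css_color
from .segment import SeedRegion

__all__ = [
    "ColorProfile",
    "HistogramEnvelope",
    "ColorAnalysisError",
    "seed_histograms",
    "build_envelope",
    "detect_envelope_outliers",
    "log_micro_analysis",
    "representative_color",
    "assign_color_codes",
    "masked_pixels",
    "plot_line_histograms",
]

CHANNELS = ("red", "green", "blue", "gray")


class ColorAnalysisError(ValueError):
    pass


@dataclass
class ColorProfile:
    seed_id: int
    hist: dict[str, np.ndarray]  # channel -> 256-bin counts
    pixel_count: int
    representative_rgb: tuple[int, int, int] | None = None
    color_codes: list[tuple[str, str]] = field(default_factory=list)
    outlier_flag: str = "none"  # none | envelope | micro | both
    hilum_flag: bool = False


@dataclass(frozen=True)
class HistogramEnvelope:
    """Per-bin mean and sd of one line's seed histograms, with width k."""

    mean: dict[str, np.ndarray]
    sd: dict[str, np.ndarray]
    k: float
    seed_ids: frozenset[int]
    mean_pixel_count: float


def masked_pixels(image: np.ndarray, region: SeedRegion) -> np.ndarray:
    """The region's pixels as an N x 4 array (R, G, B, gray)."""
    r0, c0, r1, c1 = region.bbox
    crop = np.asarray(image)[r0:r1, c0:c1]
    if crop.shape[:2] != region.mask.shape:
        raise ColorAnalysisError("region mask does not fit inside the image")
    rgb = crop[region.mask]
    gray = np.round(
        0.299 * rgb[:, 0].astype(float)
        + 0.587 * rgb[:, 1].astype(float)
        + 0.114 * rgb[:, 2].astype(float)
    ).astype(np.uint8)
    return np.column_stack([rgb, gray])


def seed_histograms(image: np.ndarray, region: SeedRegion, seed_id: int = 0) -> ColorProfile:
    """256-bin histograms over the seed mask only (background excluded)."""
    if not region.mask.any():
        raise ColorAnalysisError("empty region mask")
    px = masked_pixels(image, region)
    hist = {
        ch: np.bincount(px[:, i], minlength=256).astype(np.int64)
        for i, ch in enumerate(CHANNELS)
    }
    return ColorProfile(seed_id=seed_id, hist=hist, pixel_count=int(px.shape[0]))


def build_envelope(profiles: list[ColorProfile], k: float = 2.0) -> HistogramEnvelope:
    """Per-bin mean and sample sd across one line's seeds."""
    if len(profiles) < 3:
        raise ColorAnalysisError("an envelope needs at least 3 seeds")
    mean, sd = {}, {}
    for ch in CHANNELS:
        stack = np.stack([p.hist[ch] for p in profiles]).astype(float)
        mean[ch] = stack.mean(axis=0)
        sd[ch] = stack.std(axis=0, ddof=1)
    return HistogramEnvelope(
        mean=mean,
        sd=sd,
        k=float(k),
        seed_ids=frozenset(p.seed_id for p in profiles),
        mean_pixel_count=float(np.mean([p.pixel_count for p in profiles])),
    )


def _check_same_line(profiles, envelope) -> None:
    strangers = [p.seed_id for p in profiles if p.seed_id not in envelope.seed_ids]
    if strangers:
        raise ColorAnalysisError(
            f"profiles {strangers} are not part of the envelope's line"
        )


def detect_envelope_outliers(
    profiles: list[ColorProfile],
    envelope: HistogramEnvelope,
    excess_fraction: float = 0.05,
) -> dict[int, bool]:
    """Flag seeds whose gray histogram strays outside the line envelope.

    The statistic is the fraction of occupied bins (bins where the seed
    or the line mean has any mass) lying strictly outside
    ``mean +/- k*sd``; a seed is flagged when it exceeds
    ``excess_fraction``.
    """
    _check_same_line(profiles, envelope)
    m, s = envelope.mean["gray"], envelope.sd["gray"]
    flags: dict[int, bool] = {}
    for p in profiles:
        h = p.hist["gray"].astype(float)
        support = (h > 0) | (m > 0)
        outside = np.abs(h - m) > envelope.k * s
        frac = (outside & support).sum() / max(1, support.sum())
        flags[p.seed_id] = bool(frac > excess_fraction)
    return flags


def log_micro_analysis(
    profiles: list[ColorProfile],
    envelope: HistogramEnvelope,
    min_brightness: int = 80,
    excess_fraction: float = 0.05,
    low_bin_fraction: float = 0.01,
) -> dict[int, bool]:
    """Flag bright-coat seeds with a distinct small-area (hilum) color.

    Histograms are transformed with ``log(1 + count)`` and the envelope
    rebuilt in log space.  Only "micro" bins are inspected — bins whose
    line-mean count is below ``low_bin_fraction`` of the mean seed pixel
    count — so the bulk coat color cannot trigger the flag.  Seeds whose
    representative gray level is below ``min_brightness`` are excluded
    (dark coats occupy the same low-gray bins and swamp the signal).
    """
    _check_same_line(profiles, envelope)
    stack = np.log1p(np.stack([p.hist["gray"] for p in profiles]).astype(float))
    mean_log = stack.mean(axis=0)
    sd_log = stack.std(axis=0, ddof=1)
    mean_raw = envelope.mean["gray"]
    low = mean_raw < low_bin_fraction * envelope.mean_pixel_count
    flags: dict[int, bool] = {}
    for p in profiles:
        rep_gray = int(np.argmax(p.hist["gray"]))
        if rep_gray < min_brightness:
            flags[p.seed_id] = False
            continue
        h = p.hist["gray"].astype(float)
        occupied_low = low & (h > 0)
        outside = np.abs(np.log1p(h) - mean_log) > envelope.k * sd_log
        n_occ = occupied_low.sum()
        frac = (outside & occupied_low).sum() / n_occ if n_occ else 0.0
        flags[p.seed_id] = bool(frac > excess_fraction)
    return flags


def _channel_peaks(hist: np.ndarray, smooth_sigma: float = 0.0, distance: int = 10):
    """Peak bins of a histogram, tallest first; endpoints included."""
    h = hist.astype(float)
    if smooth_sigma > 0:
        h = gaussian_filter1d(h, smooth_sigma)
    padded = np.concatenate([[0.0], h, [0.0]])
    peaks, _ = find_peaks(padded, distance=distance)
    peaks = peaks - 1
    order = np.argsort(h[peaks])[::-1]
    return peaks[order], h


def representative_color(image: np.ndarray, region: SeedRegion,
                         profile: ColorProfile | None = None) -> tuple[int, int, int]:
    """Per-channel histogram mode, with a median fallback.

    When a channel is multi-modal with near-equal peaks (second/first
    height ratio > 0.8) the mode is ambiguous and the channel falls back
    to the median of the masked pixels.
    """
    if profile is None:
        profile = seed_histograms(image, region)
    px = masked_pixels(image, region)
    rep = []
    for i, ch in enumerate(("red", "green", "blue")):
        peaks, h = _channel_peaks(profile.hist[ch])
        if len(peaks) >= 2 and h[peaks[1]] / h[peaks[0]] > 0.8:
            rep.append(int(np.median(px[:, i])))
        else:
            rep.append(int(peaks[0]) if len(peaks) else int(np.argmax(profile.hist[ch])))
    return tuple(rep)


def assign_color_codes(
    image: np.ndarray,
    region: SeedRegion,
    profile: ColorProfile | None = None,
    bicolor_peak_ratio: float = 0.25,
    min_peak_separation: int = 40,
) -> list[tuple[str, str]]:
    """One or two (name, hex) web-color codes for a seed.

    A seed is bicolor when its gray histogram shows two peaks at least
    ``min_peak_separation`` levels apart whose smaller/larger mass ratio
    (split at the inter-peak valley) reaches ``bicolor_peak_ratio``; the
    pixels are then split at the valley and each cluster's mean RGB is
    coded.  Otherwise the representative RGB is coded alone.
    """
    if profile is None:
        profile = seed_histograms(image, region)
    peaks, h_smooth = _channel_peaks(profile.hist["gray"], smooth_sigma=1.5,
                                     distance=min_peak_separation)
    if len(peaks) >= 2:
        p1, p2 = sorted(peaks[:2])
        if p2 - p1 >= min_peak_separation:
            valley = p1 + int(np.argmin(h_smooth[p1 : p2 + 1]))
            gray_hist = profile.hist["gray"]
            mass_lo = gray_hist[: valley + 1].sum()
            mass_hi = gray_hist[valley + 1 :].sum()
            if mass_lo and mass_hi:
                ratio = min(mass_lo, mass_hi) / max(mass_lo, mass_hi)
                if ratio >= bicolor_peak_ratio:
                    px = masked_pixels(image, region)
                    lo = px[px[:, 3] <= valley, :3].mean(axis=0)
                    hi = px[px[:, 3] > valley, :3].mean(axis=0)
                    clusters = [hi, lo] if mass_hi >= mass_lo else [lo, hi]
                    return [nearest_css_color(np.round(c)) for c in clusters]
    rep = representative_color(image, region, profile)
    return [nearest_css_color(rep)]


def plot_line_histograms(profiles, envelope, path, channel: str = "gray") -> None:
    """Write a PNG of per-seed curves, the line mean, and the envelope."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.arange(256)
    fig, ax = plt.subplots(figsize=(8, 4))
    for p in profiles:
        ax.plot(x, p.hist[channel], color="0.7", lw=0.5)
    m, s = envelope.mean[channel], envelope.sd[channel]
    ax.plot(x, m, color="C0", lw=1.5, label="line mean")
    ax.fill_between(x, np.maximum(0, m - envelope.k * s), m + envelope.k * s,
                    color="C0", alpha=0.2, label=f"mean ± {envelope.k:g}·sd")
    ax.set_xlabel(f"{channel} level")
    ax.set_ylabel("pixel count")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
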