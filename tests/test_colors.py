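"""Histograms, envelope/micro outlier detection, HTML color codes."""

import numpy as np
import pytest

from seedmorph import boards
from seedmorph import colors as ca
from seedmorph.css_colors import CSS_COLORS, hex_to_rgb, nearest_css_color
from conftest import segment_top, small_spec, uniform_seeds


def flat_region(color, shape=(20, 30), bg=(235, 235, 235)):
    """A rectangular flat-colored 'seed' on background, as (image, region)."""
    from seedmorph import segment as seg

    img = np.full((shape[0] + 10, shape[1] + 10, 3), bg, dtype=np.uint8)
    img[5 : 5 + shape[0], 5 : 5 + shape[1]] = color
    mask = np.zeros(img.shape[:2], dtype=bool)
    mask[5 : 5 + shape[0], 5 : 5 + shape[1]] = True
    region = seg.label_and_filter(mask, seg.SegmentationParams(min_area_px=1))[0]
    return img, region


def two_tone_region(color_a, color_b, frac_b, shape=(20, 30)):
    img, region = flat_region(color_a, shape)
    n_b = int(round(shape[1] * frac_b))
    img[5 : 5 + shape[0], 5 + shape[1] - n_b : 5 + shape[1]] = color_b
    return img, region


class TestSeedHistograms:
    def test_uniform_seed_concentrates_in_one_bin_per_channel(self):
        img, region = flat_region((200, 150, 100))
        prof = ca.seed_histograms(img, region)
        assert prof.hist["red"][200] == prof.pixel_count
        assert prof.hist["green"][150] == prof.pixel_count
        assert prof.hist["blue"][100] == prof.pixel_count

    def test_coat_hilum_mix_has_nine_to_one_mass(self):
        img, region = two_tone_region((200, 150, 100), (30, 30, 30), 0.1)
        prof = ca.seed_histograms(img, region)
        assert prof.hist["red"][200] == 9 * prof.hist["red"][30]

    def test_histograms_conserve_pixel_count(self):
        img, region = two_tone_region((120, 90, 60), (40, 40, 40), 0.3)
        prof = ca.seed_histograms(img, region)
        for ch in ca.CHANNELS:
            assert prof.hist[ch].sum() == prof.pixel_count

    def test_empty_mask_rejected(self):
        img, region = flat_region((100, 100, 100))
        region.mask = np.zeros_like(region.mask)
        with pytest.raises(ca.ColorAnalysisError):
            ca.seed_histograms(img, region)


def make_profiles(gray_levels, n_px=500):
    """Synthetic single-bin gray profiles (RGB set to the same level)."""
    profs = []
    for i, lvl in enumerate(gray_levels):
        hist = {ch: np.zeros(256, dtype=np.int64) for ch in ca.CHANNELS}
        for ch in ca.CHANNELS:
            hist[ch][lvl] = n_px
        profs.append(ca.ColorProfile(seed_id=i, hist=hist, pixel_count=n_px))
    return profs


class TestEnvelope:
    def test_identical_profiles_collapse_to_mean(self):
        profs = make_profiles([100] * 10)
        env = ca.build_envelope(profs, k=2.0)
        assert env.sd["gray"].max() == 0.0
        assert ca.detect_envelope_outliers(profs, env) == {i: False for i in range(10)}

    def test_shifted_seed_exits_envelope(self):
        profs = make_profiles([100] * 99 + [150])
        env = ca.build_envelope(profs, k=2.0)
        flags = ca.detect_envelope_outliers(profs, env)
        assert flags[99] is True
        assert sum(flags.values()) == 1

    def test_larger_k_never_grows_the_flagged_set(self):
        rng = np.random.default_rng(0)
        levels = [100 + int(d) for d in rng.normal(0, 3, 50)] + [180, 190]
        profs = make_profiles(levels)
        flagged = {}
        for k in (1.0, 2.0, 4.0):
            env = ca.build_envelope(profs, k=k)
            flags = ca.detect_envelope_outliers(profs, env)
            flagged[k] = {i for i, v in flags.items() if v}
        assert flagged[4.0] <= flagged[2.0] <= flagged[1.0]

    def test_order_invariance(self):
        profs = make_profiles([100, 110, 105, 90, 180])
        env_a = ca.build_envelope(profs, k=2.0)
        env_b = ca.build_envelope(list(reversed(profs)), k=2.0)
        assert np.array_equal(env_a.mean["gray"], env_b.mean["gray"])
        fa = ca.detect_envelope_outliers(profs, env_a)
        fb = ca.detect_envelope_outliers(list(reversed(profs)), env_b)
        assert fa == fb

    def test_too_few_profiles_rejected(self):
        with pytest.raises(ca.ColorAnalysisError):
            ca.build_envelope(make_profiles([100, 110]))

    def test_foreign_envelope_rejected(self):
        line_a = make_profiles([100] * 5)
        line_b = make_profiles([100] * 5)
        for p in line_b:
            p.seed_id += 50
        env = ca.build_envelope(line_a)
        with pytest.raises(ca.ColorAnalysisError):
            ca.detect_envelope_outliers(line_b, env)


class TestBoardOutlierRecovery:
    def test_recolored_seeds_flagged_with_perfect_recall_precision(self):
        spec = small_spec(rng_seed=13)
        seeds = []
        # two distinct recolors, each > 60 gray levels from the coat
        recolor = {2: (40, 40, 120), 7: (30, 30, 30)}
        outliers = set(recolor)
        for i in range(10):
            rgb = recolor.get(i, (150, 110, 60))
            seeds.append(boards.SeedSpec(8.4, 6.0, 6.8, rgb, row=i // 5, col=i % 5,
                                         is_color_outlier=i in outliers))
        top, _, truth = boards.generate_board(spec, seeds)
        cleaned, regions, _ = segment_top(top, spec)
        profs = [ca.seed_histograms(cleaned.pixels, r, seed_id=i)
                 for i, r in enumerate(regions)]
        env = ca.build_envelope(profs, k=2.0)
        flags = ca.detect_envelope_outliers(profs, env)
        assert {i for i, v in flags.items() if v} == outliers


class TestMicroAnalysis:
    def _line(self, coat, hilum_on=(3,), hilum_rgb=(40, 40, 40)):
        spec = small_spec(rng_seed=17)
        seeds = []
        for i in range(10):
            kw = {}
            if i in hilum_on:
                kw = dict(hilum_rgb=hilum_rgb, hilum_fraction=0.08)
            seeds.append(boards.SeedSpec(8.4, 6.0, 6.8, coat, row=i // 5, col=i % 5, **kw))
        top, _, _ = boards.generate_board(spec, seeds)
        cleaned, regions, _ = segment_top(top, spec)
        profs = [ca.seed_histograms(cleaned.pixels, r, seed_id=i)
                 for i, r in enumerate(regions)]
        env = ca.build_envelope(profs, k=2.0)
        return ca.log_micro_analysis(profs, env, min_brightness=80)

    def test_bright_coat_hilum_seed_flagged(self):
        flags = self._line(coat=(190, 160, 120))
        assert flags[3] is True
        assert sum(flags.values()) == 1

    def test_dark_coat_excluded_by_brightness_gate(self):
        flags = self._line(coat=(50, 40, 35))
        assert not any(flags.values())

    def test_hilum_matching_coat_not_flagged(self):
        flags = self._line(coat=(190, 160, 120), hilum_rgb=(190, 160, 120))
        assert not any(flags.values())


class TestRepresentativeColor:
    def test_uniform_seed_returns_its_color(self):
        img, region = flat_region((120, 80, 40))
        assert ca.representative_color(img, region) == (120, 80, 40)

    def test_mode_dominates_at_nine_to_one(self):
        img, region = two_tone_region((200, 150, 100), (30, 30, 30), 0.1)
        assert ca.representative_color(img, region) == (200, 150, 100)


class TestColorCodes:
    def test_exact_named_color(self):
        img, region = flat_region((255, 255, 0))
        assert ca.assign_color_codes(img, region) == [("yellow", "#FFFF00")]

    def test_nearest_color_by_brute_force(self):
        # independent oracle: plain loop over the full keyword table
        target = (250, 250, 5)
        best = min(CSS_COLORS.items(),
                   key=lambda kv: sum((a - b) ** 2
                                      for a, b in zip(hex_to_rgb(kv[1]), target)))
        assert nearest_css_color(target)[1] == best[1]
        img, region = flat_region(target)
        assert ca.assign_color_codes(img, region)[0][1] == best[1]

    def test_half_and_half_seed_gets_two_codes(self):
        img, region = two_tone_region((200, 180, 120), (40, 30, 20), 0.5)
        codes = ca.assign_color_codes(img, region)
        assert len(codes) == 2
        assert codes[0] == nearest_css_color((200, 180, 120))
        assert codes[1] == nearest_css_color((40, 30, 20))

    def test_minor_secondary_mass_stays_single_code(self):
        img, region = two_tone_region((200, 180, 120), (40, 30, 20), 0.1)
        codes = ca.assign_color_codes(img, region, bicolor_peak_ratio=0.25)
        assert len(codes) == 1

    def test_css_table_has_the_standard_keyword_count(self):
        assert len(CSS_COLORS) == 147
        assert len(set(CSS_COLORS.values())) == 138
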