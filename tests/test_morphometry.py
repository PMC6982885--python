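"""Shape descriptors against analytic oracles; thickness and matching."""

import math
from dataclasses import replace

import numpy as np
import pytest

from seedmorph import boards
from seedmorph import morphometry as mo
from seedmorph import preprocess as pp
from seedmorph import segment as seg
from conftest import (CALIB_01, disk_mask, measure_board, region_from_mask,
                      small_spec, uniform_seeds)


def ramanujan_perimeter(a_mm, b_mm):
    h = ((a_mm - b_mm) / (a_mm + b_mm)) ** 2
    return math.pi * (a_mm + b_mm) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))


class TestMeasureRegion:
    def test_digital_disk_matches_circle_oracles(self):
        region = region_from_mask(disk_mask(50))
        rec = mo.measure_region(region, CALIB_01)
        assert rec.area_mm2 == pytest.approx(math.pi * 25, rel=0.02)  # 78.54 mm2
        assert 0.95 <= rec.circularity <= 1.0
        assert 0.98 <= rec.roundness <= 1.0
        assert rec.solidity >= 0.99

    def test_ellipse_roundness_and_aspect(self):
        seed = boards.SeedSpec(10.0, 6.0, 5.0, (0, 0, 0), row=0, col=0)
        region = region_from_mask(boards.render_seed_mask(seed, 0.1))
        rec = mo.measure_region(region, CALIB_01)
        assert rec.roundness == pytest.approx(0.6, rel=0.02)
        assert rec.aspect_ratio == pytest.approx(10 / 6, rel=0.02)
        assert rec.height_mm == pytest.approx(10.0, rel=0.02)
        assert rec.width_mm == pytest.approx(6.0, rel=0.02)

    def test_ellipse_circularity_matches_ramanujan(self):
        seed = boards.SeedSpec(10.0, 6.0, 5.0, (0, 0, 0), row=0, col=0)
        region = region_from_mask(boards.render_seed_mask(seed, 0.1))
        rec = mo.measure_region(region, CALIB_01)
        P = ramanujan_perimeter(5.0, 3.0)  # semi-axes in mm
        expected = 4 * math.pi * (math.pi * 5 * 3) / P**2  # ~0.909
        assert rec.circularity == pytest.approx(expected, rel=0.02)
        assert rec.perimeter_mm == pytest.approx(P, rel=0.02)

    def test_thin_region_rejected(self):
        mask = np.zeros((5, 60), dtype=bool)
        mask[2, 5:55] = True
        region = region_from_mask(mask)
        with pytest.raises(mo.MeasurementError):
            mo.measure_region(region, CALIB_01)

    def test_circularity_invariant_holds(self):
        seed = boards.SeedSpec(9.0, 6.0, 5.0, (0, 0, 0), row=0, col=0, squareness=2.2)
        rec = mo.measure_region(region_from_mask(boards.render_seed_mask(seed, 0.1)),
                                CALIB_01)
        assert rec.circularity == pytest.approx(
            min(1.0, 4 * math.pi * rec.area_mm2 / rec.perimeter_mm**2), abs=1e-9
        )


class TestScaleEquivariance:
    def test_doubling_scale_scales_lengths_and_areas(self):
        region = region_from_mask(disk_mask(40))
        c1 = pp.ScaleCalibration(mm_per_pixel=0.1, tag_pixel_length=160)
        c2 = pp.ScaleCalibration(mm_per_pixel=0.2, tag_pixel_length=80)
        r1 = mo.measure_region(region, c1)
        r2 = mo.measure_region(region, c2)
        assert r2.area_mm2 == pytest.approx(4 * r1.area_mm2, rel=1e-12)
        for trait in ("perimeter_mm", "width_mm", "height_mm"):
            assert getattr(r2, trait) == pytest.approx(2 * getattr(r1, trait), rel=1e-12)
        for trait in ("circularity", "aspect_ratio", "roundness", "solidity"):
            assert getattr(r2, trait) == getattr(r1, trait)


class TestRotationTolerance:
    def test_descriptors_stable_under_30_degree_rotation(self):
        base = dict(major_mm=9.0, minor_mm=5.5, thickness_mm=6.0,
                    base_rgb=(0, 0, 0), row=0, col=0, squareness=2.1)
        r0 = mo.measure_region(
            region_from_mask(boards.render_seed_mask(boards.SeedSpec(**base), 0.1)),
            CALIB_01)
        r30 = mo.measure_region(
            region_from_mask(
                boards.render_seed_mask(boards.SeedSpec(**base, angle_deg=30.0), 0.1)),
            CALIB_01)
        for trait in ("circularity", "aspect_ratio", "roundness", "solidity",
                      "width_mm", "height_mm", "area_mm2"):
            a, b = getattr(r0, trait), getattr(r30, trait)
            assert abs(a - b) / a < 0.02, trait


class TestBitesAndSolidity:
    @pytest.mark.parametrize("trial", range(4))
    def test_bite_lowers_solidity_never_raises_area(self, trial):
        base = boards.SeedSpec(9.0, 6.5, 6.0, (0, 0, 0), row=0, col=0, squareness=2.0)
        bitten = replace(base, bite_defects=1, bite_radius_mm=1.0)
        m0 = boards.render_seed_mask(base, 0.1)
        m1 = boards.render_seed_mask(bitten, 0.1, rng=np.random.default_rng(trial))
        r0 = mo.measure_region(region_from_mask(m0), CALIB_01)
        r1 = mo.measure_region(region_from_mask(m1), CALIB_01)
        assert r1.solidity < r0.solidity
        assert m1.sum() <= m0.sum()


class TestThickness:
    def test_profile_height_is_thickness(self):
        mask = np.zeros((80, 40), dtype=bool)
        mask[5:73, 5:35] = True  # 68 px tall
        region = seg.label_and_filter(mask, seg.SegmentationParams(min_area_px=1),
                                      view="side")[0]
        assert mo.measure_thickness(region, CALIB_01) == pytest.approx(6.8)

    def test_single_pixel_row_is_defined(self):
        mask = np.zeros((5, 300), dtype=bool)
        mask[2, 10:260] = True
        region = seg.label_and_filter(mask, seg.SegmentationParams(min_area_px=1),
                                      view="side")[0]
        assert mo.measure_thickness(region, CALIB_01) == pytest.approx(0.1)

    def test_empty_region_rejected(self):
        region = seg.SeedRegion(label=1, mask=np.zeros((3, 3), bool),
                                bbox=(0, 0, 3, 3), centroid=(1, 1), area_px=0,
                                outline=np.zeros((0, 2)), view="side")
        with pytest.raises(mo.MeasurementError):
            mo.measure_thickness(region, CALIB_01)


class TestMatching:
    def test_matched_thickness_recovers_ground_truth(self):
        spec = small_spec(rng_seed=21)
        rng = np.random.default_rng(5)
        seeds = boards.sample_seed_specs(spec, 10, rng, major_range=(7, 9),
                                         minor_range=(5, 6.5))
        top, sides, truth = boards.generate_board(spec, seeds)
        _, regions, calib, records = measure_board(top, sides, spec)
        by_cell = {(t.row, t.col): t for t in truth}
        for rec in records:
            t = by_cell[(rec.row, rec.col)]
            assert rec.thickness_mm == pytest.approx(t.thickness_mm, rel=0.02)

    def test_count_mismatch_names_the_row(self):
        rec = mo.MorphometricRecord(
            seed_id=0, line_id="L", row=1, col=0, area_mm2=1, perimeter_mm=1,
            width_mm=1, height_mm=1, circularity=1, aspect_ratio=1, roundness=1,
            solidity=1, centroid_mm=(0.0, 0.0))
        with pytest.raises(mo.MatchingError, match="row 1"):
            mo.match_top_side([rec], {1: []}, CALIB_01)

    def test_empty_rows_match_vacuously(self):
        assert mo.match_top_side([], {}, CALIB_01) == []


class TestSummaries:
    def _record(self, line, area):
        return mo.MorphometricRecord(
            seed_id=0, line_id=line, row=0, col=0, area_mm2=area, perimeter_mm=20.0,
            width_mm=6.0, height_mm=8.0, circularity=0.9, aspect_ratio=1.3,
            roundness=0.7, solidity=0.98, centroid_mm=(0.0, 0.0), thickness_mm=6.8)

    def test_identical_seeds_have_zero_spread(self):
        records = [self._record("A", 40.0) for _ in range(5)]
        summaries, stats = mo.summarize_lines(records)
        assert summaries[0].means["area_mm2"] == pytest.approx(40.0)
        assert stats.loc["Stdev.", "area_mm2"] == pytest.approx(0.0)

    def test_two_line_global_stats(self):
        records = [self._record("A", 30.0), self._record("B", 50.0)]
        _, stats = mo.summarize_lines(records)
        assert stats.loc["Average", "area_mm2"] == pytest.approx(40.0)
        assert stats.loc["Minimum", "area_mm2"] == pytest.approx(30.0)
        assert stats.loc["Maximum", "area_mm2"] == pytest.approx(50.0)

    def test_population_template_recovered(self):
        # per-line mean areas drawn around a 40.3 mm2 / sd 10.7 template
        rng = np.random.default_rng(0)
        draws = rng.normal(40.3, 10.7, size=400)
        records = [self._record(f"L{i}", a) for i, a in enumerate(draws)]
        _, stats = mo.summarize_lines(records)
        assert stats.loc["Average", "area_mm2"] == pytest.approx(40.3, abs=1.5)
        assert stats.loc["Stdev.", "area_mm2"] == pytest.approx(10.7, abs=1.5)

    def test_empty_input_rejected(self):
        with pytest.raises(mo.MeasurementError):
            mo.summarize_lines([])
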