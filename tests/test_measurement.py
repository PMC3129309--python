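"""Per-specimen measurement records and the full pipeline."""

import math

import numpy as np
import pytest

from wholemount import (
    AnalysisConfig,
    AOIPolygon,
    ODCalibration,
    PhantomSpec,
    PipelineError,
    SpatialCalibration,
    analyze_whole_mount,
    compute_density_pct,
    measure_regions,
    render_phantom,
)


class TestComputeDensityPct:
    def test_half(self):
        assert compute_density_pct(1, 2) == 50.0

    def test_ratio_of_printed_group_means(self):
        # ratio-of-means of the control group's epithelial and total areas;
        # differs from the mean-of-ratios density the same study reports
        assert round(compute_density_pct(8.15, 15.34), 1) == 53.1

    def test_zero_part_and_zero_total(self):
        assert compute_density_pct(0, 5) == 0.0
        assert compute_density_pct(0, 0) == 0.0

    def test_part_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            compute_density_pct(3, 2)


class TestMeasureRegions:
    scal = SpatialCalibration(0.001)
    ocal = ODCalibration()

    def test_empty_masks_zero_record_flagged(self):
        img = np.full((10, 10), 128, np.uint8)
        empty = np.zeros((10, 10), bool)
        m = measure_regions(img, empty, empty, self.scal, self.ocal)
        assert m.total_area_cm2 == 0 and m.total_sum_od == 0
        assert m.density_area_pct == 0 and m.density_volume_pct == 0
        assert m.density_undefined

    def test_symmetric_split_gives_fifty_percent(self):
        img = np.full((10, 10), 128, np.uint8)
        dense = np.zeros((10, 10), bool)
        dense[:, :5] = True
        m = measure_regions(img, dense, ~dense, self.scal, self.ocal)
        assert m.density_area_pct == pytest.approx(50.0)
        assert m.density_volume_pct == pytest.approx(50.0)
        assert not m.density_undefined

    def test_matches_per_pixel_oracle_on_phantom_truth(self):
        spec = PhantomSpec(stage=0.5, height=128, width=160, seed=4, n_lymph_nodes=0)
        rgb, truth = render_phantom(spec)
        gray = np.asarray(rgb[..., 2])  # blue channel carries the luminance
        m = measure_regions(
            gray, truth.epithelium_mask, truth.fat_mask, self.scal, self.ocal
        )
        epi_area = fat_area = epi_od = fat_od = 0.0
        for r in range(spec.height):
            for c in range(spec.width):
                od = min(2.4, math.log10(255 / max(int(gray[r, c]), 1)))
                if truth.epithelium_mask[r, c]:
                    epi_area += 1
                    epi_od += od
                elif truth.fat_mask[r, c]:
                    fat_area += 1
                    fat_od += od
        assert m.epithelial_area_cm2 == pytest.approx(epi_area * 1e-6, rel=1e-12)
        assert m.fat_area_cm2 == pytest.approx(fat_area * 1e-6, rel=1e-12)
        assert m.epithelial_sum_od == pytest.approx(epi_od, rel=1e-9)
        assert m.fat_sum_od == pytest.approx(fat_od, rel=1e-9)

    def test_overlapping_masks_rejected(self):
        img = np.zeros((5, 5), np.uint8)
        full = np.ones((5, 5), bool)
        with pytest.raises(ValueError):
            measure_regions(img, full, full, self.scal, self.ocal)


class TestAnalyzeWholeMount:
    def test_blank_white_image_zero_record(self):
        img = np.full((80, 80, 3), 255, np.uint8)
        aoi = AOIPolygon([(10, 10), (10, 70), (70, 70), (70, 10)])
        m = analyze_whole_mount(img, aoi)
        assert m.epithelial_area_cm2 == 0.0
        assert m.epithelial_sum_od == 0.0
        assert m.density_area_pct == 0.0

    def test_additivity_invariants_exact(self):
        rgb, truth = render_phantom(PhantomSpec(stage=0.7, seed=6))
        m = analyze_whole_mount(rgb, truth.aoi, truth.lymph_seeds)
        assert m.epithelial_area_cm2 + m.fat_area_cm2 == m.total_area_cm2
        assert m.epithelial_sum_od + m.fat_sum_od == pytest.approx(
            m.total_sum_od, rel=1e-12
        )

    def test_recovers_phantom_ground_truth_area(self):
        cfg = AnalysisConfig()
        rgb, truth = render_phantom(PhantomSpec(stage=1.0, seed=1))
        m = analyze_whole_mount(rgb, truth.aoi, truth.lymph_seeds, cfg)
        true_area = truth.true_epithelial_area_px * cfg.cm_per_pixel**2
        assert m.epithelial_area_cm2 == pytest.approx(true_area, rel=0.10)

    def test_translation_invariance(self):
        spec = PhantomSpec(stage=0.6, seed=8)
        rgb, truth = render_phantom(spec)
        shift = (7, 11)
        rolled = np.roll(rgb, shift, axis=(0, 1))
        aoi2 = AOIPolygon([(r + shift[0], c + shift[1]) for r, c in truth.aoi.vertices])
        seeds2 = [(r + shift[0], c + shift[1]) for r, c in truth.lymph_seeds]
        m1 = analyze_whole_mount(rgb, truth.aoi, truth.lymph_seeds)
        m2 = analyze_whole_mount(rolled, aoi2, seeds2)
        for name in ("epithelial_area_cm2", "fat_area_cm2", "density_area_pct"):
            assert getattr(m1, name) == pytest.approx(getattr(m2, name), rel=1e-9)
        assert m1.epithelial_sum_od == pytest.approx(m2.epithelial_sum_od, rel=1e-9)

    def test_calibration_scaling_law(self):
        rgb, truth = render_phantom(PhantomSpec(stage=0.5, seed=9))
        base = AnalysisConfig(cm_per_pixel=0.005)
        scaled = AnalysisConfig(cm_per_pixel=0.015)  # k = 3
        m1 = analyze_whole_mount(rgb, truth.aoi, truth.lymph_seeds, base)
        m2 = analyze_whole_mount(rgb, truth.aoi, truth.lymph_seeds, scaled)
        assert m2.epithelial_area_cm2 == pytest.approx(9 * m1.epithelial_area_cm2, rel=1e-12)
        assert m2.total_area_cm2 == pytest.approx(9 * m1.total_area_cm2, rel=1e-12)
        assert m2.density_area_pct == pytest.approx(m1.density_area_pct, rel=1e-12)
        assert m2.density_volume_pct == pytest.approx(m1.density_volume_pct, rel=1e-12)

    def test_stage_errors_are_labelled(self):
        img = np.full((40, 40, 3), 255, np.uint8)
        bad_aoi = AOIPolygon([(1, 1), (1, 1), (1, 1)])
        with pytest.raises(PipelineError, match="rasterize_aoi"):
            analyze_whole_mount(img, bad_aoi)
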