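"""Shared fixtures: the default developmental phantom panel, analyzed once.

The panel (7 stages × 9 phantoms, base seed 1) is the study-condition
workload for the pipeline-level checks: area/volume regression, ground-truth
recovery, segmentation overlap and growth monotonicity all read from the
same session-scoped table so the pipeline runs only once per session.
"""

from __future__ import annotations

import pandas as pd
import pytest

from wholemount import AnalysisConfig, analyze_whole_mount, growth_series
from wholemount.preprocess import (
    enhance_contrast,
    excise_regions,
    flatten_background,
    select_region_wand,
    to_grayscale,
)
from wholemount.segmentation import rasterize_aoi, threshold_dense

STAGES = tuple(i / 6 for i in range(7))
N_PER_STAGE = 9
BASE_SEED = 1


def segment_phantom(rgb, truth, cfg: AnalysisConfig):
    """Run the mask-building half of the pipeline, returning the dense mask."""
    gray = to_grayscale(rgb)
    lymph = [select_region_wand(gray, s, cfg.wand_tolerance) for s in truth.lymph_seeds]
    excised = excise_regions(gray, lymph)
    flat = flatten_background(excised, cfg.kernel_radius_for(excised.shape))
    enhanced = enhance_contrast(flat, cfg.saturate_fraction)
    aoi_mask = rasterize_aoi(truth.aoi, *gray.shape)
    dense, non_dense = threshold_dense(enhanced, aoi_mask, cfg.dense_threshold)
    return dense, non_dense


@pytest.fixture(scope="session")
def default_config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def growth_panel(default_config) -> pd.DataFrame:
    """Per-phantom results over the default developmental series."""
    cfg = default_config
    rows = []
    for spec, rgb, truth in growth_series(N_PER_STAGE, STAGES, base_seed=BASE_SEED):
        m = analyze_whole_mount(rgb, truth.aoi, truth.lymph_seeds, cfg)
        dense, _ = segment_phantom(rgb, truth, cfg)
        gt = truth.epithelium_mask
        union = int((dense | gt).sum())
        rows.append(
            {
                "stage": spec.stage,
                "seed": spec.seed,
                "measured_area_cm2": m.epithelial_area_cm2,
                "measured_sum_od": m.epithelial_sum_od,
                "density_area_pct": m.density_area_pct,
                "true_area_cm2": truth.true_epithelial_area_px * cfg.cm_per_pixel**2,
                "jaccard": (int((dense & gt).sum()) / union) if union else 1.0,
            }
        )
    return pd.DataFrame(rows)
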