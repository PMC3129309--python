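"""Per-specimen density measurements.

One whole mount yields one :class:`DensityMeasurements` record — the rodent
analogue of a mammographic density report:

========================  =====================================================
epithelial_area_cm2       area of the dense (stained epithelium) mask
fat_area_cm2              area of the non-dense (interductal fat pad) mask
total_area_cm2            their sum = area of the AOI
epithelial_sum_od         ΣOD over the dense mask ("epithelial volume")
fat_sum_od                ΣOD over the non-dense mask
total_sum_od              their sum
density_area_pct          100 × epithelial area / total area
density_volume_pct        100 × epithelial ΣOD / total ΣOD
========================  =====================================================

Because the dense and non-dense masks partition the AOI, the two additivity
identities (areas and ΣODs) hold exactly, not merely to rounding.

``analyze_whole_mount`` chains the full pipeline.  ΣOD is measured on the
lymph-node-excised grayscale image *before* flattening (flattening rescales
gray levels and would corrupt the photometry); the masks come from the
flattened, contrast-enhanced image, where segmentation is robust to shading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import (
    ODCalibration,
    SpatialCalibration,
    area_of_mask,
    sum_od_over_mask,
)
from .config import AnalysisConfig
from .preprocess import (
    enhance_contrast,
    excise_regions,
    flatten_background,
    select_region_wand,
    to_grayscale,
)
from .segmentation import AOIPolygon, rasterize_aoi, threshold_dense

__all__ = [
    "DensityMeasurements",
    "compute_density_pct",
    "measure_regions",
    "analyze_whole_mount",
    "PipelineError",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


@dataclass(frozen=True)
class DensityMeasurements:
    epithelial_area_cm2: float
    fat_area_cm2: float
    total_area_cm2: float
    epithelial_sum_od: float
    fat_sum_od: float
    total_sum_od: float
    density_area_pct: float
    density_volume_pct: float
    #: True when a density denominator was zero (empty AOI) and the
    #: percentage was reported as 0 by convention rather than computed.
    density_undefined: bool = False

    FIELDS = (
        "epithelial_area_cm2",
        "fat_area_cm2",
        "total_area_cm2",
        "epithelial_sum_od",
        "fat_sum_od",
        "total_sum_od",
        "density_area_pct",
        "density_volume_pct",
    )

    def as_dict(self) -> dict:
        d = {name: getattr(self, name) for name in self.FIELDS}
        d["density_undefined"] = self.density_undefined
        return d


def compute_density_pct(part: float, total: float) -> float:
    """Percentage ``100 * part / total``; 0 by convention when total is 0.

    ``part`` must not exceed ``total`` (a density above 100% is always an
    upstream bookkeeping error, never a measurement).
    """
    if part > total:
        raise ValueError(f"part {part} exceeds total {total}")
    if total == 0:
        return 0.0
    return 100.0 * part / total


def measure_regions(
    measurement_img: np.ndarray,
    dense: np.ndarray,
    non_dense: np.ndarray,
    scal: SpatialCalibration,
    ocal: ODCalibration,
) -> DensityMeasurements:
    """Measure areas, ΣODs and density percentages from the two masks."""
    dense = np.asarray(dense, dtype=bool)
    non_dense = np.asarray(non_dense, dtype=bool)
    if dense.shape != non_dense.shape:
        raise ValueError("dense and non-dense masks on different grids")
    if (dense & non_dense).any():
        raise ValueError("dense and non-dense masks overlap; expected a partition")

    epi_area = area_of_mask(dense, scal)
    fat_area = area_of_mask(non_dense, scal)
    epi_od = sum_od_over_mask(measurement_img, dense, ocal)
    fat_od = sum_od_over_mask(measurement_img, non_dense, ocal)
    total_area = epi_area + fat_area
    total_od = epi_od + fat_od
    return DensityMeasurements(
        epithelial_area_cm2=epi_area,
        fat_area_cm2=fat_area,
        total_area_cm2=total_area,
        epithelial_sum_od=epi_od,
        fat_sum_od=fat_od,
        total_sum_od=total_od,
        density_area_pct=compute_density_pct(epi_area, total_area),
        density_volume_pct=compute_density_pct(epi_od, total_od),
        density_undefined=(total_area == 0 or total_od == 0),
    )


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError(f"stage '{name}': {exc}") from exc


def analyze_whole_mount(
    image: np.ndarray,
    aoi: AOIPolygon,
    lymph_inputs=None,
    config: AnalysisConfig | None = None,
) -> DensityMeasurements:
    """Run the full measurement pipeline on one whole-mount image.

    Parameters
    ----------
    image
        8-bit RGB (HxWx3) or grayscale (HxW) whole-mount image.
    aoi
        Operator-traced polygon circumscribing the gland.
    lymph_inputs
        Optional iterable of lymph-node specifications, each either a
        ``(row, col)`` wand seed or a boolean mask on the image grid.
    config
        :class:`AnalysisConfig`; defaults apply when omitted.
    """
    cfg = config or AnalysisConfig()
    gray = _stage("to_grayscale", to_grayscale, image)

    lymph_masks = []
    for item in lymph_inputs or []:
        arr = np.asarray(item)
        if arr.ndim == 2:
            lymph_masks.append(arr.astype(bool))
        else:
            lymph_masks.append(
                _stage(
                    "select_lymph_node",
                    select_region_wand,
                    gray,
                    (int(arr[0]), int(arr[1])),
                    cfg.wand_tolerance,
                )
            )
    excised = _stage("excise_lymph_nodes", excise_regions, gray, lymph_masks)

    flat = _stage(
        "flatten_background",
        flatten_background,
        excised,
        cfg.kernel_radius_for(excised.shape),
    )
    enhanced = _stage("enhance_contrast", enhance_contrast, flat, cfg.saturate_fraction)
    aoi_mask = _stage("rasterize_aoi", rasterize_aoi, aoi, *gray.shape)
    dense, non_dense = _stage(
        "threshold_dense", threshold_dense, enhanced, aoi_mask, cfg.dense_threshold
    )
    # photometry from the un-flattened, lymph-excised grayscale image
    return _stage(
        "measure_regions",
        measure_regions,
        excised,
        dense,
        non_dense,
        cfg.spatial_calibration(),
        cfg.od_calibration(),
    )
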