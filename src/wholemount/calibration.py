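"""Spatial and densitometric calibration.

Two independent calibrations underpin every measurement the package makes:

* **Spatial** — a stage micrometer imaged under the same optics gives the
  physical edge length of one pixel (cm/px); areas are pixel counts scaled
  by the square of that pitch.
* **Densitometric** — transmitted gray level (0–255) is mapped onto optical
  density, the log-scale absorbance proxy used in densitometry.  The summed
  optical density over a region (ΣOD) serves as the "volume" measure of
  stained tissue: darker (more carmine-bound epithelium in the light path)
  means higher OD.

The OD curve spans 0 (fully transmitted, gray 255) to ``od_max`` (default
2.4 ≈ log10(255), the dynamic range of an 8-bit sensor).  Two functional
forms are supported: the default clamped logarithmic transmittance model

    od(g) = min(od_max, log10(255 / max(g, 1)))

and a linear ramp ``od(g) = od_max * (255 - g) / 255`` for instruments that
used a straight-line lookup table.  Both are monotone non-increasing and
share the endpoints od(255) = 0 and od(0) = od_max.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CalibrationError",
    "SpatialCalibration",
    "ODCalibration",
    "spatial_calibration_from_points",
    "gray_to_od",
    "area_of_mask",
    "sum_od_over_mask",
]

GRAY_MAX = 255


class CalibrationError(ValueError):
    """Invalid calibration input (coincident points, bad distance, ...)."""


@dataclass(frozen=True)
class SpatialCalibration:
    """Physical pixel pitch.

    Parameters
    ----------
    cm_per_pixel
        Edge length of one (square) pixel in centimetres. Must be positive.
        Anisotropic pixels are not supported.
    """

    cm_per_pixel: float

    def __post_init__(self) -> None:
        if not (self.cm_per_pixel > 0):
            raise CalibrationError(
                f"cm_per_pixel must be positive, got {self.cm_per_pixel!r}"
            )

    @property
    def cm2_per_pixel(self) -> float:
        """Area of one pixel in cm²."""
        return self.cm_per_pixel**2


@dataclass(frozen=True)
class ODCalibration:
    """Gray-level → optical-density curve.

    Parameters
    ----------
    model
        ``"log"`` (clamped transmittance logarithm, default) or ``"linear"``.
    od_max
        Optical density assigned to gray level 0; upper clamp of the curve.
    """

    model: str = "log"
    od_max: float = 2.4

    def __post_init__(self) -> None:
        if self.model not in ("log", "linear"):
            raise CalibrationError(f"unknown OD model {self.model!r}")
        if not (self.od_max > 0):
            raise CalibrationError(f"od_max must be positive, got {self.od_max!r}")

    def lookup_table(self) -> np.ndarray:
        """OD value for every gray level 0..255, shape (256,)."""
        g = np.arange(GRAY_MAX + 1, dtype=np.float64)
        if self.model == "log":
            od = np.log10(GRAY_MAX / np.maximum(g, 1.0))
        else:
            od = self.od_max * (GRAY_MAX - g) / GRAY_MAX
        return np.clip(od, 0.0, self.od_max)


def spatial_calibration_from_points(
    p1: tuple[float, float],
    p2: tuple[float, float],
    known_distance_cm: float,
) -> SpatialCalibration:
    """Calibrate the pixel pitch from two points a known distance apart.

    ``p1`` and ``p2`` are (row, col) pixel coordinates of two stage-micrometer
    marks separated by ``known_distance_cm``.
    """
    if not (known_distance_cm > 0):
        raise CalibrationError(
            f"known distance must be positive, got {known_distance_cm!r}"
        )
    d = math.hypot(p2[0] - p1[0], p2[1] - p1[1])
    if d == 0:
        raise CalibrationError("calibration points are coincident")
    return SpatialCalibration(cm_per_pixel=known_distance_cm / d)


def gray_to_od(g, cal: ODCalibration = ODCalibration()):
    """Optical density of gray level(s) ``g`` under calibration ``cal``.

    Accepts a scalar or an integer array; values must lie in [0, 255].
    Returns a float (scalar input) or float64 array.
    """
    arr = np.asarray(g)
    if arr.size and (arr.min() < 0 or arr.max() > GRAY_MAX):
        raise ValueError("gray level outside [0, 255]")
    od = cal.lookup_table()[arr.astype(np.intp)]
    return float(od) if np.isscalar(g) or arr.ndim == 0 else od


def area_of_mask(mask: np.ndarray, cal: SpatialCalibration) -> float:
    """Physical area (cm²) of a binary mask: set-pixel count × pitch²."""
    mask = np.asarray(mask, dtype=bool)
    return int(mask.sum()) * cal.cm2_per_pixel


def sum_od_over_mask(
    img: np.ndarray, mask: np.ndarray, cal: ODCalibration = ODCalibration()
) -> float:
    """ΣOD: summed per-pixel optical density of ``img`` over ``mask``.

    The image and mask must share a grid; an empty mask yields 0.
    """
    img = np.asarray(img)
    mask = np.asarray(mask, dtype=bool)
    if img.shape != mask.shape:
        raise ValueError(f"image grid {img.shape} != mask grid {mask.shape}")
    if not mask.any():
        return 0.0
    return float(gray_to_od(img[mask], cal).sum())
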