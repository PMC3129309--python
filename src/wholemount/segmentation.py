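"""AOI rasterization and dense/non-dense mask construction.

The operator traces a polygon (the area of interest, AOI) circumscribing the
gland around its most distal end buds; everything outside it — folds,
residual muscle, nipple, bare fat pad beyond the gland — is excluded from
measurement.  Inside the AOI, a gray-level threshold on the flattened and
contrast-enhanced image splits pixels into the *dense* mask (carmine-stained
epithelium, dark) and the *non-dense* mask (interductal fat pad, driven to
white by the enhancement).  The two masks partition the AOI exactly, which
makes the area and ΣOD additivity identities hold to the last pixel.

A note on polarity: stained epithelium is dark under trans-illumination, so
the dense mask is the *at-or-below*-threshold set.  The threshold defaults
to 254 at the operation level — i.e. "anything not saturated white" — which
presumes the enhancement has saturated the fat pad; the pipeline config uses
a more conservative default (see :mod:`wholemount.config`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AOIPolygon", "GeometryError", "rasterize_aoi", "threshold_dense"]


class GeometryError(ValueError):
    """Degenerate or invalid polygon."""


@dataclass(frozen=True)
class AOIPolygon:
    """Closed polygon in (row, col) pixel coordinates.

    ``vertices`` is an (n, 2) array-like, n ≥ 3, implicitly closed; either
    winding order is accepted.
    """

    vertices: tuple

    def __init__(self, vertices) -> None:
        arr = np.asarray(vertices, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
            raise GeometryError(f"need >= 3 (row, col) vertices, got shape {arr.shape}")
        object.__setattr__(self, "vertices", tuple(map(tuple, arr)))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.vertices, dtype=np.float64)

    def signed_area(self) -> float:
        """Shoelace area in px²; sign reflects winding order."""
        v = self.as_array()
        y, x = v[:, 0], v[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def rasterize_aoi(poly: AOIPolygon, height: int, width: int) -> np.ndarray:
    """Rasterize the AOI with the pixel-center even-odd rule.

    A pixel (r, c) belongs to the mask when its center lies inside the
    polygon under the even-odd (crossing-number) rule, with half-open
    boundary handling: centers on a lower boundary are included, centers on
    the opposite boundary are not, so abutting polygons tile without overlap.
    """
    if height <= 0 or width <= 0:
        raise GeometryError(f"invalid raster dimensions {height}x{width}")
    if abs(poly.signed_area()) == 0.0:
        raise GeometryError("polygon encloses zero area")
    v = poly.as_array()
    y1, x1 = v[:, 0], v[:, 1]
    y2, x2 = np.roll(y1, -1), np.roll(x1, -1)

    rows = np.arange(height, dtype=np.float64)
    cols = np.arange(width, dtype=np.float64)
    mask = np.zeros((height, width), dtype=bool)
    # crossing-number scan, one image row at a time
    for i, py in enumerate(rows):
        straddles = (y1 > py) != (y2 > py)
        if not straddles.any():
            continue
        t = (py - y1[straddles]) / (y2[straddles] - y1[straddles])
        xs = x1[straddles] + t * (x2[straddles] - x1[straddles])
        crossings = (cols[None, :] < xs[:, None]).sum(axis=0)
        mask[i] = crossings % 2 == 1
    return mask


def threshold_dense(
    enhanced: np.ndarray, aoi: np.ndarray, upper: int = 254
) -> tuple[np.ndarray, np.ndarray]:
    """Split the AOI into dense and non-dense masks at a gray threshold.

    ``dense`` collects AOI pixels with ``enhanced <= upper`` (stained,
    dark); ``non_dense`` is the remainder of the AOI.  ``upper`` must lie in
    [0, 254]: a threshold of 255 would classify every pixel as dense and is
    rejected.

    Returns ``(dense, non_dense)``, an exact partition of ``aoi``.
    """
    enhanced = np.asarray(enhanced)
    aoi = np.asarray(aoi, dtype=bool)
    if enhanced.shape != aoi.shape:
        raise ValueError(f"image grid {enhanced.shape} != AOI grid {aoi.shape}")
    if not (0 <= int(upper) <= 254):
        raise ValueError(f"threshold must be in [0, 254], got {upper}")
    dense = aoi & (enhanced <= upper)
    non_dense = aoi & ~dense
    return dense, non_dense
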