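"""Image preparation ahead of segmentation.

The measurement pipeline works on 8-bit grayscale images of trans-illuminated
whole mounts.  Preparation steps, in pipeline order:

1. ``to_grayscale`` — ITU-R 601 luminance conversion of the color capture.
2. ``select_region_wand`` / ``excise_regions`` — lymph nodes are darkly
   stained but are not epithelium; they are selected (tolerance flood fill
   from an operator seed, the "wand") and blanked to white so they contribute
   neither dense area nor ΣOD.
3. ``flatten_background`` — trans-illumination is never perfectly even; a
   smooth background estimate (grayscale closing with a disc large enough to
   swallow the ducts, then a mean filter) is divided out so the fat-pad
   background becomes uniform before thresholding.
4. ``enhance_contrast`` — quantile-anchored linear stretch that pushes the
   cleared fat pad toward white and the stained epithelium toward black.

Masks are built from the flattened+enhanced image; ΣOD is always measured on
the un-flattened (but lymph-node-excised) grayscale image, since flattening
and stretching destroy the photometric meaning of the gray levels.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import morphology, segmentation

__all__ = [
    "to_grayscale",
    "select_region_wand",
    "excise_regions",
    "flatten_background",
    "enhance_contrast",
]

WHITE = 255


def _check_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D gray image, got shape {img.shape}")
    return img


def to_grayscale(rgb: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to 8-bit luminance grayscale.

    Uses ITU-R 601 weights 0.299 R + 0.587 G + 0.114 B, rounded half up.
    A 2-D input is assumed to already be grayscale and is returned as uint8.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim == 2:
        return rgb.astype(np.uint8)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError(f"expected an HxWx3 8-bit image, got shape {rgb.shape}")
    lum = (
        0.299 * rgb[..., 0].astype(np.float64)
        + 0.587 * rgb[..., 1]
        + 0.114 * rgb[..., 2]
    )
    return np.clip(np.floor(lum + 0.5), 0, WHITE).astype(np.uint8)


def select_region_wand(
    img: np.ndarray, seed: tuple[int, int], tolerance: int = 32
) -> np.ndarray:
    """Tolerance flood fill ("wand") from a seed pixel.

    Returns the boolean mask of the 4-connected component of pixels whose
    gray level differs from the seed pixel's by at most ``tolerance``.
    """
    img = _check_gray(img)
    r, c = int(seed[0]), int(seed[1])
    if not (0 <= r < img.shape[0] and 0 <= c < img.shape[1]):
        raise ValueError(f"seed {seed} outside image of shape {img.shape}")
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    return segmentation.flood(
        img.astype(np.int16), (r, c), tolerance=tolerance, connectivity=1
    )


def excise_regions(img: np.ndarray, masks) -> np.ndarray:
    """Blank the masked regions to white (255), leaving the rest untouched.

    This removes lymph nodes (or other non-epithelial dark structures) so
    they are invisible to both the dense threshold and the ΣOD sum.
    """
    img = _check_gray(img)
    out = img.copy()
    for mask in masks:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != img.shape:
            raise ValueError(f"mask grid {mask.shape} != image grid {img.shape}")
        out[mask] = WHITE
    return out


def flatten_background(img: np.ndarray, kernel_radius_px: int) -> np.ndarray:
    """Divide out a smooth estimate of the bright background.

    The background is estimated by a grayscale closing with a disc of the
    given radius — which erases dark structures narrower than the disc —
    followed by a mean filter of the same radius.  The image is then
    renormalised as ``255 * img / background`` and clipped to [0, 255], so
    an evenly lit background maps to (near-)white everywhere regardless of
    the original shading.  The radius must exceed the widest duct, otherwise
    foreground is absorbed into the background estimate.
    """
    img = _check_gray(img)
    r = int(kernel_radius_px)
    if r < 1 or r >= min(img.shape):
        raise ValueError(
            f"kernel radius {kernel_radius_px} invalid for image {img.shape}"
        )
    # decomposed disc keeps the closing O(N) even for large radii
    footprint = morphology.disk(r, decomposition="sequence")
    closed = morphology.closing(img, footprint)
    background = ndimage.uniform_filter(closed.astype(np.float64), size=2 * r + 1)
    background = np.maximum(background, 1.0)
    flat = WHITE * img.astype(np.float64) / background
    return np.clip(np.floor(flat + 0.5), 0, WHITE).astype(np.uint8)


def enhance_contrast(img: np.ndarray, saturate_fraction: float = 0.01) -> np.ndarray:
    """Quantile-anchored linear contrast stretch.

    Gray levels at the ``saturate_fraction`` and ``1 - saturate_fraction``
    quantiles are mapped to 0 and 255; values outside are clamped.  A
    constant image maps to white (nothing is denser than anything else).
    """
    img = _check_gray(img)
    if not (0 <= saturate_fraction < 0.5):
        raise ValueError(f"saturate_fraction must be in [0, 0.5), got {saturate_fraction}")
    lo, hi = np.quantile(img, [saturate_fraction, 1.0 - saturate_fraction])
    if hi <= lo:
        return np.full_like(img, WHITE)
    stretched = (img.astype(np.float64) - lo) / (hi - lo) * WHITE
    return np.clip(np.floor(stretched + 0.5), 0, WHITE).astype(np.uint8)
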