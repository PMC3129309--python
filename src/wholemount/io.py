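"""File I/O: raster images, AOI sidecars, mask overlays.

Images travel as 8-bit TIFF or PNG.  Operator annotations (the traced AOI
polygon and lymph-node wand seeds) live in a JSON *sidecar* next to each
image::

    {"aoi": [[row, col], ...], "lymph_nodes": [[row, col], ...]}

Coordinates are 0-based (row, col) with the origin at the top-left pixel.
Any external tracing tool can produce the sidecar; this package never
invents an AOI for a real image.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .segmentation import AOIPolygon

__all__ = [
    "read_image",
    "write_image",
    "read_sidecar",
    "write_sidecar",
    "write_mask_png",
]


def read_image(path) -> np.ndarray:
    """Read an 8-bit grayscale or RGB image (TIFF via tifffile, else PIL)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        with Image.open(path) as im:
            if im.mode not in ("L", "RGB"):
                im = im.convert("RGB")
            arr = np.asarray(im)
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: expected 8-bit image, got dtype {arr.dtype}")
    if arr.ndim == 3 and arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.ndim not in (2, 3):
        raise ValueError(f"{path}: unsupported image shape {arr.shape}")
    return arr


def write_image(path, arr: np.ndarray) -> None:
    path = Path(path)
    arr = np.asarray(arr, dtype=np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


def read_sidecar(path) -> tuple[AOIPolygon, list]:
    """Read the AOI polygon and lymph-node seeds from a JSON sidecar."""
    with open(path) as fh:
        data = json.load(fh)
    if "aoi" not in data:
        raise ValueError(f"sidecar {path} lacks an 'aoi' entry")
    aoi = AOIPolygon(data["aoi"])
    lymph = [tuple(p) for p in data.get("lymph_nodes", [])]
    return aoi, lymph


def write_sidecar(path, aoi: AOIPolygon, lymph_nodes=()) -> None:
    data = {
        "aoi": [[float(r), float(c)] for r, c in aoi.vertices],
        "lymph_nodes": [[int(r), int(c)] for r, c in lymph_nodes],
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


def write_mask_png(path, mask: np.ndarray) -> None:
    """Write a boolean mask as a 1-bit PNG audit overlay."""
    Image.fromarray(np.asarray(mask, dtype=bool)).save(path, bits=1)
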