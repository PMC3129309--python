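"""Synthetic whole-mount phantoms with exact ground truth.

No public image archive of carmine-stained rodent whole mounts exists, so
the pipeline is validated against seedable phantoms that emulate the
structures a real capture shows:

* a dark, branching ductal tree with bulbous terminal end buds, growing
  from a nipple-side origin across a pale, faintly textured fat pad;
* one or more dark lymph nodes embedded in the fat pad;
* a smooth illumination gradient (trans-illumination is never even);
* Gaussian pixel noise.

The tree is a stochastic binary-branching random walk — a geometric stand-in
with realistic contrast and morphology, not a mechanistic model of ductal
elongation.  A single ``stage`` parameter in [0, 1] scales both growth
duration and branching probability, emulating the postnatal developmental
series from a small rudiment (stage 0, ~21 days of age) to a gland filling
the fat pad (stage 1, ~63 days).

Ground-truth masks are frozen *before* the gradient and noise are applied:
any disagreement between ground truth and a pipeline measurement is then
attributable to the pipeline (and to the degradations it is supposed to
withstand), not to ambiguity in the phantom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import shapely
from scipy import ndimage
from skimage import draw

from .segmentation import AOIPolygon, rasterize_aoi

__all__ = [
    "PhantomSpec",
    "DuctalTree",
    "PhantomGroundTruth",
    "grow_ductal_tree",
    "render_phantom",
    "growth_series",
]

FAT_GRAY = 242.0  # cleared fat pad under trans-illumination
EPI_GRAY = 58.0  # carmine-stained epithelium, trunk
EPI_GRAY_TIP = 88.0  # distal ducts stain slightly lighter
LYMPH_GRAY = 72.0
_MAX_TIPS = 40


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic whole mount.

    ``stage`` in [0, 1] drives development: growth steps and branching both
    scale with it. All lengths are in pixels; grays in 8-bit levels.
    Identical spec + seed reproduce the image and ground truth bit for bit.
    """

    stage: float = 1.0
    height: int = 384
    width: int = 512
    branch_prob: float = 0.09
    branch_angle_sd: float = 0.35
    segment_length_px: float = 6.0
    width_decay: float = 0.9
    trunk_width_px: float = 7.0
    end_bud_radius_px: float = 5.0
    n_lymph_nodes: int = 1
    illumination_gradient_amplitude: float = 20.0
    noise_sd: float = 3.0
    fat_texture_sd: float = 2.5
    include_tree: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.stage <= 1.0):
            raise ValueError(f"stage must lie in [0, 1], got {self.stage}")
        for name in ("segment_length_px", "trunk_width_px", "end_bud_radius_px"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")
        if not (0 < self.width_decay <= 1):
            raise ValueError("width_decay must be in (0, 1]")
        if self.noise_sd < 0 or self.branch_prob < 0 or self.n_lymph_nodes < 0:
            raise ValueError("noise_sd, branch_prob and n_lymph_nodes must be >= 0")
        if self.fat_texture_sd < 0:
            raise ValueError("fat_texture_sd must be >= 0")
        if self.height < 64 or self.width < 64:
            raise ValueError("frame must be at least 64x64 pixels")


@dataclass(frozen=True)
class DuctalTree:
    """Segments (p0, p1 in (row, col), width px, depth) and end-bud centers."""

    segments: tuple
    end_buds: tuple

    def total_length(self) -> float:
        return sum(
            math.hypot(p1[0] - p0[0], p1[1] - p0[1]) for p0, p1, _w, _d in self.segments
        )


@dataclass(frozen=True)
class PhantomGroundTruth:
    epithelium_mask: np.ndarray
    fat_mask: np.ndarray
    lymph_masks: tuple
    lymph_seeds: tuple  # (row, col) centers, convenient wand seeds
    aoi: AOIPolygon
    true_epithelial_area_px: int
    true_fat_area_px: int


def grow_ductal_tree(spec: PhantomSpec) -> DuctalTree:
    """Grow the stochastic branching ductal tree for one phantom.

    A set of tips performs a correlated random walk from the gland origin on
    the left frame edge, advancing one ``segment_length_px`` step per
    iteration.  Each step a tip may split in two (probability
    ``branch_prob * stage``); children inherit the parent heading ± a random
    divergence and a width reduced by ``width_decay``.  Tips stop at the
    frame margin; every stopped or surviving tip ends in a terminal end bud.
    The number of growth iterations scales with ``stage``.
    """
    rng = np.random.default_rng(spec.seed)
    # walk margin leaves room for the end buds plus the AOI buffer, so the
    # traced AOI always lies strictly inside the frame
    margin = spec.end_bud_radius_px + 16.0
    n_steps = int(round(12 + 48 * spec.stage))
    p_branch = spec.branch_prob * spec.stage

    # tip state: [row, col, heading (rad, 0 = +col), width, depth, alive]
    tips = [[spec.height / 2.0, margin + 2.0, 0.0, spec.trunk_width_px, 0, True]]
    segments: list = []
    buds: list = []

    for _ in range(n_steps):
        for i in range(len(tips)):  # new tips appended during the sweep grow next step
            tip = tips[i]
            if not tip[5]:
                continue
            r, c, heading, width, depth, _ = tip
            headings = [heading + rng.normal(0.0, spec.branch_angle_sd * 0.5)]
            if (
                len(tips) < _MAX_TIPS
                and width * spec.width_decay >= 1.0
                and rng.random() < p_branch
            ):
                split = 0.3 + abs(rng.normal(0.0, spec.branch_angle_sd))
                headings = [headings[0] - split, headings[0] + split]
            first = True
            for h in headings:
                w = width if first and len(headings) == 1 else width * spec.width_decay
                nr = r + spec.segment_length_px * math.sin(h)
                nc = c + spec.segment_length_px * math.cos(h)
                if not (
                    margin <= nr < spec.height - margin
                    and margin <= nc < spec.width - margin
                ):
                    # out of frame: terminate this direction in an end bud
                    if first:
                        tip[5] = False
                        buds.append((r, c))
                    first = False
                    continue
                segments.append(((r, c), (nr, nc), w, depth))
                if first:
                    tip[0], tip[1], tip[2], tip[3] = nr, nc, h, w
                    if len(headings) == 2:
                        tip[4] = depth + 1
                        tip[3] = w
                else:
                    tips.append([nr, nc, h, w, depth + 1, True])
                first = False

    for tip in tips:
        if tip[5]:
            buds.append((tip[0], tip[1]))
    return DuctalTree(segments=tuple(segments), end_buds=tuple(buds))


def _stamp_segment(canvas: np.ndarray, p0, p1, radius: float, value: float) -> None:
    length = math.hypot(p1[0] - p0[0], p1[1] - p0[1])
    n = max(2, int(math.ceil(length)) + 1)
    for t in np.linspace(0.0, 1.0, n):
        r = p0[0] + t * (p1[0] - p0[0])
        c = p0[1] + t * (p1[1] - p0[1])
        rr, cc = draw.disk((r, c), max(radius, 0.5), shape=canvas.shape)
        canvas[rr, cc] = value


def _aoi_from_tree(tree: DuctalTree, spec: PhantomSpec) -> AOIPolygon:
    pts = [p for seg in tree.segments for p in (seg[0], seg[1])]
    pts.extend(tree.end_buds)
    margin = spec.end_bud_radius_px + 8.0
    if not pts:
        # no gland grown: fall back to a frame-inset rectangular AOI
        m = margin
        return AOIPolygon(
            [(m, m), (m, spec.width - m), (spec.height - m, spec.width - m), (spec.height - m, m)]
        )
    hull = shapely.MultiPoint([(p[1], p[0]) for p in pts]).convex_hull.buffer(
        margin, quad_segs=8
    )
    verts = [(y, x) for x, y in hull.exterior.coords[:-1]]
    return AOIPolygon(verts)


def _place_lymph_nodes(spec, rng, aoi_mask, epi_mask):
    """Dark ellipses in the fat pad, kept clear of the epithelium."""
    keep_out = ndimage.binary_dilation(epi_mask, iterations=4)
    masks, seeds = [], []
    for _ in range(spec.n_lymph_nodes):
        for _try in range(100):
            r = rng.uniform(0, spec.height)
            c = rng.uniform(0, spec.width)
            ry = rng.uniform(8.0, 14.0)
            rx = rng.uniform(8.0, 14.0)
            rot = rng.uniform(0, math.pi)
            rr, cc = draw.ellipse(r, c, ry, rx, shape=(spec.height, spec.width), rotation=rot)
            if rr.size < 50:
                continue
            mask = np.zeros((spec.height, spec.width), dtype=bool)
            mask[rr, cc] = True
            if aoi_mask[rr, cc].all() and not keep_out[rr, cc].any():
                masks.append(mask)
                seeds.append((int(round(r)), int(round(c))))
                break
    return masks, seeds


def render_phantom(spec: PhantomSpec) -> tuple[np.ndarray, PhantomGroundTruth]:
    """Render one phantom: carmine-toned RGB image plus exact ground truth.

    Structure (tree, nodes, AOI) is laid down first and the ground-truth
    masks frozen; the illumination gradient and pixel noise are applied
    afterwards, so the masks describe the undegraded specimen.
    """
    tree = (
        grow_ductal_tree(spec)
        if spec.include_tree
        else DuctalTree(segments=(), end_buds=())
    )
    rng = np.random.default_rng(spec.seed + 1)  # placement/texture stream

    h, w = spec.height, spec.width
    epi_gray = np.full((h, w), np.nan)
    max_depth = max((seg[3] for seg in tree.segments), default=0) or 1
    for p0, p1, width, depth in tree.segments:
        g = EPI_GRAY + (EPI_GRAY_TIP - EPI_GRAY) * min(depth / max_depth, 1.0)
        _stamp_segment(epi_gray, p0, p1, width / 2.0, g)
    for r, c in tree.end_buds:
        rr, cc = draw.disk((r, c), spec.end_bud_radius_px, shape=(h, w))
        epi_gray[rr, cc] = EPI_GRAY_TIP

    aoi = _aoi_from_tree(tree, spec)
    aoi_mask = rasterize_aoi(aoi, h, w)
    epi_mask = ~np.isnan(epi_gray) & aoi_mask

    lymph_masks, lymph_seeds = _place_lymph_nodes(spec, rng, aoi_mask, epi_mask)

    fat_mask = aoi_mask & ~epi_mask
    for m in lymph_masks:
        fat_mask &= ~m

    truth = PhantomGroundTruth(
        epithelium_mask=epi_mask,
        fat_mask=fat_mask,
        lymph_masks=tuple(lymph_masks),
        lymph_seeds=tuple(lymph_seeds),
        aoi=aoi,
        true_epithelial_area_px=int(epi_mask.sum()),
        true_fat_area_px=int(fat_mask.sum()),
    )

    # compose the image: fat field, nodes, epithelium, then degradations
    img = np.full((h, w), FAT_GRAY)
    if spec.fat_texture_sd:
        texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (h, w)), sigma=12)
        img += texture * (spec.fat_texture_sd / max(texture.std(), 1e-9))
    for m in lymph_masks:
        img[m] = LYMPH_GRAY + rng.normal(0.0, 2.0)
    img[epi_mask] = epi_gray[epi_mask]

    if spec.illumination_gradient_amplitude:
        yy, xx = np.mgrid[0:h, 0:w]
        ramp = 0.7 * xx / max(w - 1, 1) + 0.3 * yy / max(h - 1, 1)
        img = img - spec.illumination_gradient_amplitude * ramp
    if spec.noise_sd:
        img = img + rng.normal(0.0, spec.noise_sd, (h, w))

    gray = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    rgb = _carmine_tint(gray)
    return rgb, truth


def _carmine_tint(gray: np.ndarray) -> np.ndarray:
    """Luminance-preserving red tint: dark (stained) pixels shift carmine."""
    g = gray.astype(np.float64)
    t = (255.0 - g) / 255.0
    r = np.clip(np.floor(g + 46.0 * t + 0.5), 0, 255)
    gg = np.clip(np.floor(g - 23.43 * t + 0.5), 0, 255)
    return np.stack([r, gg, g], axis=-1).astype(np.uint8)


def growth_series(
    n_per_stage: int,
    stages,
    base_seed: int = 0,
    spec: PhantomSpec = PhantomSpec(),
):
    """Reproducible developmental panel of phantoms.

    Yields ``(spec, rgb_image, ground_truth)`` for every stage in ``stages``
    (each in [0, 1]) with ``n_per_stage`` replicates; replicate seeds are
    ``base_seed + running index``.
    """
    stages = list(stages)
    if not stages:
        raise ValueError("stages must be non-empty")
    if n_per_stage < 1:
        raise ValueError("n_per_stage must be >= 1")
    out = []
    idx = 0
    for stage in stages:
        for _ in range(n_per_stage):
            s = replace(spec, stage=float(stage), seed=base_seed + idx)
            rgb, truth = render_phantom(s)
            out.append((s, rgb, truth))
            idx += 1
    return out
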