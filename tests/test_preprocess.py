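"""Grayscale conversion, wand selection, excision, flattening, contrast."""

from collections import deque

import numpy as np
import pytest
from skimage import draw

from wholemount import (
    enhance_contrast,
    excise_regions,
    flatten_background,
    select_region_wand,
    to_grayscale,
)


def bfs_flood(img, seed, tol):
    """Brute-force 4-connected flood fill, the wand oracle."""
    h, w = img.shape
    ref = int(img[seed])
    out = np.zeros((h, w), bool)
    q = deque([seed])
    out[seed] = True
    while q:
        r, c = q.popleft()
        for nr, nc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= nr < h and 0 <= nc < w and not out[nr, nc]:
                if abs(int(img[nr, nc]) - ref) <= tol:
                    out[nr, nc] = True
                    q.append((nr, nc))
    return out


class TestToGrayscale:
    @pytest.mark.parametrize("g", [0, 17, 128, 255])
    def test_gray_triplet_fixed_point(self, g):
        rgb = np.full((4, 4, 3), g, np.uint8)
        assert (to_grayscale(rgb) == g).all()

    def test_itu601_red(self):
        rgb = np.zeros((2, 2, 3), np.uint8)
        rgb[..., 0] = 255
        assert (to_grayscale(rgb) == 76).all()  # round(0.299 * 255)

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError):
            to_grayscale(np.zeros((4, 4, 4, 2), np.uint8))

    def test_idempotent_on_grayscale(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 256, (8, 8)).astype(np.uint8)
        assert (to_grayscale(to_grayscale(g)) == g).all()


class TestWand:
    def test_uniform_image_full_mask(self):
        img = np.full((10, 12), 99, np.uint8)
        assert select_region_wand(img, (3, 4), 0).all()

    def test_unique_seed_single_pixel(self):
        img = np.full((6, 6), 200, np.uint8)
        img[2, 3] = 40
        mask = select_region_wand(img, (2, 3), 0)
        assert mask.sum() == 1 and mask[2, 3]

    def test_dark_disc_exactly_selected(self):
        img = np.full((60, 60), 240, np.uint8)
        rr, cc = draw.disk((30, 30), 12)
        img[rr, cc] = 40
        mask = select_region_wand(img, (30, 30), 30)
        expected = np.zeros_like(img, bool)
        expected[rr, cc] = True
        assert (mask == expected).all()

    def test_matches_bfs_oracle_on_random_blobs(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            img = (rng.integers(0, 2, (24, 24)) * 180 + 40).astype(np.uint8)
            img = (img + rng.integers(-10, 11, img.shape)).clip(0, 255).astype(np.uint8)
            seed = (int(rng.integers(24)), int(rng.integers(24)))
            tol = int(rng.integers(0, 40))
            assert (
                select_region_wand(img, seed, tol) == bfs_flood(img, seed, tol)
            ).all()

    def test_seed_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            select_region_wand(np.zeros((5, 5), np.uint8), (5, 0), 1)


class TestExcise:
    def test_no_masks_is_identity(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 256, (9, 9)).astype(np.uint8)
        assert (excise_regions(img, []) == img).all()

    def test_full_mask_whites_out(self):
        img = np.zeros((5, 5), np.uint8)
        assert (excise_regions(img, [np.ones((5, 5), bool)]) == 255).all()

    def test_disc_mask_matches_loop_oracle_and_idempotent(self):
        rng = np.random.default_rng(2)
        img = rng.integers(0, 256, (30, 30)).astype(np.uint8)
        mask = np.zeros((30, 30), bool)
        rr, cc = draw.disk((15, 15), 7)
        mask[rr, cc] = True
        out = excise_regions(img, [mask])
        for r in range(30):
            for c in range(30):
                assert out[r, c] == (255 if mask[r, c] else img[r, c])
        assert (excise_regions(out, [mask]) == out).all()

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            excise_regions(np.zeros((4, 4), np.uint8), [np.ones((5, 5), bool)])


class TestFlatten:
    def test_uniform_image_unchanged_within_rounding(self):
        img = np.full((64, 64), 200, np.uint8)
        out = flatten_background(img, 8)
        assert np.abs(out.astype(int) - out[32, 32].astype(int)).max() <= 1

    def test_shading_ramp_variance_reduced(self):
        # gray-230 background, -60 left-to-right ramp, small dark discs
        h, w = 120, 160
        ramp = np.linspace(0, -60, w)[None, :]
        img = np.clip(230 + np.broadcast_to(ramp, (h, w)), 0, 255).copy()
        fg = np.zeros((h, w), bool)
        rng = np.random.default_rng(5)
        for _ in range(6):
            rr, cc = draw.disk(
                (rng.integers(15, h - 15), rng.integers(15, w - 15)), 5, shape=(h, w)
            )
            fg[rr, cc] = True
        img[fg] = 60
        img = img.astype(np.uint8)
        out = flatten_background(img, 15)
        bg = ~fg
        assert out[bg].std() < 0.25 * img[bg].std()

    def test_output_in_range_for_random_input(self):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 256, (50, 50)).astype(np.uint8)
        out = flatten_background(img, 6)
        assert out.dtype == np.uint8 and out.min() >= 0 and out.max() <= 255

    def test_invalid_radius_rejected(self):
        img = np.zeros((20, 20), np.uint8)
        for r in (0, 20, 40):
            with pytest.raises(ValueError):
                flatten_background(img, r)


class TestEnhanceContrast:
    def test_full_range_image_fixed_point(self):
        img = np.arange(256, dtype=np.uint8).reshape(16, 16)
        assert (enhance_contrast(img, 0.0) == img).all()

    def test_two_level_image_maps_to_extremes(self):
        img = np.array([[100, 150], [150, 100]], np.uint8)
        out = enhance_contrast(img, 0.0)
        assert set(out.ravel()) == {0, 255}
        assert (out == 0).sum() == 2

    def test_ramp_matches_linear_map_oracle(self):
        img = np.arange(256, dtype=np.uint8).reshape(16, 16)
        lo, hi = np.quantile(img, [0.1, 0.9])
        out = enhance_contrast(img, 0.1)
        for g in range(256):
            expected = min(255, max(0, int(np.floor((g - lo) / (hi - lo) * 255 + 0.5))))
            assert out.ravel()[g] == expected

    def test_constant_image_maps_to_white(self):
        assert (enhance_contrast(np.full((4, 4), 77, np.uint8), 0.0) == 255).all()

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            enhance_contrast(np.zeros((4, 4), np.uint8), 0.5)
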