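import numpy as np
import pytest
from scipy import ndimage

from leukoseg.segmentation import (
    BoundingBox,
    StructuringElement,
    ThresholdConfig,
    background_mask,
    crop_leukocyte,
    dilate,
    erode,
    erythrocyte_mask,
    largest_component_bbox,
    leukocyte_mask,
    open_mask,
    otsu_threshold,
    region_partition,
    segment_pipeline,
    PAD_GRAY,
)

# ---------------------------------------------------------------------------
# Independent oracles (naive, loop-based, kept separate from the library)
# ---------------------------------------------------------------------------

def otsu_brute_force(hist):
    """Exhaustive between-class-variance search over all 256 cuts."""
    total = sum(hist)
    best_t, best_var = 0, -1.0
    for t in range(256):
        w0 = sum(hist[: t + 1])
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            var = 0.0
        else:
            mu0 = sum(i * hist[i] for i in range(t + 1)) / w0
            mu1 = sum(i * hist[i] for i in range(t + 1, 256)) / w1
            var = (w0 / total) * (w1 / total) * (mu0 - mu1) ** 2
        if var > best_var + 1e-12:
            best_var, best_t = var, t
    return best_t


def masks_brute_force(img, t1, t2):
    h, w = img.shape[:2]
    bg = np.zeros((h, w), dtype=bool)
    ery = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            r, g, b = (int(v) for v in img[i, j])
            bg[i, j] = r > t1 and g > t1 and b > t1
            ery[i, j] = b < t2 or r > b
    return bg, ery, ~bg & ~ery


def dilate_brute_force(mask, se):
    h, w = mask.shape
    out = np.zeros((h, w), dtype=bool)
    offs = se.offsets()
    for z_r in range(h):
        for z_c in range(w):
            # reflected element at z covers z - o for each offset o
            for dr, dc in offs:
                r, c = z_r - dr, z_c - dc
                if 0 <= r < h and 0 <= c < w and mask[r, c]:
                    out[z_r, z_c] = True
                    break
    return out


def erode_brute_force(mask, se):
    h, w = mask.shape
    out = np.zeros((h, w), dtype=bool)
    offs = se.offsets()
    for z_r in range(h):
        for z_c in range(w):
            ok = True
            for dr, dc in offs:
                r, c = z_r + dr, z_c + dc
                if not (0 <= r < h and 0 <= c < w and mask[r, c]):
                    ok = False
                    break
            out[z_r, z_c] = ok
    return out


def largest_bbox_brute_force(mask):
    """Flood fill (8-connectivity); max area, ties to smallest bbox corner."""
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    best = None
    for i in range(h):
        for j in range(w):
            if not mask[i, j] or seen[i, j]:
                continue
            stack, pixels = [(i, j)], []
            seen[i, j] = True
            while stack:
                r, c = stack.pop()
                pixels.append((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            rows = [p[0] for p in pixels]
            cols = [p[1] for p in pixels]
            cand = (-len(pixels), min(rows), min(cols), max(rows) + 1, max(cols) + 1)
            if best is None or cand[:3] < best[:3]:
                best = cand
    return BoundingBox(best[1], best[2], best[3], best[4])


def _random_se(rng):
    fp = rng.random((3, 3)) < 0.6
    fp[1, 1] = True
    return StructuringElement(fp, (1, 1))


# ---------------------------------------------------------------------------
# Otsu
# ---------------------------------------------------------------------------

class TestOtsu:
    def test_two_point_masses_choose_plateau_minimum(self):
        hist = np.zeros(256, dtype=int)
        hist[50] = 100
        hist[200] = 100
        assert otsu_threshold(hist) == 50 == otsu_brute_force(hist)

    def test_uniform_histogram(self):
        hist = np.ones(256, dtype=int)
        assert otsu_threshold(hist) == 127 == otsu_brute_force(hist)

    def test_matches_exhaustive_search_on_random_histograms(self, rng):
        for _ in range(100):
            hist = rng.integers(0, 50, size=256)
            if hist.sum() == 0:
                hist[rng.integers(0, 256)] = 1
            assert otsu_threshold(hist) == otsu_brute_force(list(hist))

    def test_single_intensity_returns_it_with_warning(self):
        hist = np.zeros(256, dtype=int)
        hist[77] = 10
        with pytest.warns(UserWarning, match="degenerate"):
            assert otsu_threshold(hist) == 77

    def test_all_zero_histogram_raises(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.zeros(256, dtype=int))


# ---------------------------------------------------------------------------
# Color-rule masks
# ---------------------------------------------------------------------------

class TestColorMasks:
    def test_background_strictness(self):
        img = np.array([[[183, 183, 183], [182, 255, 255]]], dtype=np.uint8)
        bg = background_mask(img, 182)
        assert bg[0, 0] and not bg[0, 1]

    def test_all_black_has_no_background(self):
        img = np.zeros((4, 4, 3), dtype=np.uint8)
        assert not background_mask(img, 182).any()

    @pytest.mark.parametrize("pixel,expected", [
        ((200, 0, 100), True),    # blue below threshold
        ((200, 0, 180), True),    # red above blue
        ((100, 0, 180), False),   # neither disjunct
    ])
    def test_erythrocyte_disjuncts(self, pixel, expected):
        img = np.array([[pixel]], dtype=np.uint8)
        assert erythrocyte_mask(img, 150)[0, 0] == expected

    def test_leukocyte_pixel_example(self):
        img = np.array([[[120, 80, 180]]], dtype=np.uint8)
        assert leukocyte_mask(img, ThresholdConfig(182, 150))[0, 0]

    def test_masks_match_per_pixel_evaluation(self, rng):
        for _ in range(50):
            img = rng.integers(0, 256, size=(8, 8, 3), dtype=np.uint8)
            t1 = int(rng.integers(0, 256))
            t2 = int(rng.integers(0, 256))
            bg_o, ery_o, leuk_o = masks_brute_force(img, t1, t2)
            np.testing.assert_array_equal(background_mask(img, t1), bg_o)
            np.testing.assert_array_equal(erythrocyte_mask(img, t2), ery_o)
            np.testing.assert_array_equal(
                leukocyte_mask(img, ThresholdConfig(t1, t2)), leuk_o)

    def test_region_rules_are_exhaustive_and_leukocyte_disjoint(self, rng):
        for _ in range(20):
            img = rng.integers(0, 256, size=(8, 8, 3), dtype=np.uint8)
            bg = background_mask(img)
            ery = erythrocyte_mask(img)
            leuk = leukocyte_mask(img)
            assert (bg | ery | leuk).all()
            assert not (leuk & bg).any()
            assert not (leuk & ery).any()

    def test_region_partition_assigns_each_pixel_once(self, rng):
        img = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
        part = region_partition(img)
        assert set(np.unique(part)) <= {0, 1, 2}
        # leukocyte pixels in the partition match the raw leukocyte rule
        np.testing.assert_array_equal(part == 2, leukocyte_mask(img))


# ---------------------------------------------------------------------------
# Morphology
# ---------------------------------------------------------------------------

class TestMorphology:
    def test_single_pixel_dilates_to_block(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        out = dilate(mask, StructuringElement.square(3))
        expected = np.zeros((5, 5), dtype=bool)
        expected[1:4, 1:4] = True
        np.testing.assert_array_equal(out, expected)

    def test_corner_pixel_dilation_clips_at_border(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = True
        out = dilate(mask, StructuringElement.square(3))
        expected = np.zeros((4, 4), dtype=bool)
        expected[0:2, 0:2] = True
        np.testing.assert_array_equal(out, expected)

    def test_erode_block_to_center(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[1:4, 1:4] = True
        out = erode(mask, StructuringElement.square(3))
        expected = np.zeros((5, 5), dtype=bool)
        expected[2, 2] = True
        np.testing.assert_array_equal(out, expected)

    def test_identity_element(self, rng):
        mask = rng.random((8, 8)) < 0.5
        se1 = StructuringElement.square(1)
        np.testing.assert_array_equal(erode(mask, se1), mask)
        np.testing.assert_array_equal(dilate(mask, se1), mask)

    def test_matches_set_definition_oracle(self, rng):
        for _ in range(25):
            h, w = rng.integers(4, 17, size=2)
            mask = rng.random((h, w)) < 0.4
            se = _random_se(rng)
            np.testing.assert_array_equal(dilate(mask, se), dilate_brute_force(mask, se))
            np.testing.assert_array_equal(erode(mask, se), erode_brute_force(mask, se))

    def test_matches_scipy_binary_morphology(self, rng):
        """Cross-check against an independent reference implementation."""
        for _ in range(10):
            mask = rng.random((12, 12)) < 0.4
            se = _random_se(rng)
            np.testing.assert_array_equal(
                dilate(mask, se),
                ndimage.binary_dilation(mask, structure=se.footprint),
            )
            np.testing.assert_array_equal(
                erode(mask, se),
                ndimage.binary_erosion(mask, structure=se.footprint),
            )

    def test_extensivity_and_anti_extensivity(self, rng):
        se = StructuringElement.square(3)
        for _ in range(10):
            mask = rng.random((10, 10)) < 0.5
            assert (mask <= dilate(mask, se)).all()
            assert (erode(mask, se) <= mask).all()

    def test_duality_on_interior(self, rng):
        """Erosion is the complement of dilating the complement (reflected SE)."""
        se = _random_se(rng)
        for _ in range(10):
            mask = rng.random((12, 12)) < 0.5
            er = erode(mask, se)
            du = ~dilate(~mask, se.reflected())
            np.testing.assert_array_equal(er[2:-2, 2:-2], du[2:-2, 2:-2])

    def test_opening_is_erode_then_dilate(self, rng):
        mask = rng.random((10, 10)) < 0.5
        se = StructuringElement.square(3)
        np.testing.assert_array_equal(open_mask(mask, se), dilate(erode(mask, se), se))

    def test_opening_idempotent_and_anti_extensive(self, rng):
        se = StructuringElement.square(3)
        for _ in range(20):
            mask = rng.random((16, 16)) < 0.5
            once = open_mask(mask, se)
            assert (once <= mask).all()
            np.testing.assert_array_equal(open_mask(once, se), once)

    def test_opening_removes_isolated_pixel(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[4, 4] = True
        assert not open_mask(mask, StructuringElement.square(3)).any()

    def test_empty_mask_stays_empty(self):
        se = StructuringElement.disk(2)
        empty = np.zeros((6, 6), dtype=bool)
        np.testing.assert_array_equal(dilate(empty, se), empty)
        np.testing.assert_array_equal(open_mask(empty, se), empty)

    def test_invalid_structuring_elements(self):
        with pytest.raises(ValueError):
            StructuringElement(np.zeros((3, 3), dtype=bool))
        with pytest.raises(ValueError):
            StructuringElement(np.ones((3, 3), dtype=bool), origin=(5, 1))


# ---------------------------------------------------------------------------
# Components, bounding boxes, cropping
# ---------------------------------------------------------------------------

class TestLargestComponent:
    def test_largest_blob_wins(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[1:4, 1:5] = True          # area 12
        mask[6:7, 2:7] = True          # area 5
        assert largest_component_bbox(mask) == BoundingBox(1, 1, 4, 5)

    def test_single_pixel(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[3, 4] = True
        assert largest_component_bbox(mask) == BoundingBox(3, 4, 4, 5)

    def test_tie_breaks_toward_smallest_corner(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[0:2, 0:2] = True
        mask[5:7, 5:7] = True
        assert largest_component_bbox(mask) == BoundingBox(0, 0, 2, 2)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="no leukocyte"):
            largest_component_bbox(np.zeros((5, 5), dtype=bool))

    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(30):
            mask = rng.random((12, 12)) < 0.3
            if not mask.any():
                mask[0, 0] = True
            assert largest_component_bbox(mask) == largest_bbox_brute_force(mask)

    def test_diagonal_pixels_are_one_component(self):
        mask = np.zeros((6, 6), dtype=bool)
        mask[0, 0] = mask[1, 1] = mask[2, 2] = True
        assert largest_component_bbox(mask) == BoundingBox(0, 0, 3, 3)


class TestCrop:
    def test_output_is_always_requested_size(self, rng):
        img = rng.integers(0, 256, size=(192, 256, 3), dtype=np.uint8)
        for bbox in [BoundingBox(0, 0, 4, 4), BoundingBox(90, 120, 110, 160),
                     BoundingBox(188, 252, 192, 256)]:
            assert crop_leukocyte(img, bbox).shape == (128, 128, 3)

    def test_centered_window_arithmetic(self, rng):
        img = rng.integers(0, 256, size=(256, 256, 3), dtype=np.uint8)
        bbox = BoundingBox(120, 120, 136, 136)  # centered at (128, 128)
        crop = crop_leukocyte(img, bbox)
        np.testing.assert_array_equal(crop, img[64:192, 64:192])

    def test_corner_bbox_clamps_to_image(self, rng):
        img = rng.integers(0, 256, size=(256, 256, 3), dtype=np.uint8)
        crop = crop_leukocyte(img, BoundingBox(0, 0, 4, 4))
        np.testing.assert_array_equal(crop, img[0:128, 0:128])

    def test_small_image_padded_with_background_gray(self):
        img = np.zeros((64, 64, 3), dtype=np.uint8)
        crop = crop_leukocyte(img, BoundingBox(30, 30, 34, 34))
        assert crop.shape == (128, 128, 3)
        assert (crop[:32] == PAD_GRAY).all()
        assert (crop[32:96, 32:96] == 0).all()


class TestPipeline:
    def test_composition_identity(self, rng):
        from leukoseg.synthetic import generate_scene
        from leukoseg.segmentation import leukocyte_mask as lm
        scene = generate_scene(3, noise_fraction=0.01)
        cfg = ThresholdConfig()
        se = StructuringElement.disk(5)
        crop, bbox, opened = segment_pipeline(scene.image, cfg, se)
        manual_open = open_mask(lm(scene.image, cfg), se)
        np.testing.assert_array_equal(opened, manual_open)
        assert bbox == largest_component_bbox(manual_open)
        np.testing.assert_array_equal(crop, crop_leukocyte(scene.image, bbox))

    def test_bbox_contains_planted_blob_center(self):
        from leukoseg.synthetic import generate_scene
        scene = generate_scene(11, noise_fraction=0.01)
        _, bbox, _ = segment_pipeline(scene.image)
        rows, cols = np.nonzero(scene.gt_leukocyte)
        cr, cc = rows.mean(), cols.mean()
        assert bbox.row_min <= cr < bbox.row_max
        assert bbox.col_min <= cc < bbox.col_max

    def test_all_gray_image_reports_no_leukocyte(self):
        img = np.full((64, 64, 3), 210, dtype=np.uint8)
        with pytest.raises((ValueError, RuntimeError), match="no leukocyte"):
            segment_pipeline(img)
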