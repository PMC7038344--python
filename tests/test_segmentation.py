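import numpy as np
import pytest

from fruitfst import (
    BinaryMask,
    RGBImage,
    SegmentationParams,
    largest_component,
    median_filter_mask,
    rgb_to_yuv,
    segment_fruit,
    segmentation_accuracy,
    stage_accuracy_summary,
    threshold_uv,
)
from fruitfst.segmentation import YUVImage
from fruitfst.synthetic import FruitSpec, clean_scene_spec, generate_scene
from fruitfst.synthetic import SceneSpec
import dataclasses

# ---------------------------------------------------------------- oracles


def oracle_threshold(u, v, p):
    out = np.zeros(u.shape, bool)
    for r in range(u.shape[0]):
        for c in range(u.shape[1]):
            out[r, c] = p.u1 < u[r, c] < p.u2 and p.v1 < v[r, c] < p.v2
    return out


def oracle_median(mask, size):
    k = size // 2
    img = np.pad(mask.astype(np.uint8) * 255, k, mode="edge")
    out = np.zeros(mask.shape, bool)
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            out[r, c] = np.median(img[r : r + size, c : c + size]) >= 128
    return out


def oracle_largest_component(mask, connectivity=8):
    """Flood fill in row-major discovery order; max area, first-found wins ties."""
    h, w = mask.shape
    seen = np.zeros_like(mask, bool)
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    best = None
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            comp, stack = [], [(r0, c0)]
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                comp.append((r, c))
                for dr, dc in nbrs:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        stack.append((rr, cc))
            if best is None or len(comp) > len(best):
                best = comp
    out = np.zeros_like(mask)
    if best:
        for r, c in best:
            out[r, c] = True
    return out


# ------------------------------------------------------------- transform


class TestRGBToYUV:
    @pytest.mark.parametrize(
        "rgb,expected",
        [
            ((1.0, 0.0, 0.0), (0.299, -0.14713, 0.615)),
            ((0.0, 1.0, 0.0), (0.587, -0.28886, -0.51499)),
            ((0.0, 0.0, 1.0), (0.114, 0.436, -0.10001)),
            ((0.0, 0.0, 0.0), (0.0, 0.0, 0.0)),
        ],
    )
    def test_matrix_columns_on_basis_colors(self, rgb, expected):
        img = RGBImage(np.array(rgb).reshape(1, 1, 3))
        yuv = rgb_to_yuv(img)
        assert yuv.Y[0, 0] == pytest.approx(expected[0], abs=1e-9)
        assert yuv.U[0, 0] == pytest.approx(expected[1], abs=1e-9)
        assert yuv.V[0, 0] == pytest.approx(expected[2], abs=1e-9)

    def test_white_is_pure_luma(self):
        yuv = rgb_to_yuv(RGBImage(np.ones((1, 1, 3))))
        assert yuv.Y[0, 0] == pytest.approx(1.0, abs=1e-9)
        assert abs(yuv.U[0, 0]) <= 1e-5
        assert yuv.V[0, 0] == pytest.approx(0.0, abs=1e-9)  # V row sums to 0

    def test_chrominance_ranges_on_random_colors(self):
        rng = np.random.default_rng(0)
        yuv = rgb_to_yuv(RGBImage(rng.uniform(size=(64, 64, 3))))
        assert yuv.Y.min() >= 0 and yuv.Y.max() <= 1 + 1e-12
        assert np.all(np.abs(yuv.U) <= 0.436 + 1e-12)
        assert np.all(np.abs(yuv.V) <= 0.615 + 1e-12)


class TestThresholdUV:
    def test_pixel_inside_box_passes(self, default_params):
        yuv = YUVImage(np.zeros((1, 1)), np.array([[0.05]]), np.array([[0.20]]))
        assert threshold_uv(yuv, default_params).mask[0, 0]

    @pytest.mark.parametrize("u,v", [(0.18, 0.2), (-0.07, 0.2), (0.05, 0.58), (0.05, -0.12)])
    def test_boundaries_excluded_by_strict_inequality(self, u, v, default_params):
        yuv = YUVImage(np.zeros((1, 1)), np.array([[u]]), np.array([[v]]))
        assert not threshold_uv(yuv, default_params).mask[0, 0]

    def test_luma_is_ignored(self, default_params):
        for y in (0.0, 0.5, 1.0):
            yuv = YUVImage(np.full((1, 1), y), np.array([[0.05]]), np.array([[0.2]]))
            assert threshold_uv(yuv, default_params).mask[0, 0]

    def test_matches_per_pixel_oracle_on_random_fields(self, default_params):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            u = rng.uniform(-0.436, 0.436, (16, 16))
            v = rng.uniform(-0.615, 0.615, (16, 16))
            got = threshold_uv(YUVImage(np.zeros((16, 16)), u, v), default_params)
            np.testing.assert_array_equal(got.mask, oracle_threshold(u, v, default_params))


class TestMedianFilter:
    def test_constant_fields_unchanged(self):
        for fill in (False, True):
            m = BinaryMask(np.full((40, 40), fill))
            assert np.all(median_filter_mask(m, 25).mask == fill)

    def test_isolated_speckle_removed(self):
        m = np.zeros((50, 50), bool)
        m[25, 25] = True
        assert median_filter_mask(BinaryMask(m), 25).area == 0

    def test_even_size_rejected(self):
        with pytest.raises(ValueError):
            median_filter_mask(BinaryMask(np.zeros((5, 5), bool)), 4)

    def test_matches_brute_force_with_replicated_borders(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            m = rng.random((24, 24)) < rng.uniform(0.2, 0.8)
            got = median_filter_mask(BinaryMask(m), 5)
            np.testing.assert_array_equal(got.mask, oracle_median(m, 5))


class TestLargestComponent:
    def test_keeps_only_max_area_blob(self):
        m = np.zeros((30, 30), bool)
        m[2:7, 2:10] = True   # area 40
        m[20:24, 20:23] = True  # area 12
        out = largest_component(BinaryMask(m))
        assert out.area == 40
        assert np.all(out.mask[2:7, 2:10])
        assert not out.mask[20:24, 20:23].any()

    def test_empty_mask_stays_empty(self):
        out = largest_component(BinaryMask(np.zeros((10, 10), bool)))
        assert out.area == 0

    def test_tie_broken_by_scan_order(self):
        m = np.zeros((10, 10), bool)
        m[1, 1:4] = True
        m[8, 5:8] = True
        out = largest_component(BinaryMask(m))
        assert out.mask[1, 1] and not out.mask[8, 5]

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, connectivity):
        for seed in range(60):
            rng = np.random.default_rng(seed)
            m = rng.random((40, 40)) < 0.45
            got = largest_component(BinaryMask(m), connectivity)
            ref = oracle_largest_component(m, connectivity)
            np.testing.assert_array_equal(got.mask, ref)


# -------------------------------------------------------------- pipeline


class TestSegmentFruit:
    def test_single_apple_recovered_on_clean_scene(self):
        pair, truth = generate_scene(clean_scene_spec(7))
        res = segment_fruit(pair.rgb)
        acc = segmentation_accuracy(res.blob_mask, BinaryMask(truth.largest_fruit_mask))
        assert acc["accuracy_pct"] >= 95.0

    def test_all_foliage_frame_reports_no_fruit(self):
        spec = dataclasses.replace(SceneSpec(seed=3), fruits=(), speckle_fraction=0.0)
        pair, _ = generate_scene(spec)
        res = segment_fruit(pair.rgb)
        assert not res.fruit_detected
        assert res.blob_mask.area == 0

    def test_two_apples_keep_only_larger(self):
        spec = dataclasses.replace(
            SceneSpec(seed=5),
            fruits=(
                FruitSpec((55.0, 60.0), 40.0, 37.0),
                FruitSpec((95.0, 135.0), 20.0, 18.0),
            ),
        )
        pair, truth = generate_scene(spec)
        res = segment_fruit(pair.rgb)
        big, small = truth.fruit_masks
        assert (res.blob_mask.mask & big).sum() > 0
        assert (res.blob_mask.mask & small).sum() == 0

    def test_blob_area_never_exceeds_blurred_area(self):
        for seed in range(5):
            pair, _ = generate_scene(clean_scene_spec(seed))
            res = segment_fruit(pair.rgb)
            assert res.blob_mask.area <= res.blurred_mask.area

    def test_deterministic_bit_for_bit(self):
        pair, _ = generate_scene(clean_scene_spec(11))
        a = segment_fruit(pair.rgb)
        b = segment_fruit(pair.rgb)
        np.testing.assert_array_equal(a.blob_mask.mask, b.blob_mask.mask)
        np.testing.assert_array_equal(a.threshold_mask.mask, b.threshold_mask.mask)


class TestAccuracy:
    def test_identical_masks_score_100(self):
        m = BinaryMask(np.eye(8, dtype=bool))
        scores = segmentation_accuracy(m, m)
        assert scores["accuracy_pct"] == 100.0
        assert scores["iou_pct"] == 100.0

    def test_half_coverage_scores_50(self):
        truth = np.zeros((10, 10), bool)
        truth[:, :4] = True
        pred = np.zeros((10, 10), bool)
        pred[:, :2] = True
        assert segmentation_accuracy(BinaryMask(pred), BinaryMask(truth))["accuracy_pct"] == 50.0

    def test_empty_truth_rejected(self):
        m = BinaryMask(np.zeros((5, 5), bool))
        with pytest.raises(ValueError):
            segmentation_accuracy(m, m)

    def test_over_segmentation_not_rewarded(self):
        truth = np.zeros((10, 10), bool)
        truth[4:6, 4:6] = True
        pred = np.ones((10, 10), bool)
        assert segmentation_accuracy(BinaryMask(pred), BinaryMask(truth))["accuracy_pct"] == 100.0

    def test_stage_summary_means_and_sds(self):
        table = [[90.0, 92.0, 94.0], [92.0, 94.0, 96.0]]
        s = stage_accuracy_summary(table)
        np.testing.assert_allclose(s["mean"], [91.0, 93.0, 95.0])
        np.testing.assert_allclose(s["sd"], [1.4, 1.4, 1.4])

    def test_stage_accuracies_non_decreasing_on_clean_scenes(self):
        for seed in range(5):
            pair, truth = generate_scene(clean_scene_spec(seed))
            res = segment_fruit(pair.rgb)
            tm = BinaryMask(truth.largest_fruit_mask)
            accs = [
                segmentation_accuracy(m, tm)["accuracy_pct"]
                for m in (res.threshold_mask, res.blurred_mask, res.blob_mask)
            ]
            assert accs[0] <= accs[1] + 1e-9 and accs[1] <= accs[2] + 1e-9
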