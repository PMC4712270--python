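import numpy as np
import pandas as pd
import pytest

from tjquant.errors import NormalizationError
from tjquant.image_io import BinaryMask, GrayImage
from tjquant.morphometry import (
    image_entropy,
    object_stats,
    percent_of_control,
    prune_spurs,
    skeleton_metrics,
    skeletonize_mask,
)


def brute_force_entropy(px: np.ndarray, n_bins: int = 256) -> float:
    """Independent oracle: explicit bin loop over the gray-level histogram."""
    edges = np.linspace(0, 256, n_bins + 1)
    h = 0.0
    total = px.size
    for i in range(n_bins):
        count = np.sum((px >= edges[i]) & (px < edges[i + 1]))
        if count:
            p = count / total
            h -= p * np.log2(p)
    return h


class TestEntropy:
    def test_constant_image_has_zero_entropy(self, constant_image):
        assert image_entropy(constant_image()).entropy_bits == 0.0

    def test_uniform_256_levels_has_eight_bits(self):
        px = np.tile(np.arange(256, dtype=np.uint8), (256, 1))
        assert image_entropy(GrayImage(px)).entropy_bits == pytest.approx(8.0, abs=1e-12)

    def test_two_level_closed_form(self):
        px = np.full((10, 10), 7, dtype=np.uint8)
        px[:5, :5] = 200  # 25% / 75% split
        expected = -0.25 * np.log2(0.25) - 0.75 * np.log2(0.75)
        assert image_entropy(GrayImage(px)).entropy_bits == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            px = rng.integers(0, 256, (64, 64), dtype=np.uint8)
            ours = image_entropy(GrayImage(px)).entropy_bits
            assert ours == pytest.approx(brute_force_entropy(px), abs=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        px = rng.integers(0, 256, (32, 32), dtype=np.uint8)
        shuffled = rng.permutation(px.ravel()).reshape(px.shape)
        assert image_entropy(GrayImage(px)).entropy_bits == pytest.approx(
            image_entropy(GrayImage(shuffled)).entropy_bits, abs=1e-14
        )

    def test_bounded_by_log_occupied_bins(self):
        rng = np.random.default_rng(4)
        px = rng.choice([3, 17, 99, 250], size=(32, 32)).astype(np.uint8)
        res = image_entropy(GrayImage(px))
        occupied = int((res.p > 0).sum())
        assert res.entropy_bits <= np.log2(occupied) + 1e-12

    def test_histogram_sums_to_one(self, two_level_image):
        assert image_entropy(two_level_image()).p.sum() == pytest.approx(1.0)


class TestSkeletonMetrics:
    def test_straight_line(self):
        px = np.zeros((5, 15), dtype=bool)
        px[2, 2:13] = True  # 11 pixels
        m = skeleton_metrics(BinaryMask(px))
        assert m.strand_length_px == pytest.approx(10.0)
        assert m.n_branch_points == 0
        assert m.complexity_index == 0.0

    def test_plus_cross(self):
        px = np.zeros((15, 15), dtype=bool)
        px[7, 2:13] = True
        px[2:13, 7] = True  # two 11-px lines sharing the center: 21 pixels
        m = skeleton_metrics(BinaryMask(px))
        assert m.strand_length_px == pytest.approx(20.0)
        assert m.n_branch_points == 1
        assert m.complexity_index == pytest.approx(1.0 / 20.0)

    def test_diagonal_line_geodesic_weighting(self):
        px = np.zeros((12, 12), dtype=bool)
        for i in range(10):
            px[i, i] = True
        m = skeleton_metrics(BinaryMask(px))
        assert m.strand_length_px == pytest.approx(9 * np.sqrt(2.0))

    def test_count_metric_option(self):
        px = np.zeros((5, 15), dtype=bool)
        px[2, 2:13] = True
        m = skeleton_metrics(BinaryMask(px), length_metric="count")
        assert m.strand_length_px == 11

    def test_empty_skeleton_flagged_undefined(self):
        m = skeleton_metrics(BinaryMask(np.zeros((8, 8), dtype=bool)))
        assert m.strand_length_px == 0
        assert np.isnan(m.complexity_index)

    def test_staircase_corner_not_double_counted(self):
        # L-corner: diagonal adjacency shortcut by the shared 4-neighbor
        px = np.zeros((4, 4), dtype=bool)
        px[0, 0] = px[1, 0] = px[1, 1] = True
        m = skeleton_metrics(BinaryMask(px))
        assert m.strand_length_px == pytest.approx(2.0)


class TestSkeletonize:
    def test_wide_bar_thins_to_line(self):
        px = np.zeros((11, 40), dtype=bool)
        px[3:8, 5:35] = True  # 5-px-wide bar
        skel = skeletonize_mask(BinaryMask(px))
        coords = np.argwhere(skel.pixels)
        # one-pixel-wide: a single skeleton pixel in every occupied column
        cols, counts = np.unique(coords[:, 1], return_counts=True)
        assert (counts == 1).all()
        assert np.ptp(coords[:, 0]) <= 1  # stays at the bar's vertical center
        # thinning shrinks each end by at most half the bar width + 1
        assert abs((cols.max() - cols.min() + 1) - 30) <= 6

    def test_thin_diagonal_nearly_unchanged(self):
        px = np.zeros((12, 12), dtype=bool)
        for i in range(1, 11):
            px[i, i] = True
        skel = skeletonize_mask(BinaryMask(px))
        assert (px & ~skel.pixels).sum() <= 2  # endpoints at most

    def test_empty_mask(self):
        assert not skeletonize_mask(BinaryMask(np.zeros((8, 8), dtype=bool))).pixels.any()


class TestPruneSpurs:
    def test_short_spur_removed_long_arms_untouched(self):
        px = np.zeros((15, 21), dtype=bool)
        px[7, 1:20] = True   # long horizontal through-path
        px[5:7, 10] = True   # 2-px spur
        pruned = prune_spurs(BinaryMask(px), min_len=4)
        assert not pruned.pixels[5:7, 10].any()
        assert pruned.pixels[7, 1:20].all()

    def test_long_branch_kept_at_full_length(self):
        px = np.zeros((15, 21), dtype=bool)
        px[7, 1:20] = True
        px[1:7, 10] = True  # 6-px arm > min_len
        pruned = prune_spurs(BinaryMask(px), min_len=4)
        assert pruned.pixels[1:7, 10].all()


class TestObjectStats:
    def test_mean_of_three_rectangles(self, mask_from):
        px = np.zeros((20, 40), dtype=bool)
        px[1:3, 1:6] = True    # 10 px
        px[5:9, 1:6] = True    # 20 px
        px[11:16, 1:7] = True  # 30 px
        s = object_stats(mask_from(px))
        assert (s.n_objects, s.total_size_px, s.mean_object_size) == (3, 60, 20.0)

    def test_full_frame_object(self, mask_from):
        s = object_stats(mask_from(np.ones((8, 9), dtype=bool)))
        assert s.mean_object_size == 72

    def test_connectivity_semantics(self, mask_from):
        px = np.zeros((4, 4), dtype=bool)
        px[0, 0] = px[1, 1] = True
        assert object_stats(mask_from(px), connectivity=8).n_objects == 1
        assert object_stats(mask_from(px), connectivity=4).n_objects == 2

    def test_empty_mask_flagged(self, mask_from):
        s = object_stats(mask_from(np.zeros((4, 4), dtype=bool)))
        assert s.n_objects == 0 and np.isnan(s.mean_object_size)


class TestPercentOfControl:
    def test_basic_normalization(self):
        t = pd.DataFrame({"group": ["c"] * 3 + ["s"], "value": [2.0, 2.0, 2.0, 3.0]})
        out = percent_of_control(t, "c")
        assert out.loc[out.group == "s", "value_pct"].iloc[0] == pytest.approx(150.0)

    def test_control_maps_to_mean_100(self):
        t = pd.DataFrame({"group": ["c"] * 4, "value": [1.0, 2.0, 3.0, 4.0]})
        out = percent_of_control(t, "c")
        assert out["value_pct"].mean() == pytest.approx(100.0)

    def test_negative_values_pass_through(self):
        t = pd.DataFrame({"group": ["c", "s"], "value": [2.0, -1.0]})
        out = percent_of_control(t, "c")
        assert out.loc[out.group == "s", "value_pct"].iloc[0] == pytest.approx(-50.0)

    def test_zero_control_mean_rejected(self):
        t = pd.DataFrame({"group": ["c", "s"], "value": [0.0, 1.0]})
        with pytest.raises(NormalizationError):
            percent_of_control(t, "c")
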