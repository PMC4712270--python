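import numpy as np
import pytest
from skimage import draw

from tjquant.errors import CapacityError, ParameterError
from tjquant.morphometry import branch_points, skeleton_metrics
from tjquant.synthetic import (
    CellSimParams,
    JunctionSimParams,
    simulate_cell_image,
    simulate_intensity_field,
    simulate_junction_image,
)

SMALL = dict(image_size=256)


class TestJunctionSimulator:
    def test_determinism(self):
        p = JunctionSimParams(seed=7, **SMALL)
        img1, t1 = simulate_junction_image(p)
        img2, t2 = simulate_junction_image(JunctionSimParams(seed=7, **SMALL))
        assert np.array_equal(img1.pixels, img2.pixels)
        assert np.array_equal(t1.skeleton_mask.pixels, t2.skeleton_mask.pixels)
        assert np.array_equal(t1.true_branch_points, t2.true_branch_points)

    def test_single_path_has_no_branch_points(self):
        p = JunctionSimParams(seed=0, n_seeds=1, branch_prob=0.0, fragmentation=0.0,
                              noise_sd=0.0, **SMALL)
        _, truth = simulate_junction_image(p)
        assert len(truth.true_branch_points) == 0
        assert truth.true_strand_length > 0

    def test_full_fragmentation_leaves_background(self):
        p = JunctionSimParams(seed=1, fragmentation=1.0, noise_sd=0.0, **SMALL)
        img, truth = simulate_junction_image(p)
        assert not truth.skeleton_mask.pixels.any()
        assert (img.pixels == p.bg_intensity).all()

    def test_fragmentation_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            JunctionSimParams(fragmentation=1.5)

    def test_fg_must_exceed_bg(self):
        with pytest.raises(ParameterError):
            JunctionSimParams(fg_intensity=30, bg_intensity=180)

    def test_ground_truth_consistent_with_branch_rule(self):
        """Recomputing branch points from the stored centerline reproduces
        the recorded ground truth (fragmentation = 0)."""
        for seed in range(5):
            p = JunctionSimParams(seed=seed, fragmentation=0.0, noise_sd=0.0, **SMALL)
            _, truth = simulate_junction_image(p)
            recomputed = branch_points(truth.skeleton_mask.pixels)
            assert np.array_equal(recomputed, truth.true_branch_points)
            m = skeleton_metrics(truth.skeleton_mask)
            assert m.strand_length_px == pytest.approx(truth.true_strand_length)

    def test_mean_strand_length_decreases_with_fragmentation(self):
        means = []
        for frag in (0.0, 0.3, 0.6):
            lengths = [
                simulate_junction_image(
                    JunctionSimParams(seed=s, fragmentation=frag, **SMALL)
                )[1].true_strand_length
                for s in range(20)
            ]
            means.append(np.mean(lengths))
        assert means[0] > means[1] > means[2]


class TestCellSimulator:
    def test_zero_cells_gives_uniform_background(self):
        p = CellSimParams(seed=0, n_cells=0, noise_sd=0.0, image_size=128)
        img, truth = simulate_cell_image(p)
        assert truth.true_count == 0
        assert (img.pixels == p.bg_intensity).all()

    def test_exact_label_count(self):
        p = CellSimParams(seed=3, n_cells=5, noise_sd=0.0, image_size=256)
        _, truth = simulate_cell_image(p)
        labels = np.unique(truth.object_mask)
        assert truth.true_count == 5
        assert len(labels[labels > 0]) == 5

    def test_circular_cell_area_matches_rasterized_disk(self):
        """aspect=1 cells: region area equals the rasterized-ellipse oracle at
        the implied radius within 2 px^2."""
        area = 100.0
        p = CellSimParams(seed=1, n_cells=8, area_range=(area, area),
                          aspect_range=(1.0, 1.0), noise_sd=0.0, image_size=256)
        _, truth = simulate_cell_image(p)
        r = np.sqrt(area / np.pi)
        rr, cc = draw.ellipse(50.5, 50.5, r, r)  # oracle at an off-grid center
        oracle = len(rr)
        for lab in range(1, 9):
            assert abs(int((truth.object_mask == lab).sum()) - oracle) <= 2

    def test_capacity_error_reports_achieved_count(self):
        p = CellSimParams(seed=0, n_cells=200, image_size=64,
                          area_range=(80.0, 120.0), max_attempts_per_cell=50)
        with pytest.raises(CapacityError) as exc:
            simulate_cell_image(p)
        assert exc.value.n_requested == 200
        assert 0 <= exc.value.n_placed < 200

    def test_determinism(self):
        img1, _ = simulate_cell_image(CellSimParams(seed=9, image_size=256))
        img2, _ = simulate_cell_image(CellSimParams(seed=9, image_size=256))
        assert np.array_equal(img1.pixels, img2.pixels)


class TestIntensityField:
    def test_noise_free_foreground_is_exact(self):
        img, truth = simulate_intensity_field(100, 20, 0.2, 0.0, seed=0, image_size=128)
        fg = truth.extras["fg_mask"].pixels
        assert (img.pixels[fg] == 100).all()
        assert (img.pixels[~fg] == 20).all()
        assert truth.true_fg_mean - truth.true_bg_mean == pytest.approx(80.0)

    def test_zero_fraction_flagged(self):
        img, truth = simulate_intensity_field(100, 20, 0.0, 0.0, seed=0, image_size=64)
        assert np.isnan(truth.true_fg_mean)
        assert (img.pixels == 20).all()

    def test_mask_fraction_approximate(self):
        _, truth = simulate_intensity_field(180, 30, 0.3, 0.0, seed=2, image_size=256)
        frac = truth.extras["fg_mask"].pixels.mean()
        assert frac == pytest.approx(0.3, abs=0.02)

    def test_fg_below_bg_rejected(self):
        with pytest.raises(ParameterError):
            simulate_intensity_field(20, 100, 0.2, 0.0, seed=0)
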