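"""Fiber/particle segmentation and coverage quantification."""

import numpy as np
import pytest
from skimage.draw import disk as draw_disk

from sebquant import (CoverageConfig, SegmentationError, category_summary,
                      coverage_percent, estimate_coverage, generate_sem_field,
                      product_coverage, remove_background, segment_fiber,
                      segment_particles)
from sebquant.particle_coverage import CoverageResult, FiberSegmentation


def jaccard(a, b):
    return np.logical_and(a, b).sum() / np.logical_or(a, b).sum()


def make_result(mean, category):
    return CoverageResult(per_fiber_coverage=[mean], product_mean=mean,
                          product_sd=0.0, n_fibers=1, category=category)


class TestSegmentFiber:
    def test_matches_generator_truth(self, sem_field_8pct):
        img, truth = sem_field_8pct
        seg = segment_fiber(img)
        assert jaccard(seg.fiber_mask, truth.fiber_mask) >= 0.95

    def test_all_background_fails(self):
        with pytest.raises(SegmentationError, match="no fiber"):
            segment_fiber(np.full((64, 64), 70, np.uint8))

    def test_known_band_geometry(self):
        img = np.full((200, 200), 60, np.uint8)
        img[:, 60:140] = 160  # band of 80*200 = 16000 px
        seg = segment_fiber(img)
        assert seg.fiber_mask.sum() == pytest.approx(16000, rel=0.05)
        assert seg.roi_bounds[1] == pytest.approx(60, abs=10)


class TestRemoveBackground:
    def test_texture_sd_reduced_on_particle_free_fiber(self, cov_cfg):
        img, truth = generate_sem_field(target_coverage=0.0, seed=5)
        seg = segment_fiber(img)
        flat = remove_background(img, seg, cov_cfg)
        sd_in = img.pixels[seg.fiber_mask].astype(float).std()
        sd_out = flat[seg.fiber_mask].astype(float).std()
        assert sd_out <= 0.5 * sd_in

    def test_flat_fiber_left_unchanged(self, cov_cfg):
        img = np.full((200, 200), 60, np.uint8)
        img[:, 50:150] = 160
        seg = segment_fiber(img)
        flat = remove_background(img, seg, cov_cfg)
        diff = np.abs(flat[seg.fiber_mask].astype(float) - 160.0)
        assert diff.max() <= 1.0

    def test_particles_stay_dark_after_flattening(self, sem_field_8pct, cov_cfg):
        img, truth = sem_field_8pct
        seg = segment_fiber(img)
        flat = remove_background(img, seg, cov_cfg).astype(float)
        neutral = np.median(flat[seg.fiber_mask])
        # erode the truth mask a little so boundary pixels don't dominate
        from scipy.ndimage import binary_erosion
        core = binary_erosion(truth.particle_mask, iterations=1)
        assert np.median(flat[core]) <= neutral - 20.0

    def test_unrepresentable_window_fails(self):
        img = np.full((40, 40), 60, np.uint8)
        img[:, 10:30] = 160
        seg = segment_fiber(img)
        with pytest.raises(ValueError, match="not representable"):
            remove_background(img, seg, CoverageConfig(pixel_scale=0.2,
                                                       smooth_factor=10.0))


class TestSegmentParticles:
    def test_zero_particle_field_gives_empty_mask(self, cov_cfg):
        img, _ = generate_sem_field(target_coverage=0.0, seed=6)
        seg = segment_fiber(img)
        flat = remove_background(img, seg, cov_cfg)
        assert segment_particles(flat, seg, cov_cfg).sum() == 0

    def test_pixelwise_f1_against_truth(self, cov_cfg):
        img, truth = generate_sem_field(target_coverage=8.0, seed=2,
                                        noise_level=0.0)
        seg = segment_fiber(img)
        flat = remove_background(img, seg, cov_cfg)
        mask = segment_particles(flat, seg, cov_cfg)
        tp = np.logical_and(mask, truth.particle_mask).sum()
        f1 = 2 * tp / (mask.sum() + truth.particle_mask.sum())
        assert f1 >= 0.9

    def test_subresolution_speckle_removed_by_size_filter(self, cov_cfg):
        # dark single pixels (0.2 um at 0.2 um/px) under a fixed threshold:
        # every component is below the 0.5 um equivalent-area disc
        flat = np.full((100, 100), 160, np.uint8)
        speckle = np.random.default_rng(0).choice(10_000, 50, replace=False)
        flat.ravel()[speckle] = 30
        seg = FiberSegmentation(np.ones((100, 100), bool), (0, 0, 100, 100))
        cfg = CoverageConfig(pixel_scale=0.2, threshold_method="fixed",
                             threshold_value=100.0)
        assert segment_particles(flat, seg, cfg).sum() == 0


class TestCoveragePercent:
    def test_empty_particle_mask(self):
        fiber = np.ones((10, 10), bool)
        assert coverage_percent(np.zeros((10, 10), bool), fiber) == 0.0

    def test_full_coverage(self):
        fiber = np.ones((10, 10), bool)
        assert coverage_percent(fiber, fiber) == 100.0

    def test_empty_fiber_mask_fails(self):
        with pytest.raises(ValueError, match="empty fiber"):
            coverage_percent(np.ones((5, 5), bool), np.zeros((5, 5), bool))

    def test_shape_mismatch_fails(self):
        with pytest.raises(ValueError, match="shape"):
            coverage_percent(np.ones((5, 5), bool), np.ones((5, 6), bool))

    def test_machine_precision_on_generator_masks(self, sem_field_8pct):
        _, truth = sem_field_8pct
        got = coverage_percent(truth.particle_mask, truth.fiber_mask)
        assert got == pytest.approx(truth.true_coverage, abs=1e-12)

    def test_union_monotonicity(self, sem_field_8pct, rng):
        _, truth = sem_field_8pct
        base = coverage_percent(truth.particle_mask, truth.fiber_mask)
        extra = truth.particle_mask.copy()
        rr, cc = draw_disk((256, 256), 8, shape=extra.shape)
        extra[rr, cc] = True
        assert coverage_percent(extra, truth.fiber_mask) >= base


class TestPipeline:
    def test_adding_particles_never_decreases_estimate(self, cov_cfg):
        img, _ = generate_sem_field(target_coverage=4.0, seed=3)
        base, _ = estimate_coverage(img, cov_cfg)
        more = img.pixels.copy()
        rng = np.random.default_rng(1)
        for _ in range(5):
            center = (rng.integers(50, 460), rng.integers(170, 340))
            rr, cc = draw_disk(center, 5, shape=more.shape)
            more[rr, cc] = 35
        grown, _ = estimate_coverage(more, cov_cfg)
        assert grown >= base - 1e-9

    def test_scale_robustness_on_upsampled_scene(self, cov_cfg):
        img, _ = generate_sem_field(target_coverage=8.0, seed=4,
                                    image_shape=(256, 256), pixel_scale=0.25)
        cfg1 = CoverageConfig(pixel_scale=0.25)
        cov1, _ = estimate_coverage(img, cfg1)
        up = np.kron(img.pixels, np.ones((2, 2), np.uint8))
        cfg2 = CoverageConfig(pixel_scale=0.125)
        cov2, _ = estimate_coverage(up, cfg2)
        assert abs(cov1 - cov2) <= 0.5


class TestProductAndCategory:
    def test_identical_images_zero_sd(self, cov_cfg):
        img, _ = generate_sem_field(target_coverage=6.0, seed=7,
                                    image_shape=(256, 256), pixel_scale=0.25)
        cfg = CoverageConfig(pixel_scale=0.25)
        with pytest.warns(UserWarning, match="protocol expects"):
            res = product_coverage([img] * 3, cfg, product_id="P1")
        assert res.product_sd == 0.0
        assert res.n_fibers == 3

    def test_zero_truth_product_mean_zero(self):
        cfg = CoverageConfig(pixel_scale=0.25)
        imgs = [generate_sem_field(target_coverage=0.0, seed=s,
                                   image_shape=(256, 256), pixel_scale=0.25)[0]
                for s in range(3)]
        res = product_coverage(imgs, cfg, n_fibers_expected=3)
        assert res.product_mean == 0.0

    def test_partial_failures_recorded(self):
        cfg = CoverageConfig(pixel_scale=0.25)
        good = [generate_sem_field(target_coverage=4.0, seed=s,
                                   image_shape=(256, 256), pixel_scale=0.25)[0]
                for s in range(2)]
        bad = np.full((256, 256), 70, np.uint8)
        res = product_coverage(good + [bad], cfg, n_fibers_expected=3)
        assert res.n_fibers == 2 and len(res.failures) == 1
        with pytest.raises(SegmentationError, match="analysable"):
            product_coverage([bad, bad, good[0]], cfg, n_fibers_expected=3)

    def test_category_median_order_statistic(self):
        results = [make_result(m, "shampoo") for m in (2.0, 6.0, 16.0)]
        results.append(make_result(9.0, "mask"))
        out = category_summary(results)
        shampoo = out.set_index("category").loc["shampoo"]
        assert shampoo["median_coverage"] == 6.0
        assert (shampoo["min_coverage"], shampoo["max_coverage"]) == (2.0, 16.0)
        # single product per category: median = that product's mean
        assert out.set_index("category").loc["mask", "median_coverage"] == 9.0
        # ranked ascending: lower coverage is better
        assert list(out["category"]) == ["shampoo", "mask"]

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="unknown category"):
            category_summary([make_result(5.0, "serum")])
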