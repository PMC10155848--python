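"""Generators: ground-truth self-consistency, determinism, distributions."""

import numpy as np
import pytest

from sebquant import (CoverageUnreachableError, SebollutionSpec, SwatchTruth,
                      generate_sem_field, generate_skin_pair,
                      generate_study_table, generate_swatch_readings,
                      site_calibration)
from sebquant.synthetic_data import sample_particle_diameters


class TestSebollutionSpec:
    @pytest.mark.parametrize("kwargs", [
        {"cb_fraction": 0.0},
        {"skin_dose": -2.0},
        {"particle_diameter_mean": 0.2, "particle_diameter_sd": 0.3},
    ])
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SebollutionSpec(**kwargs)

    def test_defaults_match_protocol(self, spec):
        assert spec.skin_dose == 2.0
        assert spec.swatch_dose == 90.0
        assert spec.particle_diameter_mean == 2.07


class TestSemField:
    def test_zero_target_gives_empty_particle_mask(self):
        img, truth = generate_sem_field(target_coverage=0.0, seed=1)
        assert truth.particle_mask.sum() == 0
        assert truth.true_coverage == 0.0

    def test_coverage_within_tolerance_by_pixel_count(self, sem_field_8pct):
        _, truth = sem_field_8pct
        counted = 100.0 * np.count_nonzero(
            truth.particle_mask & truth.fiber_mask
        ) / np.count_nonzero(truth.fiber_mask)
        assert counted == pytest.approx(truth.true_coverage, abs=1e-12)
        assert 7.75 <= counted <= 8.25

    def test_particles_confined_to_fiber(self, sem_field_8pct):
        _, truth = sem_field_8pct
        assert not np.any(truth.particle_mask & ~truth.fiber_mask)

    def test_bit_identical_for_same_seed(self):
        a_img, a_truth = generate_sem_field(target_coverage=4.0, seed=11,
                                            image_shape=(128, 128))
        b_img, b_truth = generate_sem_field(target_coverage=4.0, seed=11,
                                            image_shape=(128, 128))
        assert np.array_equal(a_img.pixels, b_img.pixels)
        assert np.array_equal(a_truth.particle_mask, b_truth.particle_mask)
        c_img, _ = generate_sem_field(target_coverage=4.0, seed=12,
                                      image_shape=(128, 128))
        assert not np.array_equal(a_img.pixels, c_img.pixels)

    def test_diameter_distribution_matches_spec(self, spec, rng):
        d = sample_particle_diameters(spec, 10_000, rng)
        assert d.mean() == pytest.approx(2.07, abs=0.02)
        assert d.std(ddof=1) == pytest.approx(0.3, abs=0.02)
        assert d.min() > 0.5

    def test_unreachable_coverage_reports_achieved_maximum(self):
        # Single particles span ~half the tiny fiber: any addition overshoots
        # a 3% target, so the generator must fail and report what it reached.
        with pytest.raises(CoverageUnreachableError) as exc:
            generate_sem_field(target_coverage=3.0, image_shape=(64, 64),
                               pixel_scale=0.07, seed=0)
        assert exc.value.achieved < 3.0

    def test_coarse_pixel_scale_rejected(self):
        with pytest.raises(ValueError, match="4 px"):
            generate_sem_field(pixel_scale=1.0, seed=0)


class TestSkinPair:
    def test_full_cleaning_leaves_no_dark_pixels(self):
        _, t1, truth = generate_skin_pair(40.0, 100.0, seed=2)
        assert truth.t1_dark_fraction == 0.0
        assert t1.truth_mask.sum() == 0

    def test_no_cleaning_keeps_dark_fraction(self):
        t0, t1, truth = generate_skin_pair(40.0, 0.0, seed=2)
        assert truth.t1_dark_fraction == truth.t0_dark_fraction
        assert t0.truth_mask.sum() == t1.truth_mask.sum()

    def test_t1_fraction_is_arithmetic_of_t0(self):
        # 40% baseline, 75% cleanability -> 10% remaining, up to one pixel.
        t0, t1, truth = generate_skin_pair(40.0, 75.0, (256, 256), seed=7)
        one_px = 100.0 / (256 * 256)
        assert truth.t1_dark_fraction == pytest.approx(10.0, abs=one_px)
        # masks are the source of truth
        assert truth.t0_dark_fraction == pytest.approx(
            100.0 * t0.truth_mask.mean(), abs=1e-12)
        assert truth.t1_dark_fraction == pytest.approx(
            100.0 * t1.truth_mask.mean(), abs=1e-12)

    def test_t1_dark_pixels_subset_of_t0(self):
        t0, t1, _ = generate_skin_pair(30.0, 50.0, seed=9)
        assert not np.any(t1.truth_mask & ~t0.truth_mask)


class TestSwatchReadings:
    def test_noiseless_wash_reading_inverts_the_index(self):
        truth = SwatchTruth(L_control=85, L_sebollution=35,
                            true_cleanability=60, replicate_noise_sd=0.0)
        (ctrl, seb, wash), = generate_swatch_readings(truth, 1, seed=0)
        assert wash.L == pytest.approx(65.0, abs=1e-12)
        assert ctrl.L == 85.0 and seb.L == 35.0

    def test_zero_cleanability_keeps_tainted_lightness(self):
        truth = SwatchTruth(true_cleanability=0.0, replicate_noise_sd=0.0)
        (_, seb, wash), = generate_swatch_readings(truth, 1, seed=0)
        assert wash.L == seb.L

    def test_control_noise_sd_is_about_one(self):
        # E[sample sd] for n=6 normal draws is c4(6)*sigma = 0.952*sigma;
        # check the mean over seeds and that ~95% of seeds sit inside the
        # chi-square 95% band for sigma = 1.
        truth = SwatchTruth(replicate_noise_sd=1.0)
        sds = []
        for seed in range(200):
            triples = generate_swatch_readings(truth, 6, seed=seed)
            sds.append(np.std([t[0].L for t in triples], ddof=1))
        sds = np.asarray(sds)
        assert sds.mean() == pytest.approx(0.952, abs=0.08)
        lo = np.sqrt(0.8312 / 5)  # chi2.ppf(0.025, 5) / 5
        hi = np.sqrt(12.8325 / 5)  # chi2.ppf(0.975, 5) / 5
        assert np.mean((sds > lo) & (sds < hi)) > 0.85

    def test_invalid_truth_rejected(self):
        with pytest.raises(ValueError):
            SwatchTruth(L_control=30, L_sebollution=35)
        with pytest.raises(ValueError):
            generate_swatch_readings(SwatchTruth(), n_replicates=0)


class TestStudyTable:
    def test_noiseless_table_recovered_exactly(self):
        table, truth = generate_study_table(6, (0.9, 5.0, 0.0), seed=4)
        fit = site_calibration(table)
        assert fit["slope"] == pytest.approx(0.9, rel=1e-12)
        assert fit["intercept"] == pytest.approx(5.0, rel=1e-9)
        assert fit["r_squared"] == pytest.approx(1.0, abs=1e-12)

    def test_table_shape_and_finiteness(self):
        table, _ = generate_study_table(42, (1.0, 0.0, 5.0), seed=1)
        assert len(table) == 42
        assert np.isfinite(table["forearm_cleanability"]).all()
        assert np.isfinite(table["scalp_cleanability"]).all()

    def test_needs_two_formulae(self):
        with pytest.raises(ValueError):
            generate_study_table(1, (1.0, 0.0, 0.0), seed=0)
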