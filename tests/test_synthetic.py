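from dataclasses import replace

import numpy as np
import pytest

from lqli.profiling import bin_counts, smooth_profile, to_density
from lqli.synthetic import (
    CELLS_PER_MM2_ANCHORS,
    MM2_TO_PER_5000UM2,
    SimulationConfig,
    default_config,
    homogeneous_points,
    intensity_function,
    match_centroids,
    sample_tma_cores,
    simulate_cohort,
    simulate_profile,
    simulate_slide,
    simulate_tma_density,
)


class TestIntensityFunction:
    def test_pattern3_is_flat_at_anchor_density(self):
        lam = intensity_function(default_config(3))
        v = np.linspace(0, 4000, 50)
        np.testing.assert_allclose(lam(v), 392 * MM2_TO_PER_5000UM2)  # 1.96

    def test_pattern2_peak_location_and_height(self):
        cfg = default_config(2)
        lam = intensity_function(cfg)
        v = np.linspace(0, 4000, 8001)
        assert v[np.argmax(lam(v))] == pytest.approx(1600.0, abs=1.0)
        assert lam(1600.0) == pytest.approx(cfg.lambda_out + 6.7)

    def test_pattern2_asymmetric_widths(self):
        lam = intensity_function(default_config(2))
        # 200 um on the host side of the center sits at 1 sigma_out;
        # 200 um on the tumor side at 2 sigma_in: much further down
        rise = lam(1400.0) - 1.5
        fall = lam(1800.0) - 1.5
        assert rise == pytest.approx(6.7 * np.exp(-0.5), rel=1e-6)
        assert fall == pytest.approx(6.7 * np.exp(-2.0), rel=1e-6)

    def test_pattern1_step_and_degenerate_case(self):
        cfg = default_config(1)
        lam = intensity_function(cfg)
        assert lam(1000.0) == cfg.lambda_out
        assert lam(3000.0) == pytest.approx(922 * MM2_TO_PER_5000UM2)  # 4.61
        flat = intensity_function(replace(cfg, lambda_in=cfg.lambda_out))
        np.testing.assert_allclose(flat(np.linspace(0, 4000, 9)), cfg.lambda_out)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(pattern=4, lambda_out=1, lambda_in=1)
        with pytest.raises(ValueError):
            SimulationConfig(pattern=2, lambda_out=-1, lambda_in=1)


class TestSimulateProfile:
    def test_constant_rate_sample_mean(self):
        cfg = SimulationConfig(pattern=3, lambda_out=2.0, lambda_in=2.0)
        sim = simulate_profile(cfg, seed=8)
        assert 1.8 <= sim.profile.density.mean() <= 2.2  # 99% Poisson band at n=800

    def test_same_seed_reproduces(self):
        cfg = default_config(2)
        a = simulate_profile(cfg, seed=13).profile.density
        b = simulate_profile(cfg, seed=13).profile.density
        np.testing.assert_array_equal(a, b)

    def test_zero_intensity_gives_zero_profile(self):
        cfg = SimulationConfig(pattern=3, lambda_out=0.0, lambda_in=0.0)
        assert not simulate_profile(cfg, seed=1).profile.density.any()

    def test_mean_over_seeds_converges_to_intensity(self):
        """Law of large numbers: seed-averaged curves approach lambda(v)."""
        cfg = default_config(2)
        rng = np.random.default_rng(42)
        n = 500
        acc = np.zeros(800)
        for _ in range(n):
            acc += simulate_profile(cfg, rng).profile.density
        mean = acc / n
        centers = np.linspace(2.5, 3997.5, 800)
        lam = intensity_function(cfg)(centers)
        se = np.sqrt(lam / n)
        assert np.mean(np.abs(mean - lam) <= 3 * se + 1e-9) > 0.99


class TestSimulateSlide:
    def test_expected_cell_count(self):
        cfg = default_config(2)
        centers = np.linspace(2.5, 3997.5, 800)
        expected = intensity_function(cfg)(centers).sum()
        counts = [len(simulate_slide(cfg, seed=s).centroids) for s in range(5)]
        for c in counts:
            assert abs(c - expected) <= 3 * np.sqrt(expected)

    def test_zero_density_renders_no_cells(self):
        cfg = SimulationConfig(
            pattern=3, lambda_out=0.0, lambda_in=0.0, width_um=200, length_um=500
        )
        truth = simulate_slide(cfg, seed=2)
        assert len(truth.centroids) == 0

    def test_centroids_inside_image(self):
        cfg = SimulationConfig(
            pattern=1, lambda_out=1.0, lambda_in=4.0, width_um=300, length_um=1000
        )
        truth = simulate_slide(cfg, seed=3)
        h_um, w_um = truth.image.shape_um
        assert (truth.centroids[:, 0] >= 0).all() and (truth.centroids[:, 0] <= w_um).all()
        assert (truth.centroids[:, 1] >= 0).all() and (truth.centroids[:, 1] <= h_um).all()

    def test_profile_shape_recovered_through_detection(self):
        """Slide -> detect -> bin -> density correlates with lambda(v)."""
        from lqli.detection import detect_cells

        cfg = default_config(2)
        rng = np.random.default_rng(6)
        acc = np.zeros(800)
        n_slides = 3
        for _ in range(n_slides):
            truth = simulate_slide(cfg, rng)
            dets = detect_cells(truth.image, truth.roi)
            acc += to_density(bin_counts(dets, truth.roi), truth.roi).density
        from lqli.profiling import DensityProfile

        mean_prof = DensityProfile(bin_edges=truth.roi.bin_edges, density=acc / n_slides)
        smoothed = smooth_profile(mean_prof, 21).density
        centers = np.linspace(2.5, 3997.5, 800)
        lam = intensity_function(cfg)(centers)
        r = np.corrcoef(smoothed, lam)[0, 1]
        assert r >= 0.9


class TestSimulateCohort:
    def test_mixture_proportions(self):
        sims = simulate_cohort(1000, seed=17)
        labels = np.array([s.true_pattern for s in sims])
        props = [np.mean(labels == p) for p in (1, 2, 3)]
        for got, want in zip(props, (0.21, 0.61, 0.18)):
            assert abs(got - want) <= 0.03

    def test_pure_mixture(self):
        sims = simulate_cohort(20, mixture=(1.0, 0.0, 0.0), seed=1)
        assert all(s.true_pattern == 1 for s in sims)

    def test_empty_cohort(self):
        assert simulate_cohort(0, seed=0) == []

    def test_invalid_mixture_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(10, mixture=(0.5, 0.5, 0.5), seed=0)

    def test_pattern2_heights_span_reported_range(self):
        sims = simulate_cohort(300, seed=23)
        heights = [s.config.peak_height for s in sims if s.true_pattern == 2]
        assert min(heights) >= 3.0 and max(heights) <= 14.0
        assert max(heights) - min(heights) > 5.0


class TestTMASampling:
    def test_homogeneous_density_recovered(self):
        """Mean core density over many seeds matches the generating rate."""
        rate = 612.0  # cells/mm^2
        rng = np.random.default_rng(31)
        estimates = []
        for _ in range(100):
            pts = homogeneous_points(rate, 1000.0, 2000.0, rng)
            res = sample_tma_cores(pts, (-500, 500), (0, 2000), seed=rng)
            estimates.append(res.mean_density_per_mm2)
        mean = np.mean(estimates)
        se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(mean - rate) <= 2 * se + 5.0

    def test_zero_density_gives_zero(self):
        res = sample_tma_cores(np.empty((0, 2)), (-500, 500), (0, 2000), seed=0)
        assert res.mean_density_per_mm2 == 0.0

    def test_core_sampling_noisier_than_whole_roi(self):
        """Single 0.6 mm cores vary more than whole-rectangle densities
        on the same pattern-2 truth (the motivation for wide-area counts)."""
        cfg = default_config(2)
        rng = np.random.default_rng(7)
        core_est, roi_est = [], []
        area_mm2 = 4.0
        for _ in range(150):
            from lqli.synthetic import _sample_points_uv  # point process only

            pts = _sample_points_uv(cfg, rng)
            roi_est.append(len(pts) / area_mm2)
            res = sample_tma_cores(pts, (-500, 500), (2000, 4000), n_cores=1, seed=rng)
            core_est.append(res.core_densities_per_mm2[0])
        assert np.var(core_est, ddof=1) > np.var(roi_est, ddof=1)

    def test_slide_truth_wrapper(self):
        cfg = default_config(1)
        truth = simulate_slide(cfg, seed=9)
        res = simulate_tma_density(truth, seed=1)
        assert res.mean_density_per_mm2 > 0
        assert len(res.core_densities_per_mm2) == 3

    def test_region_too_small_rejected(self):
        with pytest.raises(ValueError):
            sample_tma_cores(np.empty((0, 2)), (0, 100), (0, 100), seed=0)


class TestMatchCentroids:
    def test_exact_match(self):
        pts = np.array([[0.0, 0.0], [10.0, 10.0]])
        m = match_centroids(pts, pts + 0.5)
        assert m["n_matched"] == 2 and m["recall"] == 1.0 and m["precision"] == 1.0

    def test_one_to_one_matching(self):
        true = np.array([[0.0, 0.0]])
        dets = np.array([[1.0, 0.0], [0.0, 1.0]])
        m = match_centroids(true, dets)
        assert m["n_matched"] == 1
        assert m["precision"] == 0.5

    def test_out_of_radius_not_matched(self):
        m = match_centroids(np.array([[0.0, 0.0]]), np.array([[10.0, 0.0]]))
        assert m["n_matched"] == 0
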