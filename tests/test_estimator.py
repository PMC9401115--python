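import numpy as np
import pandas as pd
import pytest

import krillsurvey as ks
from krillsurvey.simulate import SurveyScenario, _draw_densities, generate_survey

# Transect-level survey report inputs: raw lengths (n.mile), boundary
# coverage weights and per-transect mean densities (g m^-2).
RAW_LENGTHS = np.array([205.8, 278.7, 275.4, 252.2, 243.3, 72.0])
COVERAGE = np.array([0.5, 1.0, 1.0, 1.0, 1.0, 0.5])
DENSITIES = np.array([5.1, 11.4, 5.4, 5.0, 3.7, 0.1])


def naive_jolly_hampton(densities, lengths):
    """Direct-summation oracle: explicit loops, no shared code path."""
    n = len(densities)
    mean_len = sum(lengths) / n
    w = [length / mean_len for length in lengths]
    num = sum(wj * rj for wj, rj in zip(w, densities))
    rho = num / sum(w)
    ss = sum(wj**2 * (rj - rho) ** 2 for wj, rj in zip(w, densities))
    var = (n / (n - 1)) * ss / sum(w) ** 2
    return rho, var, w


class TestIntervalWeight:
    def test_perfect_track(self):
        assert ks.interval_weight(0.01, 0.01) == 1.0

    def test_deviation_beyond_threshold_kept_raw(self):
        assert ks.interval_weight(1.0, 0.8) == pytest.approx(0.8)

    def test_deviation_within_threshold_snaps_to_one(self):
        assert ks.interval_weight(1.0, 0.95) == 1.0

    def test_zero_planned_change_rejected(self):
        with pytest.raises(ks.ValidationError):
            ks.interval_weight(0.0, 0.01)

    def test_vectorised(self):
        w = ks.interval_weight([1.0, 1.0, -1.0], [0.8, 0.95, -1.0])
        np.testing.assert_allclose(w, [0.8, 1.0, 1.0])


class TestEffectiveLength:
    def test_full_coverage(self):
        iv = pd.DataFrame({"interval_weight": np.ones(100)})
        assert ks.effective_length(iv, 1.0) == 100.0

    def test_boundary_transect_halved(self):
        iv = pd.DataFrame({"interval_weight": np.ones(100)})
        assert ks.effective_length(iv, 0.5) == 50.0

    def test_survey_boundary_transect_value(self):
        # 205.8 n.mile on the boundary -> 102.9 effective
        iv = pd.DataFrame({"interval_weight": np.full(206, 205.8 / 206)})
        assert ks.effective_length(iv, 0.5) == pytest.approx(102.9)

    def test_empty_transect_rejected(self):
        with pytest.raises(ks.ValidationError):
            ks.effective_length(pd.DataFrame({"interval_weight": []}))


class TestJollyHampton:
    def test_survey_report_worked_example(self):
        est = ks.jolly_hampton(DENSITIES, RAW_LENGTHS * COVERAGE)
        np.testing.assert_allclose(
            est.transect_weights, [0.519, 1.407, 1.390, 1.273, 1.228, 0.182], atol=5e-4
        )
        assert est.mean_density == pytest.approx(6.2, abs=0.05)
        assert 100 * est.cv == pytest.approx(24.2, abs=0.5)

    def test_equal_lengths_reduce_to_unweighted_mean(self):
        est = ks.jolly_hampton([2.0, 4.0], [100.0, 100.0])
        assert est.mean_density == pytest.approx(3.0)
        np.testing.assert_allclose(est.transect_weights, [1.0, 1.0])

    def test_matches_naive_oracle_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            n = rng.integers(2, 9)
            dens = rng.gamma(2.0, 3.0, n)
            lens = rng.uniform(30, 300, n)
            est = ks.jolly_hampton(dens, lens)
            rho, var, w = naive_jolly_hampton(dens, lens)
            assert est.mean_density == pytest.approx(rho, rel=1e-12)
            assert est.variance == pytest.approx(var, rel=1e-12)
            np.testing.assert_allclose(est.transect_weights, w, rtol=1e-12)

    def test_weights_sum_to_transect_count(self):
        est = ks.jolly_hampton(DENSITIES, RAW_LENGTHS * COVERAGE)
        assert est.transect_weights.sum() == pytest.approx(6.0)

    def test_scale_equivariance(self):
        est1 = ks.jolly_hampton(DENSITIES, RAW_LENGTHS * COVERAGE)
        est2 = ks.jolly_hampton(3.0 * DENSITIES, RAW_LENGTHS * COVERAGE)
        assert est2.mean_density == pytest.approx(3 * est1.mean_density)
        assert np.sqrt(est2.variance) == pytest.approx(3 * np.sqrt(est1.variance))
        assert est2.cv == pytest.approx(est1.cv)

    def test_single_transect_rejected(self):
        with pytest.raises(ks.ValidationError):
            ks.jolly_hampton([5.0], [100.0])

    def test_negative_density_rejected(self):
        with pytest.raises(ks.ValidationError):
            ks.jolly_hampton([5.0, -1.0], [100.0, 100.0])


class TestBiomass:
    def test_unit_identity(self):
        est = ks.jolly_hampton([1.0, 1.0], [1.0, 1.0])
        est = ks.biomass(est, 1.0)
        assert est.biomass == pytest.approx(1.0)

    def test_survey_area_scaling_with_bounds(self):
        est = ks.jolly_hampton(DENSITIES, RAW_LENGTHS * COVERAGE)
        est = ks.biomass(est, 775732.0)
        assert est.biomass / 1e6 == pytest.approx(4.8, abs=0.05)
        assert est.bounds[0] / 1e6 == pytest.approx(2.5, abs=0.05)
        assert est.bounds[1] / 1e6 == pytest.approx(7.1, abs=0.05)

    def test_bounds_floored_at_zero(self):
        est = ks.jolly_hampton([0.1, 10.0], [100.0, 100.0])
        est = ks.biomass(est, 100.0)
        assert est.bounds[0] == 0.0


class TestEstimateSurvey:
    def test_constant_density_conserved_with_zero_cv(self):
        iv = pd.DataFrame({
            "transect_id": np.repeat(["T1", "T2", "T3"], 10),
            "density": 4.2,
        })
        est = ks.estimate_survey(iv)
        assert est.mean_density == pytest.approx(4.2)
        assert est.cv == pytest.approx(0.0, abs=1e-12)
        assert est.variance == pytest.approx(0.0, abs=1e-12)

    def test_day_only_filter_raises_estimate_when_day_denser(self, default_survey):
        iv = default_survey["intervals"].rename(columns={"density_true": "density"})
        cov = default_survey["truth"]["coverage_weights"]
        all_est = ks.estimate_survey(iv, coverage_weights=cov)
        day_est = ks.estimate_survey(iv, coverage_weights=cov, day_only=True)
        assert day_est.mean_density > all_est.mean_density

    def test_transects_without_intervals_dropped_with_decremented_n(self, caplog):
        iv = pd.DataFrame({
            "transect_id": np.repeat(["T1", "T2", "T3"], 4),
            "density": np.tile([1.0, 2.0, 3.0, 4.0], 3),
            "in_division": np.r_[np.zeros(4, bool), np.ones(8, bool)],
        })
        with caplog.at_level("WARNING"):
            est = ks.estimate_survey(iv)
        assert est.n_transects == 2
        assert "T1" in caplog.text

    def test_interval_weights_downweight_deviant_intervals(self):
        iv = pd.DataFrame({
            "transect_id": np.repeat(["T1", "T2"], 4),
            "density": [8.0, 0.0, 0.0, 0.0, 2.0, 2.0, 2.0, 2.0],
            "interval_weight": [1.0, 0.1, 0.1, 0.1, 1.0, 1.0, 1.0, 1.0],
        })
        est = ks.estimate_survey(iv)
        # T1's weighted mean = 8*1/(1.3) ~ 6.15, not the raw mean 2.0
        assert est.transect_densities[0] == pytest.approx(8.0 / 1.3)
        assert est.effective_lengths[0] == pytest.approx(1.3)


class TestDesignProperties:
    """Frequentist behaviour of the estimator over replicated surveys."""

    def test_unbiased_on_synthetic_surveys(self, default_survey):
        sc = SurveyScenario(seed=0)
        layout = default_survey["intervals"][["transect_id", "lat", "day"]].copy()
        day_frac = default_survey["truth"]["day_fraction"]
        cov = default_survey["truth"]["coverage_weights"]
        rng = np.random.default_rng(77)
        means = np.empty(300)
        for r in range(300):
            iv = layout.copy()
            iv["density"] = _draw_densities(sc, layout, day_frac, rng)
            means[r] = ks.estimate_survey(iv, coverage_weights=cov).mean_density
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - sc.true_mean_density) < 2 * se

    def test_ci_coverage_on_gaussian_field(self):
        """Normal-theory 1.96 bounds on an equal-weight Gaussian-field
        design: the z-for-t approximation at N = 8 transects costs a few
        points of coverage but stays inside the design-based tolerance."""
        layout = pd.DataFrame({"transect_id": np.repeat([f"T{i}" for i in range(8)], 150)})
        rng = np.random.default_rng(88)
        mu = 6.2
        hits = 0
        reps = 800
        for _ in range(reps):
            iv = layout.copy()
            iv["density"] = rng.normal(mu, 3.0, len(layout))
            est = ks.estimate_survey(iv)
            half = 1.96 * est.cv * est.mean_density
            hits += est.mean_density - half <= mu <= est.mean_density + half
        assert 0.88 <= hits / reps <= 0.98
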