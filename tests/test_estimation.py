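"""Tests of the change statistics, binned moments, fits and recovery."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings
from hypothesis import strategies as st

from spinedyn import (
    BinnedChangeStats,
    GeneratorConfig,
    bin_and_summarize,
    choose_shift,
    compute_stepwise_changes,
    fit_size_dependence,
    generate_baseline_dataset,
    lognormal_params_from_moments,
    pooled_change_stats,
    recover_parameters,
    sample_shifted_lognormal,
)
from spinedyn.estimation import EstimationError
from spinedyn.synthetic_data import default_ground_truth


class TestStepwiseChanges:
    def test_consecutive_differences(self):
        out = compute_stepwise_changes(np.array([[1.0, 2.0, 3.0]]))
        assert np.array_equal(out, [[1.0, 1.0]])
        const = compute_stepwise_changes(np.full((4, 5), 0.3))
        assert np.array_equal(const, np.zeros((4, 4)))

    def test_shape_and_missing_propagation(self):
        areas = np.random.default_rng(0).uniform(0.1, 1.0, (20, 8))
        areas[3, 4] = np.nan
        out = compute_stepwise_changes(areas)
        assert out.shape == (20, 7)
        assert np.isnan(out[3, 3]) and np.isnan(out[3, 4])

    def test_single_timepoint_rejected(self):
        with pytest.raises(ValueError):
            compute_stepwise_changes(np.ones((5, 1)))


class TestBinning:
    def test_half_open_bins_anchored_at_zero(self):
        stats = bin_and_summarize([0.10, 0.20, 0.31], [0.0, 0.1, -0.1],
                                  bin_width=0.15, n_boot=10)
        assert np.allclose(stats.bin_edges, [0.0, 0.15, 0.30, 0.45])
        assert list(stats.n) == [1, 1, 1]

    def test_constant_changes(self):
        sizes = np.repeat([0.1, 0.4], 10)
        stats = bin_and_summarize(sizes, np.full(20, 0.7), n_boot=10)
        occ = stats.n > 0
        assert np.allclose(stats.mu_s[occ], 0.7)
        assert np.allclose(stats.sigma_s[occ], 0.0)

    def test_counts_conserve(self, rng):
        v = rng.uniform(0.01, 1.5, 500)
        d = rng.normal(0, 0.07, 500)
        stats = bin_and_summarize(v, d, n_boot=10)
        assert stats.n.sum() == 500

    def test_bootstrap_mean_ci_coverage(self, rng):
        # studentized bootstrap mean CI on normal data: coverage near 95%
        hits = 0
        reps = 300
        for r in range(reps):
            x = rng.normal(0.02, 0.074, 60)
            stats = bin_and_summarize(np.full(60, 0.2), x, n_boot=400, seed=r)
            k = int(np.flatnonzero(stats.n)[0])
            lo, hi = stats.ci_mu[k]
            hits += lo <= 0.02 <= hi
        assert 0.91 <= hits / reps <= 0.99

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bin_and_summarize([], [], n_boot=10)


class TestSizeDependenceFit:
    @staticmethod
    def _stats_on_line(slope_mu, icept_mu, slope_sg, icept_sg, centers):
        edges = np.concatenate([centers - 0.075, [centers[-1] + 0.075]])
        n = np.full(centers.size, 50)
        mu = icept_mu + slope_mu * centers
        sg = icept_sg + slope_sg * centers
        nanci = np.full((centers.size, 2), np.nan)
        return BinnedChangeStats(
            bin_edges=edges, n=n, mu_s=mu, sigma_s=sg,
            ci_mu=nanci, ci_sigma=nanci, usable=n >= 5,
        )

    def test_exact_line_recovered(self):
        centers = np.array([0.225, 0.375, 0.525, 0.675])
        stats = self._stats_on_line(-0.1, 0.05, 0.08, 0.04, centers)
        fit = fit_size_dependence(stats)
        assert fit.slope_mu == pytest.approx(-0.1, abs=1e-12)
        assert fit.intercept_mu == pytest.approx(0.05, abs=1e-12)
        assert fit.slope_sigma == pytest.approx(0.08, abs=1e-12)

    def test_noisy_line_within_2se(self, rng):
        v = rng.uniform(0.05, 1.2, 4000)
        d = (0.05 - 0.1 * v) + rng.normal(0, 0.07, v.size)
        stats = bin_and_summarize(v, d, n_boot=10)
        fit = fit_size_dependence(stats)
        assert abs(fit.slope_mu - (-0.1)) < 2 * fit.stderr["slope_mu"] + 1e-9

    def test_squared_form(self):
        centers = np.array([0.225, 0.375, 0.525, 0.675])
        edges = np.concatenate([centers - 0.075, [centers[-1] + 0.075]])
        n = np.full(4, 50)
        mu = 0.02 - 0.05 * centers**2
        sg = 0.04 + 0.06 * centers**2
        nanci = np.full((4, 2), np.nan)
        stats = BinnedChangeStats(edges, n, mu, sg, nanci, nanci, n >= 5)
        fit = fit_size_dependence(stats, form="linear_in_V_squared")
        assert fit.slope_mu == pytest.approx(-0.05, abs=1e-10)
        assert fit.sigma(0.5) == pytest.approx(0.04 + 0.06 * 0.25, abs=1e-10)

    def test_too_few_bins(self):
        stats = bin_and_summarize([0.2] * 10, np.random.default_rng(0).normal(size=10),
                                  n_boot=10)
        with pytest.raises(EstimationError):
            fit_size_dependence(stats)

    def test_size_dependence_signs(self, study_scale_series):
        # spontaneous data: binned mean change decreases with size while
        # its SD increases (small spines grow and are quiet; large spines
        # shrink and are noisy)
        rec = recover_parameters(study_scale_series, n_boot=20)
        assert rec.raw_fit.slope_mu < 0
        assert rec.raw_fit.slope_sigma > 0


class TestMomentTransform:
    def test_zero_sigma_limit(self):
        p = lognormal_params_from_moments(0.3, 0.0, 1.0)
        assert p.sigma_log == 0.0
        assert p.mu_log == pytest.approx(np.log(1.3))

    def test_domain_error(self):
        with pytest.raises(ValueError):
            lognormal_params_from_moments(-1.5, 0.1, 1.0)

    def test_monte_carlo_roundtrip(self, rng):
        p = lognormal_params_from_moments(0.0, 0.074, 1.0)
        x = sample_shifted_lognormal(p, 10**6, rng)
        assert abs(x.mean()) < 0.01 * 0.074
        assert x.std(ddof=1) == pytest.approx(0.074, rel=0.01)


class TestChooseShift:
    def test_rule_arithmetic(self):
        assert choose_shift([-0.5, 0.5]) == pytest.approx(0.51)
        assert choose_shift([0.1, 0.2]) == pytest.approx(0.001)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=50))
    def test_defining_property(self, changes):
        d = choose_shift(changes)
        assert min(changes) + d > 0


class TestPooledStats:
    def test_closed_form(self):
        ps = pooled_change_stats([-1.0, 1.0])
        assert ps.mu == 0.0
        assert ps.sigma == pytest.approx(np.sqrt(2))

    def test_sampling_distribution(self, rng):
        x = rng.normal(0, 0.074, 5810)
        ps = pooled_change_stats(x)
        se_sd = 0.074 / np.sqrt(2 * 5810)
        assert abs(ps.sigma - 0.074) < 3 * se_sd

    def test_minimum_n(self):
        with pytest.raises(ValueError):
            pooled_change_stats([0.1])


class TestRecovery:
    def test_recovers_ground_truth(self, study_scale_series):
        gt = default_ground_truth()
        rec = recover_parameters(study_scale_series, n_boot=20)
        assert abs(rec.theta_hat - gt.theta) < 3 * rec.se_theta
        assert abs(rec.theta_tilde_hat - gt.theta_tilde) < 3 * rec.se_theta_tilde
        assert rec.drift_identified
        assert abs(rec.mu_tilde_hat - gt.mu_tilde) < 4 * rec.se_mu_tilde
        # the canonical noise fit carries the SD map
        assert rec.fit.slope_sigma == pytest.approx(gt.fit.slope_sigma, abs=0.03)

    def test_null_rates_not_detected(self):
        gt = replace(default_ground_truth(), theta=0.0, theta_tilde=0.0)
        cfg = GeneratorConfig.for_cohort(
            "activity_independent", seed=23, n_spines=600, ground_truth=gt
        )
        data = generate_baseline_dataset(cfg)
        rec = recover_parameters(data, n_boot=20)
        assert abs(rec.theta_hat) < 3 * rec.se_theta
        assert abs(rec.theta_tilde_hat) < 3 * rec.se_theta_tilde

    def test_degenerate_input_raises_cleanly(self):
        with pytest.raises(EstimationError):
            recover_parameters(np.full((50, 8), 0.35))

    def test_too_few_timepoints(self):
        with pytest.raises(EstimationError):
            recover_parameters(np.random.default_rng(0).uniform(0.1, 1, (50, 2)))
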