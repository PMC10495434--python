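"""Unit and property tests for the stochastic spine-dynamics models."""

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from spinedyn import (
    LNNoiseParams,
    LNOUConfig,
    NegMomentumConfig,
    OUConfig,
    SizeDependentFit,
    StimulationModifier,
    WalledGaussianConfig,
    gaussian_walled_step,
    ln_ou_step,
    ln_step,
    lognormal_params_from_moments,
    negative_momentum_step,
    ou_step,
    sample_shifted_lognormal,
    simulate,
    simulate_stimulation_protocol,
)
from spinedyn.core_models import ConfigurationError
from spinedyn.synthetic_data import default_ground_truth


class TestShiftedLognormal:
    def test_degenerate_point_mass(self, rng):
        p = LNNoiseParams(mu_log=0.0, sigma_log=0.0, delta_hat=1.0)
        x = sample_shifted_lognormal(p, 100, rng)
        assert np.allclose(x, 0.0)

    def test_support_bound(self, rng):
        p = lognormal_params_from_moments(0.02, 0.074, 1.0)
        x = sample_shifted_lognormal(p, 10**6, rng)
        assert x.min() > -p.delta_hat

    def test_moments_match_request(self, rng):
        # oracle: the moment transform is exact, so large-sample moments of
        # the draws must approach the requested (mu_s, sigma_s)
        p = lognormal_params_from_moments(0.02, 0.074, 1.0)
        x = sample_shifted_lognormal(p, 10**6, rng)
        assert x.mean() == pytest.approx(0.02, abs=4 * 0.074 / 1000)
        assert x.std(ddof=1) == pytest.approx(0.074, rel=0.01)

    def test_agrees_with_scipy_parameterization(self, rng):
        # independent route: scipy's lognorm with loc = -delta_hat
        p = lognormal_params_from_moments(0.0, 0.1, 0.5)
        x = sample_shifted_lognormal(p, 5000, rng)
        ref = sps.lognorm(s=p.sigma_log, scale=np.exp(p.mu_log), loc=-p.delta_hat)
        stat, pval = sps.kstest(x, ref.cdf)
        assert pval > 0.01

    def test_invalid_n(self, rng):
        p = LNNoiseParams(mu_log=0.0, sigma_log=0.1, delta_hat=1.0)
        with pytest.raises(ValueError):
            sample_shifted_lognormal(p, 0, rng)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        mu_s=st.floats(-0.3, 0.5),
        sigma_s=st.floats(0.001, 0.5),
        delta=st.floats(0.4, 3.0),
    )
    def test_transform_closed_form_roundtrip(self, mu_s, sigma_s, delta):
        # analytic inversion: mean = exp(mu_log + sigma_log^2/2) - delta_hat,
        # var = (exp(sigma_log^2) - 1) exp(2 mu_log + sigma_log^2)
        p = lognormal_params_from_moments(mu_s, sigma_s, delta)
        mean = np.exp(p.mu_log + p.sigma_log**2 / 2) - delta
        var = (np.exp(p.sigma_log**2) - 1) * np.exp(2 * p.mu_log + p.sigma_log**2)
        assert mean == pytest.approx(mu_s, abs=1e-10)
        assert np.sqrt(var) == pytest.approx(sigma_s, rel=1e-9)


class TestWalledGaussian:
    def test_zero_noise_identity(self, rng):
        cfg = WalledGaussianConfig(mu=0.0, sigma=0.0, wall_left=0.0, wall_right=2.0)
        v = np.array([0.3, 0.5, 1.9])
        assert np.array_equal(gaussian_walled_step(v, cfg, rng), v)

    def test_no_change_clamp_at_wall(self, rng):
        cfg = WalledGaussianConfig(mu=1.0, sigma=0.0, wall_left=0.0, wall_right=2.0)
        v = np.array([2.0])  # proposal 3.0 exits -> no change
        assert gaussian_walled_step(v, cfg, rng)[0] == 2.0

    def test_bounce_mechanism_reflects(self, rng):
        cfg = WalledGaussianConfig(
            mu=1.0, sigma=0.0, wall_left=0.0, wall_right=2.0, mechanism="bounce"
        )
        v = np.array([1.5])  # proposal 2.5 reflects to 1.5
        assert gaussian_walled_step(v, cfg, rng)[0] == pytest.approx(1.5)

    def test_left_wall_pileup_and_rising_mean(self, rng):
        # driftless run: the wall folds sub-wall mass up, so compared with an
        # unwalled walk there is extra mass just above the wall, none below
        # it, and the population mean rises
        init = rng.lognormal(np.log(0.32), 0.55, size=2000)
        wl, wr = np.percentile(init, 5), init.max()
        cfg = WalledGaussianConfig(mu=0.0, sigma=0.074, wall_left=wl, wall_right=wr)
        free = WalledGaussianConfig(mu=0.0, sigma=0.074, wall_left=-1e9,
                                    wall_right=1e9)
        walled = simulate(cfg, init, 150, seed=3).sizes[:, -1]
        unwalled = simulate(free, init, 150, seed=3).sizes[:, -1]
        assert walled.min() >= wl
        assert (unwalled < wl).mean() > 0.02  # the free walk does go below
        band = (wl, wl + 0.1)
        in_band = lambda x: np.mean((x >= band[0]) & (x < band[1]))
        assert in_band(walled) > in_band(unwalled)
        assert walled.mean() > init.mean()

    def test_invalid_walls(self):
        with pytest.raises(ConfigurationError):
            WalledGaussianConfig(mu=0, sigma=0.1, wall_left=1.0, wall_right=0.5)


class TestOU:
    def test_fixed_point_and_full_reversion(self, rng):
        cfg = OUConfig(theta=0.3, mu_bar=0.4, sigma=0.0)
        v = np.full(5, 0.4)
        assert np.allclose(ou_step(v, cfg, rng), 0.4)
        cfg1 = OUConfig(theta=1.0, mu_bar=0.4, sigma=0.0)
        assert np.allclose(ou_step(np.array([0.1, 2.0]), cfg1, rng), 0.4)

    def test_stationary_variance_closed_form(self):
        theta, sigma = 0.2, 0.074
        cfg = OUConfig(theta=theta, mu_bar=0.35, sigma=sigma)
        trace = simulate(cfg, np.full(4000, 0.35), 200, seed=5)
        final = trace.sizes[:, -1]
        expected = sigma**2 / (1 - (1 - theta) ** 2)
        mc_se = expected * np.sqrt(2 / (final.size - 1))
        assert abs(final.var(ddof=1) - expected) < 3 * mc_se


class TestNegativeMomentum:
    def test_deterministic_arithmetic(self, rng):
        cfg = NegMomentumConfig(theta=0.5, sigma=0.0)
        out = negative_momentum_step(np.array([1.0]), np.array([2.0]), cfg, rng)
        assert out[0] == pytest.approx(1.5)
        same = negative_momentum_step(np.array([2.0]), np.array([2.0]), cfg, rng)
        assert same[0] == pytest.approx(2.0)

    def test_length_mismatch(self, rng):
        cfg = NegMomentumConfig(theta=0.5, sigma=0.0)
        with pytest.raises(ValueError):
            negative_momentum_step(np.zeros(2), np.zeros(3), cfg, rng)

    @pytest.mark.parametrize("theta", [0.1, 0.3, 0.5])
    def test_lag1_change_correlation_is_minus_theta(self, theta):
        # dV_{i+1} = -theta dV_i + eta is AR(1): corr(dV_{i+1}, dV_i) = -theta
        cfg = NegMomentumConfig(theta=theta, sigma=0.074)
        trace = simulate(cfg, np.full(4000, 0.35), 60, seed=int(theta * 10))
        ch = np.diff(trace.sizes[:, 10:], axis=1)
        r = np.corrcoef(ch[:, :-1].ravel(), ch[:, 1:].ravel())[0, 1]
        assert r == pytest.approx(-theta, abs=0.02)


class TestLNSteps:
    def test_point_mass_noise_limit(self, rng):
        fit = SizeDependentFit(
            slope_mu=0.0, intercept_mu=0.05, slope_sigma=0.0,
            intercept_sigma=1e-9, valid_range=(0.01, 2.0),
        )
        v = np.array([0.2, 0.5, 1.0])
        out = ln_step(v, fit, delta_hat=1.0, size_floor=0.01, rng=rng)
        assert np.allclose(out, v + 0.05, atol=1e-6)

    def test_sigma_validation_names_size(self, rng):
        fit = SizeDependentFit(
            slope_mu=0.0, intercept_mu=0.0, slope_sigma=-0.1,
            intercept_sigma=0.05, valid_range=(0.01, 0.4),
        )
        with pytest.raises(ConfigurationError, match="0.9"):
            ln_step(np.array([0.2, 0.9]), fit, 1.0, 0.01, rng)

    def test_pooled_changes_gaussian(self, rng):
        # population change of many spines is approximately normal
        gt = default_ground_truth()
        v = rng.lognormal(np.log(0.32), 0.55, 830)
        changes = []
        cur = np.maximum(v, 0.01)
        for i in range(7):
            nxt = ln_step(cur, gt.fit, gt.delta_hat, gt.size_floor,
                          np.random.default_rng(100 + i))
            changes.append(nxt - cur)
            cur = nxt
        d = np.concatenate(changes)
        sub = np.random.default_rng(1).choice(d, 500, replace=False)
        _, p = sps.kstest(sub, "norm", args=(sub.mean(), sub.std(ddof=1)))
        assert p > 0.05

    def test_declining_mean_under_decreasing_fmu(self, rng):
        # decreasing mean map / increasing SD map: population mean drifts down
        fit = SizeDependentFit(
            slope_mu=-0.1, intercept_mu=0.02, slope_sigma=0.085,
            intercept_sigma=0.0375, valid_range=(0.01, 5.0),
        )
        cfg = LNOUConfig(fit=fit, theta=0.0, theta_tilde=0.0, mu_tilde=0.35,
                         delta_hat=1.0)
        init = np.maximum(rng.lognormal(np.log(0.4), 0.5, 2000), 0.01)
        trace = simulate(cfg, init, 30, seed=9)
        means = trace.sizes.mean(axis=0)
        assert means[-1] < means[0] - 0.02

    def test_lnou_reduces_to_ln_when_rates_zero(self):
        gt = default_ground_truth()
        v = np.linspace(0.1, 1.0, 50)
        prev = v + 0.05
        cfg0 = LNOUConfig(fit=gt.fit, theta=0.0, theta_tilde=0.0,
                          mu_tilde=gt.mu_tilde, delta_hat=gt.delta_hat)
        a = ln_ou_step(prev, v, cfg0, np.random.default_rng(42))
        b = ln_step(v, gt.fit, gt.delta_hat, cfg0.size_floor,
                    np.random.default_rng(42))
        assert np.array_equal(a, b)

    def test_noise_suppressed_reduces_to_ou(self, rng):
        fit = SizeDependentFit(
            slope_mu=0.0, intercept_mu=0.0, slope_sigma=0.0,
            intercept_sigma=1e-12, valid_range=(0.01, 2.0),
        )
        cfg = LNOUConfig(fit=fit, theta=0.0, theta_tilde=0.2, mu_tilde=0.4,
                         delta_hat=1.0)
        v = np.array([0.2, 0.6])
        out = ln_ou_step(v, v, cfg, rng)
        expect = v + 0.2 * (0.4 - v)
        assert np.allclose(out, expect, atol=1e-6)

    def test_size_floor_applied_and_counted(self):
        fit = SizeDependentFit(
            slope_mu=0.0, intercept_mu=-0.5, slope_sigma=0.0,
            intercept_sigma=0.01, valid_range=(0.01, 2.0),
        )
        cfg = LNOUConfig(fit=fit, theta=0.0, theta_tilde=0.0, mu_tilde=0.35,
                         delta_hat=1.0, size_floor=0.01)
        trace = simulate(cfg, np.full(100, 0.1), 5, seed=0)
        assert trace.sizes.min() >= cfg.size_floor
        assert trace.floor_hits > 0


class TestSimulate:
    def test_zero_steps_returns_init(self):
        cfg = OUConfig(theta=0.1, mu_bar=0.35, sigma=0.05)
        init = np.array([0.2, 0.4])
        trace = simulate(cfg, init, 0, seed=1)
        assert trace.sizes.shape == (2, 1)
        assert np.array_equal(trace.sizes[:, 0], init)

    def test_seed_determinism(self):
        gt = default_ground_truth()
        init = np.linspace(0.1, 1.0, 30)
        a = simulate(gt, init, 10, seed=123)
        b = simulate(gt, init, 10, seed=123)
        assert np.array_equal(a.sizes, b.sizes)
        c = simulate(gt, init, 10, seed=124)
        assert not np.array_equal(a.sizes, c.sizes)

    def test_first_momentum_step_has_no_kick(self, rng):
        # V_{-1} = V_0: with zero noise, a pure-momentum model must not move
        cfg = NegMomentumConfig(theta=0.9, sigma=0.0)
        trace = simulate(cfg, np.array([0.3, 0.8]), 1, seed=0)
        assert np.array_equal(trace.sizes[:, 1], trace.sizes[:, 0])

    def test_empty_init_rejected(self):
        with pytest.raises(ValueError):
            simulate(OUConfig(theta=0.1, mu_bar=0.3, sigma=0.05), [], 5, seed=0)


class TestStimulationProtocol:
    def test_null_modifier_matches_plain_simulate(self):
        gt = default_ground_truth()
        mod = StimulationModifier(
            stim_fit=gt.fit, delta_mu=0.0, disable_momentum_at_stim=False
        )
        init = np.linspace(0.1, 1.0, 40)
        a = simulate_stimulation_protocol(gt, mod, 2, 4, init, seed=5)
        b = simulate(gt, init, 7, seed=5)
        assert np.array_equal(a.sizes, b.sizes)
        assert a.step_labels == ("baseline",) * 2 + ("stimulation",) + ("post",) * 4

    def test_infinite_tau_gives_constant_shifted_target(self):
        gt = default_ground_truth()
        mod = StimulationModifier(stim_fit=gt.fit, delta_mu=0.2, tau=np.inf)
        for t in (0, 5, 100):
            assert mod.drift_target(gt, t) == pytest.approx(gt.mu_tilde + 0.2)
        mod_decay = StimulationModifier(stim_fit=gt.fit, delta_mu=0.2, tau=3.0)
        assert mod_decay.drift_target(gt, 0) == pytest.approx(gt.mu_tilde + 0.2)
        assert mod_decay.drift_target(gt, 9) == pytest.approx(
            gt.mu_tilde + 0.2 * np.exp(-3.0)
        )

    def test_stim_fit_only_transient(self, rng):
        # fast-component-only stimulation: mean jumps then relaxes back
        from spinedyn.synthetic_data import default_stim_modifier
        from dataclasses import replace

        gt = default_ground_truth()
        mod = replace(default_stim_modifier("stim15"), delta_mu=0.0)
        raw = np.maximum(rng.lognormal(np.log(0.32), 0.55, 500), gt.size_floor)
        init = simulate(gt, raw, 40, seed=2).sizes[:, -1]
        tr = simulate_stimulation_protocol(gt, mod, 2, 50, init, seed=3)
        m = tr.sizes.mean(axis=0)
        jump = m[3] - m[2]
        assert jump > 0.05
        assert m[-1] - m[2] < 0.5 * jump

    def test_invalid_schedule(self):
        gt = default_ground_truth()
        mod = StimulationModifier(stim_fit=gt.fit)
        with pytest.raises(ValueError):
            simulate_stimulation_protocol(gt, mod, 0, 4, np.ones(3), seed=0)
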