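"""Timing and shape priors: solving, fitting, density, and sampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.optimize import bisect
from pulsedecon.model import impulse_response
from pulsedecon.priors import (
    LatentState,
    PriorSet,
    ShapePrior,
    constrained_gamma_loglik,
    fit_interval_prior,
    fit_shape_prior,
    log_prior,
    normalize_intervals,
    sample_prior,
    solve_heart_rate_prior,
)
from pulsedecon.templates import synthetic_pulse_templates


class TestHeartRatePrior:
    def test_range_mass_is_exact(self):
        tp = solve_heart_rate_prior(30.0, 150.0, 0.99999)
        assert abs(tp.range_mass() - 0.99999) < 1e-9

    def test_equal_tails(self):
        tp = solve_heart_rate_prior()
        d = tp.hr_dist
        assert d.cdf(0.5) == pytest.approx(5e-6, rel=1e-4)
        assert d.sf(2.5) == pytest.approx(5e-6, rel=1e-4)

    def test_mean_inside_band(self):
        tp = solve_heart_rate_prior()
        assert 0.5 < tp.mean_hr < 2.5

    def test_against_independent_bisection(self):
        # independent route: bisect alpha on the upper-tail gap, solving
        # lambda from the lower-tail condition at every step
        tail = 5e-6

        def gap(alpha):
            lam = stats.gamma.ppf(tail, alpha) / 0.5
            return stats.gamma.sf(2.5, alpha, scale=1 / lam) - tail

        alpha_ref = bisect(gap, 2.0, 2000.0, xtol=1e-10)
        lam_ref = stats.gamma.ppf(tail, alpha_ref) / 0.5
        tp = solve_heart_rate_prior()
        assert tp.alpha_hr == pytest.approx(alpha_ref, rel=1e-6)
        assert tp.lambda_hr == pytest.approx(lam_ref, rel=1e-6)

    def test_constrained_interval_gamma_has_mean_one(self):
        tp = solve_heart_rate_prior(alpha_zpp=123.0)
        assert tp.zpp_dist.mean() == pytest.approx(1.0, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            solve_heart_rate_prior(150.0, 30.0)
        with pytest.raises(ValueError):
            solve_heart_rate_prior(mass=1.5)


class TestNormalizeIntervals:
    def test_constant_intervals(self):
        np.testing.assert_allclose(normalize_intervals([1.0, 1.0, 1.0]), 1.0)

    def test_mean_one_preserved(self):
        z = normalize_intervals([0.5, 1.5])
        np.testing.assert_allclose(z, [0.5, 1.5])
        assert z.mean() == pytest.approx(1.0)

    @settings(max_examples=30, deadline=None)
    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance(self, c):
        iv = np.array([0.7, 0.9, 1.1, 0.8])
        np.testing.assert_allclose(normalize_intervals(iv * c),
                                   normalize_intervals(iv), rtol=1e-9)

    def test_rejects_short_or_negative(self):
        with pytest.raises(ValueError):
            normalize_intervals([1.0])
        with pytest.raises(ValueError):
            normalize_intervals([1.0, -0.5])


class TestIntervalPriorFit:
    def test_parameter_recovery_within_2pct(self):
        rng = np.random.default_rng(1)
        z = rng.gamma(25.0, 1.0 / 25.0, size=100_000)
        alpha_hat = fit_interval_prior(z)
        assert abs(alpha_hat - 25.0) / 25.0 < 0.02
        # cross-check with a grid search over the same likelihood
        grid = np.linspace(20.0, 30.0, 2001)
        lls = [constrained_gamma_loglik(z, a) for a in grid]
        assert abs(grid[int(np.argmax(lls))] - alpha_hat) < 0.01

    def test_degenerate_input_clamps_with_warning(self):
        with pytest.warns(RuntimeWarning):
            alpha = fit_interval_prior(np.ones(50))
        assert alpha >= 1e6

    def test_cv_moment_identity(self):
        rng = np.random.default_rng(2)
        z = rng.gamma(100.0, 1.0 / 100.0, size=200_000)
        alpha_hat = fit_interval_prior(z)
        cv = z.std() / z.mean()
        assert cv == pytest.approx(1.0 / np.sqrt(alpha_hat), rel=0.02)


class TestShapePriorFit:
    def test_self_consistency_recovery(self, priors):
        # shapes generated exactly by the model are recovered almost exactly
        sp = priors.shape
        rng = np.random.default_rng(3)
        t = np.arange(-0.3, 1.8, 1 / 64)
        shapes = []
        for _ in range(6):
            w = rng.multivariate_normal(sp.mu_w, sp.Sigma_w, method="cholesky")
            shapes.append((t, impulse_response(t, sp.make_shape(1.3, w))))
        fitted = fit_shape_prior(shapes, K=sp.K, f_h=sp.f_h,
                                 g_init=sp.window_params, ridge=1e-9)
        # residual of the joint fit: refit the linear part at the fitted
        # window and compare against the generated shapes
        from pulsedecon.priors import _fit_linear_given_window
        coefs, ssr = _fit_linear_given_window(
            [(t_, v_) for t_, v_ in shapes],
            np.array(fitted.window_params), sp.K, sp.f_h, ridge=1e-9)
        total = sum(float(v @ v) for _, v in shapes)
        # residual norm below 1e-4 of the shape norm
        assert np.sqrt(ssr / total) < 1e-4

    def test_identical_shapes_give_floor_covariance(self):
        t, v = synthetic_pulse_templates(n=1)[0]
        fitted = fit_shape_prior([(t, v), (t, v), (t, v)])
        eig = np.linalg.eigvalsh(fitted.Sigma_w)
        assert eig.max() < 1e-6  # regularization floor only

    def test_mu_is_mean_of_fitted_weights(self):
        shapes = synthetic_pulse_templates(n=8)
        fitted = fit_shape_prior(shapes)
        from pulsedecon.priors import _fit_linear_given_window

        def pad(t, v):
            dt = float(np.median(np.diff(t)))
            n_l, n_r = round(0.4 / dt), round(0.6 / dt)
            tp = np.concatenate([t[0] - dt * np.arange(n_l, 0, -1), t,
                                 t[-1] + dt * np.arange(1, n_r + 1)])
            vp = np.concatenate([np.zeros(n_l), v, np.zeros(n_r)])
            return tp, vp

        coefs, _ = _fit_linear_given_window(
            [pad(t, v) for t, v in shapes],
            np.array(fitted.window_params), fitted.K, fitted.f_h, ridge=1e-3)
        ws = coefs[:, 1:] / coefs[:, :1]
        np.testing.assert_allclose(fitted.mu_w, ws.mean(axis=0), rtol=1e-8)

    def test_too_few_shapes_rejected(self):
        t, v = synthetic_pulse_templates(n=1)[0]
        with pytest.raises(ValueError):
            fit_shape_prior([(t, v)])

    def test_parameter_recovery_small_basis(self):
        # mu within 5% relative, Sigma diagonal within 20%, K=8, 200 draws;
        # the truth window is steep enough that the pulse vanishes inside
        # the grid (zero-padding is then consistent with the model)
        rng = np.random.default_rng(5)
        g = (30.0, 0.05, 14.0, 0.75)
        mu = np.array([0.8, -0.4, 0.3, 0.5, -0.2, 0.1, 0.05, -0.1])
        sd = np.array([0.08, 0.06, 0.05, 0.05, 0.04, 0.03, 0.02, 0.02])
        Sigma = np.diag(sd**2)
        truth = ShapePrior(mu_w=mu, Sigma_w=Sigma, g1=g[0], g2=g[1],
                           g3=g[2], g4=g[3], f_h=0.5)
        t = np.arange(-0.15, 1.65, 1 / 64)
        shapes = []
        for _ in range(200):
            w = rng.multivariate_normal(mu, Sigma)
            shapes.append((t, impulse_response(t, truth.make_shape(1.0, w))))
        fitted = fit_shape_prior(shapes, K=8, f_h=0.5, g_init=g, ridge=1e-9,
                                 pad=(0.08, 0.1))
        assert np.linalg.norm(fitted.mu_w - mu) / np.linalg.norm(mu) < 0.05
        ratio = np.diag(fitted.Sigma_w) / sd**2
        assert np.all(ratio > 0.8) and np.all(ratio < 1.2)


class TestLogPriorAndSampling:
    def test_anchor_outside_support_is_minus_inf(self, priors):
        st_ = sample_prior((0.0, 10.0), priors, seed=0)
        bad = LatentState(f_hr=st_.f_hr, zpp=st_.zpp, z_m=st_.t0 - 0.1,
                          m=st_.m, t0=st_.t0, w=st_.w)
        assert log_prior(bad, priors) == -np.inf

    def test_mean_weights_maximize_shape_term(self, priors):
        st_ = sample_prior((0.0, 10.0), priors, seed=1)
        at_mu = LatentState(f_hr=st_.f_hr, zpp=st_.zpp, z_m=st_.z_m,
                            m=st_.m, t0=st_.t0, w=priors.shape.mu_w)
        rng = np.random.default_rng(5)
        for _ in range(5):
            w = rng.multivariate_normal(priors.shape.mu_w, priors.shape.Sigma_w)
            other = LatentState(f_hr=st_.f_hr, zpp=st_.zpp, z_m=st_.z_m,
                                m=st_.m, t0=st_.t0, w=w)
            assert log_prior(at_mu, priors) >= log_prior(other, priors)

    def test_density_matches_term_by_term_oracle(self, priors):
        st_ = sample_prior((0.0, 10.0), priors, seed=2)
        tp, sp = priors.timing, priors.shape
        # independent recomputation, one scipy logpdf per factor
        expected = stats.gamma.logpdf(st_.f_hr, tp.alpha_hr,
                                      scale=1 / tp.lambda_hr)
        expected += stats.gamma.logpdf(np.asarray(st_.zpp), tp.alpha_zpp,
                                       scale=1 / tp.alpha_zpp).sum()
        width = st_.zpp[st_.m - 2] / st_.f_hr
        expected += stats.uniform.logpdf(st_.z_m, loc=st_.t0, scale=width)
        expected += stats.multivariate_normal.logpdf(
            st_.w, mean=sp.mu_w, cov=sp.Sigma_w, allow_singular=True)
        assert log_prior(st_, priors) == pytest.approx(expected, rel=1e-9)

    def test_sampled_heart_rate_respects_range(self, priors):
        rng = np.random.default_rng(6)
        tp = priors.timing
        draws = rng.gamma(tp.alpha_hr, 1 / tp.lambda_hr, size=100_000)
        frac = np.mean((draws >= 0.5) & (draws <= 2.5))
        assert frac >= 0.9999

    def test_sampled_pulses_cover_window(self, priors):
        for seed in range(20):
            st_ = sample_prior((0.0, 11.0), priors, seed=seed)
            z = st_.timing.z
            assert z[0] < 0.0 and z[-1] > 11.0
            # anchor is the first pulse after the window center
            assert z[st_.m - 1] > st_.t0 >= z[st_.m - 2]

    def test_normalized_interval_mean_is_one(self, priors):
        rng = np.random.default_rng(7)
        tp = priors.timing
        n = 1_000_000
        draws = rng.gamma(tp.alpha_zpp, 1 / tp.alpha_zpp, size=n)
        se = draws.std() / np.sqrt(n)
        assert abs(draws.mean() - 1.0) < 3 * se


class TestPriorSetSerialization:
    def test_json_round_trip(self, priors, tmp_path):
        p = tmp_path / "priors.json"
        priors.save(p)
        loaded = PriorSet.load(p)
        np.testing.assert_allclose(loaded.shape.mu_w, priors.shape.mu_w, rtol=1e-12)
        np.testing.assert_allclose(loaded.shape.Sigma_w, priors.shape.Sigma_w, rtol=1e-12)
        assert loaded.timing.alpha_hr == priors.timing.alpha_hr
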