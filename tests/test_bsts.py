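"""Structural time-series core: filtering, state sampling, spike-and-slab."""

import numpy as np
import pytest
from scipy import stats

from searchimpact.bsts import (
    InsufficientDataError,
    PosteriorDraws,
    SpikeSlabPrior,
    TrendSpec,
    build_state_space,
    fit_bsts,
    kalman_filter,
    kalman_smooth,
    posterior_predict,
    sample_regression,
    sample_states,
)
from searchimpact.panel import ConfigurationError


def _local_level_model(sigma_level, sigma_obs, a0=0.0, p0=1.0):
    """Local level with the seasonal block silenced (pure level dynamics)."""
    model = build_state_space("local_level", S=2)
    model.sigma_level = sigma_level
    model.sigma_obs = sigma_obs
    model.sigma_seasonal = 0.0
    model.a0 = np.array([a0, 0.0])
    model.P0 = np.diag([p0, 0.0])
    return model


class TestBuildStateSpace:
    @pytest.mark.parametrize(
        "kind,expected",
        [("local_level", 12), ("local_linear", 13),
         ("semilocal_linear", 13), ("student_local_linear", 13)],
    )
    def test_state_dimensions(self, kind, expected):
        assert build_state_space(kind, S=12).state_dim == expected

    def test_semilocal_with_unit_persistence_equals_local_linear(self):
        semi = build_state_space(TrendSpec("semilocal_linear", ar_persistence=1.0, slope_mean=0.0))
        ll = build_state_space("local_linear")
        Ts, cs = semi.transition()
        Tl, cl = ll.transition()
        assert np.array_equal(Ts, Tl)
        assert np.array_equal(cs, np.zeros_like(cs))

    def test_small_period_rejected(self):
        with pytest.raises(ConfigurationError):
            build_state_space("local_level", S=1)


class TestKalmanFilter:
    def test_noiseless_constant_series_tracked_exactly(self):
        model = _local_level_model(0.0, 0.0, a0=5.0, p0=4.0)
        y = np.full(6, 5.0)
        res = kalman_filter(model, y)
        assert np.allclose(res.filtered_mean[:, 0], 5.0)

    def test_conjugate_normal_updating_oracle(self):
        # static level (sigma_level = 0): posterior after t obs has
        # precision 1/p0 + t/r2 and mean precision-weighted
        a0, p0, r = 1.0, 4.0, 0.8
        y = np.array([2.0, 2.5, 1.7])
        model = _local_level_model(0.0, r, a0=a0, p0=p0)
        res = kalman_filter(model, y)
        for t in range(3):
            prec = 1 / p0 + (t + 1) / r**2
            mean = (a0 / p0 + y[: t + 1].sum() / r**2) / prec
            assert res.filtered_mean[t, 0] == pytest.approx(mean, abs=1e-8)
            assert res.filtered_cov[t, 0, 0] == pytest.approx(1 / prec, abs=1e-8)

    @pytest.mark.parametrize("n", [1, 3, 5])
    def test_matches_direct_joint_gaussian_conditioning(self, n):
        # joint normal of (mu_1..mu_n, y_1..y_n) built from first principles
        a0, p0, q, r = 0.5, 2.0, 0.7, 1.1
        rng = np.random.default_rng(5)
        y = rng.normal(0, 2, n)
        model = _local_level_model(q, r, a0=a0, p0=p0)
        res = kalman_filter(model, y)
        cov_mu = np.empty((n, n))
        for s in range(n):
            for t in range(n):
                cov_mu[s, t] = p0 + q**2 * min(s, t)
        cov_y = cov_mu + r**2 * np.eye(n)
        mean_mu = np.full(n, a0)
        for t in range(n):
            S = cov_y[: t + 1, : t + 1]
            c = cov_mu[t, : t + 1]
            sol = np.linalg.solve(S, y[: t + 1] - a0)
            post_mean = a0 + c @ sol
            post_var = cov_mu[t, t] - c @ np.linalg.solve(S, c)
            assert res.filtered_mean[t, 0] == pytest.approx(post_mean, abs=1e-8)
            assert res.filtered_cov[t, 0, 0] == pytest.approx(post_var, abs=1e-8)

    def test_steady_state_gain_closed_form(self):
        # local level signal-to-noise q: K_ss = (-q + sqrt(q^2 + 4q)) / 2
        for q in (0.1, 1.0, 3.0):
            model = _local_level_model(np.sqrt(q), 1.0, a0=0.0, p0=1.0)
            y = np.zeros(300)
            from searchimpact.bsts import _model_arrays
            from searchimpact import _ssm

            args = _model_arrays(model, y)
            _, _, _, _, _, F, K, _, _ = _ssm.kalman_filter_core(*args)
            k_ss = (-q + np.sqrt(q**2 + 4 * q)) / 2
            assert K[-1][0] == pytest.approx(k_ss, abs=1e-6)

    def test_missing_values_use_prediction_only_updates(self):
        model = _local_level_model(0.5, 1.0, a0=0.0, p0=10.0)
        y = np.array([1.0, np.nan, np.nan, 1.0])
        res = kalman_filter(model, y)
        # no update during the gap: filtered mean stays flat, variance grows
        assert res.filtered_mean[1, 0] == pytest.approx(res.filtered_mean[0, 0])
        assert res.filtered_cov[2, 0, 0] > res.filtered_cov[0, 0, 0]


class TestSampleStates:
    def test_zero_variances_give_deterministic_filtered_path(self):
        model = _local_level_model(0.0, 0.0, a0=3.0, p0=0.0)
        y = np.full(8, 3.0)
        draw = sample_states(model, y, np.random.default_rng(0))
        assert np.allclose(draw[:, 0], 3.0, atol=1e-4)

    def test_mean_of_draws_matches_smoother(self):
        model = _local_level_model(0.6, 1.0, a0=0.0, p0=5.0)
        rng = np.random.default_rng(8)
        y = np.cumsum(rng.normal(0, 0.6, 10)) + rng.normal(0, 1, 10)
        smooth = kalman_smooth(model, y)[:, 0]
        draws = np.array(
            [sample_states(model, y, np.random.default_rng(100 + i))[:, 0] for i in range(2000)]
        )
        mc_se = draws.std(axis=0) / np.sqrt(len(draws))
        assert np.all(np.abs(draws.mean(axis=0) - smooth) < 3 * mc_se)

    def test_reproducible_given_rng_seed(self):
        model = _local_level_model(0.5, 1.0)
        y = np.sin(np.arange(12) / 3.0)
        d1 = sample_states(model, y, np.random.default_rng(42))
        d2 = sample_states(model, y, np.random.default_rng(42))
        assert np.array_equal(d1, d2)


class TestSampleRegression:
    def test_spike_only_prior_forces_zero_coefficients(self, rng):
        X = rng.normal(size=(50, 3))
        y = X @ np.array([1.0, 2.0, -1.0]) + rng.normal(0, 0.1, 50)
        prior = SpikeSlabPrior(inclusion_probabilities=np.zeros(3))
        for _ in range(10):
            gamma, beta, sigma = sample_regression(y, X, prior, rng)
            assert np.all(beta == 0.0)
            assert not gamma.any()

    def test_two_model_bayes_factor_oracle(self):
        # single covariate: exact posterior inclusion probability from the
        # normal-inverse-gamma marginal (multivariate-t density of y)
        rng = np.random.default_rng(3)
        n = 40
        x = rng.normal(size=(n, 1))
        y = 0.45 * x[:, 0] + rng.normal(0, 1, n)
        y = y - y.mean()
        prior = SpikeSlabPrior(inclusion_probabilities=np.array([0.5]))
        kappa = 0.01 * n
        A = (kappa / n) * (x.T @ x).item()
        df0 = max(0.01 * n, 1.0)
        ss0 = df0 * 0.5 * np.var(y)
        scale0 = (ss0 / df0) * np.eye(n)
        scale1 = (ss0 / df0) * (np.eye(n) + (x @ x.T) / A)
        m0 = stats.multivariate_t.logpdf(y, loc=np.zeros(n), shape=scale0, df=df0)
        m1 = stats.multivariate_t.logpdf(y, loc=np.zeros(n), shape=scale1, df=df0)
        p_oracle = 1.0 / (1.0 + np.exp(m0 - m1))
        draws = []
        r = np.random.default_rng(17)
        for _ in range(500):
            gamma, _, _ = sample_regression(y, x, prior, r)
            draws.append(int(gamma[0]))
        p_hat = np.mean(draws)
        mc_se = max(np.sqrt(p_oracle * (1 - p_oracle) / 500), 1e-3)
        assert abs(p_hat - p_oracle) < 3 * mc_se

    def test_duplicated_covariates_get_equal_inclusion(self):
        # exactly duplicated columns are exchangeable conditional on y
        rng = np.random.default_rng(6)
        x = rng.normal(size=80)
        X = np.column_stack([x, x])
        y = 0.8 * x + rng.normal(0, 1, 80)
        y = y - y.mean()
        prior = SpikeSlabPrior(inclusion_probabilities=np.array([0.5, 0.5]))
        freq = np.zeros(2)
        r = np.random.default_rng(9)
        gamma = None
        n_draws = 1500
        for i in range(n_draws + 100):
            gamma, _, _ = sample_regression(y, X, prior, r, gamma=gamma)
            if i >= 100:  # burn-in before tallying the chain
                freq += gamma
        freq /= n_draws
        assert freq.min() > 0.1  # both are genuine candidates
        assert abs(freq[0] - freq[1]) < 0.1


class TestFitBsts:
    def test_iteration_and_burnin_accounting(self, small_series):
        y = small_series.panel.response[("SYN", "synthetic")][:72]
        draws = fit_bsts(y, trend_spec="local_level", n_iterations=50, burn_in=10, seed=1)
        assert draws.n_iterations == 50
        assert draws.n_kept == 40
        assert draws.states.shape == (40, 72, 12)

    def test_zero_variance_series_converges_without_crash(self):
        y = np.full(48, 37.0)
        draws = fit_bsts(y, trend_spec="local_level", n_iterations=100, seed=2)
        assert np.median(draws.sigma_obs) < 0.1
        level = draws.component_means()["level"]
        assert np.max(np.abs(level - 37.0)) < 1.0

    def test_insufficient_data_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_bsts(np.ones(20), n_iterations=10)

    def test_draw_log_round_trip(self, small_series, tmp_path):
        y = small_series.panel.response[("SYN", "synthetic")][:72]
        X = small_series.panel.covariates["SYN"][["une"]].to_numpy()[:72]
        draws = fit_bsts(y, X, trend_spec="local_level", n_iterations=60,
                         seed=6, covariate_names=["une"])
        path = tmp_path / "draws.csv"
        draws.to_csv(path)
        import pandas as pd

        log = pd.read_csv(path, index_col="draw")
        assert len(log) == draws.n_kept
        assert np.allclose(log["beta_une"], draws.beta[:, 0])
        assert set(log["inc_une"]) <= {0, 1}

    def test_semilocal_persistence_stays_in_unit_interval(self, small_series):
        y = small_series.panel.response[("SYN", "synthetic")][:72]
        draws = fit_bsts(y, trend_spec="semilocal_linear", n_iterations=100, seed=3)
        assert np.all(np.abs(draws.phi) < 1.0)

    def test_seasonal_posterior_mean_nearly_zero_sum(self, small_series):
        y = small_series.panel.response[("SYN", "synthetic")][:72]
        draws = fit_bsts(y, trend_spec="local_level", n_iterations=300, seed=4)
        seas = draws.component_means()["seasonal"]
        rolling = np.convolve(seas, np.ones(12), mode="valid")
        assert np.max(np.abs(rolling)) < 0.5 * np.std(y)


def _point_mass_draws(level, n_draws=2000, S=12, sigma_obs=0.0, sigma_level=0.0,
                      sigma_seasonal=0.0, seasonal=None):
    m = 1 + (S - 1)
    states = np.zeros((n_draws, 1, m))
    states[:, 0, 0] = level
    if seasonal is not None:
        states[:, 0, 1:] = seasonal
    z = np.zeros(n_draws)
    return PosteriorDraws(
        trend=TrendSpec("local_level"),
        S=S,
        covariate_names=[],
        states=states,
        beta=np.zeros((n_draws, 0)),
        inclusion=np.zeros((n_draws, 0), dtype=bool),
        sigma_obs=z + sigma_obs,
        sigma_level=z + sigma_level,
        sigma_slope=z,
        sigma_seasonal=z + sigma_seasonal,
        phi=z + 1.0,
        slope_mean=z,
        n_iterations=n_draws,
        burn_in=0,
    )


class TestPosteriorPredict:
    def test_degenerate_model_predicts_constant(self):
        draws = _point_mass_draws(level=7.0, n_draws=50)
        pred = posterior_predict(draws, 6, rng=1)
        assert np.allclose(pred, 7.0)

    def test_predictive_variance_grows_with_horizon(self, small_series):
        y = small_series.panel.response[("SYN", "synthetic")][:72]
        fit = fit_bsts(y, trend_spec="local_level", n_iterations=400, seed=5)
        pred = posterior_predict(fit, 12, rng=6)
        var = pred.var(axis=0)
        # compare first vs last horizon (pointwise growth is noisy)
        assert var[-1] > var[0]

    def test_one_step_predictive_moments_match_filter_forecast(self):
        # point-mass posterior: one step ahead is N(level + next seasonal,
        # sigma_u^2 + sigma_w^2 + sigma_eps^2)
        seasonal = np.arange(11) - 5.0
        draws = _point_mass_draws(
            level=2.0, n_draws=40000, sigma_obs=0.5, sigma_level=0.3,
            sigma_seasonal=0.2, seasonal=seasonal,
        )
        pred = posterior_predict(draws, 1, rng=7)[:, 0]
        mean_expected = 2.0 + (-seasonal.sum())
        var_expected = 0.3**2 + 0.2**2 + 0.5**2
        assert pred.mean() == pytest.approx(mean_expected, abs=4 * pred.std() / 200)
        assert pred.var() == pytest.approx(var_expected, rel=0.05)

    def test_covariate_mismatch_rejected(self):
        draws = _point_mass_draws(level=0.0, n_draws=10)
        with pytest.raises(ConfigurationError):
            posterior_predict(draws, 3, X_future=np.ones((3, 2)), rng=0)
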