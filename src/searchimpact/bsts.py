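"""Bayesian structural time series with spike-and-slab regression.

The observation equation decomposes a monthly series into trend, 12-month
seasonality, a static regression on covariates and Gaussian noise::

    y_t = mu_t + gamma_t + beta' x_t + eps_t

with a random-walk level ``mu_t = mu_{t-1} + delta_{t-1} + u_t``, an optional
slope, and the zero-sum seasonal recursion
``gamma_t = -(gamma_{t-1} + ... + gamma_{t-S+1}) + w_t``.  Four trend
specifications are supported:

``local_level``
    random-walk level, no slope;
``local_linear``
    random-walk level and random-walk slope;
``semilocal_linear``
    random-walk level, slope a stationary AR(1) around a long-run mean
    (``delta_t = D + phi (delta_{t-1} - D) + v_t``), with ``phi`` and ``D``
    sampled;
``student_local_linear``
    local linear trend with heavy-tailed (Student-t) level and slope
    innovations, implemented by per-time normal scale-mixture latents.

Estimation is a Gibbs sampler: states by the Durbin-Koopman simulation
smoother, innovation variances from conjugate inverse-gamma conditionals,
and the regression by a spike-and-slab scan with a Zellner-style slab,
yielding posterior inclusion probabilities per covariate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import _ssm
from .panel import ConfigurationError

TREND_KINDS = ("local_level", "local_linear", "semilocal_linear", "student_local_linear")


class InsufficientDataError(ValueError):
    """Raised when fewer than two seasonal cycles of data are usable."""


@dataclass
class TrendSpec:
    """Trend specification and its (initial) hyperparameters."""

    kind: str = "local_linear"
    ar_persistence: float = 0.8  # phi, sampled for semilocal_linear
    slope_mean: float = 0.0  # D, sampled for semilocal_linear
    tail_dof: float = 30.0  # nu > 2, fixed, student trend only

    def __post_init__(self) -> None:
        if self.kind not in TREND_KINDS:
            raise ConfigurationError(f"unknown trend kind {self.kind!r}")
        if not -1.0 < self.ar_persistence <= 1.0:
            raise ConfigurationError("ar_persistence must lie in (-1, 1]")
        if self.tail_dof <= 2.0:
            raise ConfigurationError("tail_dof must exceed 2")

    @property
    def has_slope(self) -> bool:
        return self.kind != "local_level"

    @property
    def is_student(self) -> bool:
        return self.kind == "student_local_linear"


@dataclass
class SpikeSlabPrior:
    """Spike-and-slab hyperparameters.

    ``expected_model_size`` sets the default prior inclusion probability
    (size / #covariates).  ``information_weight`` is the slab precision in
    units of prior observations (default ``0.01 n``); the slab precision
    matrix is the usual average of the full and diagonalized Gram matrices.
    The residual variance carries an inverse-gamma prior worth
    ``residual_prior_weight * n`` observations at ``(1 - expected_rsquare)``
    times the sample variance.
    """

    expected_model_size: float = 3.0
    information_weight: float | None = None
    residual_prior_weight: float = 0.01
    expected_rsquare: float = 0.5
    inclusion_probabilities: np.ndarray | None = None

    def inclusion(self, p: int) -> np.ndarray:
        if self.inclusion_probabilities is not None:
            pi = np.asarray(self.inclusion_probabilities, dtype=float)
            if pi.shape != (p,):
                raise ConfigurationError("inclusion_probabilities length mismatch")
        else:
            pi = np.full(p, min(self.expected_model_size / max(p, 1), 1.0))
        if ((pi < 0) | (pi > 1)).any():
            raise ConfigurationError("inclusion probabilities must lie in [0, 1]")
        return pi


@dataclass
class BSTSModel:
    """Assembled state-space structure plus current hyperparameter values."""

    trend: TrendSpec
    S: int = 12
    n_covariates: int = 0
    sigma_obs: float = 1.0
    sigma_level: float = 0.1
    sigma_slope: float = 0.01
    sigma_seasonal: float = 0.01
    a0: np.ndarray | None = None
    P0: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.S < 2:
            raise ConfigurationError("seasonal period S must be >= 2")

    @property
    def trend_dim(self) -> int:
        return 2 if self.trend.has_slope else 1

    @property
    def state_dim(self) -> int:
        return self.trend_dim + (self.S - 1)

    @property
    def seasonal_offset(self) -> int:
        return self.trend_dim

    def observation_vector(self) -> np.ndarray:
        Z = np.zeros(self.state_dim)
        Z[0] = 1.0
        Z[self.seasonal_offset] = 1.0
        return Z

    def transition(self) -> tuple[np.ndarray, np.ndarray]:
        """Transition matrix and offset for the current trend parameters."""
        m = self.state_dim
        T = np.zeros((m, m))
        c = np.zeros(m)
        T[0, 0] = 1.0
        if self.trend.has_slope:
            T[0, 1] = 1.0
            if self.trend.kind == "semilocal_linear":
                phi = self.trend.ar_persistence
                T[1, 1] = phi
                c[1] = (1.0 - phi) * self.trend.slope_mean
            else:
                T[1, 1] = 1.0
        o = self.seasonal_offset
        T[o, o : o + self.S - 1] = -1.0
        for j in range(1, self.S - 1):
            T[o + j, o + j - 1] = 1.0
        return T, c

    def innovation_diag(
        self,
        n: int,
        level_scales: np.ndarray | None = None,
        slope_scales: np.ndarray | None = None,
    ) -> np.ndarray:
        """Per-time diagonal state innovation variances, (n, m)."""
        Q = np.zeros((n, self.state_dim))
        lu = level_scales if level_scales is not None else np.ones(n)
        Q[:, 0] = self.sigma_level**2 * lu
        if self.trend.has_slope:
            lv = slope_scales if slope_scales is not None else np.ones(n)
            Q[:, 1] = self.sigma_slope**2 * lv
        Q[:, self.seasonal_offset] = self.sigma_seasonal**2
        return Q

    def default_initial_state(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        finite = y[np.isfinite(y)]
        level0 = float(finite[0]) if finite.size else 0.0
        var_y = float(np.var(finite)) if finite.size > 1 else 1.0
        var_y = max(var_y, 1e-8)
        a0 = np.zeros(self.state_dim)
        a0[0] = level0
        if self.trend.kind == "semilocal_linear":
            a0[1] = self.trend.slope_mean
        P0 = np.diag(np.full(self.state_dim, var_y))
        if self.trend.has_slope:
            P0[1, 1] = var_y * 0.01 + 1e-8
        return a0, P0


def build_state_space(
    trend_spec: TrendSpec | str, S: int = 12, covariate_count: int = 0
) -> BSTSModel:
    """Assemble the state-space model for a trend spec and seasonal period."""
    if isinstance(trend_spec, str):
        trend_spec = TrendSpec(kind=trend_spec)
    return BSTSModel(trend=trend_spec, S=S, n_covariates=covariate_count)


@dataclass
class FilterResult:
    filtered_mean: np.ndarray  # (n, m)
    filtered_cov: np.ndarray  # (n, m, m)
    predicted_mean: np.ndarray
    predicted_cov: np.ndarray
    loglik: float


def _adjusted(y, X, beta):
    y = np.asarray(y, dtype=float)
    if X is not None and beta is not None and len(beta):
        y = y - np.asarray(X, dtype=float) @ np.asarray(beta, dtype=float)
    return y


def _model_arrays(model: BSTSModel, y: np.ndarray, level_scales=None, slope_scales=None):
    n = len(y)
    Z = model.observation_vector()
    T, c = model.transition()
    Q = model.innovation_diag(n, level_scales, slope_scales)
    H = np.full(n, model.sigma_obs**2)
    a0, P0 = (model.a0, model.P0)
    if a0 is None or P0 is None:
        d0, D0 = model.default_initial_state(y)
        a0 = d0 if a0 is None else a0
        P0 = D0 if P0 is None else P0
    mask = np.isfinite(y).astype(np.bool_)
    y_filled = np.where(mask, y, 0.0)
    return y_filled, mask, Z, T, c, Q, H, np.asarray(a0, float), np.asarray(P0, float)


def kalman_filter(model: BSTSModel, y, X=None, beta=None) -> FilterResult:
    """Linear-Gaussian filtering at the model's current hyperparameters.

    Missing observations (NaN) receive prediction-only updates.
    """
    y_adj = _adjusted(y, X, beta)
    args = _model_arrays(model, y_adj)
    apred, Ppred, att, Ptt, _, _, _, _, ll = _ssm.kalman_filter_core(*args)
    if not math.isfinite(ll):
        raise FloatingPointError("non-finite filter log-likelihood")
    return FilterResult(att, Ptt, apred, Ppred, ll)


def kalman_smooth(model: BSTSModel, y, X=None, beta=None) -> np.ndarray:
    """Smoothed state means E[alpha_t | y]."""
    y_adj = _adjusted(y, X, beta)
    args = _model_arrays(model, y_adj)
    alphahat, _ = _ssm.smooth_core(*args)
    return alphahat


def sample_states(
    model: BSTSModel,
    y,
    rng: np.random.Generator,
    X=None,
    beta=None,
    level_scales=None,
    slope_scales=None,
) -> np.ndarray:
    """One draw from p(states | y, hyperparameters), (n, m)."""
    y_adj = _adjusted(y, X, beta)
    yf, mask, Z, T, c, Q, H, a0, P0 = _model_arrays(model, y_adj, level_scales, slope_scales)
    n, m = len(yf), model.state_dim
    P0L = np.linalg.cholesky(P0 + 1e-12 * np.eye(m))
    z_init = rng.standard_normal(m)
    z_state = rng.standard_normal((n, m))
    z_obs = rng.standard_normal(n)
    return _ssm.dk_draw(yf, mask, Z, T, c, Q, H, a0, P0, P0L, z_init, z_state, z_obs)


def sample_regression(
    residual_target: np.ndarray,
    X: np.ndarray,
    prior: SpikeSlabPrior,
    rng: np.random.Generator,
    gamma: np.ndarray | None = None,
    n_scans: int = 1,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One spike-and-slab Gibbs step: (inclusion, beta, sigma_obs).

    ``residual_target`` is the response net of the current trend and
    seasonal draw.  Indicators are scanned with conjugate odds, then the
    coefficients of the included set are drawn from their conditional slab
    posterior (excluded components are exactly zero), then the residual sd.
    """
    y = np.asarray(residual_target, dtype=float)
    X = np.asarray(X, dtype=float)
    keep = np.isfinite(y)
    y, Xo = y[keep], X[keep]
    n, p = Xo.shape
    XtX = Xo.T @ Xo
    Xty = Xo.T @ y
    yty = float(y @ y)
    kappa = prior.information_weight if prior.information_weight is not None else 0.01 * n
    A = (kappa / max(n, 1)) * (0.5 * XtX + 0.5 * np.diag(np.diag(XtX)))
    A[np.diag_indices_from(A)] += 1e-10  # ridge guard for singular designs
    var_y = max(float(np.var(y)), 1e-12)
    prior_df = max(prior.residual_prior_weight * n, 1.0)
    prior_ss = prior_df * (1.0 - prior.expected_rsquare) * var_y
    pi = prior.inclusion(p)
    with np.errstate(divide="ignore"):
        log_odds = np.log(pi) - np.log1p(-pi)
    log_odds = np.clip(log_odds, -1e10, 1e10)
    if gamma is None:
        gamma = np.zeros(p, dtype=np.int8)
    gamma = np.ascontiguousarray(gamma, dtype=np.int8)
    for _ in range(n_scans):
        gamma = _ssm.ssvs_scan(
            XtX, Xty, yty, A, gamma, float(n), prior_df, prior_ss, log_odds, rng.random(p)
        )
    inc = gamma.astype(bool)
    beta = np.zeros(p)
    if inc.any():
        M = A[np.ix_(inc, inc)] + XtX[np.ix_(inc, inc)]
        L = np.linalg.cholesky(M)
        mu = np.linalg.solve(M, Xty[inc])
        Sn = max(yty - Xty[inc] @ mu, 1e-12)
        sigma2 = (prior_ss + Sn) / rng.chisquare(prior_df + n)
        z = rng.standard_normal(inc.sum())
        beta[inc] = mu + math.sqrt(sigma2) * np.linalg.solve(L.T, z)
    else:
        sigma2 = (prior_ss + yty) / rng.chisquare(prior_df + n)
    return gamma, beta, math.sqrt(sigma2)


@dataclass
class PosteriorDraws:
    """Retained MCMC output of :func:`fit_bsts`."""

    trend: TrendSpec
    S: int
    covariate_names: list[str]
    states: np.ndarray  # (kept, n, m)
    beta: np.ndarray  # (kept, p)
    inclusion: np.ndarray  # (kept, p) bool
    sigma_obs: np.ndarray
    sigma_level: np.ndarray
    sigma_slope: np.ndarray
    sigma_seasonal: np.ndarray
    phi: np.ndarray
    slope_mean: np.ndarray
    n_iterations: int
    burn_in: int

    @property
    def n_kept(self) -> int:
        return self.states.shape[0]

    @property
    def trend_dim(self) -> int:
        return 2 if self.trend.has_slope else 1

    @property
    def state_dim(self) -> int:
        return self.trend_dim + (self.S - 1)

    def inclusion_probabilities(self) -> np.ndarray:
        """Posterior inclusion probability per covariate."""
        if self.inclusion.size == 0:
            return np.zeros(0)
        return self.inclusion.mean(axis=0)

    def component_means(self) -> dict[str, np.ndarray]:
        """Posterior-mean trend and seasonal paths."""
        mean_states = self.states.mean(axis=0)
        out = {"level": mean_states[:, 0], "seasonal": mean_states[:, self.trend_dim]}
        if self.trend.has_slope:
            out["slope"] = mean_states[:, 1]
        return out

    def draw_log(self):
        """Per-draw hyperparameters, coefficients and indicators as a frame."""
        import pandas as pd

        data = {
            "sigma_obs": self.sigma_obs,
            "sigma_level": self.sigma_level,
            "sigma_slope": self.sigma_slope,
            "sigma_seasonal": self.sigma_seasonal,
            "phi": self.phi,
            "slope_mean": self.slope_mean,
        }
        for j, name in enumerate(self.covariate_names):
            data[f"beta_{name}"] = self.beta[:, j]
            data[f"inc_{name}"] = self.inclusion[:, j].astype(int)
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        """Audit log of the retained draws (states excluded)."""
        self.draw_log().to_csv(path, index_label="draw")


def _draw_ig_variance(rng, df_prior, ss_prior, resid_sq_sum, n_terms):
    return (ss_prior + resid_sq_sum) / rng.chisquare(df_prior + n_terms)


def fit_bsts(
    y,
    X=None,
    trend_spec: TrendSpec | str = "local_linear",
    n_iterations: int = 1000,
    burn_in: int | None = None,
    seed: int | np.random.Generator = 0,
    prior: SpikeSlabPrior | None = None,
    S: int = 12,
    covariate_names: list[str] | None = None,
) -> PosteriorDraws:
    """Fit the structural model by Gibbs sampling on the training window.

    ``y`` should cover the pre-intervention window only (NaNs allowed,
    handled by prediction-only filter updates); ``X`` is optional — without
    it the regression step is skipped.  ``burn_in`` defaults to 20% of the
    iterations.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    n_obs = int(np.isfinite(y).sum())
    if n_obs < 24:
        raise InsufficientDataError(f"need >= 24 usable months, got {n_obs}")
    if isinstance(trend_spec, str):
        trend_spec = TrendSpec(kind=trend_spec)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if burn_in is None:
        burn_in = n_iterations // 5
    if burn_in >= n_iterations:
        raise ConfigurationError("burn_in must be smaller than n_iterations")
    prior = prior or SpikeSlabPrior()

    p = 0
    if X is not None:
        X = np.asarray(X, dtype=float)
        if X.shape[0] != n:
            raise ConfigurationError("X and y lengths differ")
        p = X.shape[1]
    names = list(covariate_names or [f"x{j}" for j in range(p)])

    model = build_state_space(trend_spec, S=S, covariate_count=p)
    finite = y[np.isfinite(y)]
    sd_y = float(np.std(finite)) if finite.size > 1 else 0.0
    sd_y_eff = max(sd_y, 1e-4)
    model.sigma_obs = max(0.5 * sd_y, 1e-4)
    model.sigma_level = 0.1 * sd_y_eff
    model.sigma_slope = 0.01 * sd_y_eff
    model.sigma_seasonal = 0.01 * sd_y_eff
    model.a0, model.P0 = model.default_initial_state(y)

    # inverse-gamma priors: weight w*n observations at the stated sd guesses
    df_state = max(0.01 * n_obs, 1.0)
    ss_level = df_state * (0.1 * sd_y_eff) ** 2
    ss_slope = df_state * (0.01 * sd_y_eff) ** 2
    ss_seas = df_state * (0.01 * sd_y_eff) ** 2
    df_obs = max(prior.residual_prior_weight * n_obs, 1.0)
    ss_obs = df_obs * (1.0 - prior.expected_rsquare) * max(sd_y**2, 1e-12)

    has_slope = trend_spec.has_slope
    is_semilocal = trend_spec.kind == "semilocal_linear"
    is_student = trend_spec.is_student
    nu = trend_spec.tail_dof
    lam_u = np.ones(n)
    lam_v = np.ones(n)
    beta = np.zeros(p)
    gamma = np.zeros(p, dtype=np.int8)
    o = model.seasonal_offset

    kept = n_iterations - burn_in
    m = model.state_dim
    out_states = np.empty((kept, n, m))
    out_beta = np.empty((kept, p))
    out_inc = np.empty((kept, p), dtype=bool)
    out_sobs = np.empty(kept)
    out_slev = np.empty(kept)
    out_sslope = np.empty(kept)
    out_sseas = np.empty(kept)
    out_phi = np.empty(kept)
    out_D = np.empty(kept)

    for it in range(n_iterations):
        # --- states | everything else
        scales_u = lam_u if is_student else None
        scales_v = lam_v if is_student else None
        draw = sample_states(model, y, rng, X=X, beta=beta,
                             level_scales=scales_u, slope_scales=scales_v)
        mu = draw[:, 0]
        delta = draw[:, 1] if has_slope else None
        s_block = draw[:, o : o + S - 1]

        # --- innovation variances | states
        u = np.diff(mu) - (delta[:-1] if has_slope else 0.0)
        if is_student:
            lam_u[1:] = (nu + (u**2) / max(model.sigma_level**2, 1e-300)) / rng.chisquare(
                nu + 1.0, size=n - 1
            )
            lam_u[0] = nu / rng.chisquare(nu)
            su2 = _draw_ig_variance(rng, df_state, ss_level, float(np.sum(u**2 / lam_u[1:])), n - 1)
        else:
            su2 = _draw_ig_variance(rng, df_state, ss_level, float(np.sum(u**2)), n - 1)
        model.sigma_level = math.sqrt(su2)

        if has_slope:
            if is_semilocal:
                phi = trend_spec.ar_persistence
                D = trend_spec.slope_mean
                sv2 = model.sigma_slope**2
                # phi | D, slope path (prior N(0,1), truncated to (-1,1))
                z = delta - D
                zz = float(np.sum(z[:-1] ** 2))
                zx = float(np.sum(z[1:] * z[:-1]))
                prec = zz / max(sv2, 1e-300) + 1.0
                mean = (zx / max(sv2, 1e-300)) / prec
                sd = math.sqrt(1.0 / prec)
                lo, hi = (-0.999 - mean) / sd, (0.999 - mean) / sd
                phi = float(stats.truncnorm.ppf(rng.random(), lo, hi, loc=mean, scale=sd))
                # D | phi, slope path (prior N(0, (1+sd_y)^2))
                resp = delta[1:] - phi * delta[:-1]
                coef = 1.0 - phi
                prior_var_D = (1.0 + sd_y_eff) ** 2
                precD = (n - 1) * coef**2 / max(sv2, 1e-300) + 1.0 / prior_var_D
                meanD = (coef * float(np.sum(resp)) / max(sv2, 1e-300)) / precD
                D = float(rng.normal(meanD, math.sqrt(1.0 / precD)))
                trend_spec.ar_persistence = phi
                trend_spec.slope_mean = D
                v = delta[1:] - D - phi * (delta[:-1] - D)
            else:
                v = np.diff(delta)
            if is_student:
                lam_v[1:] = (nu + (v**2) / max(model.sigma_slope**2, 1e-300)) / rng.chisquare(
                    nu + 1.0, size=n - 1
                )
                lam_v[0] = nu / rng.chisquare(nu)
                sv2_new = _draw_ig_variance(
                    rng, df_state, ss_slope, float(np.sum(v**2 / lam_v[1:])), n - 1
                )
            else:
                sv2_new = _draw_ig_variance(rng, df_state, ss_slope, float(np.sum(v**2)), n - 1)
            model.sigma_slope = math.sqrt(sv2_new)

        w = s_block[1:, 0] + s_block[:-1].sum(axis=1)
        sw2 = _draw_ig_variance(rng, df_state, ss_seas, float(np.sum(w**2)), n - 1)
        model.sigma_seasonal = math.sqrt(sw2)

        # --- regression and observation variance | states
        target = y - mu - s_block[:, 0]
        if p:
            gamma, beta, sigma_obs = sample_regression(target, X, prior, rng, gamma=gamma)
            model.sigma_obs = max(sigma_obs, 1e-8)
        else:
            resid = target[np.isfinite(target)]
            so2 = _draw_ig_variance(rng, df_obs, ss_obs, float(np.sum(resid**2)), resid.size)
            model.sigma_obs = max(math.sqrt(so2), 1e-8)

        if it >= burn_in:
            j = it - burn_in
            out_states[j] = draw
            out_beta[j] = beta
            out_inc[j] = gamma.astype(bool)
            out_sobs[j] = model.sigma_obs
            out_slev[j] = model.sigma_level
            out_sslope[j] = model.sigma_slope if has_slope else 0.0
            out_sseas[j] = model.sigma_seasonal
            out_phi[j] = trend_spec.ar_persistence if is_semilocal else 1.0
            out_D[j] = trend_spec.slope_mean if is_semilocal else 0.0

    return PosteriorDraws(
        trend=trend_spec,
        S=S,
        covariate_names=names,
        states=out_states,
        beta=out_beta,
        inclusion=out_inc,
        sigma_obs=out_sobs,
        sigma_level=out_slev,
        sigma_slope=out_sslope,
        sigma_seasonal=out_sseas,
        phi=out_phi,
        slope_mean=out_D,
        n_iterations=n_iterations,
        burn_in=burn_in,
    )


def posterior_predict(
    draws: PosteriorDraws,
    horizon: int,
    X_future=None,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """Predictive draws over a future horizon, (n_kept, horizon).

    Each retained draw is propagated through its own transition equations
    with fresh innovations (and its own regression coefficients applied to
    ``X_future``), giving the full posterior predictive distribution of the
    no-intervention path.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    p = draws.beta.shape[1]
    if (X_future is None) != (p == 0):
        raise ConfigurationError("X_future must be supplied iff the model has covariates")
    if X_future is not None:
        X_future = np.asarray(X_future, dtype=float)
        if X_future.shape != (horizon, p):
            raise ConfigurationError(
                f"X_future shape {X_future.shape} does not match (horizon, p)=({horizon}, {p})"
            )
    k = draws.n_kept
    m = draws.state_dim
    td = draws.trend_dim
    S = draws.S
    o = td
    has_slope = draws.trend.has_slope
    is_semilocal = draws.trend.kind == "semilocal_linear"
    is_student = draws.trend.is_student
    nu = draws.trend.tail_dof

    alpha = draws.states[:, -1, :].copy()  # (k, m)
    out = np.empty((k, horizon))
    for h in range(horizon):
        new = np.empty_like(alpha)
        if is_student:
            eta_u = draws.sigma_level * rng.standard_t(nu, size=k)
        else:
            eta_u = draws.sigma_level * rng.standard_normal(k)
        new[:, 0] = alpha[:, 0] + (alpha[:, 1] if has_slope else 0.0) + eta_u
        if has_slope:
            if is_student:
                eta_v = draws.sigma_slope * rng.standard_t(nu, size=k)
            else:
                eta_v = draws.sigma_slope * rng.standard_normal(k)
            if is_semilocal:
                new[:, 1] = (
                    draws.slope_mean + draws.phi * (alpha[:, 1] - draws.slope_mean) + eta_v
                )
            else:
                new[:, 1] = alpha[:, 1] + eta_v
        eta_w = draws.sigma_seasonal * rng.standard_normal(k)
        new[:, o] = -alpha[:, o : o + S - 1].sum(axis=1) + eta_w
        for j in range(1, S - 1):
            new[:, o + j] = alpha[:, o + j - 1]
        alpha = new
        level_plus_seasonal = alpha[:, 0] + alpha[:, o]
        reg = draws.beta @ X_future[h] if X_future is not None else 0.0
        eps = draws.sigma_obs * rng.standard_normal(k)
        out[:, h] = level_plus_seasonal + reg + eps
    return out
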