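"""Bayesian dynamic mixture models over covariate subsets.

With n candidate covariates (plus an always-included constant term), every
subset defines a state-space regression component ``y_t = x_tk' theta_tk +
eps_tk`` whose coefficients drift as a multivariate random walk.  All
K = 2^n components are enumerated, started from zero coefficients and equal
weights 1/K, and advanced recursively: each component's coefficient state
is updated by its Kalman filter, and the mixture weights are multiplied by
each component's one-step predictive density of the new observation and
renormalized.  Inputs are standardized on the pre-intervention window; the
counterfactual forecast over the post period freezes the end-of-pre states
and weights (updating on post data would absorb the causal effect into the
counterfactual) and de-standardizes the weight-averaged predictions.

The state-innovation covariance of each component is unspecified in the
underlying construction; the default here inflates the state covariance by
a forgetting factor each step (an explicit diagonal covariance mode is also
available), and the component observation-noise variance is tracked by an
exponentially weighted residual variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _ssm
from .panel import AlignmentError, ConfigurationError, StandardizationConstants


@dataclass
class BdmmConfig:
    """Tunable recursion parameters.

    ``forgetting`` inflates state covariances by 1/forgetting per step
    (1.0 = no drift); ``ew_weight`` is the exponential weight of the
    residual-variance tracker; ``state_innovation_sd`` switches to an
    explicit diagonal random-walk covariance instead of forgetting.
    """

    forgetting: float = 0.99
    ew_weight: float = 0.95
    initial_state_variance: float = 10.0
    initial_noise_variance: float = 1.0
    state_innovation_sd: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.forgetting <= 1.0:
            raise ConfigurationError("forgetting must lie in (0, 1]")
        if not 0.0 < self.ew_weight <= 1.0:
            raise ConfigurationError("ew_weight must lie in (0, 1]")


@dataclass
class MixtureState:
    """All component models plus the current normalized weights.

    Component k's covariate subset is the binary expansion of k; the
    constant term (design column 0) is active in every component.  Arrays
    are padded to the maximal state dimension; ``active_idx[k, :active_len[k]]``
    gives component k's design columns.
    """

    covariate_names: list[str]
    active_idx: np.ndarray  # (K, n+1) int64
    active_len: np.ndarray  # (K,)
    theta: np.ndarray  # (K, n+1) coefficient means (padded)
    cov: np.ndarray  # (K, n+1, n+1) coefficient covariances (padded)
    noise_var: np.ndarray  # (K,)
    log_weights: np.ndarray  # (K,) normalized
    config: BdmmConfig = field(default_factory=BdmmConfig)
    t: int = 0
    weight_path: np.ndarray | None = None
    pred_path: np.ndarray | None = None  # one-step mixture predictive means
    standardization: dict[str, StandardizationConstants] | None = None

    @property
    def n_components(self) -> int:
        return len(self.active_len)

    @property
    def weights(self) -> np.ndarray:
        w = np.exp(self.log_weights - self.log_weights.max())
        return w / w.sum()

    def component_mask(self, k: int) -> np.ndarray:
        """Boolean mask over the n non-constant covariates for component k."""
        n = len(self.covariate_names)
        return np.array([(k >> j) & 1 for j in range(n)], dtype=bool)

    def export_weights(self, path, top_m: int = 10) -> None:
        """Write the weight paths of the top-m final components as CSV."""
        import pandas as pd

        if self.weight_path is None:
            raise ConfigurationError("no weight path recorded yet")
        order = np.argsort(self.weights)[::-1][:top_m]
        cols = {}
        for k in order:
            names = "+".join(
                ["const"]
                + [nm for j, nm in enumerate(self.covariate_names) if (int(k) >> j) & 1]
            )
            cols[names] = self.weight_path[:, k]
        pd.DataFrame(cols).to_csv(path, index_label="step")

    def top_components(self, m: int = 10) -> list[tuple[int, float, tuple[str, ...]]]:
        w = self.weights
        order = np.argsort(w)[::-1][:m]
        out = []
        for k in order:
            names = tuple(
                nm for j, nm in enumerate(self.covariate_names) if (int(k) >> j) & 1
            )
            out.append((int(k), float(w[k]), names))
        return out


def enumerate_components(
    covariate_names: list[str], config: BdmmConfig | None = None
) -> MixtureState:
    """Enumerate all 2^n covariate-subset components with equal weights.

    Coefficients start at zero with a diffuse diagonal covariance; the
    design is assumed to carry the constant term in column 0 and the named
    covariates in columns 1..n.
    """
    n = len(covariate_names)
    if n > 20:
        raise ConfigurationError(f"2^{n} components exceed the resource guard (n <= 20)")
    config = config or BdmmConfig()
    K = 2**n
    pmax = n + 1
    active_idx = np.zeros((K, pmax), dtype=np.int64)
    active_len = np.zeros(K, dtype=np.int64)
    for k in range(K):
        cols = [0] + [j + 1 for j in range(n) if (k >> j) & 1]
        active_len[k] = len(cols)
        active_idx[k, : len(cols)] = cols
    theta = np.zeros((K, pmax))
    cov = np.zeros((K, pmax, pmax))
    for k in range(K):
        for i in range(active_len[k]):
            cov[k, i, i] = config.initial_state_variance
    return MixtureState(
        covariate_names=list(covariate_names),
        active_idx=active_idx,
        active_len=active_len,
        theta=theta,
        cov=cov,
        noise_var=np.full(K, config.initial_noise_variance),
        log_weights=np.full(K, -np.log(K)),
        config=config,
    )


def _design(X: np.ndarray | None, n_names: int, T: int) -> np.ndarray:
    """Design matrix with a leading constant column."""
    out = np.ones((T, n_names + 1))
    if n_names:
        if X is None or X.shape != (T, n_names):
            raise AlignmentError("covariate matrix does not match names/length")
        out[:, 1:] = X
    return out


def _w_diag(state: MixtureState) -> tuple[np.ndarray, bool]:
    cfg = state.config
    if cfg.state_innovation_sd is not None:
        return np.full(state.theta.shape[1], cfg.state_innovation_sd**2), True
    return np.zeros(state.theta.shape[1]), False


def mixture_step(state: MixtureState, y_t: float, x_t: np.ndarray | None) -> MixtureState:
    """Advance every component one step and re-weight by predictive density.

    ``x_t`` holds the n covariate values (the constant is implicit).
    The update is in place; the state is returned for chaining.
    """
    n = len(state.covariate_names)
    X = _design(None if n == 0 else np.asarray(x_t, float).reshape(1, n), n, 1)
    Wdiag, use_W = _w_diag(state)
    wpath, pred = _ssm.mixture_filter_core(
        np.array([float(y_t)]),
        X,
        state.active_idx,
        state.active_len,
        state.config.forgetting,
        state.config.ew_weight,
        Wdiag,
        use_W,
        state.theta,
        state.cov,
        state.noise_var,
        state.log_weights,
    )
    state.t += 1
    state.weight_path = (
        wpath if state.weight_path is None else np.vstack([state.weight_path, wpath])
    )
    state.pred_path = (
        pred if state.pred_path is None else np.concatenate([state.pred_path, pred])
    )
    return state


def fit_mixture(
    y_pre: np.ndarray,
    X_pre: np.ndarray | None,
    covariate_names: list[str] | None = None,
    config: BdmmConfig | None = None,
) -> MixtureState:
    """Run the mixture recursion over the standardized pre-intervention data.

    Returns the final state including the full weight path (T x K).
    """
    y = np.asarray(y_pre, dtype=float)
    if len(y) < 2:
        raise AlignmentError("insufficient pre-intervention data")
    if covariate_names is None:
        covariate_names = (
            [f"x{j}" for j in range(X_pre.shape[1])] if X_pre is not None else []
        )
    state = enumerate_components(covariate_names, config)
    X = _design(X_pre, len(covariate_names), len(y))
    Wdiag, use_W = _w_diag(state)
    wpath, pred = _ssm.mixture_filter_core(
        y,
        X,
        state.active_idx,
        state.active_len,
        state.config.forgetting,
        state.config.ew_weight,
        Wdiag,
        use_W,
        state.theta,
        state.cov,
        state.noise_var,
        state.log_weights,
    )
    state.t = len(y)
    state.weight_path = wpath
    state.pred_path = pred
    return state


def forecast_counterfactual(
    state: MixtureState,
    X_post: np.ndarray | None,
    constants: StandardizationConstants | None = None,
) -> np.ndarray:
    """Weight-averaged forecasts with frozen states, de-standardized.

    Component states and mixture weights stay at their end-of-pre values
    (no observation updates over the post period).  ``constants`` are the
    pre-window standardization constants of the response; if omitted the
    forecast stays on the standardized scale.
    """
    n = len(state.covariate_names)
    h = len(X_post) if X_post is not None else 0
    if n and (X_post is None):
        raise AlignmentError("post-period covariates required")
    X = _design(X_post, n, h) if h else np.ones((0, n + 1))
    yhat = _ssm.mixture_forecast_core(
        X, state.active_idx, state.active_len, state.theta, state.log_weights
    )
    if constants is not None:
        yhat = yhat * constants.sd + constants.mean
    return yhat
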