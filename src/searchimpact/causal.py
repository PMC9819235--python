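"""Counterfactual causal-impact estimation on top of the structural model.

The causal impact of an intervention on a series is the difference between
its observed post-intervention values and the posterior predictive
distribution of the values that would have been observed with no
intervention.  The model is trained strictly on the pre-intervention
window; the counterfactual is the posterior predictive path over the post
window given the post-period covariates.  Because covariates must
themselves be unaffected by the intervention for the counterfactual to be
valid, a two-step screening procedure first models every candidate
covariate (with a covariate-free structural model) and excludes those whose
own lockdown effect is significant, alongside a-priori keep/drop lists.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bsts import SpikeSlabPrior, TrendSpec, fit_bsts, posterior_predict
from .panel import COVARIATE_NAMES, AlignmentError, MonthlyPanel, StandardizationConstants


@dataclass
class McmcSettings:
    n_iterations: int = 1000
    burn_in: int | None = None

    def __post_init__(self) -> None:
        if self.burn_in is None:
            self.burn_in = self.n_iterations // 5


@dataclass
class CausalImpactResult:
    """Posterior summaries of the intervention effect for one series.

    ``pointwise`` holds observed-minus-predicted draws (draw x post-month);
    ``average`` and ``cumulative`` are per-draw summaries over the post
    window; ``relative`` is cumulative effect over cumulative counterfactual.
    Significance is judged by the 95% central credible interval of the
    average effect excluding zero; ``tail_area_p`` is the posterior
    probability mass on the null side of the detected sign (a one-sided
    Bayesian tail-area probability).
    """

    pointwise: np.ndarray
    average: np.ndarray
    cumulative: np.ndarray
    relative: np.ndarray
    predicted: np.ndarray  # counterfactual draws (draw x post-month)
    observed: np.ndarray  # observed post-period values
    interval_average: tuple[float, float]
    interval_cumulative: tuple[float, float]
    interval_relative: tuple[float, float]
    tail_area_p: float
    significant: bool
    sign: str  # positive / negative / none
    dropped_covariates: list[str] = field(default_factory=list)
    fitted_pre: np.ndarray | None = None  # posterior-mean fit on the pre window

    @property
    def relative_effect_point(self) -> float:
        return float(np.median(self.relative))

    @property
    def average_effect_point(self) -> float:
        return float(np.mean(self.average))


def _central_interval(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    lo = (1.0 - level) / 2.0
    return (float(np.quantile(draws, lo)), float(np.quantile(draws, 1.0 - lo)))


def summarize_effect_draws(
    observed_post: np.ndarray, predicted: np.ndarray, level: float = 0.95
) -> CausalImpactResult:
    """Effect summaries from observed post values and counterfactual draws."""
    observed_post = np.asarray(observed_post, dtype=float)
    pointwise = observed_post[None, :] - predicted
    average = pointwise.mean(axis=1)
    cumulative = pointwise.sum(axis=1)
    cum_pred = predicted.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        relative = np.where(cum_pred != 0, cumulative / cum_pred, np.nan)
    ia = _central_interval(average, level)
    significant = bool(ia[0] > 0 or ia[1] < 0)
    if significant:
        sign = "positive" if ia[0] > 0 else "negative"
    else:
        sign = "none"
    p_leq = float(np.mean(average <= 0))
    p_geq = float(np.mean(average >= 0))
    tail = min(p_leq, p_geq)
    return CausalImpactResult(
        pointwise=pointwise,
        average=average,
        cumulative=cumulative,
        relative=relative,
        predicted=predicted,
        observed=observed_post,
        interval_average=ia,
        interval_cumulative=_central_interval(cumulative, level),
        interval_relative=_central_interval(relative[np.isfinite(relative)], level)
        if np.isfinite(relative).any()
        else (float("nan"), float("nan")),
        tail_area_p=tail,
        significant=significant,
        sign=sign,
    )


def estimate_impact(
    y_full,
    X_full,
    intervention_index: int,
    trend_spec: TrendSpec | str = "semilocal_linear",
    lagged: bool = False,
    mcmc: McmcSettings | None = None,
    seed: int = 0,
    prior: SpikeSlabPrior | None = None,
    covariate_names: list[str] | None = None,
    S: int = 12,
) -> CausalImpactResult:
    """Fit on the pre window, predict the post window, summarize the effect.

    ``intervention_index`` is the first post-period month (integer position).
    With ``lagged=True`` the covariates are shifted one month forward
    (x_t replaced by x_{t-1}) and the first month is dropped.  Covariates
    are standardized on the pre window; columns constant over the pre
    window carry no counterfactual information and are dropped (recorded
    in ``dropped_covariates``).
    """
    mcmc = mcmc or McmcSettings()
    y_full = np.asarray(y_full, dtype=float)
    n = len(y_full)
    k = int(intervention_index)
    if not 0 < k < n:
        raise AlignmentError("intervention_index must leave >=1 pre and post month")
    X = None
    names: list[str] = []
    dropped: list[str] = []
    if X_full is not None:
        X = np.asarray(X_full, dtype=float)
        if X.shape[0] != n:
            raise AlignmentError("covariates do not cover the full sample")
        names = list(covariate_names or [f"x{j}" for j in range(X.shape[1])])
    if lagged:
        if X is not None:
            X = X[:-1]
        y_full = y_full[1:]
        n -= 1
        # intervention keeps its calendar position; one pre month is consumed
        k -= 1
    y_pre, y_post = y_full[:k], y_full[k:]
    horizon = n - k
    X_pre = X_post = None
    if X is not None:
        pre = X[:k]
        sds = np.nanstd(pre, axis=0, ddof=1)
        keep = sds > 1e-12
        dropped = [nm for nm, k_ in zip(names, keep) if not k_]
        names = [nm for nm, k_ in zip(names, keep) if k_]
        X = X[:, keep]
        if X.shape[1] == 0:
            X = None
        else:
            means = np.nanmean(X[:k], axis=0)
            sds = np.nanstd(X[:k], axis=0, ddof=1)
            X = (X - means) / sds
            X_pre, X_post = X[:k], X[k:]
    if np.isnan(y_post).any() or (X_post is not None and np.isnan(X_post).any()):
        raise AlignmentError("missing post-period observations or covariates")
    draws = fit_bsts(
        y_pre,
        X=X_pre,
        trend_spec=trend_spec,
        n_iterations=mcmc.n_iterations,
        burn_in=mcmc.burn_in,
        seed=seed,
        prior=prior,
        S=S,
        covariate_names=names,
    )
    rng = np.random.default_rng([seed, 2**20])
    predicted = posterior_predict(draws, horizon, X_future=X_post, rng=rng)
    result = summarize_effect_draws(y_post, predicted)
    result.dropped_covariates = dropped
    mean_states = draws.states.mean(axis=0)
    fitted = mean_states[:, 0] + mean_states[:, draws.trend_dim]
    if X_pre is not None:
        fitted = fitted + X_pre @ draws.beta.mean(axis=0)
    result.fitted_pre = fitted
    return result


def summarize_impact(result: CausalImpactResult) -> tuple[bool, str, float, float]:
    """(significant, sign, point relative effect, tail-area probability)."""
    return (result.significant, result.sign, result.relative_effect_point, result.tail_area_p)


# ----------------------------------------------------------------- screening


@dataclass
class ScreeningDecision:
    covariate: str
    status: str  # kept / excluded_affected / kept_a_priori / excluded_a_priori
    relative_effect: float | None = None
    tail_area_p: float | None = None
    reason: str = ""


def screen_covariates(
    panel: MonthlyPanel,
    country: str,
    trend_spec: TrendSpec | str = "semilocal_linear",
    a_priori_keep: tuple[str, ...] = ("ec_act", "oil"),
    a_priori_drop: tuple[str, ...] = ("stringency_index",),
    mcmc: McmcSettings | None = None,
    seed: int = 0,
    candidates: tuple[str, ...] | None = None,
) -> list[ScreeningDecision]:
    """First step of the two-step procedure: audit candidate covariates.

    Every candidate not on an a-priori list is modeled as a response with a
    covariate-free structural model; it is kept iff the 95% credible
    interval of its own lockdown effect includes zero.  Global series
    (``ec_act``, ``oil``) are kept a priori; the stringency index is
    excluded a priori by construction.  The kept set is admissible for the
    second-step impact model.
    """
    mcmc = mcmc or McmcSettings()
    cov = panel.covariates[country]
    month = panel.intervention_month.get(country)
    if month is None:
        raise AlignmentError(f"no intervention month for {country}")
    k = panel.month_index(month)
    decisions: list[ScreeningDecision] = []
    for name in candidates if candidates is not None else COVARIATE_NAMES:
        if name not in cov.columns:
            decisions.append(ScreeningDecision(name, "excluded_affected", reason="absent"))
            continue
        if name in a_priori_drop:
            decisions.append(ScreeningDecision(name, "excluded_a_priori"))
            continue
        if name in a_priori_keep:
            decisions.append(ScreeningDecision(name, "kept_a_priori"))
            continue
        series = cov[name].to_numpy(dtype=float)
        if np.isfinite(series[:k]).sum() < 24:
            decisions.append(
                ScreeningDecision(name, "excluded_affected", reason="series too short")
            )
            continue
        if np.nanstd(series[:k]) < 1e-12:
            # constant before the intervention, varying after: affected by
            # construction (pandemic covariates under breakpoint zeroing)
            affected = np.nanstd(series[k:]) > 1e-12
            status = "excluded_affected" if affected else "kept"
            decisions.append(
                ScreeningDecision(name, status, reason="constant pre-intervention")
            )
            continue
        res = estimate_impact(
            series, None, k, trend_spec=trend_spec, mcmc=mcmc,
            seed=(int(seed) * 1_000_003 + zlib.crc32(name.encode())) % 2**31,
        )
        status = "excluded_affected" if res.significant else "kept"
        decisions.append(
            ScreeningDecision(name, status, res.relative_effect_point, res.tail_area_p)
        )
    return decisions


def admissible_covariates(decisions: list[ScreeningDecision]) -> list[str]:
    return [d.covariate for d in decisions if d.status in ("kept", "kept_a_priori")]


# ------------------------------------------------------------- effect tables


@dataclass
class EffectMatrices:
    """Country x term matrices of significant relative effects."""

    no_lag: pd.DataFrame
    lagged: pd.DataFrame

    def counts(self, which: str) -> tuple[int, int]:
        """(total significant, negative significant) for one matrix."""
        mat = getattr(self, which)
        vals = mat.to_numpy(dtype=float)
        finite = np.isfinite(vals)
        return int(finite.sum()), int((vals[finite] < 0).sum())

    @property
    def terms_with_effect(self) -> set[str]:
        out = set()
        for mat in (self.no_lag, self.lagged):
            nonempty = mat.columns[mat.notna().any(axis=0)]
            out.update(nonempty)
        return out

    def drop_empty_columns(self, which: str) -> pd.DataFrame:
        mat = getattr(self, which)
        return mat.loc[:, mat.notna().any(axis=0)]

    def contradictions(self) -> list[tuple[str, str]]:
        """Cells where the two matrices carry significant opposite signs."""
        both = self.no_lag.notna() & self.lagged.notna()
        out = []
        for country in both.index:
            for term in both.columns:
                if both.loc[country, term]:
                    a, b = self.no_lag.loc[country, term], self.lagged.loc[country, term]
                    if np.sign(a) != np.sign(b):
                        out.append((country, term))
        return out


def effect_table_from_fixture(table: pd.DataFrame, countries, terms) -> pd.DataFrame:
    """Long fixture (country, term, relative_effect) -> country x term matrix."""
    mat = pd.DataFrame(np.nan, index=list(countries), columns=list(terms))
    for _, row in table.iterrows():
        mat.loc[row["country"], row["term"]] = row["relative_effect"]
    return mat


def effect_matrix(
    results: dict[tuple[str, str], dict[str, CausalImpactResult]],
    countries: list[str],
    terms: list[str],
) -> EffectMatrices:
    """Assemble significant-effect matrices from per-cell impact results.

    ``results`` maps (country, term) to a dict with keys ``no_lag`` and/or
    ``lagged``.  Nonsignificant cells stay empty; each matrix reports the
    point relative effect of significant cells only.
    """
    mats = {
        name: pd.DataFrame(np.nan, index=list(countries), columns=list(terms))
        for name in ("no_lag", "lagged")
    }
    for (country, term), pair in results.items():
        for name, res in pair.items():
            if res is not None and res.significant:
                mats[name].loc[country, term] = res.relative_effect_point
    return EffectMatrices(no_lag=mats["no_lag"], lagged=mats["lagged"])
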