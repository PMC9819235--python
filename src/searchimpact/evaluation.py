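"""Benchmark forecasts and the model-comparison layer.

Counterfactual forecasts from every model are compared on the
post-intervention window under quadratic loss: root mean square error per
model, pairwise Diebold-Mariano tests of equal forecast accuracy with the
Harvey-Leybourne-Newbold small-sample correction, and the Model Confidence
Set procedure (range statistic over pairwise t-statistics, moving-block
bootstrap, iterative elimination) yielding the set of models not
significantly outperformed at the chosen confidence level.  Benchmarks are
the no-change (naive) forecast and a bounded stepwise AIC search over ARIMA
orders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel import ConfigurationError


# ----------------------------------------------------------------- forecasts


def naive_forecast(y, intervention_index: int, horizon: int) -> np.ndarray:
    """No-change forecast: every post month equals the last pre observation."""
    y = np.asarray(y, dtype=float)
    pre = y[:intervention_index]
    pre = pre[np.isfinite(pre)]
    if pre.size == 0:
        raise ConfigurationError("empty pre-intervention window")
    return np.full(horizon, pre[-1])


@dataclass
class ArimaFit:
    order: tuple[int, int, int]
    aic: float
    forecast: np.ndarray
    params: dict[str, float]
    fitted: np.ndarray | None = None  # one-step in-sample predictions


def _kpss_d(y: np.ndarray, max_d: int = 2) -> int:
    """Differencing order by repeated KPSS tests at the 5% level."""
    from statsmodels.tsa.stattools import kpss

    d = 0
    x = y.copy()
    while d < max_d:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                pval = kpss(x, regression="c", nlags="auto")[1]
            except (ValueError, OverflowError):
                break
        if pval >= 0.05:
            break
        x = np.diff(x)
        d += 1
    return d


def auto_arima_forecast(
    y_pre,
    horizon: int,
    max_p: int = 5,
    max_q: int = 5,
    return_fit: bool = False,
):
    """Stepwise AIC order selection and mean forecast.

    The differencing order is chosen by KPSS tests; (p, q) by a stepwise
    neighbourhood search (start points (0,0), (1,0), (0,1), (2,2); moves of
    +-1 in each order) minimizing AIC, with bounded maxima to guarantee
    termination.  Deterministic for a given input.
    """
    from statsmodels.tsa.arima.model import ARIMA

    y = np.asarray(y_pre, dtype=float)
    if not np.isfinite(y).all():
        raise ConfigurationError("auto-ARIMA requires a fully observed series")
    if len(y) < 24:
        raise ConfigurationError("need >= 24 pre months")
    d = _kpss_d(y)
    cache: dict[tuple[int, int], float] = {}
    fits: dict[tuple[int, int], object] = {}

    def score(p, q):
        if (p, q) in cache:
            return cache[(p, q)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = ARIMA(y, order=(p, d, q), trend="c" if d == 0 else "n").fit()
                aic = float(fit.aic)
                roots = np.concatenate([np.abs(fit.arroots), np.abs(fit.maroots)])
                if roots.size and roots.min() < 1.01:
                    aic = np.inf  # near unit-circle root: inadmissible fit
            except (np.linalg.LinAlgError, ValueError):
                aic = np.inf
                fit = None
        cache[(p, q)] = aic
        fits[(p, q)] = fit
        return aic

    current = min(((0, 0), (1, 0), (0, 1), (2, 2)), key=lambda pq: score(*pq))
    improved = True
    while improved:
        improved = False
        p0, q0 = current
        for dp, dq in ((1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (-1, -1)):
            p, q = p0 + dp, q0 + dq
            if 0 <= p <= max_p and 0 <= q <= max_q and score(p, q) < score(*current):
                current = (p, q)
                improved = True
    fit = fits[current]
    if fit is None:
        raise ConfigurationError("no ARIMA order could be fitted")
    fc = np.asarray(fit.forecast(horizon)) if horizon else np.empty(0)
    if return_fit:
        params = dict(zip(fit.model.param_names, np.asarray(fit.params)))
        return fc, ArimaFit(
            (current[0], d, current[1]),
            float(fit.aic),
            fc,
            params,
            fitted=np.asarray(fit.fittedvalues),
        )
    return fc


# --------------------------------------------------------------------- loss


def rmse(observed, forecast) -> float:
    """Root mean square error between an observed and a forecast series."""
    o = np.asarray(observed, dtype=float)
    f = np.asarray(forecast, dtype=float)
    if o.shape != f.shape:
        raise ConfigurationError("length mismatch")
    if o.size == 0:
        raise ConfigurationError("empty input")
    return float(np.sqrt(np.mean((o - f) ** 2)))


@dataclass
class LossMatrix:
    """Post-period squared forecast errors, months x models."""

    losses: pd.DataFrame

    def __post_init__(self) -> None:
        if self.losses.isna().any().any():
            raise ConfigurationError("loss matrix has missing entries")

    @classmethod
    def from_forecasts(cls, observed, forecasts: dict[str, np.ndarray]) -> "LossMatrix":
        o = np.asarray(observed, dtype=float)
        cols = {}
        for name, fc in forecasts.items():
            fc = np.asarray(fc, dtype=float)
            if fc.shape != o.shape:
                raise ConfigurationError(f"forecast {name!r} length mismatch")
            cols[name] = (o - fc) ** 2
        return cls(pd.DataFrame(cols))

    @property
    def models(self) -> list[str]:
        return list(self.losses.columns)

    def rmse_table(self) -> pd.Series:
        return np.sqrt(self.losses.mean(axis=0))


# ------------------------------------------------------------------ DM test


def dm_test(
    errors_a,
    errors_b,
    one_sided: bool = True,
    h: int = 1,
    squared: bool = True,
) -> float:
    """Diebold-Mariano p-value with the Harvey small-sample correction.

    ``errors_a``/``errors_b`` are forecast errors (squared already if
    ``squared=False``).  The loss differential is d_t = e_a^2 - e_b^2; its
    long-run variance uses a truncated autocovariance window with h-1 lags
    (plain sample variance for one-step losses).  The statistic is scaled
    by sqrt((T + 1 - 2h + h(h-1)/T)/T) and referred to a t distribution
    with T-1 degrees of freedom.  One-sided alternative: forecast a is more
    accurate (smaller loss).  Exact ties return 0.5.
    """
    la = np.asarray(errors_a, dtype=float)
    lb = np.asarray(errors_b, dtype=float)
    if squared:
        la, lb = la**2, lb**2
    if la.shape != lb.shape:
        raise ConfigurationError("error series length mismatch")
    T = la.size
    if T < 4:
        raise ConfigurationError("need at least 4 evaluation points")
    d = la - lb
    dbar = d.mean()
    dc = d - dbar
    # long-run variance of dbar, truncated at h-1 lags
    lrv = float(np.mean(dc**2))
    for lag in range(1, h):
        cov = float(np.mean(dc[lag:] * dc[:-lag]))
        lrv += 2.0 * cov
    if lrv <= 0:
        return 0.5  # degenerate: exact ties or negative LRV estimate
    dm = dbar / np.sqrt(lrv / T)
    correction = np.sqrt((T + 1 - 2 * h + h * (h - 1) / T) / T)
    dm *= correction
    if one_sided:
        return float(stats.t.cdf(dm, df=T - 1))  # small loss of a => dm < 0 => small p
    return float(2.0 * stats.t.sf(abs(dm), df=T - 1))


# ---------------------------------------------------------------------- MCS


@dataclass
class ComparisonResult:
    rmse: pd.Series
    dm_p: pd.DataFrame
    mcs_superior_set: list[str]
    mcs_pvalues: pd.Series


def _block_bootstrap_indices(rng, T, B, block_length):
    n_blocks = int(np.ceil(T / block_length))
    starts = rng.integers(0, T, size=(B, n_blocks))
    offsets = np.arange(block_length)
    idx = (starts[:, :, None] + offsets[None, None, :]) % T
    return idx.reshape(B, -1)[:, :T]


def mcs(
    loss: LossMatrix,
    n_bootstrap: int = 1000,
    confidence: float = 0.90,
    rng: np.random.Generator | int = 0,
    block_length: int = 3,
) -> tuple[list[str], pd.Series]:
    """Model Confidence Set by iterative elimination with the TR statistic.

    The equal-predictive-ability null is tested with the range statistic
    over pairwise t-ratios of mean loss differentials, its null
    distribution approximated by a moving-block bootstrap of the loss rows.
    While the null is rejected at level 1-confidence, the model with the
    largest standardized loss disadvantage is eliminated.  Returns the
    surviving set and the sequential MCS p-values per model.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    L = loss.losses.to_numpy(dtype=float)
    names = list(loss.losses.columns)
    if len(names) < 2:
        raise ConfigurationError("need at least 2 models")
    T = L.shape[0]
    if T < 8:
        raise ConfigurationError("need at least 8 evaluation months")
    alive = list(range(len(names)))
    pvals: dict[str, float] = {}
    boot_idx = _block_bootstrap_indices(rng, T, n_bootstrap, block_length)
    p_max = 0.0
    while len(alive) > 1:
        La = L[:, alive]
        dbar = La.mean(axis=0)  # (m,)
        diff = dbar[:, None] - dbar[None, :]
        boot_means = La[boot_idx].mean(axis=1)  # (B, m)
        boot_diff = boot_means[:, :, None] - boot_means[:, None, :]
        var = ((boot_diff - diff[None]) ** 2).mean(axis=0)
        sd = np.sqrt(var)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(sd > 0, diff / sd, 0.0)
            tboot = np.where(sd[None] > 0, (boot_diff - diff[None]) / sd[None], 0.0)
        TR = float(np.max(np.abs(tstat)))
        TR_boot = np.max(np.abs(tboot), axis=(1, 2))
        p = float(np.mean(TR_boot >= TR)) if TR > 0 else 1.0
        p_max = max(p_max, p)
        if p >= 1.0 - confidence:
            for i in alive:
                pvals.setdefault(names[i], p_max)
            break
        worst_local = int(np.argmax(tstat.max(axis=1)))
        pvals[names[alive[worst_local]]] = p_max
        alive.pop(worst_local)
    if len(alive) == 1:
        pvals.setdefault(names[alive[0]], 1.0)
    superior = [names[i] for i in alive] if len(alive) > 1 else [names[alive[0]]]
    # models never tested (eliminated before entry) cannot occur; fill order
    pseries = pd.Series({nm: pvals.get(nm, 1.0) for nm in names})
    return superior, pseries


def compare_models(
    observed,
    forecasts: dict[str, np.ndarray],
    reference: str | None = None,
    n_bootstrap: int = 1000,
    confidence: float = 0.90,
    rng: np.random.Generator | int = 0,
) -> ComparisonResult:
    """RMSE + DM (vs a reference model) + MCS for one evaluation window."""
    loss = LossMatrix.from_forecasts(observed, forecasts)
    rmse_tab = loss.rmse_table()
    reference = reference or rmse_tab.idxmin()
    o = np.asarray(observed, dtype=float)
    dm = {}
    for name, fc in forecasts.items():
        if name == reference:
            continue
        dm[name] = dm_test(o - np.asarray(forecasts[reference]), o - np.asarray(fc))
    dm_frame = pd.DataFrame({reference: pd.Series(dm)})
    superior, pvals = mcs(loss, n_bootstrap=n_bootstrap, confidence=confidence, rng=rng)
    return ComparisonResult(
        rmse=rmse_tab, dm_p=dm_frame, mcs_superior_set=superior, mcs_pvalues=pvals
    )


# ------------------------------------------------------------- aggregation


@dataclass
class SummaryTables:
    rmse_by_country: pd.DataFrame  # model x country means over terms
    rmse_by_term: pd.DataFrame  # model x term means over countries
    dm_by_country: pd.DataFrame
    dm_by_term: pd.DataFrame
    mcs_frequency: pd.Series  # share of cells where each model survived
    best_model_share: pd.Series  # share of cells where each model had min RMSE


def aggregate_tables(
    results: dict[tuple[str, str], ComparisonResult],
    reference: str | None = None,
) -> SummaryTables:
    """Grid-level averages: RMSE and DM-p means by country and by term,
    superior-set membership frequency, and best-RMSE shares."""
    rows = []
    dm_rows = []
    mcs_counts: dict[str, int] = {}
    best_counts: dict[str, int] = {}
    n_cells = 0
    for (country, term), res in results.items():
        n_cells += 1
        for model, val in res.rmse.items():
            rows.append((country, term, model, float(val)))
        col = res.dm_p.iloc[:, 0] if reference is None else res.dm_p.get(reference)
        if col is not None:
            for model, val in col.items():
                if np.isfinite(val):
                    dm_rows.append((country, term, model, float(val)))
        for model in res.mcs_superior_set:
            mcs_counts[model] = mcs_counts.get(model, 0) + 1
        best = res.rmse.idxmin()
        best_counts[best] = best_counts.get(best, 0) + 1
    rmse_frame = pd.DataFrame(rows, columns=["country", "term", "model", "rmse"])
    dm_frame = pd.DataFrame(dm_rows, columns=["country", "term", "model", "p"])
    by_country = rmse_frame.pivot_table(index="model", columns="country", values="rmse")
    by_term = rmse_frame.pivot_table(index="model", columns="term", values="rmse")
    if len(dm_frame):
        dm_country = dm_frame.pivot_table(index="model", columns="country", values="p")
        dm_term = dm_frame.pivot_table(index="model", columns="term", values="p")
    else:
        dm_country = pd.DataFrame()
        dm_term = pd.DataFrame()
    denom = max(n_cells, 1)
    mcs_freq = pd.Series({m: c / denom for m, c in mcs_counts.items()}).sort_values(
        ascending=False
    )
    best_share = pd.Series({m: c / denom for m, c in best_counts.items()}).sort_values(
        ascending=False
    )
    return SummaryTables(
        rmse_by_country=by_country,
        rmse_by_term=by_term,
        dm_by_country=dm_country,
        dm_by_term=dm_term,
        mcs_frequency=mcs_freq,
        best_model_share=best_share,
    )
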