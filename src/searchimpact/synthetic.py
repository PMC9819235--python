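"""Synthetic panel generator and packaged fixture tables.

The study design needs monthly search-intensity panels whose ground truth is
known: a latent structural series (trend + 12-month seasonality + static
regression on a known covariate subset + Gaussian noise) mapped to the
bounded 0-100 integer index scale, persistent autoregressive macro
covariates, pandemic covariates that are exactly zero before a breakpoint
month, and additive post-intervention effects of configurable shape.  The
generator here produces such panels deterministically from a seed, and the
module also ships small transcribed reference tables (term and country
rosters, detected-effect matrices) used by the summarization layer.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .panel import (
    COVARIATE_NAMES,
    COVID_COVARIATES,
    INDICATOR_NAMES,
    ConfigurationError,
    MonthlyPanel,
)

TREND_SPECS = ("local_level", "local_linear", "semilocal_linear", "student_local_linear")
EFFECT_SHAPES = ("step", "pulse", "decay")

_FIXTURES = ("detected_effects_nolag", "detected_effects_lagged", "term_list", "country_list", "no_effect_terms")


@dataclass
class SimulationConfig:
    """Data-generating-process parameters for one synthetic panel.

    The defaults mirror the study conditions: a January-2004 month axis with
    195 pre-intervention and 15 post-intervention months (210 in total), a
    local linear trend, 12-month seasonality, a small true covariate support,
    and pandemic covariates switching on one month before the intervention.
    Index units refer to the 0-100 search-intensity scale after the affine
    latent-to-index mapping.
    """

    n_pre: int = 195
    n_post: int = 15
    trend_spec: str = "local_linear"
    seasonal_amplitude: float = 3.0
    true_support: tuple[str, ...] = ("une", "epu", "stocks")
    true_coefficients: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    level_sd: float = 0.3
    slope_sd: float = 0.02
    seasonal_sd: float = 0.1
    effect_size: float = 10.0
    effect_shape: str = "step"
    decay_ratio: float = 0.7
    seed: int = 0
    start_month: str = "2004-01-01"
    ar_persistence: float = 0.9
    ar_innovation_sd: float = 1.0
    covid_breakpoint: int | None = None  # month index; default n_pre - 1
    initial_level: float = 0.0
    initial_slope: float = 0.0
    ar_slope_mean: float = 0.0  # semilocal: long-run slope D
    ar_slope_persistence: float = 0.6  # semilocal: phi
    tail_dof: float = 5.0  # student trend innovations

    def __post_init__(self) -> None:
        if self.n_pre < 24:
            raise ConfigurationError("n_pre must be >= 24 (two seasonal cycles)")
        if self.n_post < 0:
            raise ConfigurationError("n_post must be >= 0")
        if self.trend_spec not in TREND_SPECS:
            raise ConfigurationError(f"unknown trend_spec {self.trend_spec!r}")
        if self.effect_shape not in EFFECT_SHAPES:
            raise ConfigurationError(f"unknown effect_shape {self.effect_shape!r}")
        for name in ("noise_sd", "level_sd", "slope_sd", "seasonal_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        unknown = set(self.true_support) - set(COVARIATE_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown covariates in true_support: {sorted(unknown)}")
        if not isinstance(self.seed, (int, np.integer)) or self.seed < 0:
            raise ConfigurationError("seed must be a nonnegative integer")
        if not self.true_coefficients:
            self.true_coefficients = {name: 1.0 for name in self.true_support}

    @property
    def n_months(self) -> int:
        return self.n_pre + self.n_post

    @property
    def months(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_month, periods=self.n_months, freq="MS")

    @property
    def breakpoint_index(self) -> int:
        if self.covid_breakpoint is not None:
            return int(self.covid_breakpoint)
        return max(self.n_pre - 1, 0)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "true_support" in raw:
            raw["true_support"] = tuple(raw["true_support"])
        return cls(**raw)


@dataclass
class SeriesTruth:
    """Latent ground truth recorded for one simulated series."""

    latent: np.ndarray  # pre-rounding latent values on the index scale
    trend: np.ndarray
    seasonal: np.ndarray
    regression: np.ndarray
    noise: np.ndarray
    map_offset: float
    map_scale: float
    coefficients: dict[str, float]
    effect_path: np.ndarray
    counterfactual_response: np.ndarray  # integer response before injection


@dataclass
class SyntheticPanel:
    """A monthly panel together with its per-series ground truth."""

    panel: MonthlyPanel
    truth: dict[tuple[str, str], SeriesTruth]
    config: SimulationConfig


def _substream(seed: int, *labels) -> np.random.Generator:
    """Deterministic child stream keyed by string/integer labels."""
    key = [int(seed)]
    for lab in labels:
        if isinstance(lab, str):
            key.append(zlib.crc32(lab.encode()))
        else:
            key.append(int(lab))
    return np.random.default_rng(key)


def _lognormal_pulse(s: np.ndarray, center: float, width: float) -> np.ndarray:
    """Smooth nonnegative epidemic-wave pulse over months-since-breakpoint."""
    t = np.maximum(s, 0.0) + 0.5
    return np.exp(-0.5 * ((np.log(t) - np.log(center)) / width) ** 2)


def simulate_covariates(config: SimulationConfig, country: str = "SYN") -> pd.DataFrame:
    """Simulate the 12-covariate matrix for one country.

    Macro covariates are stationary AR(1) paths with persistence
    ``config.ar_persistence``; pandemic covariates are zero before the
    breakpoint month and follow smooth nonnegative pulses after it;
    the stringency index is a piecewise-constant step series.
    """
    n = config.n_months
    bp = config.breakpoint_index
    rng = _substream(config.seed, "covariates", country)
    cols: dict[str, np.ndarray] = {}
    phi, isd = config.ar_persistence, config.ar_innovation_sd
    stat_sd = isd / np.sqrt(1.0 - phi**2) if abs(phi) < 1 else isd
    for name in ("i_rate", "cpi", "une", "stocks", "gpr", "epu", "ec_act", "oil"):
        x = np.empty(n)
        x[0] = rng.normal(0.0, stat_sd)
        shocks = rng.normal(0.0, isd, size=n - 1)
        for t in range(1, n):
            x[t] = phi * x[t - 1] + shocks[t - 1]
        cols[name] = x

    s = np.arange(n, dtype=float) - bp
    post = s >= 0
    cases = np.zeros(n)
    for center, width, amp in ((3.0, 0.6, 4000.0), (10.0, 0.4, 6000.0)):
        cases[post] += amp * _lognormal_pulse(s[post], center, width)
    cases[post] *= np.exp(rng.normal(0.0, 0.1, size=post.sum()))
    deaths = np.zeros(n)
    deaths[post] = 0.02 * np.concatenate([[0.0], cases[post][:-1]])  # one-month lag
    repro = np.zeros(n)
    repro[post] = np.maximum(
        0.0, 1.0 + 1.5 * np.exp(-s[post] / 8.0) + rng.normal(0.0, 0.05, size=post.sum())
    )
    stringency = np.zeros(n)
    steps = ((0, 3, 75.0), (3, 9, 55.0), (9, n, 35.0))
    for lo, hi, level in steps:
        sel = post & (s >= lo) & (s < hi)
        stringency[sel] = level
    cols["new_cases_per_million"] = cases
    cols["new_deaths_per_million"] = deaths
    cols["reproduction_rate"] = repro
    cols["stringency_index"] = stringency
    try:
        index = config.months
    except pd.errors.OutOfBoundsDatetime:
        index = pd.RangeIndex(n)  # horizons beyond the ns-datetime range
    return pd.DataFrame(cols, index=index, columns=list(COVARIATE_NAMES))


def _simulate_trend(config: SimulationConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    mu = np.empty(n)
    mu[0] = config.initial_level
    kind = config.trend_spec
    if kind == "local_level":
        u = rng.normal(0.0, config.level_sd, size=n - 1)
        mu[1:] = mu[0] + np.cumsum(u)
        return mu
    delta = config.initial_slope
    phi, d_bar = config.ar_slope_persistence, config.ar_slope_mean
    for t in range(1, n):
        u = rng.normal(0.0, config.level_sd)
        if kind == "student_local_level":  # pragma: no cover - not in roster
            raise AssertionError
        if kind == "student_local_linear":
            u = config.level_sd * rng.standard_t(config.tail_dof)
            v = config.slope_sd * rng.standard_t(config.tail_dof)
        else:
            v = rng.normal(0.0, config.slope_sd)
        mu[t] = mu[t - 1] + delta + u
        if kind == "semilocal_linear":
            delta = d_bar + phi * (delta - d_bar) + v
        else:  # local_linear / student_local_linear: random-walk slope
            delta = delta + v
    return mu


def _seasonal_pattern(amplitude: float, period: int = 12) -> np.ndarray:
    pattern = amplitude * np.cos(2 * np.pi * np.arange(period) / period)
    return pattern - pattern.mean()  # exact zero-sum over one cycle


def _simulate_seasonal(config: SimulationConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    period = 12
    pattern = _seasonal_pattern(config.seasonal_amplitude, period)
    gamma = np.empty(n)
    gamma[: period - 1] = pattern[: period - 1]
    for t in range(period - 1, n):
        w = rng.normal(0.0, config.seasonal_sd) if config.seasonal_sd > 0 else 0.0
        gamma[t] = -np.sum(gamma[t - period + 1 : t]) + w
    return gamma


def simulate_response(
    config: SimulationConfig,
    covariates: pd.DataFrame,
    country: str = "SYN",
    term: str = "synthetic",
) -> SyntheticPanel:
    """Build one response series from the structural DGP and wrap it in a panel.

    The latent series is trend + seasonal + regression + noise; it is then
    affine-mapped so that its pre-intervention range spans [5, 95], rounded
    to integers and clipped to [0, 100].  Pre-rounding values and the map
    are recorded in the truth record.
    """
    n = config.n_months
    if len(covariates) != n:
        raise ConfigurationError("covariate matrix does not cover n_pre + n_post months")
    unknown = set(config.true_support) - set(covariates.columns)
    if unknown:
        raise ConfigurationError(f"true_support names unknown covariates: {sorted(unknown)}")
    rng = _substream(config.seed, "response", country, term)
    trend = _simulate_trend(config, rng, n)
    seasonal = _simulate_seasonal(config, rng, n)
    regression = np.zeros(n)
    for name in config.true_support:
        regression += config.true_coefficients[name] * covariates[name].to_numpy()
    noise = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else np.zeros(n)
    latent = trend + seasonal + regression + noise

    pre = latent[: config.n_pre]
    lo, hi = float(pre.min()), float(pre.max())
    if hi > lo:
        scale = 90.0 / (hi - lo)
        offset = 5.0 - scale * lo
    else:
        scale, offset = 1.0, 50.0 - lo
    mapped = offset + scale * latent
    response = np.clip(np.round(mapped), 0, 100).astype(float)

    months = config.months
    intervention = months[config.n_pre] if config.n_post > 0 else None
    panel = MonthlyPanel(
        months=months,
        countries=[country],
        terms=[term],
        response={(country, term): response},
        covariates={country: covariates},
        intervention_month={country: intervention},
    )
    truth = SeriesTruth(
        latent=mapped,
        trend=trend,
        seasonal=seasonal,
        regression=regression,
        noise=noise,
        map_offset=offset,
        map_scale=scale,
        coefficients=dict(config.true_coefficients),
        effect_path=np.zeros(n),
        counterfactual_response=response.copy(),
    )
    return SyntheticPanel(panel=panel, truth={(country, term): truth}, config=config)


def effect_path(
    n_post: int, effect_size: float, effect_shape: str, decay_ratio: float = 0.7
) -> np.ndarray:
    """The additive post-period effect path for the configured shape."""
    if effect_shape not in EFFECT_SHAPES:
        raise ConfigurationError(f"unknown effect_shape {effect_shape!r}")
    if effect_shape == "step":
        return np.full(n_post, float(effect_size))
    if effect_shape == "pulse":
        path = np.zeros(n_post)
        if n_post:
            path[0] = effect_size
        return path
    return effect_size * decay_ratio ** np.arange(n_post, dtype=float)


def inject_intervention_effect(
    synth: SyntheticPanel,
    start_month,
    effect_size: float,
    effect_shape: str = "step",
    decay_ratio: float = 0.7,
    keys: list[tuple[str, str]] | None = None,
) -> SyntheticPanel:
    """Shift post-period responses by an additive effect path (in place).

    The pre-period is untouched; values are re-rounded and clipped to
    [0, 100] after the shift.  The injected path and the pre-injection
    (counterfactual) response are recorded per series.
    """
    panel = synth.panel
    start = pd.Timestamp(start_month) if not isinstance(start_month, (int, np.integer)) else None
    idx = panel.month_index(start) if start is not None else int(start_month)
    if not 0 <= idx < panel.n_months:
        raise IndexError(f"start_month index {idx} outside panel range")
    n_post = panel.n_months - idx
    path = effect_path(n_post, effect_size, effect_shape, decay_ratio)
    for key in keys or list(panel.response):
        truth = synth.truth[key]
        base = truth.counterfactual_response
        shifted = base.astype(float).copy()
        shifted[idx:] = np.clip(np.round(base[idx:] + path), 0, 100)
        panel.response[key] = shifted
        truth.effect_path = np.concatenate([np.zeros(idx), path])
    return synth


def simulate_study_panel(
    config: SimulationConfig,
    countries: list[str],
    terms: list[str],
    effects: dict[tuple[str, str], float] | None = None,
) -> SyntheticPanel:
    """A multi-country, multi-term panel sharing one configuration.

    Each country gets its own covariate substream and each (country, term)
    its own response substream; ``effects`` optionally assigns a per-series
    step effect size (series not listed get no injected effect).
    """
    months = config.months
    response: dict[tuple[str, str], np.ndarray] = {}
    covariates: dict[str, pd.DataFrame] = {}
    truth: dict[tuple[str, str], SeriesTruth] = {}
    intervention = {c: months[config.n_pre] if config.n_post else None for c in countries}
    for country in countries:
        covariates[country] = simulate_covariates(config, country)
        for term in terms:
            single = simulate_response(config, covariates[country], country, term)
            response[(country, term)] = single.panel.response[(country, term)]
            truth[(country, term)] = single.truth[(country, term)]
    panel = MonthlyPanel(
        months=months,
        countries=list(countries),
        terms=list(terms),
        response=response,
        covariates=covariates,
        intervention_month=intervention,
    )
    synth = SyntheticPanel(panel=panel, truth=truth, config=config)
    if effects and config.n_post:
        for key, size in effects.items():
            inject_intervention_effect(
                synth, int(config.n_pre), size, config.effect_shape, config.decay_ratio, keys=[key]
            )
    return synth


def simulate_policy_indicators(
    seed: int,
    schedule: list[tuple[str, str, str, int]] | list[tuple[str, str, str]],
    start: str | None = None,
    end: str | None = None,
) -> pd.DataFrame:
    """Daily ordinal policy-indicator series matching an interval schedule.

    ``schedule`` rows are ``(indicator, first_day, last_day[, level])``.
    Overlapping intervals for the same indicator with contradictory levels
    raise a configuration error.  Days not covered by any interval are 0.
    """
    del seed  # the schedule is deterministic; kept for interface symmetry
    norm = []
    for row in schedule:
        if len(row) == 3:
            name, d0, d1 = row
            level = 1
        else:
            name, d0, d1, level = row
        if name not in INDICATOR_NAMES:
            raise ConfigurationError(f"unknown indicator {name!r}")
        d0, d1 = pd.Timestamp(d0), pd.Timestamp(d1)
        if d0 > d1:
            raise ConfigurationError("interval start after end")
        norm.append((name, d0, d1, int(level)))
    if start is None:
        start = min((d0 for _, d0, _, _ in norm), default=pd.Timestamp("2020-01-01"))
    if end is None:
        end = max((d1 for _, _, d1, _ in norm), default=pd.Timestamp("2020-12-31"))
    days = pd.date_range(start, end, freq="D")
    out = pd.DataFrame(0, index=days, columns=list(INDICATOR_NAMES))
    for name, d0, d1, level in norm:
        sel = (days >= d0) & (days <= d1)
        current = out.loc[sel, name]
        clash = current[(current != 0) & (current != level)]
        if len(clash):
            raise ConfigurationError(
                f"contradictory overlapping intervals for {name!r} around {clash.index[0].date()}"
            )
        out.loc[sel, name] = level
    return out


def load_fixture(name: str) -> pd.DataFrame:
    """Load one of the packaged transcription tables.

    Available: ``detected_effects_nolag`` and ``detected_effects_lagged`` (detected relative
    effects by country and term for the unlagged / lagged headline models),
    ``term_list`` (the 23 search terms), ``country_list`` (the 15 country
    codes), ``no_effect_terms`` (terms for which neither headline model
    detected an effect).
    """
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {_FIXTURES}")
    ref = resources.files("searchimpact.fixtures") / f"{name}.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path)
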