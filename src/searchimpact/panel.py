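"""Monthly panel container and preprocessing.

The analysis operates on a country x search-term panel of monthly
search-intensity indices (integers on a 0-100 scale) together with a fixed
roster of twelve per-country covariates: macroeconomic series (short-term
interest rate, CPI inflation, unemployment, stock index), uncertainty indices
(geopolitical risk, economic-policy uncertainty), global series (real-activity
index, oil price), and pandemic series (new cases / deaths per million,
reproduction rate, stringency index).  This module provides the container,
the aggregation of daily pandemic data to months, missing-value handling
(last observation carried forward, with a fixed breakpoint before which
pandemic series are defined as zero), bilingual averaging, panel rescaling,
pre-window standardization, and the lockdown-period detector that derives
each country's intervention month from daily policy indicators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The fixed covariate roster, in its conventional order.
COVARIATE_NAMES: tuple[str, ...] = (
    "i_rate",
    "cpi",
    "une",
    "stocks",
    "gpr",
    "epu",
    "ec_act",
    "oil",
    "new_cases_per_million",
    "new_deaths_per_million",
    "reproduction_rate",
    "stringency_index",
)

#: Covariates derived from pandemic surveillance data; exactly zero before the
#: breakpoint month by convention.
COVID_COVARIATES: tuple[str, ...] = (
    "new_cases_per_million",
    "new_deaths_per_million",
    "reproduction_rate",
    "stringency_index",
)

#: Daily policy indicators consumed by the lockdown detector.
INDICATOR_NAMES: tuple[str, ...] = (
    "movement_restrictions",
    "school_closing",
    "workplace_closing",
    "gathering_restrictions",
)

#: Default breakpoint before which pandemic series are defined as zero.
DEFAULT_COVID_BREAKPOINT = pd.Timestamp("2020-03-01")


class AlignmentError(ValueError):
    """Raised when series do not share the required axis."""


class ConfigurationError(ValueError):
    """Raised for invalid configuration values."""


class DegenerateSeriesError(ValueError):
    """Raised when an operation requires non-degenerate variation."""


@dataclass
class LockdownPeriod:
    """A maximal run of months each containing at least one lockdown day."""

    country: str
    start_month: pd.Timestamp
    end_month: pd.Timestamp

    def __post_init__(self) -> None:
        if self.start_month > self.end_month:
            raise ValueError("start_month must not exceed end_month")


@dataclass
class MonthlyPanel:
    """Country x term x month panel of responses, covariates and interventions.

    Parameters
    ----------
    months
        Ordered month labels (first-of-month timestamps), shared by every
        series in the panel.
    countries, terms
        Country codes and search terms spanning the response grid.
    response
        ``(country, term) -> float array`` of index values in ``[0, 100]``
        (NaN marks missing months).
    covariates
        ``country -> DataFrame`` (months x covariate roster).
    intervention_month
        ``country -> Timestamp`` (or ``None`` for no intervention).
    """

    months: pd.DatetimeIndex
    countries: list[str]
    terms: list[str]
    response: dict[tuple[str, str], np.ndarray]
    covariates: dict[str, pd.DataFrame] = field(default_factory=dict)
    intervention_month: dict[str, pd.Timestamp | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.months = pd.DatetimeIndex(self.months)
        self.validate()

    def validate(self) -> None:
        if len(self.months) == 0:
            raise ConfigurationError("empty month axis")
        diffs = np.diff(self.months.values)
        if len(diffs) and not (diffs > np.timedelta64(0, "ns")).all():
            raise ConfigurationError("month axis must be strictly increasing")
        if (self.months.day != 1).any():
            raise ConfigurationError("months must be labeled by their first day")
        n = len(self.months)
        for key, series in self.response.items():
            arr = np.asarray(series, dtype=float)
            if arr.shape != (n,):
                raise AlignmentError(f"response {key} does not match month axis")
            finite = arr[np.isfinite(arr)]
            if finite.size and (finite.min() < 0 or finite.max() > 100):
                raise ConfigurationError(f"response {key} outside [0, 100]")
            self.response[key] = arr
        for country, mat in self.covariates.items():
            if len(mat) != n:
                raise AlignmentError(f"covariates for {country} do not match month axis")
            unknown = set(mat.columns) - set(COVARIATE_NAMES)
            if unknown:
                raise ConfigurationError(f"unknown covariates for {country}: {sorted(unknown)}")

    @property
    def n_months(self) -> int:
        return len(self.months)

    def series(self, country: str, term: str) -> np.ndarray:
        return self.response[(country, term)]

    def month_index(self, month: pd.Timestamp) -> int:
        loc = self.months.get_indexer([pd.Timestamp(month)])[0]
        if loc < 0:
            raise KeyError(f"{month} not on the panel month axis")
        return int(loc)

    # ------------------------------------------------------------------ I/O

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format view: date, country, variable, role, value."""
        rows = []
        for (country, term), series in self.response.items():
            rows.append(
                pd.DataFrame(
                    {
                        "date": self.months,
                        "country": country,
                        "variable": term,
                        "role": "response",
                        "value": series,
                    }
                )
            )
        for country, mat in self.covariates.items():
            for name in mat.columns:
                rows.append(
                    pd.DataFrame(
                        {
                            "date": self.months,
                            "country": country,
                            "variable": name,
                            "role": "covariate",
                            "value": mat[name].to_numpy(),
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_long_frame().to_csv(path, index=False)

    @classmethod
    def from_long_frame(
        cls,
        frame: pd.DataFrame,
        intervention_month: dict[str, pd.Timestamp | None] | None = None,
    ) -> "MonthlyPanel":
        frame = frame.copy()
        frame["date"] = pd.to_datetime(frame["date"])
        months = pd.DatetimeIndex(sorted(frame["date"].unique()))
        resp = frame[frame["role"] == "response"]
        cov = frame[frame["role"] == "covariate"]
        response: dict[tuple[str, str], np.ndarray] = {}
        for (country, term), grp in resp.groupby(["country", "variable"], sort=True):
            series = grp.set_index("date")["value"].reindex(months)
            response[(country, term)] = series.to_numpy(dtype=float)
        covariates: dict[str, pd.DataFrame] = {}
        for country, grp in cov.groupby("country", sort=True):
            mat = grp.pivot_table(index="date", columns="variable", values="value")
            mat = mat.reindex(months)
            order = [c for c in COVARIATE_NAMES if c in mat.columns]
            covariates[country] = mat[order]
        countries = sorted({c for c, _ in response} | set(covariates))
        terms = sorted({t for _, t in response})
        return cls(
            months=months,
            countries=countries,
            terms=terms,
            response=response,
            covariates=covariates,
            intervention_month=dict(intervention_month or {}),
        )

    @classmethod
    def read_csv(cls, path, **kwargs) -> "MonthlyPanel":
        return cls.from_long_frame(pd.read_csv(path), **kwargs)


# --------------------------------------------------------------------------
# preprocessing operations
# --------------------------------------------------------------------------


def aggregate_covid_monthly(daily: pd.Series, kind: str) -> pd.Series:
    """Aggregate a daily series to calendar months.

    ``kind="sum"`` for flow variables (new cases / deaths per million),
    ``kind="mean"`` for state variables (reproduction rate, stringency).
    Months with no observations come out missing.
    """
    if kind not in ("sum", "mean"):
        raise ConfigurationError(f"unknown aggregation kind: {kind!r}")
    daily = daily.copy()
    daily.index = pd.DatetimeIndex(daily.index)
    grouped = daily.resample("MS")
    if kind == "sum":
        return grouped.sum(min_count=1)
    return grouped.mean()


def fill_locf_and_zero(
    series: pd.Series,
    breakpoint_month: pd.Timestamp | None = None,
    is_covid: bool = False,
) -> pd.Series:
    """Missing-value policy: breakpoint zeroing for pandemic series, then LOCF.

    Pandemic series are defined as exactly zero before the breakpoint month
    (default March 2020).  Remaining interior gaps are filled with the most
    recent non-missing value.  Leading missing values (nothing to carry
    forward) are left missing and reported with a warning.
    """
    out = series.copy()
    if is_covid:
        bp = pd.Timestamp(breakpoint_month or DEFAULT_COVID_BREAKPOINT)
        out.loc[out.index < bp] = 0.0
    out = out.ffill()
    n_leading = int(out.isna().sum())
    if n_leading:
        warnings.warn(
            f"{n_leading} leading missing value(s) could not be filled",
            UserWarning,
            stacklevel=2,
        )
    return out


@dataclass
class LockdownRule:
    """Ordinal cutoffs for the lockdown definition.

    A day counts as a lockdown day iff internal movement restrictions are in
    place, or schools and workplaces are both closing (at least for some
    levels or categories) while gatherings are restricted to small groups.
    The indicator series are ordinal codes; the defaults treat any nonzero
    level (>= 1) as active.  Stricter corpora can raise the cutoffs (e.g.
    gathering level 4 for a ten-person limit in OxCGRT-style coding).
    """

    movement: int = 1
    school: int = 1
    workplace: int = 1
    gathering: int = 1


def lockdown_days(indicators: pd.DataFrame, rule: LockdownRule | None = None) -> pd.Series:
    """Boolean daily series of lockdown days under the two-case definition."""
    rule = rule or LockdownRule()
    missing = set(INDICATOR_NAMES) - set(indicators.columns)
    if missing:
        raise AlignmentError(f"missing indicator series: {sorted(missing)}")
    case1 = indicators["movement_restrictions"] >= rule.movement
    case2 = (
        (indicators["school_closing"] >= rule.school)
        & (indicators["workplace_closing"] >= rule.workplace)
        & (indicators["gathering_restrictions"] >= rule.gathering)
    )
    return case1 | case2


def detect_lockdown_months(
    indicators: pd.DataFrame,
    country: str = "",
    rule: LockdownRule | None = None,
) -> list[LockdownPeriod]:
    """Detect maximal runs of lockdown months from daily policy indicators.

    A month belongs to a lockdown period iff it contains at least one
    lockdown day.  The intervention month of a country is the first month
    of the first detected period.
    """
    indicators = indicators.copy()
    indicators.index = pd.DatetimeIndex(indicators.index)
    days = lockdown_days(indicators, rule)
    monthly = days.resample("MS").max()
    flagged = monthly.fillna(False).astype(bool)
    periods: list[LockdownPeriod] = []
    run_start: pd.Timestamp | None = None
    prev: pd.Timestamp | None = None
    for month, on in flagged.items():
        if on and run_start is None:
            run_start = month
        elif not on and run_start is not None:
            periods.append(LockdownPeriod(country, run_start, prev))
            run_start = None
        prev = month
    if run_start is not None:
        periods.append(LockdownPeriod(country, run_start, prev))
    return periods


def average_bilingual(series_a: np.ndarray, series_b: np.ndarray) -> np.ndarray:
    """Element-wise average of two language versions of the same term."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise AlignmentError("bilingual series must have equal length")
    return (a + b) / 2.0


def rescale_relative(series: np.ndarray) -> np.ndarray:
    """Divide a series by its full-sample mean (pooled-panel rescaling)."""
    arr = np.asarray(series, dtype=float)
    mean = np.nanmean(arr)
    if not np.isfinite(mean) or mean == 0:
        raise DegenerateSeriesError("cannot rescale a series with zero mean")
    return arr / mean


@dataclass
class StandardizationConstants:
    mean: float
    sd: float


def standardize(
    series: np.ndarray,
    reference_window: slice | int | None = None,
    inverse: bool = False,
    constants: StandardizationConstants | None = None,
) -> tuple[np.ndarray, StandardizationConstants]:
    """Standardize using pre-intervention mean/sd; exact inverse round-trip.

    Forward: ``(x - m) / s`` with ``m, s`` computed over ``reference_window``
    (an int is shorthand for ``slice(0, n_pre)``; ``None`` uses the full
    series).  Inverse requires the stored constants.
    """
    arr = np.asarray(series, dtype=float)
    if inverse:
        if constants is None:
            raise ConfigurationError("inverse standardization requires constants")
        return arr * constants.sd + constants.mean, constants
    if constants is None:
        if isinstance(reference_window, int):
            reference_window = slice(0, reference_window)
        ref = arr[reference_window] if reference_window is not None else arr
        ref = ref[np.isfinite(ref)]
        if ref.size == 0:
            raise DegenerateSeriesError("empty reference window")
        m = float(np.mean(ref))
        s = float(np.std(ref, ddof=1)) if ref.size > 1 else 0.0
        if s == 0:
            raise DegenerateSeriesError("reference window has zero standard deviation")
        constants = StandardizationConstants(mean=m, sd=s)
    return (arr - constants.mean) / constants.sd, constants


def read_indicator_csv(path) -> dict[str, pd.DataFrame]:
    """Read a daily indicator CSV (date, country, indicator, value)."""
    frame = pd.read_csv(path, parse_dates=["date"])
    out = {}
    for country, grp in frame.groupby("country"):
        out[country] = grp.pivot_table(index="date", columns="indicator", values="value")
    return out
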