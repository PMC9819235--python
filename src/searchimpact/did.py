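"""Difference-in-differences variants.

The per-country regression is

    y_t = a0 + a1' year_t + a2' month_t + a3 lambda_t + a4' x_t + e_t

with yearly and monthly seasonal dummies, a lockdown dummy ``lambda_t``
equal to 1 during and after the lockdown, and one of four covariate sets:
none (0), deaths only (1), {cases, deaths, epu, gpr} (2), or all twelve
(3).  Lagged variants replace x_t with x_{t-1}; "fixed-effects" variants
are the same regression entered through categorical factors (numerically
identical under OLS, kept as separately named models); the pooled panel
variant adds country effects, uses mean-rescaled responses, and assumes
no intervention for countries without an explicit lockdown.  The
coefficient of interest is a3, the pre/post shift in average search
intensity.  For the forecast-comparison layer each model contributes its
no-lockdown counterfactual: fitted values with the lockdown dummy forced
to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .panel import COVARIATE_NAMES, AlignmentError, ConfigurationError, MonthlyPanel, rescale_relative

COVARIATE_SETS: dict[int, tuple[str, ...]] = {
    0: (),
    1: ("new_deaths_per_million",),
    2: ("new_cases_per_million", "new_deaths_per_million", "epu", "gpr"),
    3: tuple(COVARIATE_NAMES),
}


@dataclass
class DiDSpec:
    covariate_set: int = 0
    lagged: bool = False
    fixed_effects: bool = False
    panel: bool = False

    def __post_init__(self) -> None:
        if self.covariate_set not in COVARIATE_SETS:
            raise ConfigurationError("covariate_set must be one of 0..3")
        if self.lagged and self.covariate_set == 0:
            raise ConfigurationError("nothing to lag in the no-covariate model")

    @property
    def covariates(self) -> tuple[str, ...]:
        return COVARIATE_SETS[self.covariate_set]

    @property
    def name(self) -> str:
        parts = ["DiD"]
        if self.panel:
            parts.append("p")
        elif self.fixed_effects:
            parts.append("FE")
        parts.append(str(self.covariate_set))
        if self.lagged:
            parts.append("l")
        return "_".join(parts)


@dataclass
class DiDResult:
    spec: DiDSpec
    intercept: float
    year_effects: pd.Series
    month_effects: pd.Series
    lockdown_coefficient: float  # a3
    lockdown_se: float
    covariate_coefficients: pd.Series
    residual_variance: float
    fitted: np.ndarray
    counterfactual: np.ndarray  # fitted with lambda forced to 0
    design_columns: list[str]
    degenerate_lockdown: bool = False


def _dummies(values: pd.Series, prefix: str) -> pd.DataFrame:
    """One-hot columns with the first (reference) category dropped."""
    d = pd.get_dummies(values, prefix=prefix, drop_first=True, dtype=float)
    return d


def build_design(
    months: pd.DatetimeIndex,
    response: np.ndarray,
    covariates: pd.DataFrame | None,
    spec: DiDSpec,
    intervention_month: pd.Timestamp | None,
    country_labels: pd.Series | None = None,
    lockdown_by_row: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Assemble the regression design and response for one DiD variant.

    Reference categories (first year, first month, first country) are
    dropped.  Lagged specs shift the covariates one month and drop the
    first row.  For the panel variant, pass stacked rows with
    ``country_labels`` and a per-row lockdown dummy.
    """
    months = pd.DatetimeIndex(months)
    y = np.asarray(response, dtype=float)
    if len(y) != len(months):
        raise AlignmentError("response does not match month axis")
    if lockdown_by_row is not None:
        lam = np.asarray(lockdown_by_row, dtype=float)
    elif intervention_month is not None:
        lam = (months >= pd.Timestamp(intervention_month)).astype(float)
    else:
        lam = np.zeros(len(months))
    frame = pd.DataFrame(index=pd.RangeIndex(len(months)))
    frame["const"] = 1.0
    frame = pd.concat(
        [
            frame,
            _dummies(pd.Series(months.year, index=frame.index), "year"),
            _dummies(pd.Series(months.month, index=frame.index), "month"),
        ],
        axis=1,
    )
    if country_labels is not None:
        frame = pd.concat(
            [frame, _dummies(pd.Series(np.asarray(country_labels), index=frame.index), "country")],
            axis=1,
        )
    frame["lockdown"] = lam
    names = spec.covariates
    if names:
        if covariates is None:
            raise AlignmentError("covariates required for this spec")
        missing = [nm for nm in names if nm not in covariates.columns]
        if missing:
            raise AlignmentError(f"missing covariates: {missing}")
        mat = covariates[list(names)].to_numpy(dtype=float)
        for j, nm in enumerate(names):
            frame[nm] = mat[:, j]
    if spec.lagged and names:
        for nm in names:
            frame[nm] = frame[nm].shift(1)
        frame = frame.iloc[1:]
        y = y[1:]
    return frame.reset_index(drop=True), y


def fit_did(design: pd.DataFrame, response: np.ndarray, spec: DiDSpec | None = None) -> DiDResult:
    """Ordinary least squares via a numerically stable decomposition.

    Raises on rank deficiency, naming the offending columns.  Returns the
    lockdown coefficient with its conventional standard error, fitted
    values, and the no-lockdown counterfactual path.
    """
    spec = spec or DiDSpec()
    lam = design["lockdown"].to_numpy(dtype=float)
    degenerate = bool(lam.min() == lam.max())
    if degenerate:
        # all-pre or all-post lockdown dummy: carry a flag, fit without it
        design = design.drop(columns=["lockdown"])
    X = design.to_numpy(dtype=float)
    y = np.asarray(response, dtype=float)
    if X.shape[0] <= X.shape[1]:
        raise ConfigurationError("more columns than rows in the DiD design")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify collinear columns by pivoted QR magnitude
        _, R, piv = _qr_pivots(X)
        bad = [design.columns[j] for j in piv[rank:]]
        raise ConfigurationError(f"rank-deficient design; collinear columns: {bad}")
    model = sm.OLS(y, X)
    fit = model.fit()
    cols = list(design.columns)
    params = pd.Series(fit.params, index=cols)
    bse = pd.Series(fit.bse, index=cols)
    if degenerate:
        params["lockdown"] = 0.0
        bse["lockdown"] = float("nan")
    counterfactual = fit.fittedvalues - params["lockdown"] * lam
    year_cols = [c for c in cols if c.startswith("year_")]
    month_cols = [c for c in cols if c.startswith("month_")]
    cov_cols = [c for c in cols if c in COVARIATE_NAMES]
    return DiDResult(
        spec=spec,
        intercept=float(params["const"]),
        year_effects=params[year_cols],
        month_effects=params[month_cols],
        lockdown_coefficient=float(params["lockdown"]),
        lockdown_se=float(bse["lockdown"]),
        covariate_coefficients=params[cov_cols],
        residual_variance=float(fit.mse_resid),
        fitted=np.asarray(fit.fittedvalues),
        counterfactual=np.asarray(counterfactual),
        design_columns=cols,
        degenerate_lockdown=degenerate,
    )


def _qr_pivots(X: np.ndarray):
    from scipy.linalg import qr

    Q, R, piv = qr(X, pivoting=True, mode="economic")
    return Q, R, piv


def _single_country_roster() -> list[DiDSpec]:
    roster = []
    for fe in (False, True):
        for cs in (0, 1, 2, 3):
            roster.append(DiDSpec(covariate_set=cs, fixed_effects=fe))
        for cs in (1, 2, 3):
            roster.append(DiDSpec(covariate_set=cs, fixed_effects=fe, lagged=True))
    return roster


def _panel_roster() -> list[DiDSpec]:
    roster = [DiDSpec(covariate_set=cs, panel=True) for cs in (0, 1, 2, 3)]
    roster += [DiDSpec(covariate_set=cs, panel=True, lagged=True) for cs in (1, 2, 3)]
    return roster


def fit_all_variants(
    panel: MonthlyPanel,
    term: str,
    country: str | None = None,
    no_intervention_countries: tuple[str, ...] = ("JPN", "SWE"),
) -> dict[str, DiDResult | Exception]:
    """Estimate the full DiD roster for one term.

    With ``country`` given: the 14 per-country models (4 contemporaneous +
    3 lagged, each in dummy and fixed-effects form).  Without it: the 7
    pooled panel models over all countries, with mean-rescaled responses
    and no intervention assumed for ``no_intervention_countries``.
    Per-model failures are collected, not raised.
    """
    out: dict[str, DiDResult | Exception] = {}
    if country is not None:
        y = panel.series(country, term)
        cov = panel.covariates.get(country)
        month = panel.intervention_month.get(country)
        for spec in _single_country_roster():
            try:
                design, resp = build_design(panel.months, y, cov, spec, month)
                out[spec.name] = fit_did(design, resp, spec)
            except Exception as exc:  # noqa: BLE001 - per-model isolation
                out[spec.name] = exc
        return out
    # pooled panel: stack countries, rescale responses by full-sample means
    rows_y, rows_lam, rows_country = [], [], []
    rows_cov = []
    for c in panel.countries:
        y = rescale_relative(panel.series(c, term))
        rows_y.append(y)
        month = None if c in no_intervention_countries else panel.intervention_month.get(c)
        lam = (
            (panel.months >= pd.Timestamp(month)).astype(float)
            if month is not None
            else np.zeros(panel.n_months)
        )
        rows_lam.append(lam)
        rows_country.append(np.full(panel.n_months, c, dtype=object))
        rows_cov.append(panel.covariates[c])
    y_all = np.concatenate(rows_y)
    lam_all = np.concatenate(rows_lam)
    months_all = pd.DatetimeIndex(np.tile(panel.months.values, len(panel.countries)))
    cov_all = pd.concat(rows_cov, ignore_index=True)
    labels = pd.Series(np.concatenate(rows_country))
    n_c, n_m = len(panel.countries), panel.n_months
    for spec in _panel_roster():
        try:
            if spec.lagged:
                # lag within each country block, dropping its first month
                keep = np.tile(np.arange(n_m) >= 1, n_c)
                cov_lagged = cov_all.groupby(labels.values).shift(1)
                design, resp = build_design(
                    months_all[keep],
                    y_all[keep],
                    cov_lagged[keep].reset_index(drop=True),
                    DiDSpec(covariate_set=spec.covariate_set, panel=True),
                    None,
                    country_labels=labels[keep].reset_index(drop=True),
                    lockdown_by_row=lam_all[keep],
                )
            else:
                design, resp = build_design(
                    months_all, y_all, cov_all, spec, None,
                    country_labels=labels, lockdown_by_row=lam_all,
                )
            out[spec.name] = fit_did(design, resp, spec)
        except Exception as exc:  # noqa: BLE001
            out[spec.name] = exc
    return out
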