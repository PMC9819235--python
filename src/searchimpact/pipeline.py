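"""Study orchestration.

Runs the full design over a country x term grid: covariate screening, the
structural-model causal impacts (all trend specifications, lagged and
unlagged covariates), dynamic-mixture and difference-in-differences
counterfactuals, benchmark forecasts, the forecast-comparison layer, and
the significant-effect matrices with their summary counts.  Per-cell
failures are isolated and logged; every stochastic step derives its seed
from the master seed and the (country, term, model) labels, so reruns are
reproducible and order-independent.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bdmm, causal, did, evaluation
from .bsts import TrendSpec
from .panel import ConfigurationError, MonthlyPanel, StandardizationConstants
from .synthetic import load_fixture

log = logging.getLogger("searchimpact")

#: Trend specification behind each structural-model roster name.
BSTS_TRENDS: dict[str, str] = {
    "BSTS_1": "local_linear",
    "BSTS_2": "local_level",
    "BSTS_3": "semilocal_linear",
    "BSTS_4": "student_local_linear",
}

NON_PANEL_DID = [
    "DiD_0", "DiD_1", "DiD_2", "DiD_3",
    "DiD_1_l", "DiD_2_l", "DiD_3_l",
    "DiD_FE_0", "DiD_FE_1", "DiD_FE_2", "DiD_FE_3",
    "DiD_FE_1_l", "DiD_FE_2_l", "DiD_FE_3_l",
]
PANEL_DID = ["DiD_p_0", "DiD_p_1", "DiD_p_2", "DiD_p_3", "DiD_p_1_l", "DiD_p_2_l", "DiD_p_3_l"]
ROSTER_NAMES = (
    ["BDMM", "BDMM_l"]
    + list(BSTS_TRENDS)
    + [f"{m}_l" for m in BSTS_TRENDS]
    + NON_PANEL_DID
    + PANEL_DID
    + ["ARIMA", "NAIVE"]
)


def cell_seed(master_seed: int, *labels: str) -> int:
    """Stable per-cell seed below 2^31 from the master seed and labels."""
    h = zlib.crc32("|".join(labels).encode())
    return (int(master_seed) * 1_000_003 + h) % (2**31 - 1)


@dataclass
class StudyConfig:
    """Study design: grid, roster, intervention handling, MCMC sizes."""

    terms: list[str]
    countries: list[str]
    models: list[str] = field(default_factory=lambda: list(ROSTER_NAMES))
    impact_models: tuple[str, str] = ("BSTS_3", "BSTS_3_l")
    reference_model: str = "BSTS_3_l"
    intervention: dict[str, str | None] = field(default_factory=dict)
    contrived_intervention: str = "2020-04-01"
    no_lockdown_countries: tuple[str, ...] = ("JPN", "SWE")
    screen: bool = True
    n_iterations: int = 1000
    burn_in: int | None = None
    mcs_bootstrap: int = 1000
    mcs_confidence: float = 0.90
    eval_window: str = "post"  # post | insample
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.models) - set(ROSTER_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown roster models: {sorted(unknown)}")
        if self.eval_window not in ("post", "insample"):
            raise ConfigurationError("eval_window must be 'post' or 'insample'")

    @classmethod
    def from_fixtures(cls, **overrides) -> "StudyConfig":
        """The transcribed study grid: 23 terms x 15 countries."""
        terms = load_fixture("term_list")["term"].tolist()
        countries = load_fixture("country_list")["code"].tolist()
        return cls(terms=terms, countries=countries, **overrides)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def grid(self) -> list[tuple[str, str]]:
        return [(c, t) for c in self.countries for t in self.terms]

    @property
    def mcmc(self) -> causal.McmcSettings:
        return causal.McmcSettings(self.n_iterations, self.burn_in)


@dataclass
class CellResult:
    forecasts: dict[str, np.ndarray]
    comparison: evaluation.ComparisonResult | None
    impacts: dict[str, causal.CausalImpactResult]
    errors: dict[str, str]


@dataclass
class StudyResult:
    config: StudyConfig
    cells: dict[tuple[str, str], CellResult]
    effect_matrices: causal.EffectMatrices
    tables: evaluation.SummaryTables | None
    screening: dict[str, list[causal.ScreeningDecision]]
    manifest: dict

    def summary(self) -> dict:
        counts_nolag = self.effect_matrices.counts("no_lag")
        counts_lagged = self.effect_matrices.counts("lagged")
        terms = set(self.config.terms)
        with_effect = self.effect_matrices.terms_with_effect & terms
        share = 100.0 * len(with_effect) / len(terms) if terms else 0.0
        out = {
            "n_series": len(self.cells),
            "significant_no_lag": counts_nolag[0],
            "negative_no_lag": counts_nolag[1],
            "significant_lagged": counts_lagged[0],
            "negative_lagged": counts_lagged[1],
            "terms_with_effect": sorted(with_effect),
            "term_effect_share_pct": share,
            "contradictions": self.effect_matrices.contradictions(),
        }
        if self.tables is not None:
            out["best_model_share"] = self.tables.best_model_share.to_dict()
            out["mcs_frequency"] = self.tables.mcs_frequency.to_dict()
        return out


def _standardize_for_mixture(X: np.ndarray, n_pre: int) -> np.ndarray:
    """Column standardization on the pre window; columns constant over the
    pre window fall back to the full-sample sd (pandemic covariates)."""
    out = np.empty_like(X, dtype=float)
    for j in range(X.shape[1]):
        col = X[:, j]
        m = col[:n_pre].mean()
        s = col[:n_pre].std(ddof=1) if n_pre > 1 else 0.0
        s_full = col.std(ddof=1)
        # pandemic covariates are (near-)constant before the breakpoint: the
        # pre-window sd is degenerate, fall back to the full-sample scale
        if s <= 0.01 * s_full:
            s = s_full
        if s <= 1e-12:
            s = 1.0
        out[:, j] = (col - m) / s
    return out


def _bdmm_forecast(y, X, k_orig, lagged) -> tuple[np.ndarray, np.ndarray]:
    """(post counterfactual, in-sample one-step fit aligned to months 1..k-1)."""
    k = k_orig
    if lagged:
        X = X[:-1]
        y = y[1:]
        k -= 1
    ys, consts = _std_series(y, k)
    Xs = _standardize_for_mixture(X, k)
    state = bdmm.fit_mixture(ys[:k], Xs[:k], covariate_names=[f"x{j}" for j in range(X.shape[1])])
    fc = bdmm.forecast_counterfactual(state, Xs[k:], consts)
    fitted = state.pred_path * consts.sd + consts.mean
    fitted = fitted if lagged else fitted[1:]
    return fc, fitted


def _std_series(y: np.ndarray, k: int) -> tuple[np.ndarray, StandardizationConstants]:
    m = float(np.mean(y[:k]))
    s = float(np.std(y[:k], ddof=1))
    s = s if s > 1e-12 else 1.0
    consts = StandardizationConstants(mean=m, sd=s)
    return (y - m) / s, consts


def run_cell(
    panel: MonthlyPanel,
    country: str,
    term: str,
    config: StudyConfig,
    admissible: list[str] | None = None,
    panel_did: dict[str, did.DiDResult | Exception] | None = None,
) -> CellResult:
    """All requested models for one (country, term) cell."""
    y = panel.series(country, term)
    months = panel.months
    month = panel.intervention_month.get(country) or pd.Timestamp(
        config.contrived_intervention
    )
    k = panel.month_index(month)
    horizon = panel.n_months - k
    cov = panel.covariates.get(country)
    cov_all = cov.to_numpy(dtype=float) if cov is not None else None
    names_all = list(cov.columns) if cov is not None else []
    if admissible is not None and cov is not None:
        keep = [nm for nm in names_all if nm in admissible]
        X_adm = cov[keep].to_numpy(dtype=float)
        adm_names = keep
    else:
        X_adm, adm_names = cov_all, names_all

    forecasts: dict[str, np.ndarray] = {}
    fits: dict[str, np.ndarray] = {}  # in-sample one-step fits, months 1..k-1
    impacts: dict[str, causal.CausalImpactResult] = {}
    errors: dict[str, str] = {}

    for name in config.models:
        try:
            if name == "ARIMA":
                fc, afit = evaluation.auto_arima_forecast(y[:k], horizon, return_fit=True)
                forecasts[name] = fc
                fits[name] = afit.fitted[1:k]
            elif name == "NAIVE":
                forecasts[name] = evaluation.naive_forecast(y, k, horizon)
                fits[name] = y[: k - 1]
            elif name.startswith("BSTS"):
                base = name[:-2] if name.endswith("_l") else name
                lagged = name.endswith("_l")
                res = causal.estimate_impact(
                    y,
                    X_adm,
                    k,
                    trend_spec=TrendSpec(kind=BSTS_TRENDS[base]),
                    lagged=lagged,
                    mcmc=config.mcmc,
                    seed=cell_seed(config.seed, country, term, name),
                    covariate_names=adm_names,
                )
                forecasts[name] = res.predicted.mean(axis=0)
                fits[name] = res.fitted_pre if lagged else res.fitted_pre[1:]
                if name in config.impact_models:
                    impacts["lagged" if lagged else "no_lag"] = res
            elif name.startswith("BDMM"):
                if cov_all is None:
                    raise ConfigurationError("BDMM requires covariates")
                forecasts[name], fits[name] = _bdmm_forecast(
                    y, cov_all, k, name.endswith("_l")
                )
            elif name.startswith("DiD_p"):
                if panel_did is None:
                    raise ConfigurationError("panel DiD results not supplied")
                res = panel_did.get(name)
                if isinstance(res, Exception) or res is None:
                    raise ConfigurationError(f"panel model failed: {res}")
                forecasts[name], fits[name] = _panel_did_paths(
                    res, panel, country, term, k
                )
            elif name.startswith("DiD"):
                forecasts[name], fits[name] = _did_paths(panel, country, term, name, k)
            else:  # pragma: no cover
                raise ConfigurationError(f"unhandled model {name}")
        except Exception as exc:  # noqa: BLE001 - cell isolation
            errors[name] = f"{type(exc).__name__}: {exc}"
            log.warning("cell (%s, %s) model %s failed: %s", country, term, name, exc)

    if config.eval_window == "post":
        observed, series, min_len = y[k:], forecasts, 8
    else:  # insample: pre-window one-step fits, months 1..k-1
        observed, series, min_len = y[1:k], fits, 8
    comparison = None
    ok = {
        n: f
        for n, f in series.items()
        if f is not None and len(f) == len(observed) and np.all(np.isfinite(f))
    }
    if len(ok) >= 2 and len(observed) >= min_len:
        reference = config.reference_model if config.reference_model in ok else None
        comparison = evaluation.compare_models(
            observed,
            ok,
            reference=reference,
            n_bootstrap=config.mcs_bootstrap,
            confidence=config.mcs_confidence,
            rng=np.random.default_rng(cell_seed(config.seed, country, term, "mcs")),
        )
    return CellResult(forecasts=forecasts, comparison=comparison, impacts=impacts, errors=errors)


def _did_paths(panel, country, term, name, k) -> tuple[np.ndarray, np.ndarray]:
    """(post counterfactual, pre-window fitted values for months 1..k-1)."""
    spec = _spec_from_name(name)
    month = panel.months[k]
    design, resp = did.build_design(
        panel.months,
        panel.series(country, term),
        panel.covariates.get(country),
        spec,
        month,
    )
    fit = did.fit_did(design, resp, spec)
    horizon = panel.n_months - k
    # lagged designs dropped the first row; post rows are the last (n-k)
    cf = fit.counterfactual[-horizon:]
    pre_fit = fit.fitted[: k - 1] if spec.lagged else fit.fitted[1:k]
    return cf, pre_fit


def _spec_from_name(name: str) -> did.DiDSpec:
    parts = name.split("_")
    lagged = parts[-1] == "l"
    if lagged:
        parts = parts[:-1]
    fe = "FE" in parts
    pnl = "p" in parts
    cs = int(parts[-1])
    return did.DiDSpec(covariate_set=cs, lagged=lagged, fixed_effects=fe, panel=pnl)


def _panel_did_paths(res, panel, country, term, k) -> tuple[np.ndarray, np.ndarray]:
    """This country's post counterfactual and pre fit from the pooled model,
    de-rescaled back to the country's index scale."""
    n_m = panel.n_months
    ci = panel.countries.index(country)
    mean = float(np.nanmean(panel.series(country, term)))
    if res.spec.lagged:
        block_start = ci * (n_m - 1)
        cf = res.counterfactual[block_start + k - 1 : block_start + n_m - 1]
        pre_fit = res.fitted[block_start : block_start + k - 1]
    else:
        block_start = ci * n_m
        cf = res.counterfactual[block_start + k : block_start + n_m]
        pre_fit = res.fitted[block_start + 1 : block_start + k]
    return cf * mean, pre_fit * mean


def run_study(config: StudyConfig, panel: MonthlyPanel) -> StudyResult:
    """Execute the full study grid on a panel.

    Validates the configuration and panel up front, screens covariates per
    country (when enabled), fits every requested model per cell, and
    assembles the comparison tables and effect matrices.
    """
    missing = [
        (c, t) for c in config.countries for t in config.terms if (c, t) not in panel.response
    ]
    if missing:
        raise ConfigurationError(f"panel lacks response series, e.g. {missing[:3]}")
    # resolve interventions: config override > panel > contrived date
    for c in config.countries:
        if c in config.intervention:
            v = config.intervention[c]
            panel.intervention_month[c] = pd.Timestamp(v) if v else None
        if panel.intervention_month.get(c) is None:
            panel.intervention_month[c] = pd.Timestamp(config.contrived_intervention)

    screening: dict[str, list[causal.ScreeningDecision]] = {}
    admissible: dict[str, list[str] | None] = {}
    for c in config.countries:
        if config.screen and c in panel.covariates:
            decisions = causal.screen_covariates(
                panel, c, trend_spec="semilocal_linear",
                mcmc=config.mcmc, seed=cell_seed(config.seed, c, "screen"),
            )
            screening[c] = decisions
            admissible[c] = causal.admissible_covariates(decisions)
        else:
            admissible[c] = None

    panel_did_by_term: dict[str, dict] = {}
    if any(m.startswith("DiD_p") for m in config.models):
        for t in config.terms:
            panel_did_by_term[t] = did.fit_all_variants(
                panel, t, country=None,
                no_intervention_countries=config.no_lockdown_countries,
            )

    cells: dict[tuple[str, str], CellResult] = {}
    for c in config.countries:
        for t in config.terms:
            cells[(c, t)] = run_cell(
                panel, c, t, config,
                admissible=admissible[c],
                panel_did=panel_did_by_term.get(t),
            )

    impact_grid = {key: cell.impacts for key, cell in cells.items() if cell.impacts}
    matrices = causal.effect_matrix(impact_grid, config.countries, config.terms)
    comparisons = {
        key: cell.comparison for key, cell in cells.items() if cell.comparison is not None
    }
    tables = (
        evaluation.aggregate_tables(comparisons, reference=None) if comparisons else None
    )
    manifest = {
        "seed": config.seed,
        "config": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if not isinstance(v, (pd.Timestamp,))
        },
        "n_months": panel.n_months,
        "grid": len(cells),
    }
    return StudyResult(
        config=config,
        cells=cells,
        effect_matrices=matrices,
        tables=tables,
        screening=screening,
        manifest=manifest,
    )


def report(result: StudyResult, out_dir: str | Path | None = None) -> dict:
    """Render summary tables and counts; optionally write CSV/JSONL files."""
    summary = result.summary()
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.effect_matrices.no_lag.to_csv(out / "effects_no_lag.csv")
        result.effect_matrices.lagged.to_csv(out / "effects_lagged.csv")
        if result.tables is not None:
            result.tables.rmse_by_country.to_csv(out / "rmse_by_country.csv")
            result.tables.rmse_by_term.to_csv(out / "rmse_by_term.csv")
            result.tables.dm_by_country.to_csv(out / "dm_by_country.csv")
            result.tables.dm_by_term.to_csv(out / "dm_by_term.csv")
            result.tables.mcs_frequency.to_csv(out / "mcs_frequency.csv", header=["freq"])
        with open(out / "impacts.jsonl", "w") as fh:
            for (c, t), cell in result.cells.items():
                for mode, res in cell.impacts.items():
                    fh.write(
                        json.dumps(
                            {
                                "country": c,
                                "term": t,
                                "model": mode,
                                "significant": res.significant,
                                "sign": res.sign,
                                "relative_effect": res.relative_effect_point,
                                "average_effect": res.average_effect_point,
                                "tail_area_p": res.tail_area_p,
                            }
                        )
                        + "\n"
                    )
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=str)
        with open(out / "manifest.json", "w") as fh:
            json.dump(result.manifest, fh, indent=2, default=str)
    return summary


def reference_effect_summary() -> dict:
    """Summary counts of the packaged detected-effect tables.

    Builds the country x term matrices from the transcribed fixtures and
    returns the significant / negative counts per matrix and the share of
    terms with at least one detected effect in either matrix.
    """
    terms = load_fixture("term_list")["term"].tolist()
    countries = load_fixture("country_list")["code"].tolist()
    no_lag = causal.effect_table_from_fixture(load_fixture("detected_effects_nolag"), countries, terms)
    lagged = causal.effect_table_from_fixture(load_fixture("detected_effects_lagged"), countries, terms)
    mats = causal.EffectMatrices(no_lag=no_lag, lagged=lagged)
    n_sig, n_neg = mats.counts("no_lag")
    n_sig_l, n_neg_l = mats.counts("lagged")
    share = 100.0 * len(mats.terms_with_effect) / len(terms)
    return {
        "significant_no_lag": n_sig,
        "negative_no_lag": n_neg,
        "significant_lagged": n_sig_l,
        "negative_lagged": n_neg_l,
        "terms_with_effect": sorted(mats.terms_with_effect),
        "term_effect_share_pct": share,
        "no_effect_terms": load_fixture("no_effect_terms")["term"].tolist(),
        "contradictions": mats.contradictions(),
    }
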