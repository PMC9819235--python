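"""Causal-impact estimation, screening, and effect matrices."""

import copy

import numpy as np
import pandas as pd
import pytest

from searchimpact.causal import (
    CausalImpactResult,
    McmcSettings,
    ScreeningDecision,
    admissible_covariates,
    effect_matrix,
    effect_table_from_fixture,
    estimate_impact,
    screen_covariates,
    summarize_effect_draws,
    summarize_impact,
)
from searchimpact.panel import AlignmentError
from searchimpact.synthetic import (
    SimulationConfig,
    inject_intervention_effect,
    load_fixture,
    simulate_covariates,
    simulate_response,
)


class TestSummaries:
    def test_quantile_oracle_on_known_draws(self, rng):
        # build predicted draws so that average-effect draws equal a known
        # normal(2, 1) sample; the interval must match empirical quantiles
        sample = rng.normal(2.0, 1.0, 800)
        observed = np.array([10.0, 12.0])
        predicted = observed[None, :] - sample[:, None]
        res = summarize_effect_draws(observed, predicted)
        assert np.allclose(res.average, sample)
        lo, hi = res.interval_average
        assert lo == pytest.approx(np.quantile(sample, 0.025))
        assert hi == pytest.approx(np.quantile(sample, 0.975))

    def test_all_positive_draws_give_zero_tail_probability(self):
        predicted = np.full((100, 3), 5.0)
        observed = np.array([7.0, 8.0, 9.0])
        res = summarize_effect_draws(observed, predicted)
        assert res.tail_area_p == 0.0
        assert res.sign == "positive"
        assert res.significant

    def test_symmetric_draws_are_not_significant(self, rng):
        draws = rng.normal(0.0, 1.0, (500, 4))
        observed = np.zeros(4)
        res = summarize_effect_draws(observed, observed[None] - draws)
        assert not res.significant
        assert res.sign == "none"

    def test_observed_equals_prediction_gives_null_result(self):
        observed = np.array([5.0, 6.0, 7.0])
        predicted = np.tile(observed, (50, 1))
        res = summarize_effect_draws(observed, predicted)
        assert res.relative_effect_point == 0.0
        assert not res.significant
        sig, sign, rel, tail = summarize_impact(res)
        assert (sig, sign, rel) == (False, "none", 0.0)

    def test_sign_agrees_with_mean_effect_when_significant(self, rng):
        # counterfactual levels are positive on the 0-100 index scale
        observed = np.full(5, 50.0)
        for shift in (-3.0, 3.0):
            predicted = observed[None, :] - rng.normal(shift, 0.5, (400, 5))
            res = summarize_effect_draws(observed, predicted)
            assert res.significant
            expected = "positive" if shift > 0 else "negative"
            assert res.sign == expected
            assert np.sign(res.relative_effect_point) == np.sign(res.average.mean())


class TestEstimateImpact:
    def test_step_effect_recovered_within_interval(self, small_series):
        synth = copy.deepcopy(small_series)
        k = synth.config.n_pre
        inject_intervention_effect(synth, k, 15.0, "step")
        y = synth.panel.response[("SYN", "synthetic")]
        res = estimate_impact(y, None, k, trend_spec="local_level",
                              mcmc=McmcSettings(400), seed=7)
        lo, hi = res.interval_average
        assert lo <= 15.0 <= hi
        assert res.significant and res.sign == "positive"

    def test_alignment_errors(self, small_series):
        y = small_series.panel.response[("SYN", "synthetic")]
        with pytest.raises(AlignmentError):
            estimate_impact(y, None, 0, mcmc=McmcSettings(10))
        X_short = np.ones((10, 2))
        with pytest.raises(AlignmentError):
            estimate_impact(y, X_short, 72, mcmc=McmcSettings(10))

    def test_lagged_mode_consumes_one_month(self, small_series):
        synth = copy.deepcopy(small_series)
        k = synth.config.n_pre
        y = synth.panel.response[("SYN", "synthetic")]
        X = synth.panel.covariates["SYN"][["une", "epu"]].to_numpy()
        res = estimate_impact(y, X, k, trend_spec="local_level", lagged=True,
                              mcmc=McmcSettings(150), seed=8,
                              covariate_names=["une", "epu"])
        # post horizon unchanged: the dropped month comes out of the pre window
        assert res.observed.shape == (synth.config.n_post,)

    def test_constant_pre_covariates_are_dropped(self, small_series):
        synth = copy.deepcopy(small_series)
        k = synth.config.n_pre
        y = synth.panel.response[("SYN", "synthetic")]
        X = synth.panel.covariates["SYN"][["une", "new_cases_per_million"]].to_numpy()
        X[: k - 1, 1] = 0.0  # constant over the training window
        X[k - 1, 1] = 0.0
        res = estimate_impact(y, X, k, trend_spec="local_level",
                              mcmc=McmcSettings(100), seed=9,
                              covariate_names=["une", "new_cases_per_million"])
        assert res.dropped_covariates == ["new_cases_per_million"]


@pytest.fixture(scope="module")
def screening_panel():
    cfg = SimulationConfig(n_pre=72, n_post=12, trend_spec="local_level",
                           true_support=(), seed=41, start_month="2013-01-01")
    synth = simulate_response(cfg, simulate_covariates(cfg))
    return synth.panel


class TestScreening:
    def test_a_priori_lists_applied_without_fitting(self, screening_panel):
        decisions = screen_covariates(
            screening_panel, "SYN", mcmc=McmcSettings(60), seed=1,
            candidates=("ec_act", "oil", "stringency_index"),
        )
        by_name = {d.covariate: d for d in decisions}
        assert by_name["stringency_index"].status == "excluded_a_priori"
        assert by_name["ec_act"].status == "kept_a_priori"
        assert by_name["oil"].status == "kept_a_priori"
        assert by_name["ec_act"].relative_effect is None

    def test_unaffected_macro_covariate_kept(self, screening_panel):
        decisions = screen_covariates(
            screening_panel, "SYN", trend_spec="local_level",
            mcmc=McmcSettings(300), seed=2, candidates=("une",),
        )
        assert decisions[0].status == "kept"

    def test_breakpoint_covid_covariates_flagged_affected(self, screening_panel):
        decisions = screen_covariates(
            screening_panel, "SYN", mcmc=McmcSettings(60), seed=3,
            candidates=("new_cases_per_million", "new_deaths_per_million"),
        )
        assert all(d.status == "excluded_affected" for d in decisions)

    def test_shifted_covariate_screened_out(self):
        # a covariate with a +5 sigma post-intervention shift must be caught
        hits = 0
        for rep in range(20):
            cfg = SimulationConfig(n_pre=72, n_post=12, trend_spec="local_level",
                                   true_support=(), seed=500 + rep,
                                   start_month="2013-01-01")
            synth = simulate_response(cfg, simulate_covariates(cfg))
            panel = synth.panel
            cov = panel.covariates["SYN"].copy()
            une = cov["une"].to_numpy().copy()
            une[72:] += 5.0 * np.std(une[:72])
            cov["une"] = une
            panel.covariates["SYN"] = cov
            decisions = screen_covariates(
                panel, "SYN", trend_spec="local_level",
                mcmc=McmcSettings(300), seed=600 + rep, candidates=("une",),
            )
            hits += decisions[0].status == "excluded_affected"
        assert hits >= 18  # >= 90% of 20 replicates

    def test_admissible_set_excludes_dropped(self):
        decisions = [
            ScreeningDecision("a", "kept"),
            ScreeningDecision("b", "excluded_affected"),
            ScreeningDecision("c", "kept_a_priori"),
            ScreeningDecision("d", "excluded_a_priori"),
        ]
        assert admissible_covariates(decisions) == ["a", "c"]


def _result(rel, significant, sign):
    k = 100
    return CausalImpactResult(
        pointwise=np.zeros((k, 1)),
        average=np.zeros(k),
        cumulative=np.zeros(k),
        relative=np.full(k, rel),
        predicted=np.ones((k, 1)),
        observed=np.ones(1),
        interval_average=(-1, 1) if not significant else ((0.1, 1) if sign == "positive" else (-1, -0.1)),
        interval_cumulative=(0, 0),
        interval_relative=(0, 0),
        tail_area_p=0.5,
        significant=significant,
        sign=sign,
    )


class TestEffectMatrix:
    def test_all_null_results_give_empty_matrices(self):
        results = {
            ("A", "t1"): {"no_lag": _result(0.0, False, "none")},
            ("B", "t2"): {"lagged": _result(0.0, False, "none")},
        }
        mats = effect_matrix(results, ["A", "B"], ["t1", "t2"])
        assert mats.counts("no_lag") == (0, 0)
        assert mats.counts("lagged") == (0, 0)
        assert mats.terms_with_effect == set()

    def test_significant_cells_and_counts(self):
        results = {
            ("A", "t1"): {"no_lag": _result(0.5, True, "positive"),
                          "lagged": _result(0.4, True, "positive")},
            ("A", "t2"): {"no_lag": _result(-0.3, True, "negative")},
            ("B", "t1"): {"no_lag": _result(0.0, False, "none")},
        }
        mats = effect_matrix(results, ["A", "B"], ["t1", "t2"])
        assert mats.counts("no_lag") == (2, 1)
        assert mats.counts("lagged") == (1, 0)
        assert mats.terms_with_effect == {"t1", "t2"}
        assert mats.contradictions() == []
        assert list(mats.drop_empty_columns("lagged").columns) == ["t1"]

    def test_opposite_signs_reported_as_contradiction(self):
        results = {
            ("A", "t1"): {"no_lag": _result(0.5, True, "positive"),
                          "lagged": _result(-0.5, True, "negative")},
        }
        mats = effect_matrix(results, ["A"], ["t1"])
        assert mats.contradictions() == [("A", "t1")]

    def test_fixture_tables_are_mutually_consistent(self):
        terms = load_fixture("term_list")["term"].tolist()
        countries = load_fixture("country_list")["code"].tolist()
        no_lag = effect_table_from_fixture(load_fixture("detected_effects_nolag"), countries, terms)
        lagged = effect_table_from_fixture(load_fixture("detected_effects_lagged"), countries, terms)
        from searchimpact.causal import EffectMatrices

        mats = EffectMatrices(no_lag=no_lag, lagged=lagged)
        # the two headline models never carry significant opposite signs
        assert mats.contradictions() == []
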