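"""Panel container and preprocessing operations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from searchimpact import panel as pnl
from searchimpact.panel import (
    AlignmentError,
    ConfigurationError,
    DegenerateSeriesError,
    LockdownRule,
    MonthlyPanel,
    StandardizationConstants,
    aggregate_covid_monthly,
    average_bilingual,
    detect_lockdown_months,
    fill_locf_and_zero,
    lockdown_days,
    rescale_relative,
    standardize,
)
from searchimpact.synthetic import simulate_policy_indicators


class TestAggregateCovidMonthly:
    def test_sum_of_constant_days(self):
        days = pd.date_range("2020-04-01", "2020-04-30", freq="D")
        out = aggregate_covid_monthly(pd.Series(1.0, index=days), "sum")
        assert out.loc["2020-04-01"] == 30

    def test_mean_of_two_days(self):
        s = pd.Series([2.0, 4.0], index=pd.to_datetime(["2020-05-03", "2020-05-20"]))
        assert aggregate_covid_monthly(s, "mean").loc["2020-05-01"] == 3.0

    def test_matches_brute_force_groupby_on_irregular_gaps(self, rng):
        dates = pd.date_range("2020-03-01", "2020-05-31", freq="D")
        keep = rng.random(len(dates)) < 0.6
        s = pd.Series(rng.normal(5, 2, keep.sum()), index=dates[keep])
        for kind, fn in (("sum", np.sum), ("mean", np.mean)):
            out = aggregate_covid_monthly(s, kind)
            expected = {}
            for d, v in s.items():
                key = pd.Timestamp(d.year, d.month, 1)
                expected.setdefault(key, []).append(v)
            for month, vals in expected.items():
                assert out.loc[month] == pytest.approx(fn(vals))

    def test_unknown_kind_rejected(self):
        s = pd.Series([1.0], index=pd.to_datetime(["2020-01-01"]))
        with pytest.raises(ConfigurationError):
            aggregate_covid_monthly(s, "median")


class TestFillLocf:
    months = pd.date_range("2020-01-01", periods=4, freq="MS")

    def test_interior_gaps_carried_forward(self):
        s = pd.Series([1.0, np.nan, np.nan, 4.0], index=self.months)
        assert fill_locf_and_zero(s).tolist() == [1.0, 1.0, 1.0, 4.0]

    def test_covid_zeroed_before_breakpoint(self):
        s = pd.Series([np.nan, np.nan, 5.0, 7.0], index=self.months)
        out = fill_locf_and_zero(s, breakpoint_month="2020-03-01", is_covid=True)
        assert out.tolist() == [0.0, 0.0, 5.0, 7.0]

    def test_all_missing_reported_not_raised(self):
        s = pd.Series([np.nan] * 4, index=self.months)
        with pytest.warns(UserWarning, match="leading missing"):
            out = fill_locf_and_zero(s)
        assert out.isna().all()


class TestLockdownDetector:
    def test_all_off_gives_no_periods(self):
        ind = simulate_policy_indicators(0, [], start="2020-01-01", end="2020-03-31")
        assert detect_lockdown_months(ind) == []

    def test_movement_restriction_alone_triggers(self):
        ind = simulate_policy_indicators(
            0,
            [("movement_restrictions", "2020-03-10", "2020-04-20")],
            start="2020-01-01",
            end="2020-06-30",
        )
        periods = detect_lockdown_months(ind, "XXX")
        assert len(periods) == 1
        assert periods[0].start_month == pd.Timestamp("2020-03-01")
        assert periods[0].end_month == pd.Timestamp("2020-04-01")

    def test_school_and_workplace_require_gathering_limit(self):
        sched = [
            ("school_closing", "2020-03-01", "2020-03-31"),
            ("workplace_closing", "2020-03-01", "2020-03-31"),
        ]
        ind = simulate_policy_indicators(0, sched, start="2020-01-01", end="2020-05-31")
        assert detect_lockdown_months(ind) == []
        sched.append(("gathering_restrictions", "2020-03-05", "2020-03-20"))
        ind = simulate_policy_indicators(0, sched, start="2020-01-01", end="2020-05-31")
        periods = detect_lockdown_months(ind)
        assert [p.start_month for p in periods] == [pd.Timestamp("2020-03-01")]

    def test_matches_per_day_brute_force_on_random_schedules(self):
        rule = LockdownRule()
        rng = np.random.default_rng(77)
        days = pd.date_range("2020-01-01", "2020-12-31", freq="D")
        for _ in range(200):
            ind = pd.DataFrame(
                rng.integers(0, 2, size=(len(days), 4)),
                index=days,
                columns=list(pnl.INDICATOR_NAMES),
            )
            # thin out so runs of months appear
            ind.iloc[rng.random(len(days)) < 0.7] = 0
            got = detect_lockdown_months(ind, rule=rule)
            # brute force: evaluate rule day by day, collect months, find runs
            flag_days = [
                d
                for d, row in ind.iterrows()
                if row["movement_restrictions"] >= 1
                or (
                    row["school_closing"] >= 1
                    and row["workplace_closing"] >= 1
                    and row["gathering_restrictions"] >= 1
                )
            ]
            months = sorted({pd.Timestamp(d.year, d.month, 1) for d in flag_days})
            runs = []
            for m in months:
                if runs and m == runs[-1][-1] + pd.DateOffset(months=1):
                    runs[-1].append(m)
                else:
                    runs.append([m])
            expected = [(r[0], r[-1]) for r in runs]
            assert [(p.start_month, p.end_month) for p in got] == expected

    def test_misaligned_indicators_rejected(self):
        days = pd.date_range("2020-01-01", periods=10, freq="D")
        ind = pd.DataFrame(0, index=days, columns=list(pnl.INDICATOR_NAMES)[:-1])
        with pytest.raises(AlignmentError):
            lockdown_days(ind)


class TestSeriesOps:
    def test_bilingual_idempotent_and_midpoint(self, rng):
        x = rng.integers(0, 100, 24).astype(float)
        assert np.array_equal(average_bilingual(x, x), x)
        assert average_bilingual(np.array([0.0]), np.array([100.0]))[0] == 50.0
        y = rng.integers(0, 100, 24).astype(float)
        assert np.allclose(average_bilingual(x, y), (x + y) / 2)
        with pytest.raises(AlignmentError):
            average_bilingual(x, y[:-1])

    def test_rescale_examples_and_zero_mean(self):
        assert np.allclose(rescale_relative(np.full(10, 7.0)), 1.0)
        assert rescale_relative(np.array([1.0, 3.0])).tolist() == [0.5, 1.5]
        with pytest.raises(DegenerateSeriesError):
            rescale_relative(np.array([-1.0, 1.0]))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_rescale_output_mean_is_one(self, seed):
        r = np.random.default_rng(seed)
        x = r.uniform(1, 100, size=r.integers(2, 60))
        assert np.mean(rescale_relative(x)) == pytest.approx(1.0, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_standardize_round_trip(self, seed):
        r = np.random.default_rng(seed)
        x = r.normal(50, 10, 48)
        z, consts = standardize(x, reference_window=36)
        back, _ = standardize(z, inverse=True, constants=consts)
        assert np.allclose(back, x, atol=1e-12)

    def test_standardize_reference_window_oracle(self, rng):
        x = rng.normal(10, 4, 60)
        z, consts = standardize(x, reference_window=40)
        assert consts.mean == pytest.approx(np.mean(x[:40]))
        assert consts.sd == pytest.approx(np.std(x[:40], ddof=1))
        assert np.allclose(z, (x - consts.mean) / consts.sd)

    def test_standardize_degenerate_inputs(self):
        z, c = standardize(np.full(30, 4.0), constants=StandardizationConstants(4.0, 2.0))
        assert np.allclose(z, 0.0)
        with pytest.raises(DegenerateSeriesError):
            standardize(np.full(30, 4.0), reference_window=20)


class TestMonthlyPanel:
    def test_month_axis_must_increase_without_duplicates(self):
        months = pd.to_datetime(["2020-01-01", "2020-01-01", "2020-02-01"])
        with pytest.raises(ConfigurationError):
            MonthlyPanel(months=months, countries=[], terms=[], response={})

    def test_response_bounds_enforced(self):
        months = pd.date_range("2020-01-01", periods=3, freq="MS")
        with pytest.raises(ConfigurationError):
            MonthlyPanel(
                months=months,
                countries=["A"],
                terms=["t"],
                response={("A", "t"): np.array([0.0, 50.0, 101.0])},
            )

    def test_csv_round_trip(self, toy_panel, tmp_path):
        path = tmp_path / "panel.csv"
        toy_panel.panel.to_csv(path)
        loaded = MonthlyPanel.read_csv(path)
        assert list(loaded.months) == list(toy_panel.panel.months)
        for key, series in toy_panel.panel.response.items():
            assert np.allclose(loaded.response[key], series)
        for c, mat in toy_panel.panel.covariates.items():
            assert np.allclose(loaded.covariates[c].to_numpy(), mat.to_numpy())
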