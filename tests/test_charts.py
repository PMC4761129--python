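"""Control charts: baseline, step arithmetic, alarm logic, reinitialization."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from gaitspc import (
    DailyRecord,
    EwmaChart,
    StandardizedCusumChart,
    TabularCusumChart,
    estimate_baseline,
    run_chart,
)
from gaitspc.charts import Baseline, ChartConfig, daily_records_from_frame
from gaitspc.errors import (
    InitializationError,
    ParameterError,
    StandardizationError,
)

from conftest import records_from_medians


def manual_baseline(mu0, sigma0):
    return Baseline(mu0=mu0, sigma0=sigma0, window=(1, 14), n_days=14, n_obs=14)


class TestBaseline:
    def test_constant_medians(self):
        recs = records_from_medians([3.0] * 5)
        b = estimate_baseline(recs)
        assert (b.mu0, b.sigma0) == (3.0, 0.0)

    def test_hand_values(self):
        b = estimate_baseline(records_from_medians([4.0, 6.0]))
        assert b.mu0 == pytest.approx(5.0)
        assert b.sigma0 == pytest.approx(math.sqrt(2.0))

    def test_requires_two_usable_days(self):
        recs = [DailyRecord(day=1, times=(4.0,)), DailyRecord(day=2, times=())]
        with pytest.raises(InitializationError):
            estimate_baseline(recs)

    def test_window_filter_skips_empty_days(self):
        recs = [
            DailyRecord(day=1, times=(4.0,)),
            DailyRecord(day=2, times=()),
            DailyRecord(day=3, times=(6.0,)),
            DailyRecord(day=4, times=(100.0,)),
        ]
        b = estimate_baseline(recs, window=(1, 3))
        assert b.mu0 == pytest.approx(5.0)
        assert b.n_days == 2

    def test_simulated_stable_level(self, rng):
        from gaitspc import MODELS, generate_scenario, catalog

        series = generate_scenario(catalog("Tr_S"), rng=rng)
        b = estimate_baseline(series.records[:14])
        # centre of the median series: near the model median exp(1.504)=4.50
        assert b.mu0 == pytest.approx(MODELS["SGM"].median, abs=0.6)
        assert b.sigma0 > 0


class TestCusumStep:
    """Direct arithmetic of the tabular recursion on a hand example."""

    def fit_one(self, chart, medians, n_i=1):
        recs = records_from_medians([4.5] * 14, n_i=n_i) + records_from_medians(
            medians, n_i=n_i, start_day=15
        )
        return chart.fit(recs)

    def test_at_target_stays_zero(self):
        chart = TabularCusumChart(k=0.5, h=3.0)
        # pooled sd > 0 via two measurements per day straddling the median
        recs = [DailyRecord(day=d, times=(4.0, 5.0)) for d in range(1, 40)]
        chart.fit(recs)
        monitored = chart.results_[~chart.results_["in_init"]]
        assert (monitored["cplus"] == 0).all()
        assert (monitored["cminus"] == 0).all()
        assert not monitored["flag"].any()

    def test_single_step_arithmetic(self):
        # mu0=4.5, sigma0=0.5, k=0.5, h=3: K=0.125, UCL=1.5
        chart = TabularCusumChart(k=0.5, h=3.0)
        state = chart._init_state(manual_baseline(4.5, 0.5))
        state, row, flag = chart._step(state, 5.0, 1, manual_baseline(4.5, 0.5), 1)
        assert row["cplus"] == pytest.approx(0.375)
        assert row["cminus"] == 0.0
        assert row["ucl"] == pytest.approx(1.5)
        assert not flag

    def test_rational_subgroup_scaling(self):
        # same step with n_i=4: K and UCL divided by 2
        chart = TabularCusumChart(k=0.5, h=3.0, rational_subgroups=True)
        b = manual_baseline(4.5, 0.5)
        state, row, flag = chart._step(chart._init_state(b), 5.0, 4, b, 1)
        assert row["cplus"] == pytest.approx(0.4375)
        assert row["ucl"] == pytest.approx(0.75)

    def test_standardized_step(self):
        chart = StandardizedCusumChart(k=0.5, h=3.0)
        b = manual_baseline(4.5, 0.5)
        state, row, flag = chart._step(chart._init_state(b), 5.0, 1, b, 1)
        # y = 1, K = 0.25 -> C+ = 0.75
        assert row["cplus"] == pytest.approx(0.75)
        assert row["ucl"] == pytest.approx(3.0)

    def test_nonnegative_branches(self, rng):
        chart = TabularCusumChart(k=0.5, h=3.0)
        medians = 4.5 + rng.normal(0, 2.0, size=120)
        medians = np.clip(medians, 0.1, None)
        chart.fit(records_from_medians([4.5] * 14) + records_from_medians(
            medians, start_day=15))
        assert (chart.results_[["cplus", "cminus"]].fillna(0) >= 0).all().all()

    def test_standardized_equals_tabular_flags(self, rng):
        """Scale invariance: the standardized chart flags exactly when the
        tabular chart does, on any series (with and without subgroups)."""
        recs = []
        for day in range(1, 120):
            n = int(rng.integers(1, 6))
            recs.append(DailyRecord(day=day, times=tuple(
                np.exp(rng.normal(1.5, 0.2, size=n)))))
        for rs in (False, True):
            tc = TabularCusumChart(k=0.5, h=3.0, rational_subgroups=rs).fit(recs)
            sc = StandardizedCusumChart(k=0.5, h=3.0, rational_subgroups=rs).fit(recs)
            pd.testing.assert_series_equal(
                tc.results_["flag"], sc.results_["flag"]
            )

    def test_standardized_needs_dispersion(self):
        recs = records_from_medians([4.0] * 30)
        with pytest.raises(StandardizationError):
            StandardizedCusumChart().fit(recs)


class TestEwma:
    def test_fixed_point_at_target(self, flat_series):
        chart = EwmaChart(lambda_w=0.18, L=2.0).fit(flat_series)
        monitored = chart.results_[~chart.results_["in_init"]]
        assert np.allclose(monitored["z"], 5.0)
        assert not monitored["flag"].any()

    def test_first_step_value_and_width(self):
        chart = EwmaChart(lambda_w=0.18, L=2.0)
        b = manual_baseline(4.5, 0.5)
        z, row, flag = chart._step(chart._init_state(b), 5.0, 1, b, 1)
        assert z == pytest.approx(4.59)
        # day-1 half width collapses to L*sigma0*lambda
        assert row["ucl"] - b.mu0 == pytest.approx(2.0 * 0.5 * 0.18)

    def test_steady_state_width(self):
        chart = EwmaChart(lambda_w=0.18, L=1.0)
        b = manual_baseline(0.0, 1.0)
        z = chart._init_state(b)
        for i in range(1, 400):
            z, row, _ = chart._step(z, 0.0, 1, b, i)
        assert row["ucl"] == pytest.approx(math.sqrt(0.18 / 1.82), rel=1e-6)
        assert math.sqrt(0.18 / 1.82) == pytest.approx(0.3145, abs=2e-4)

    def test_limits_monotone_nondecreasing(self, rng):
        medians = np.clip(4.5 + rng.normal(0, 0.3, 80), 0.1, None)
        chart = EwmaChart(lambda_w=0.2, L=3.0).fit(
            records_from_medians([4.5] * 14) + records_from_medians(
                medians, start_day=15))
        ucl = chart.results_["ucl"].dropna().to_numpy()
        assert np.all(np.diff(ucl) >= -1e-12)

    @settings(max_examples=25, deadline=None)
    @given(
        lam=st.floats(0.05, 1.0),
        data=st.lists(st.floats(0.5, 20.0), min_size=1, max_size=40),
    )
    def test_recursion_equals_closed_form(self, lam, data):
        """Brute-force oracle: z_i = lam*sum (1-lam)^j x_{i-j} + (1-lam)^i z0."""
        chart = EwmaChart(lambda_w=lam, L=3.0)
        b = manual_baseline(5.0, 1.0)
        z = chart._init_state(b)
        for i, x in enumerate(data, start=1):
            z, _, _ = chart._step(z, x, 1, b, i)
        n = len(data)
        closed = lam * sum(
            (1 - lam) ** j * data[n - 1 - j] for j in range(n)
        ) + (1 - lam) ** n * b.mu0
        assert z == pytest.approx(closed, abs=1e-9)

    def test_lambda_one_is_shewhart(self, rng):
        """lambda=1 degenerates to plotting raw medians with fixed limits."""
        medians = np.clip(4.5 + rng.normal(0, 0.3, 60), 0.1, None)
        recs = records_from_medians([4.5] * 14) + records_from_medians(
            medians, start_day=15)
        chart = EwmaChart(lambda_w=1.0, L=3.0).fit(recs)
        monitored = chart.results_.dropna(subset=["z"])
        np.testing.assert_allclose(monitored["z"], monitored["median"])
        b = chart.baseline_
        np.testing.assert_allclose(monitored["ucl"], b.mu0 + 3 * b.sigma0)

    def test_lambda_out_of_range(self, flat_series):
        with pytest.raises(ParameterError):
            EwmaChart(lambda_w=0.0).fit(flat_series)
        with pytest.raises(ParameterError):
            EwmaChart(lambda_w=1.2).fit(flat_series)


class TestAlarmLogic:
    def shift_series(self, shift=10.0, n_days=60, shift_day=30):
        """In-control at 4.5 then a permanent level shift of `shift` sigma0
        units (sigma0 ~ 0.1 from within-day spread)."""
        recs = []
        for day in range(1, n_days + 1):
            level = 4.5 if day < shift_day else 4.5 + shift * 0.1
            recs.append(DailyRecord(day=day, times=(level - 0.1, level, level + 0.1)))
        return recs

    def test_constant_series_no_alarms(self, flat_series):
        for chart in (TabularCusumChart(), EwmaChart(), EwmaChart(lambda_w=0.18, L=2)):
            run = run_chart(flat_series, chart)
            assert run.alarm_events == []

    def test_large_shift_alarms_promptly(self):
        recs = self.shift_series()
        run = run_chart(recs, EwmaChart(lambda_w=0.18, L=2.0))
        assert run.alarm_events
        ev = run.alarm_events[0]
        assert 30 <= ev.start_day <= 31
        assert ev.trigger_day <= 32  # confirmed within confirm_days + 1

    def test_no_flags_during_initialization(self):
        recs = self.shift_series(shift_day=5)  # shift inside init window
        run = run_chart(recs, EwmaChart(lambda_w=0.18, L=2.0))
        init_rows = run.results[run.results["in_init"]]
        assert not init_rows["flag"].any()

    def test_empty_days_do_not_break_runs(self):
        recs = self.shift_series()
        # empty day in the middle of the alarm run
        recs[30] = DailyRecord(day=31, times=())
        run = run_chart(recs, EwmaChart(lambda_w=0.18, L=2.0))
        assert run.alarm_events
        assert run.alarm_events[0].start_day == 30

    def test_single_flag_day_is_not_an_alarm(self):
        recs = self.shift_series()
        # revert to baseline right after one shifted day
        for i in range(30, 60):
            recs[i] = DailyRecord(day=i + 1, times=(4.4, 4.5, 4.6))
        run = run_chart(recs, EwmaChart(lambda_w=1.0, L=3.0))
        assert run.alarm_events == []

    def test_rational_subgroups_identity_at_n1(self, rng):
        """With n_i = 1 every day, the subgroup chart is bit-for-bit the
        plain chart."""
        medians = np.clip(4.5 + rng.normal(0, 0.5, 100), 0.1, None)
        recs = records_from_medians(list(medians))
        for cls in (TabularCusumChart, StandardizedCusumChart, EwmaChart):
            plain = cls().fit(recs).results_
            rs = cls(rational_subgroups=True).fit(recs).results_
            pd.testing.assert_frame_equal(plain, rs)

    def test_reinitialization_resets_state(self):
        recs = self.shift_series(n_days=80)
        chart = EwmaChart(lambda_w=0.18, L=2.0, reinitialize=True).fit(recs)
        res = chart.results_
        assert res["reinit_event"].any()
        assert len(chart.baseline_history_) >= 2
        reinit_day = res.loc[res["reinit_event"], "day"].iloc[0]
        after = res[res["day"] > reinit_day].iloc[0]
        b1 = chart.baseline_history_[1]
        # EWMA restarts from the new centre line with day-1 narrow limits
        lam = 0.18
        assert after["z"] == pytest.approx(lam * after["median"] + (1 - lam) * b1.mu0)
        assert after["ucl"] - b1.mu0 == pytest.approx(2.0 * b1.sigma0 * lam)
        # new baseline reflects the post-shift level
        assert b1.mu0 > chart.baseline_.mu0

    def test_reinit_enables_second_trend_detection(self):
        """After re-baselining on the shifted level, a later return to the
        original level is detected again."""
        recs = []
        for day in range(1, 121):
            level = 4.5 if day < 40 or day >= 80 else 5.5
            recs.append(DailyRecord(day=day, times=(level - 0.1, level, level + 0.1)))
        with_ra = run_chart(recs, EwmaChart(lambda_w=0.18, L=2.0, reinitialize=True))
        starts = [ev.start_day for ev in with_ra.alarm_events]
        assert any(s < 45 for s in starts)
        assert any(78 <= s <= 85 for s in starts)
        without = run_chart(recs, EwmaChart(lambda_w=0.18, L=2.0))
        # without reinitialization the chart never re-arms: one endless event
        assert len(without.alarm_events) == 1

    def test_cusum_reset_after_reinit(self):
        recs = self.shift_series(n_days=80)
        chart = TabularCusumChart(k=0.5, h=3.0, reinitialize=True).fit(recs)
        res = chart.results_
        assert res["reinit_event"].any()
        reinit_day = res.loc[res["reinit_event"], "day"].iloc[0]
        after = res[res["day"] > reinit_day].iloc[0]
        b1 = chart.baseline_history_[1]
        expected = max(0.0, after["median"] - (b1.mu0 + 0.25 * b1.sigma0))
        assert after["cplus"] == pytest.approx(expected)

    def test_series_shorter_than_init_errors(self):
        with pytest.raises(InitializationError):
            EwmaChart().fit(records_from_medians([4.5] * 10))


class TestSklearnProtocol:
    def test_get_set_params_clone(self):
        chart = EwmaChart(lambda_w=0.18, L=2.0, rational_subgroups=True)
        params = chart.get_params()
        assert params["lambda_w"] == 0.18
        twin = clone(chart)
        assert twin.get_params() == params
        twin.set_params(L=3.0)
        assert twin.L == 3.0 and chart.L == 2.0

    def test_fit_predict_marks_alarm_days(self):
        recs = TestAlarmLogic().shift_series()
        y = EwmaChart(lambda_w=0.18, L=2.0).fit_predict(recs)
        assert set(np.unique(y)) <= {0, 1}
        assert y[:29].sum() == 0 and y.sum() > 0

    def test_fit_does_not_mutate_params(self, flat_series):
        chart = EwmaChart(lambda_w=0.18, L=2.0)
        before = chart.get_params()
        chart.fit(flat_series)
        assert chart.get_params() == before


class TestConfigAndDialects:
    def test_config_build_roundtrip(self):
        cfg = ChartConfig(family="tabular_cusum", k=0.42, h=2.08, reinitialize=True)
        est = cfg.build()
        assert isinstance(est, TabularCusumChart)
        assert est.get_params()["k"] == 0.42

    def test_config_rejects_unknown_family_and_keys(self):
        with pytest.raises(ParameterError):
            ChartConfig(family="shewhart").build()
        with pytest.raises(ParameterError):
            ChartConfig.from_mapping({"familly": "ewma"})

    def test_medians_dialect_equivalent_to_raw(self, rng):
        """With one measurement per day the two input dialects give the
        same chart output."""
        medians = np.round(np.clip(4.5 + rng.normal(0, 0.4, 60), 0.1, None), 4)
        raw = pd.DataFrame({
            "day": np.arange(1, 61),
            "transfer_time_s": medians,
        })
        med = pd.DataFrame({
            "day": np.arange(1, 61),
            "median_s": medians,
            "n_i": 1,
        })
        a = EwmaChart(lambda_w=0.18, L=2.0).fit(raw).results_
        b = EwmaChart(lambda_w=0.18, L=2.0).fit(med).results_
        pd.testing.assert_frame_equal(a, b)

    def test_frame_with_empty_day(self):
        df = pd.DataFrame({
            "day": [1, 1, 2, 3],
            "transfer_time_s": [4.0, 5.0, np.nan, 6.0],
        })
        recs = daily_records_from_frame(df)
        assert [r.n_i for r in recs] == [2, 0, 1]
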