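"""Control charts over daily transfer-time medians.

The monitored statistic is the median of each day's transfer-time
measurements.  A baseline (centre line ``mu0`` and dispersion ``sigma0``) is
estimated from the raw measurements of an initialization window of usable
days; the charts then track either cumulative sums of deviations (tabular or
standardized CUSUM) or an exponentially weighted moving average (EWMA) of the
daily medians against control limits expressed as multiples of ``sigma0``.

Two refinements from industrial practice are supported:

* *rational subgroups* — each day's slack/limits are divided by ``sqrt(n_i)``
  (``n_i`` = number of measurements behind that day's median), so days backed
  by few measurements get wide limits and influence the chart less;
* *reinitialization* — after three consecutive alarm days the baseline is
  re-estimated from the 14 usable days preceding the last alarm day and the
  chart state is reset, so a later second trend remains detectable.

An *alarm event* is a maximal run of at least ``confirm_days`` (default 2)
consecutive usable flagged days; the event's *trigger day* is the day the run
reached ``confirm_days``.

The estimators follow the scikit-learn protocol (``fit`` / ``fit_predict``,
``get_params`` / ``set_params``) and expose fitted attributes with a trailing
underscore.  ``run_chart`` is the thin functional wrapper.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import (
    DataError,
    InitializationError,
    ParameterError,
    StandardizationError,
)

__all__ = [
    "DailyRecord",
    "Baseline",
    "AlarmEvent",
    "ChartRun",
    "ChartConfig",
    "TabularCusumChart",
    "StandardizedCusumChart",
    "EwmaChart",
    "estimate_baseline",
    "run_chart",
    "as_daily_records",
    "daily_records_from_frame",
]


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DailyRecord:
    """One day of transfer-time measurements.

    Either built from raw ``times`` (the usual case) or, for medians-only
    inputs, from a precomputed median and count.
    """

    day: int
    times: tuple[float, ...] | None = None
    n: int | None = None
    median: float | None = None

    def __post_init__(self) -> None:
        if self.times is not None:
            times = tuple(float(t) for t in self.times)
            if any(t <= 0 for t in times):
                raise DataError(f"day {self.day}: non-positive transfer time")
            object.__setattr__(self, "times", times)
            object.__setattr__(self, "n", len(times))
            object.__setattr__(
                self, "median", float(np.median(times)) if times else None
            )
        else:
            if self.n is None:
                raise DataError(f"day {self.day}: need times or (median, n)")
            if self.n >= 1 and self.median is None:
                raise DataError(f"day {self.day}: n >= 1 but no median given")

    @property
    def n_i(self) -> int:
        return int(self.n or 0)

    @property
    def usable(self) -> bool:
        return self.n_i >= 1 and self.median is not None

    @property
    def pooled_values(self) -> tuple[float, ...]:
        """Values this day contributes to a pooled baseline estimate."""
        if self.times is not None:
            return self.times
        return (float(self.median),) if self.usable else ()


@dataclass(frozen=True)
class Baseline:
    """Centre line and dispersion of the in-control process.

    ``mu0`` is the mean of the daily medians in the initialization window —
    the centre of the series the chart actually monitors (for the skewed
    transfer-time distribution the pooled raw mean would sit above it and
    bias the chart toward downward alarms).  ``sigma0`` is the sample
    standard deviation (ddof=1) of all raw measurements in the window, i.e. a
    per-measurement dispersion; with rational subgroups ``sigma0 / sqrt(n_i)``
    then approximates the sampling dispersion of a day's median, the standard
    variable-subgroup-size scaling.
    """

    mu0: float
    sigma0: float
    window: tuple[int, int]
    n_days: int
    n_obs: int


@dataclass(frozen=True)
class AlarmEvent:
    """A confirmed alarm: a maximal run of consecutive flagged usable days."""

    start_day: int
    end_day: int
    trigger_day: int  # day the run reached confirm_days


@dataclass
class ChartRun:
    """Result of monitoring one series: per-day table plus event summaries."""

    results: pd.DataFrame
    alarm_events: list[AlarmEvent]
    baseline_history: list[Baseline]
    init_window: tuple[int, int]

    @property
    def baseline(self) -> Baseline:
        return self.baseline_history[0]


# ---------------------------------------------------------------------------
# input coercion
# ---------------------------------------------------------------------------


def daily_records_from_frame(df: pd.DataFrame) -> list[DailyRecord]:
    """Build daily records from a long-format or medians-only DataFrame.

    Raw dialect: columns ``day`` and ``transfer_time_s`` (one row per
    measurement; a row with a missing time marks an empty day).  Medians
    dialect: columns ``day``, ``median_s``, ``n_i``.
    """
    cols = set(df.columns)
    if {"day", "transfer_time_s"} <= cols:
        records = []
        for day, grp in df.groupby("day", sort=True):
            times = grp["transfer_time_s"].dropna().to_numpy(dtype=float)
            records.append(DailyRecord(day=int(day), times=tuple(times)))
        return records
    if {"day", "median_s", "n_i"} <= cols:
        records = []
        for row in df.itertuples(index=False):
            n = int(row.n_i)
            med = float(row.median_s) if n >= 1 else None
            records.append(DailyRecord(day=int(row.day), n=n, median=med))
        return sorted(records, key=lambda r: r.day)
    raise DataError(
        "expected columns (day, transfer_time_s) or (day, median_s, n_i); "
        f"got {sorted(cols)}"
    )


def as_daily_records(X) -> list[DailyRecord]:
    """Coerce supported inputs to a day-sorted list of :class:`DailyRecord`."""
    if isinstance(X, pd.DataFrame):
        return daily_records_from_frame(X)
    if hasattr(X, "records"):  # SimulatedSeries
        return list(X.records)
    X = list(X)
    if all(isinstance(r, DailyRecord) for r in X):
        return sorted(X, key=lambda r: r.day)
    # bare sequence of per-day median values (day = position, n_i = 1)
    return [
        DailyRecord(day=i + 1, times=(float(v),)) for i, v in enumerate(X)
    ]


# ---------------------------------------------------------------------------
# baseline
# ---------------------------------------------------------------------------


def estimate_baseline(
    records: Iterable[DailyRecord],
    window: tuple[int, int] | None = None,
) -> Baseline:
    """Estimate the in-control baseline from an initialization window.

    ``mu0`` is the mean of the usable days' medians; ``sigma0`` the sample
    standard deviation of every raw measurement in ``window`` (all given
    records when ``window`` is None).  For medians-only inputs each day
    contributes its median once, so ``sigma0`` degrades to the dispersion of
    the median series.  At least two usable days are required.
    """
    recs = [r for r in records if r.usable]
    if window is not None:
        lo, hi = window
        recs = [r for r in recs if lo <= r.day <= hi]
    if len(recs) < 2:
        raise InitializationError(
            f"initialization window has {len(recs)} usable day(s); need >= 2"
        )
    values = np.concatenate([np.asarray(r.pooled_values) for r in recs])
    sigma0 = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return Baseline(
        mu0=float(np.mean([r.median for r in recs])),
        sigma0=sigma0,
        window=(recs[0].day, recs[-1].day),
        n_days=len(recs),
        n_obs=int(values.size),
    )


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


class _BaseControlChart(BaseEstimator):
    """Shared monitoring engine; subclasses define the per-day statistic."""

    _stat_columns: tuple[str, ...] = ()

    def __init__(
        self,
        rational_subgroups: bool = False,
        reinitialize: bool = False,
        confirm_days: int = 2,
        reinit_after_alarm_days: int = 3,
        init_length_days: int = 14,
    ):
        self.rational_subgroups = rational_subgroups
        self.reinitialize = reinitialize
        self.confirm_days = confirm_days
        self.reinit_after_alarm_days = reinit_after_alarm_days
        self.init_length_days = init_length_days

    # subclass hooks ------------------------------------------------------
    def _check_params(self) -> None:
        if self.confirm_days < 1:
            raise ParameterError("confirm_days must be >= 1")
        if self.reinit_after_alarm_days < 1:
            raise ParameterError("reinit_after_alarm_days must be >= 1")
        if self.init_length_days < 2:
            raise ParameterError("init_length_days must be >= 2")

    def _check_baseline(self, baseline: Baseline) -> None:  # noqa: B027
        pass

    def _init_state(self, baseline: Baseline):
        raise NotImplementedError

    def _step(self, state, x: float, n_i: int, baseline: Baseline, i_since: int):
        """Advance one usable day; return (state, row_dict, flag)."""
        raise NotImplementedError

    # engine --------------------------------------------------------------
    def fit(self, X, y=None):
        """Run the chart over a daily series.

        Parameters
        ----------
        X : DataFrame, sequence of DailyRecord, SimulatedSeries or 1-d values
            The daily series to monitor.

        Sets ``results_`` (per-day table), ``alarm_events_``,
        ``baseline_history_``, ``baseline_`` and ``init_window_``.
        """
        self._check_params()
        records = as_daily_records(X)
        usable = [r for r in records if r.usable]
        if len(usable) < self.init_length_days:
            raise InitializationError(
                f"series has {len(usable)} usable days; initialization "
                f"needs {self.init_length_days}"
            )
        init_records = usable[: self.init_length_days]
        baseline = estimate_baseline(init_records)
        self._check_baseline(baseline)
        init_end = init_records[-1].day
        init_window = (records[0].day, init_end)

        rows: list[dict] = []
        events: list[AlarmEvent] = []
        history = [baseline]
        state = self._init_state(baseline)
        i_since = 0
        run: list[int] = []  # row indices of the current flagged run
        trigger_day: int | None = None
        reinit_at = max(self.reinit_after_alarm_days, self.confirm_days)

        def close_run(end_idx_exclusive: int | None = None) -> None:
            nonlocal run, trigger_day
            if len(run) >= self.confirm_days:
                events.append(
                    AlarmEvent(
                        start_day=rows[run[0]]["day"],
                        end_day=rows[run[-1]]["day"],
                        trigger_day=trigger_day,
                    )
                )
            run = []
            trigger_day = None

        for rec in records:
            base_row = {
                "day": rec.day,
                "n_i": rec.n_i,
                "median": rec.median if rec.usable else math.nan,
                "in_init": rec.day <= init_end,
                "flag": False,
                "alarm_day": False,
                "reinit_event": False,
            }
            if not rec.usable or rec.day <= init_end:
                base_row.update({c: math.nan for c in self._stat_columns})
                base_row.update({"ucl": math.nan, "lcl": math.nan})
                rows.append(base_row)
                continue

            i_since += 1
            state, stat_row, flag = self._step(
                state, rec.median, rec.n_i, baseline, i_since
            )
            base_row.update(stat_row)
            base_row["flag"] = bool(flag)
            rows.append(base_row)
            idx = len(rows) - 1

            if flag:
                run.append(idx)
                if len(run) == self.confirm_days:
                    trigger_day = rec.day
                    for j in run:
                        rows[j]["alarm_day"] = True
                elif len(run) > self.confirm_days:
                    rows[idx]["alarm_day"] = True
                if self.reinitialize and len(run) == reinit_at:
                    rows[idx]["reinit_event"] = True
                    close_run()
                    # baseline from the init_length_days usable days strictly
                    # before the last alarm day (alarm days inside that span
                    # are deliberately not excluded)
                    prior = [r for r in usable if r.day < rec.day]
                    window = prior[-self.init_length_days:]
                    baseline = estimate_baseline(window)
                    self._check_baseline(baseline)
                    history.append(baseline)
                    state = self._init_state(baseline)
                    i_since = 0
            else:
                close_run()
        close_run()

        self.results_ = pd.DataFrame(rows)
        self.alarm_events_ = events
        self.baseline_history_ = history
        self.baseline_ = history[0]
        self.init_window_ = init_window
        self.n_days_ = len(records)
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        """Run the chart and return the per-day alarm indicator (0/1)."""
        self.fit(X)
        return self.results_["alarm_day"].to_numpy(dtype=int)

    def to_chart_run(self) -> ChartRun:
        return ChartRun(
            results=self.results_,
            alarm_events=list(self.alarm_events_),
            baseline_history=list(self.baseline_history_),
            init_window=self.init_window_,
        )


class TabularCusumChart(_BaseControlChart):
    """Tabular CUSUM of daily medians.

    Accumulates deviations beyond a slack ``K = (k/2) sigma0`` into a positive
    and a negative branch,

        C+_i = max(0, x_i - (mu0 + K) + C+_{i-1})
        C-_i = max(0, (mu0 - K) - x_i + C-_{i-1}),

    and flags a day when either branch exceeds ``h sigma0``.  With rational
    subgroups both the slack and the limit are divided by ``sqrt(n_i)``.
    """

    _stat_columns = ("cplus", "cminus")

    def __init__(
        self,
        k: float = 0.5,
        h: float = 3.0,
        rational_subgroups: bool = False,
        reinitialize: bool = False,
        confirm_days: int = 2,
        reinit_after_alarm_days: int = 3,
        init_length_days: int = 14,
    ):
        super().__init__(
            rational_subgroups=rational_subgroups,
            reinitialize=reinitialize,
            confirm_days=confirm_days,
            reinit_after_alarm_days=reinit_after_alarm_days,
            init_length_days=init_length_days,
        )
        self.k = k
        self.h = h

    def _check_params(self) -> None:
        super()._check_params()
        if self.k < 0:
            raise ParameterError("k must be >= 0")
        if self.h <= 0:
            raise ParameterError("h must be > 0")

    def _init_state(self, baseline: Baseline):
        return (0.0, 0.0)

    def _slack_and_limit(self, baseline: Baseline):
        return 0.5 * self.k * baseline.sigma0, self.h * baseline.sigma0

    def _step(self, state, x, n_i, baseline, i_since):
        cp, cm = state
        K, limit = self._slack_and_limit(baseline)
        if self.rational_subgroups:
            rootn = math.sqrt(n_i)
            K, limit = K / rootn, limit / rootn
        cp = max(0.0, x - (baseline.mu0 + K) + cp)
        cm = max(0.0, (baseline.mu0 - K) - x + cm)
        flag = cp > limit or cm > limit
        row = {"cplus": cp, "cminus": cm, "ucl": limit, "lcl": -limit}
        return (cp, cm), row, flag


class StandardizedCusumChart(TabularCusumChart):
    """CUSUM on standardized deviations ``y_i = (x_i - mu0) / sigma0``.

    After standardization the working scale has unit dispersion, so the slack
    is ``k/2`` and the limit ``h`` with no ``sigma0`` factor.
    """

    def _check_baseline(self, baseline: Baseline) -> None:
        if baseline.sigma0 == 0:
            raise StandardizationError("sigma0 is zero; cannot standardize")

    def _slack_and_limit(self, baseline: Baseline):
        return 0.5 * self.k, float(self.h)

    def _step(self, state, x, n_i, baseline, i_since):
        y = (x - baseline.mu0) / baseline.sigma0
        cp, cm = state
        K, limit = self._slack_and_limit(baseline)
        if self.rational_subgroups:
            rootn = math.sqrt(n_i)
            K, limit = K / rootn, limit / rootn
        cp = max(0.0, y - K + cp)
        cm = max(0.0, -K - y + cm)
        flag = cp > limit or cm > limit
        row = {"cplus": cp, "cminus": cm, "ucl": limit, "lcl": -limit}
        return (cp, cm), row, flag


class EwmaChart(_BaseControlChart):
    """EWMA chart of daily medians with time-varying control limits.

    Tracks ``z_i = lambda_w x_i + (1 - lambda_w) z_{i-1}`` (``z_0 = mu0``)
    against

        mu0 +/- L sigma0 sqrt(lambda_w/(2-lambda_w) (1-(1-lambda_w)^{2i})),

    where ``i`` counts usable days since (re)initialization, so the limits
    start narrow and widen to their steady state.  With rational subgroups
    ``L`` is divided by ``sqrt(n_i)`` for that day's limits.
    """

    _stat_columns = ("z",)

    def __init__(
        self,
        lambda_w: float = 0.15,
        L: float = 3.0,
        rational_subgroups: bool = False,
        reinitialize: bool = False,
        confirm_days: int = 2,
        reinit_after_alarm_days: int = 3,
        init_length_days: int = 14,
    ):
        super().__init__(
            rational_subgroups=rational_subgroups,
            reinitialize=reinitialize,
            confirm_days=confirm_days,
            reinit_after_alarm_days=reinit_after_alarm_days,
            init_length_days=init_length_days,
        )
        self.lambda_w = lambda_w
        self.L = L

    def _check_params(self) -> None:
        super()._check_params()
        if not 0 < self.lambda_w <= 1:
            raise ParameterError("lambda_w must be in (0, 1]")
        if self.L <= 0:
            raise ParameterError("L must be > 0")

    def _init_state(self, baseline: Baseline):
        return baseline.mu0

    def _step(self, state, x, n_i, baseline, i_since):
        lam = self.lambda_w
        z = lam * x + (1.0 - lam) * state
        L_eff = self.L / math.sqrt(n_i) if self.rational_subgroups else self.L
        width = (
            L_eff
            * baseline.sigma0
            * math.sqrt(lam / (2.0 - lam) * (1.0 - (1.0 - lam) ** (2 * i_since)))
        )
        ucl = baseline.mu0 + width
        lcl = baseline.mu0 - width
        flag = z > ucl or z < lcl
        row = {"z": z, "ucl": ucl, "lcl": lcl}
        return z, row, flag


# ---------------------------------------------------------------------------
# configuration / functional wrapper
# ---------------------------------------------------------------------------

_FAMILIES = {
    "tabular_cusum": TabularCusumChart,
    "standardized_cusum": StandardizedCusumChart,
    "ewma": EwmaChart,
}


@dataclass
class ChartConfig:
    """Plain-data chart configuration; ``build()`` yields the estimator."""

    family: str = "ewma"
    k: float = 0.5
    h: float = 3.0
    lambda_w: float = 0.15
    L: float = 3.0
    rational_subgroups: bool = False
    reinitialize: bool = False
    confirm_days: int = 2
    reinit_after_alarm_days: int = 3
    init_length_days: int = 14

    def build(self) -> _BaseControlChart:
        if self.family not in _FAMILIES:
            raise ParameterError(
                f"unknown chart family {self.family!r}; "
                f"choose from {sorted(_FAMILIES)}"
            )
        common = dict(
            rational_subgroups=self.rational_subgroups,
            reinitialize=self.reinitialize,
            confirm_days=self.confirm_days,
            reinit_after_alarm_days=self.reinit_after_alarm_days,
            init_length_days=self.init_length_days,
        )
        if self.family == "ewma":
            return EwmaChart(lambda_w=self.lambda_w, L=self.L, **common)
        return _FAMILIES[self.family](k=self.k, h=self.h, **common)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "ChartConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ParameterError(f"unknown chart config keys: {sorted(unknown)}")
        return cls(**mapping)


def run_chart(
    series,
    config: "ChartConfig | _BaseControlChart",
    init_length_days: int | None = None,
) -> ChartRun:
    """Monitor a daily series and return the complete :class:`ChartRun`."""
    chart = config.build() if isinstance(config, ChartConfig) else config
    from sklearn.base import clone

    chart = clone(chart)
    if init_length_days is not None:
        chart.set_params(init_length_days=init_length_days)
    chart.fit(series)
    return chart.to_chart_run()
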