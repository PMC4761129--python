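"""Scoring chart runs against ground truth.

Three criteria summarize a monitoring method over replicated simulations:

* **Detection Rate (DR)** — percentage of ground-truth transitions during
  which at least one correct alarm event starts;
* **Average Run Length (ARL)** — mean number of days from the start of a
  transition to its detection (the alarm's trigger day, counted inclusively),
  over detected transitions only;
* **FPR** — mean number of false alarm events per week outside transition
  and initialization periods.

Alarm-correctness rules: an alarm event is *correct* when it starts inside a
transition window (for an abrupt switch: within the 4 days following the
switch) or exactly one day before the window; an event starting two or more
days before a window, or after it, is *false*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone

from .charts import AlarmEvent, ChartRun, _BaseControlChart, ChartConfig
from .errors import InitializationError, SpecificationError
from .simulate import (
    DEFAULT_RATE,
    MeasurementRate,
    SimulatedSeries,
    catalog,
    generate_scenario,
    replicate_rng,
)

__all__ = [
    "AlarmClassification",
    "EvalSummary",
    "classify_alarms",
    "detection_and_run_length",
    "false_alarm_rate",
    "evaluate_series",
    "evaluate",
    "pooled_metrics",
    "init_length_sweep",
    "summaries_to_frame",
]

GRACE_DAYS_BEFORE = 2  # events starting >= 2 days before a window are false


@dataclass(frozen=True)
class AlarmClassification:
    event: AlarmEvent
    label: str  # "correct" | "false"
    matched_window: int | None  # index into truth_windows


def _check_windows(truth_windows) -> list[tuple[int, int]]:
    windows = sorted((int(a), int(b)) for a, b in truth_windows)
    for (a, b), (c, d) in zip(windows, windows[1:]):
        if c <= b:
            raise SpecificationError(f"overlapping truth windows {(a, b)} and {(c, d)}")
    if any(a > b for a, b in windows):
        raise SpecificationError("truth window with start > end")
    return windows


def classify_alarms(
    run: ChartRun | list[AlarmEvent], truth_windows
) -> list[AlarmClassification]:
    """Label each alarm event of a run as correct or false."""
    windows = _check_windows(truth_windows)
    events = run.alarm_events if isinstance(run, ChartRun) else run
    out = []
    for ev in events:
        matched = None
        for j, (a, b) in enumerate(windows):
            if a <= ev.start_day <= b or ev.start_day == a - 1:
                matched = j
                break
        label = "correct" if matched is not None else "false"
        out.append(AlarmClassification(event=ev, label=label, matched_window=matched))
    return out


def detection_and_run_length(
    classifications: list[AlarmClassification], truth_windows
) -> list[tuple[bool, int | None]]:
    """Per truth window: (detected, run length in days or None).

    The run length is counted inclusively from the window start to the first
    day of the earliest correct event (the first flagged day of the run that
    went on to confirm), so an alarm whose run begins on the window's start
    day gives a run length of 1.  Events whose grace-day start precedes the
    window are clamped to 1.
    """
    windows = _check_windows(truth_windows)
    out = []
    for j, (a, _) in enumerate(windows):
        firsts = [
            c.event
            for c in classifications
            if c.label == "correct" and c.matched_window == j
        ]
        if not firsts:
            out.append((False, None))
            continue
        start = min(ev.start_day for ev in firsts)
        out.append((True, max(1, start - a + 1)))
    return out


def false_alarm_rate(
    classifications: list[AlarmClassification],
    series_length_days: int,
    truth_windows,
    init_windows,
) -> float | None:
    """False alarm events per week of eligible (no-transition) time.

    Eligible days are those outside every truth window and outside every
    initialization window.  Returns None when no day is eligible.
    """
    blocked = set()
    for a, b in list(truth_windows) + list(init_windows):
        blocked.update(range(int(a), int(b) + 1))
    eligible = sum(
        1 for d in range(1, series_length_days + 1) if d not in blocked
    )
    if eligible == 0:
        return None
    n_false = sum(1 for c in classifications if c.label == "false")
    return n_false / (eligible / 7.0)


# ---------------------------------------------------------------------------
# replicate-level evaluation
# ---------------------------------------------------------------------------


@dataclass
class ReplicateResult:
    """Outcome of monitoring one simulated replicate."""

    detections: list[tuple[bool, int | None]]
    fpr: float | None
    n_false: int
    n_events: int


def evaluate_series(
    series: SimulatedSeries,
    chart: _BaseControlChart | ChartConfig,
    init_length_days: int | None = None,
) -> ReplicateResult:
    """Run a chart over one simulated series and score it against its truth."""
    est = chart.build() if isinstance(chart, ChartConfig) else clone(chart)
    if init_length_days is not None:
        est.set_params(init_length_days=init_length_days)
    est.fit(series)
    run = est.to_chart_run()
    cls = classify_alarms(run, series.truth_windows)
    detections = detection_and_run_length(cls, series.truth_windows)
    fpr = false_alarm_rate(
        cls, series.total_days, series.truth_windows, [run.init_window]
    )
    return ReplicateResult(
        detections=detections,
        fpr=fpr,
        n_false=sum(1 for c in cls if c.label == "false"),
        n_events=len(cls),
    )


@dataclass
class EvalSummary:
    """DR / ARL / FPR for one scenario aggregated over replicates.

    For two-trend scenarios the per-transition DR and ARL are averaged into
    the scenario-level values; the scenario ARL standard deviation is taken
    over the pooled detected run lengths of all transitions.
    """

    scenario_id: str
    n_replicates: int
    n_transitions: int
    dr: float | None
    arl_mean: float | None
    arl_sd: float | None
    fpr_mean: float
    fpr_sd: float
    dr_per_transition: list[float] = field(default_factory=list)
    arl_per_transition: list[tuple[float | None, float | None, int]] = field(
        default_factory=list
    )

    def to_rows(self) -> list[dict]:
        rows = [
            dict(scenario_id=self.scenario_id, metric="DR", mean=self.dr,
                 sd=None, n=self.n_replicates),
            dict(scenario_id=self.scenario_id, metric="ARL",
                 mean=self.arl_mean, sd=self.arl_sd, n=self.n_replicates),
            dict(scenario_id=self.scenario_id, metric="FPR",
                 mean=self.fpr_mean, sd=self.fpr_sd, n=self.n_replicates),
        ]
        for j, (dr, (am, asd, nd)) in enumerate(
            zip(self.dr_per_transition, self.arl_per_transition), start=1
        ):
            rows.append(dict(scenario_id=f"{self.scenario_id}/T{j}", metric="DR",
                             mean=dr, sd=None, n=self.n_replicates))
            rows.append(dict(scenario_id=f"{self.scenario_id}/T{j}", metric="ARL",
                             mean=am, sd=asd, n=nd))
        return rows


def _aggregate(
    scenario_id: str, results: list[ReplicateResult], n_transitions: int
) -> EvalSummary:
    n_rep = len(results)
    dr_per, arl_per = [], []
    pooled_rls: list[int] = []
    for j in range(n_transitions):
        det = [r.detections[j] for r in results]
        detected = [d for d, _ in det]
        rls = [rl for d, rl in det if d]
        pooled_rls.extend(rls)
        dr_per.append(100.0 * sum(detected) / n_rep)
        if rls:
            arl_per.append(
                (float(np.mean(rls)),
                 float(np.std(rls, ddof=1)) if len(rls) > 1 else 0.0,
                 len(rls))
            )
        else:
            arl_per.append((None, None, 0))
    fprs = [r.fpr for r in results if r.fpr is not None]
    arl_means = [m for m, _, _ in arl_per if m is not None]
    return EvalSummary(
        scenario_id=scenario_id,
        n_replicates=n_rep,
        n_transitions=n_transitions,
        dr=float(np.mean(dr_per)) if dr_per else None,
        arl_mean=float(np.mean(arl_means)) if arl_means else None,
        arl_sd=(
            float(np.std(pooled_rls, ddof=1))
            if len(pooled_rls) > 1
            else (0.0 if pooled_rls else None)
        ),
        fpr_mean=float(np.mean(fprs)) if fprs else math.nan,
        fpr_sd=(float(np.std(fprs, ddof=1)) if len(fprs) > 1 else 0.0),
        dr_per_transition=dr_per,
        arl_per_transition=arl_per,
    )


def evaluate(
    scenario_ids,
    chart: _BaseControlChart | ChartConfig,
    n_replicates: int = 20,
    master_seed: int = 0,
    rate: MeasurementRate = DEFAULT_RATE,
    init_length_days: int | None = None,
) -> tuple[list[EvalSummary], dict]:
    """Simulate, monitor and score each scenario over replicates.

    Returns the per-scenario summaries and the pooled (unweighted across
    scenarios) means.  Replicate RNG streams depend only on
    ``(master_seed, scenario_id, replicate)``, so different chart
    configurations see common random numbers.
    """
    if isinstance(scenario_ids, str):
        scenario_ids = [scenario_ids]
    summaries = []
    for sid in scenario_ids:
        spec = catalog(sid)
        results = []
        for rep in range(n_replicates):
            rng = replicate_rng(master_seed, sid, rep)
            series = generate_scenario(spec, rate=rate, rng=rng, replicate=rep)
            results.append(evaluate_series(series, chart, init_length_days))
        summaries.append(_aggregate(sid, results, len(spec.truth_windows)))
    return summaries, pooled_metrics(summaries)


def pooled_metrics(summaries: list[EvalSummary]) -> dict:
    """Unweighted scenario-mean DR / ARL / FPR (two-trend scenarios enter
    through their per-scenario transition averages)."""
    drs = [s.dr for s in summaries if s.dr is not None]
    arls = [s.arl_mean for s in summaries if s.arl_mean is not None]
    fprs = [s.fpr_mean for s in summaries if not math.isnan(s.fpr_mean)]
    return {
        "DR": float(np.mean(drs)) if drs else None,
        "ARL": float(np.mean(arls)) if arls else None,
        "FPR": float(np.mean(fprs)) if fprs else None,
    }


def init_length_sweep(
    scenario_ids,
    chart: _BaseControlChart | ChartConfig,
    lengths=range(1, 61),
    n_replicates: int = 20,
    master_seed: int = 0,
    rate: MeasurementRate = DEFAULT_RATE,
) -> pd.DataFrame:
    """Averaged DR / ARL / FPR as a function of initialization length.

    Lengths whose baseline cannot be estimated (fewer than two usable days)
    are reported as failed rows rather than raising.
    """
    rows = []
    for length in lengths:
        try:
            summaries, pooled = evaluate(
                scenario_ids,
                chart,
                n_replicates=n_replicates,
                master_seed=master_seed,
                rate=rate,
                init_length_days=int(length),
            )
        except (InitializationError, ValueError) as exc:
            rows.append(dict(init_length_days=int(length), dr=math.nan,
                             arl=math.nan, fpr=math.nan, failed=True,
                             note=str(exc)))
            continue
        rows.append(dict(
            init_length_days=int(length),
            dr=pooled["DR"] if pooled["DR"] is not None else math.nan,
            arl=pooled["ARL"] if pooled["ARL"] is not None else math.nan,
            fpr=pooled["FPR"] if pooled["FPR"] is not None else math.nan,
            failed=False,
            note="",
        ))
    return pd.DataFrame(rows)


def summaries_to_frame(summaries: list[EvalSummary]) -> pd.DataFrame:
    """Tidy (scenario_id, metric, mean, sd, n) table for export."""
    rows = []
    for s in summaries:
        rows.extend(s.to_rows())
    return pd.DataFrame(rows)
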