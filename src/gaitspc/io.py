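"""CSV exchange formats.

Everything is plain CSV: simulated series in long format (one row per
measurement; an empty day keeps a row with a blank time), ground-truth
windows as a sidecar, chart runs day by day, and tidy metric tables.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .charts import ChartRun, DailyRecord, daily_records_from_frame
from .errors import DataError
from .simulate import SimulatedSeries

__all__ = [
    "series_to_frame",
    "write_series_csv",
    "read_series_csv",
    "write_truth_csv",
    "write_chart_run_csv",
    "write_alarm_log",
]


def series_to_frame(series_list: Iterable[SimulatedSeries]) -> pd.DataFrame:
    """Long-format table: scenario_id, replicate, day, measurement_index,
    transfer_time_s.  Empty days appear once with a blank time."""
    rows = []
    for s in series_list:
        rep = s.replicate if s.replicate is not None else 0
        for rec in s.records:
            if rec.n_i == 0:
                rows.append((s.scenario_id, rep, rec.day, 0, np.nan))
            else:
                for j, t in enumerate(rec.times, start=1):
                    rows.append((s.scenario_id, rep, rec.day, j, t))
    return pd.DataFrame(
        rows,
        columns=[
            "scenario_id", "replicate", "day", "measurement_index",
            "transfer_time_s",
        ],
    )


def write_series_csv(series_list, path) -> None:
    if isinstance(series_list, SimulatedSeries):
        series_list = [series_list]
    series_to_frame(series_list).to_csv(path, index=False, float_format="%.6f")


def read_series_csv(path) -> list[DailyRecord]:
    """Read one daily series (raw long format or medians dialect).

    Raises :class:`DataError` with a line reference for malformed rows.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise DataError(f"{path}: cannot parse CSV ({exc})") from exc
    if "transfer_time_s" in df.columns:
        bad = df.index[df["transfer_time_s"].notna() & (df["transfer_time_s"] <= 0)]
        if len(bad):
            raise DataError(
                f"{path}: non-positive transfer time at data line {bad[0] + 2}"
            )
    try:
        return daily_records_from_frame(df)
    except DataError:
        raise
    except Exception as exc:
        raise DataError(f"{path}: {exc}") from exc


def write_truth_csv(series_list, path) -> None:
    """Sidecar with one row per ground-truth window."""
    if isinstance(series_list, SimulatedSeries):
        series_list = [series_list]
    rows = []
    for s in series_list:
        rep = s.replicate if s.replicate is not None else 0
        for a, b in s.truth_windows:
            rows.append((s.scenario_id, rep, a, b))
    pd.DataFrame(
        rows,
        columns=["scenario_id", "replicate", "window_start_day", "window_end_day"],
    ).to_csv(path, index=False)


def write_chart_run_csv(run: ChartRun, path) -> None:
    run.results.to_csv(path, index=False, float_format="%.6f")


def write_alarm_log(run: ChartRun, path) -> None:
    """Human-readable alarm / reinitialization log."""
    lines = []
    for ev in run.alarm_events:
        lines.append(
            f"alarm: days {ev.start_day}-{ev.end_day} "
            f"(triggered day {ev.trigger_day})"
        )
    reinits = run.results.loc[run.results["reinit_event"], "day"].tolist()
    for d in reinits:
        lines.append(f"reinitialized after day {d}")
    for i, b in enumerate(run.baseline_history):
        lines.append(
            f"baseline {i}: mu0={b.mu0:.4f} s, sigma0={b.sigma0:.4f} s, "
            f"days {b.window[0]}-{b.window[1]} ({b.n_obs} measurements)"
        )
    if not run.alarm_events:
        lines.insert(0, "no alarms")
    Path(path).write_text("\n".join(lines) + "\n")
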