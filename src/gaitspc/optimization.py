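"""Grid search of chart parameters on the training scenarios.

Every grid node is scored with the same pre-simulated replicate datasets
(common random numbers), so differences between nodes reflect the parameters
rather than Monte-Carlo noise.  The operating point is picked with a
deterministic lexicographic policy mirroring the visual choice on a
DR/ARL/FPR trade-off plot: maximize DR first, then minimize ARL, then FPR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import ParameterGrid

from .charts import _BaseControlChart
from .errors import ParameterError
from .evaluation import _aggregate, evaluate_series, pooled_metrics
from .simulate import (
    DEFAULT_RATE,
    MeasurementRate,
    TRAINING_IDS,
    catalog,
    generate_scenario,
    replicate_rng,
)

__all__ = [
    "GridResult",
    "default_param_grid",
    "grid_evaluate",
    "select_operating_point",
    "export_tradeoff",
    "plot_tradeoff",
]


@dataclass(frozen=True)
class GridResult:
    """Pooled training metrics at one parameter combination."""

    params: tuple[tuple[str, float], ...]
    dr: float | None
    arl: float | None
    fpr: float | None

    @property
    def params_dict(self) -> dict:
        return dict(self.params)


def default_param_grid(family: str, step_small: float = 0.02, step_wide: float = 0.04):
    """Full factorial ranges: k in [0, 1] / lambda in (0, 1] by ``step_small``;
    h, L in [2, 4] by ``step_wide``.  lambda = 0 is excluded (degenerate)."""
    wide = np.round(np.arange(2.0, 4.0 + 1e-9, step_wide), 10).tolist()
    if family in ("tabular_cusum", "standardized_cusum"):
        return {"k": np.round(np.arange(0.0, 1.0 + 1e-9, step_small), 10).tolist(),
                "h": wide}
    if family == "ewma":
        return {
            "lambda_w": np.round(
                np.arange(step_small, 1.0 + 1e-9, step_small), 10
            ).tolist(),
            "L": wide,
        }
    raise ParameterError(f"unknown chart family {family!r}")


def grid_evaluate(
    chart: _BaseControlChart,
    param_grid: dict,
    scenario_ids=TRAINING_IDS,
    n_replicates: int = 20,
    master_seed: int = 0,
    rate: MeasurementRate = DEFAULT_RATE,
) -> list[GridResult]:
    """Evaluate every node of ``param_grid`` on shared simulated replicates.

    ``chart`` is the template estimator (its rational-subgroup /
    reinitialization switches are kept); ``param_grid`` maps parameter names
    to candidate values, e.g. ``{"lambda_w": [...], "L": [...]}``.
    """
    try:
        grid = list(ParameterGrid(param_grid))
    except (ValueError, TypeError) as exc:
        raise ParameterError(f"invalid parameter grid: {exc}") from exc
    if not grid:
        raise ParameterError("empty parameter grid")
    if isinstance(scenario_ids, str):
        scenario_ids = [scenario_ids]

    # simulate once; every node reuses the same replicates
    datasets = {}
    for sid in scenario_ids:
        spec = catalog(sid)
        datasets[sid] = [
            generate_scenario(
                spec, rate=rate, rng=replicate_rng(master_seed, sid, rep),
                replicate=rep,
            )
            for rep in range(n_replicates)
        ]

    out = []
    for params in grid:
        est = clone(chart).set_params(**params)
        summaries = []
        for sid, series_list in datasets.items():
            results = [evaluate_series(s, est) for s in series_list]
            summaries.append(
                _aggregate(sid, results, len(series_list[0].truth_windows))
            )
        pooled = pooled_metrics(summaries)
        out.append(
            GridResult(
                params=tuple(sorted(params.items())),
                dr=pooled["DR"],
                arl=pooled["ARL"],
                fpr=pooled["FPR"],
            )
        )
    return out


_SECONDARY_ORDER = ("L", "h", "lambda_w", "k")  # deterministic final tie-break


def select_operating_point(
    grid: list[GridResult], policy=None, dr_tie_pp: float = 0.5
) -> GridResult:
    """Pick the operating point from a grid.

    Default policy: keep nodes whose DR is within ``dr_tie_pp`` percentage
    points of the best; among them minimize ARL; break remaining ties by
    minimal FPR, then by smaller limit width (L or h), then smaller weight
    (lambda or k).  A custom ``policy`` callable receives the grid and
    returns the chosen node.
    """
    if not grid:
        raise ParameterError("empty grid")
    if policy is not None:
        return policy(grid)

    def key_params(g: GridResult):
        p = g.params_dict
        return tuple(p.get(name, math.inf) for name in _SECONDARY_ORDER)

    best_dr = max(g.dr if g.dr is not None else -math.inf for g in grid)
    cand = [g for g in grid if g.dr is not None and g.dr >= best_dr - dr_tie_pp]
    if not cand:  # no scenario had transitions; fall back to FPR only
        return min(grid, key=lambda g: (g.fpr if g.fpr is not None else math.inf,
                                        key_params(g)))
    min_arl = min(g.arl if g.arl is not None else math.inf for g in cand)
    cand = [g for g in cand if (g.arl if g.arl is not None else math.inf) == min_arl]
    min_fpr = min(g.fpr if g.fpr is not None else math.inf for g in cand)
    cand = [g for g in cand if (g.fpr if g.fpr is not None else math.inf) == min_fpr]
    return min(cand, key=key_params)


def export_tradeoff(grid: list[GridResult]) -> pd.DataFrame:
    """Plot-ready table: one row per node with DR, ARL, FPR and parameters."""
    if not grid:
        raise ParameterError("empty grid")
    rows = []
    for g in grid:
        row = {"DR": g.dr, "ARL": g.arl, "FPR": g.fpr}
        row.update(g.params_dict)
        rows.append(row)
    return pd.DataFrame(rows)


def plot_tradeoff(grid: list[GridResult], path=None, highlight=()):
    """Scatter DR (x) vs ARL (y), colored by FPR; optionally mark named
    parameter combinations.  Requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = export_tradeoff(grid)
    fig, ax = plt.subplots(figsize=(6, 5))
    sc = ax.scatter(df["DR"], df["ARL"], c=df["FPR"], cmap="viridis", s=18)
    fig.colorbar(sc, ax=ax, label="false alarms / week")
    for label, params in highlight:
        match = [g for g in grid if dict(g.params) == dict(params)]
        if match:
            g = match[0]
            ax.scatter([g.dr], [g.arl], marker="x", s=90, color="red")
            ax.annotate(label, (g.dr, g.arl), textcoords="offset points",
                        xytext=(4, 4))
    ax.set_xlabel("Detection Rate [%]")
    ax.set_ylabel("Average Run Length [days]")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
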