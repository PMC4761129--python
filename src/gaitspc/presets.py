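"""Named chart configurations.

``rot-*`` presets use the textbook rule-of-thumb parameters for detecting
small shifts; ``optimized-*`` presets are the grid-search operating points of
the two best-performing variants: tabular CUSUM with reinitialization (TCRA)
and EWMA with rational subgroups and reinitialization (ERSRA).
"""

from __future__ import annotations

from .charts import ChartConfig
from .errors import ParameterError

__all__ = ["PRESETS", "preset_config", "preset_chart"]

PRESETS: dict[str, ChartConfig] = {
    "rot-tcusum": ChartConfig(family="tabular_cusum", k=0.5, h=3.0),
    "rot-ewma": ChartConfig(family="ewma", lambda_w=0.15, L=3.0),
    "optimized-tcra": ChartConfig(
        family="tabular_cusum", k=0.42, h=2.08, reinitialize=True
    ),
    "optimized-ersra": ChartConfig(
        family="ewma", lambda_w=0.18, L=2.0,
        rational_subgroups=True, reinitialize=True,
    ),
}


def preset_config(name: str) -> ChartConfig:
    try:
        return PRESETS[name]
    except KeyError:
        raise ParameterError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None


def preset_chart(name: str):
    """Unfitted estimator for a named preset."""
    return preset_config(name).build()
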