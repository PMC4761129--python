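"""Synthetic daily transfer-time series from log-logistic gait models.

A person's transfer times (seconds to cross a fixed zone at home) are modelled
as log-logistic: ``log(X)`` follows a logistic distribution with location
``mu`` (log-seconds) and scale ``sigma``, so the distribution median is
``exp(mu)``.  Four named parameterizations span the health states of
interest:

======  ========  ========  ==========================================
label   mu        sigma     meaning
======  ========  ========  ==========================================
SGM     1.504     0.155     stable gait (short times, low spread)
TGM1    1.504     0.206     theoretical: spread of UGM, level of SGM
TGM2    2.097     0.155     theoretical: level of UGM, spread of SGM
UGM     2.097     0.206     unstable gait (long times, high spread)
======  ========  ========  ==========================================

The number of measurements per day is Poisson (mean 5 by default, redrawn
when above a cap of twice the mean, matching observed 0-10 counts).  Health
transitions are emulated by linearly interpolating (mu, sigma) day by day
between two gait models over a transition period; a zero-length transition is
an abrupt switch.

Scenario catalogs cover a training set (12/28/44-week series with 4-week
transitions) and a 52-week validation set with transition lengths 0/4/8/12
weeks and single-parameter (mu-only / sigma-only) transitions.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import logit

from .charts import DailyRecord
from .errors import CatalogError, DataError, DomainError, FitError, ParameterError

__all__ = [
    "GaitModel",
    "MeasurementRate",
    "ScenarioSpec",
    "SimulatedSeries",
    "MODELS",
    "DEFAULT_RATE",
    "HALVED_RATE",
    "TRAINING_IDS",
    "VALIDATION_IDS",
    "sample_daily_count",
    "sample_transfer_times",
    "loglogistic_pdf",
    "fit_loglogistic",
    "interpolate_model",
    "generate_scenario",
    "catalog",
    "catalog_ids",
    "load_catalog_config",
    "replicate_rng",
]

DAYS_PER_WEEK = 7


# ---------------------------------------------------------------------------
# gait model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GaitModel:
    """Log-logistic transfer-time distribution (location mu, scale sigma)."""

    mu: float
    sigma: float
    label: str = "custom"

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ParameterError(f"sigma must be > 0, got {self.sigma}")

    @property
    def median(self) -> float:
        """Distribution median, exp(mu), in seconds."""
        return float(np.exp(self.mu))

    def pdf(self, x) -> np.ndarray | float:
        return loglogistic_pdf(x, self)

    def to_scipy(self):
        """Equivalent ``scipy.stats.fisk`` frozen distribution."""
        return stats.fisk(c=1.0 / self.sigma, scale=np.exp(self.mu))


MODELS: dict[str, GaitModel] = {
    "SGM": GaitModel(1.504, 0.155, "SGM"),
    "TGM1": GaitModel(1.504, 0.206, "TGM1"),
    "TGM2": GaitModel(2.097, 0.155, "TGM2"),
    "UGM": GaitModel(2.097, 0.206, "UGM"),
}


def loglogistic_pdf(x, model: GaitModel):
    """Log-logistic density ``(1/(sigma x)) e^z / (1 + e^z)^2`` with
    ``z = (log x - mu)/sigma``; defined for x > 0."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr <= 0):
        raise DomainError("transfer time must be > 0")
    z = (np.log(arr) - model.mu) / model.sigma
    # e^z/(1+e^z)^2 written through logistic.pdf for overflow safety
    dens = stats.logistic.pdf(z) / (model.sigma * arr)
    return float(dens) if np.isscalar(x) else dens


def sample_transfer_times(model: GaitModel, count: int, rng: np.random.Generator):
    """Draw ``count`` i.i.d. log-logistic transfer times (seconds).

    Inverse-CDF sampling: ``exp(mu + sigma * logit(U))``, U ~ Uniform(0, 1).
    """
    if count < 0:
        raise ParameterError("count must be >= 0")
    if count == 0:
        return np.empty(0, dtype=float)
    tiny = np.finfo(float).tiny
    u = rng.uniform(tiny, 1.0, size=count)
    return np.exp(model.mu + model.sigma * logit(u))


def fit_loglogistic(times: Sequence[float]) -> GaitModel:
    """Maximum-likelihood fit of (mu, sigma).

    Equivalent to a logistic-distribution MLE on log(times); delegated to
    ``scipy.stats.logistic.fit``.  Requires at least 10 strictly positive
    observations.
    """
    arr = np.asarray(times, dtype=float)
    if arr.size < 10:
        raise DataError(f"need >= 10 observations to fit, got {arr.size}")
    if np.any(arr <= 0):
        raise DomainError("all transfer times must be > 0")
    logs = np.log(arr)
    if np.ptp(logs) == 0:  # degenerate: all observations identical
        return GaitModel(mu=float(logs[0]), sigma=np.finfo(float).eps, label="fit")
    try:
        loc, scale = stats.logistic.fit(logs)
    except Exception as exc:  # pragma: no cover - scipy failure surface
        raise FitError(f"logistic MLE failed: {exc}") from exc
    if not (np.isfinite(loc) and np.isfinite(scale) and scale > 0):
        raise FitError(f"logistic MLE returned loc={loc}, scale={scale}")
    return GaitModel(mu=float(loc), sigma=float(scale), label="fit")


def interpolate_model(
    frm: GaitModel, to: GaitModel, day_in_transition: int, transition_length_days: int
) -> GaitModel:
    """Gait model on day ``day_in_transition`` (1-based) of a transition.

    Both parameters move linearly with fraction ``d / (length + 1)`` so every
    transition day is strictly between the endpoint models.
    """
    if transition_length_days < 1:
        raise ParameterError("transition_length_days must be >= 1")
    if not 1 <= day_in_transition <= transition_length_days:
        raise ParameterError(
            f"day_in_transition {day_in_transition} outside "
            f"1..{transition_length_days}"
        )
    f = day_in_transition / (transition_length_days + 1)
    return GaitModel(
        mu=frm.mu + f * (to.mu - frm.mu),
        sigma=frm.sigma + f * (to.sigma - frm.sigma),
        label=f"{frm.label}->{to.label}",
    )


# ---------------------------------------------------------------------------
# measurement rate
# ---------------------------------------------------------------------------

_AUTO = "auto"


@dataclass(frozen=True)
class MeasurementRate:
    """Per-day measurement count model: Poisson(poisson_mean), redrawn above
    ``cap`` (default twice the mean; None disables the cap)."""

    poisson_mean: float = 5.0
    cap: int | None | str = _AUTO

    def __post_init__(self) -> None:
        if self.poisson_mean < 0:
            raise ParameterError("poisson_mean must be >= 0")
        if self.cap == _AUTO:
            object.__setattr__(self, "cap", int(round(2 * self.poisson_mean)))
        if self.cap is not None and self.cap < 0:
            raise ParameterError("cap must be >= 0 or None")


DEFAULT_RATE = MeasurementRate(5.0)  # observed daily counts 0-10
HALVED_RATE = MeasurementRate(2.5)  # halved-rate variant, counts 0-5


def sample_daily_count(rate: MeasurementRate, rng: np.random.Generator) -> int:
    """Poisson draw of a day's measurement count, redrawn while above cap."""
    n = int(rng.poisson(rate.poisson_mean))
    if rate.cap is not None:
        while n > rate.cap:
            n = int(rng.poisson(rate.poisson_mean))
    return n


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioSpec:
    """Ordered gait-model segments joined by (possibly zero-length)
    transition periods, with derived ground-truth windows."""

    scenario_id: str
    segments: tuple[tuple[GaitModel, int], ...]  # (model, duration in days)
    transitions: tuple[int, ...]  # transition lengths in days

    def __post_init__(self) -> None:
        if len(self.transitions) != len(self.segments) - 1:
            raise ParameterError(
                "need exactly one transition length between consecutive segments"
            )
        if any(d <= 0 for _, d in self.segments):
            raise ParameterError("segment durations must be positive")
        if any(t < 0 for t in self.transitions):
            raise ParameterError("transition lengths must be >= 0")

    @property
    def total_days(self) -> int:
        return sum(d for _, d in self.segments) + sum(self.transitions)

    @property
    def truth_windows(self) -> tuple[tuple[int, int], ...]:
        """Ground-truth transition windows [start, end], 1-based inclusive.

        A zero-length (abrupt) transition gets a 4-day window starting on the
        first day of the new segment, within which an alarm counts as correct.
        """
        windows = []
        pos = 0
        for j, (seg, _) in enumerate(zip(self.segments, self.segments[1:])):
            pos += self.segments[j][1]
            tlen = self.transitions[j]
            if tlen > 0:
                windows.append((pos + 1, pos + tlen))
            else:
                windows.append((pos + 1, min(pos + 4, self.total_days)))
            pos += tlen
        return tuple(windows)

    def model_for_day(self, day: int) -> GaitModel:
        """Active (possibly interpolated) gait model on a 1-based day."""
        if not 1 <= day <= self.total_days:
            raise ParameterError(f"day {day} outside 1..{self.total_days}")
        pos = 0
        for j, (model, dur) in enumerate(self.segments):
            if day <= pos + dur:
                return model
            pos += dur
            if j < len(self.transitions):
                tlen = self.transitions[j]
                if day <= pos + tlen:
                    return interpolate_model(
                        model, self.segments[j + 1][0], day - pos, tlen
                    )
                pos += tlen
        raise AssertionError("unreachable: day accounting error")


@dataclass(frozen=True)
class SimulatedSeries:
    """One simulated replicate: daily records plus ground truth."""

    scenario_id: str
    records: tuple[DailyRecord, ...]
    truth_windows: tuple[tuple[int, int], ...]
    seed: int | None = None
    replicate: int | None = None

    @property
    def total_days(self) -> int:
        return len(self.records)


def generate_scenario(
    spec: ScenarioSpec,
    rate: MeasurementRate = DEFAULT_RATE,
    rng: np.random.Generator | None = None,
    *,
    seed: int | None = None,
    replicate: int | None = None,
) -> SimulatedSeries:
    """Simulate one replicate of a scenario.

    For each day 1..total_days the measurement count is drawn from ``rate``
    and that many transfer times are drawn from the day's active model.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    records = []
    for day in range(1, spec.total_days + 1):
        model = spec.model_for_day(day)
        n = sample_daily_count(rate, rng)
        times = sample_transfer_times(model, n, rng)
        records.append(DailyRecord(day=day, times=tuple(times)))
    return SimulatedSeries(
        scenario_id=spec.scenario_id,
        records=tuple(records),
        truth_windows=spec.truth_windows,
        seed=seed,
        replicate=replicate,
    )


def replicate_rng(master_seed: int, scenario_id: str, replicate: int):
    """Deterministic per-(scenario, replicate) RNG, shared across chart
    configurations so grid nodes see common random numbers."""
    tag = zlib.crc32(scenario_id.encode("utf-8"))
    return np.random.default_rng(
        np.random.SeedSequence((int(master_seed), tag, int(replicate)))
    )


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------

_W = DAYS_PER_WEEK * 1  # one week in days
_SEG = 12 * DAYS_PER_WEEK  # standard 12-week segment
_VALID_TOTAL = 52 * DAYS_PER_WEEK

# training scenarios: model sequence; all transitions 4 weeks
_TRAINING = {
    "Tr_S": ("SGM",),
    "Tr_U": ("UGM",),
    "Tr_SU": ("SGM", "UGM"),
    "Tr_US": ("UGM", "SGM"),
    "Tr_SUS": ("SGM", "UGM", "SGM"),
    "Tr_USU": ("UGM", "SGM", "UGM"),
}

# validation scenarios: model sequence and whether the transition length is
# selectable (0/4/8/12 weeks) or fixed at 4 weeks
_VALIDATION = {
    "V_S": (("SGM",), False),
    "V_U": (("UGM",), False),
    "V_SU": (("SGM", "UGM"), True),
    "V_ST1": (("SGM", "TGM1"), False),
    "V_ST2": (("SGM", "TGM2"), False),
    "V_US": (("UGM", "SGM"), True),
    "V_UT1": (("UGM", "TGM1"), False),
    "V_UT2": (("UGM", "TGM2"), False),
    "V_SUS": (("SGM", "UGM", "SGM"), True),
    "V_ST1S": (("SGM", "TGM1", "SGM"), False),
    "V_ST2S": (("SGM", "TGM2", "SGM"), False),
    "V_USU": (("UGM", "SGM", "UGM"), True),
    "V_UT1U": (("UGM", "TGM1", "UGM"), False),
    "V_UT2U": (("UGM", "TGM2", "UGM"), False),
}

TRAINING_IDS = tuple(_TRAINING)
VALIDATION_IDS = tuple(_VALIDATION)
_VARIANT_WEEKS = (0, 4, 8, 12)


def catalog_ids() -> list[str]:
    """All accepted catalog identifiers (variable-length scenarios also
    accept a ':<weeks>' suffix with weeks in {0, 4, 8, 12})."""
    ids = list(_TRAINING)
    for vid, (_, variable) in _VALIDATION.items():
        ids.append(vid)
        if variable:
            ids.extend(f"{vid}:{w}" for w in _VARIANT_WEEKS)
    return ids


def catalog(
    scenario_id: str, models: dict[str, GaitModel] | None = None
) -> ScenarioSpec:
    """Build the :class:`ScenarioSpec` for a catalog identifier.

    Training series use 12-week segments with 4-week transitions (totals 12,
    28 and 44 weeks).  Validation series total 52 weeks: the first segment is
    12 weeks, the inter-transition segment of two-trend scenarios is 12 weeks,
    and the final segment absorbs the remainder.  ``V_SU:8`` selects the
    8-week transition variant (default 4 weeks).
    """
    models = models or MODELS
    base, _, suffix = scenario_id.partition(":")
    tweeks = None
    if suffix:
        try:
            tweeks = int(suffix)
        except ValueError:
            raise CatalogError(
                f"bad transition-length suffix {suffix!r} in {scenario_id!r}"
            ) from None
        if tweeks not in _VARIANT_WEEKS:
            raise CatalogError(
                f"transition length {tweeks} weeks not in {_VARIANT_WEEKS}"
            )

    if base in _TRAINING:
        if tweeks not in (None, 4):
            raise CatalogError(f"training scenario {base} has fixed 4-week transitions")
        seq = _TRAINING[base]
        segments = tuple((models[m], _SEG) for m in seq)
        transitions = tuple(4 * _W for _ in seq[1:])
        return ScenarioSpec(scenario_id, segments, transitions)

    if base in _VALIDATION:
        seq, variable = _VALIDATION[base]
        if not variable and tweeks not in (None, 4):
            raise CatalogError(f"scenario {base} has a fixed 4-week transition")
        tdays = (tweeks if tweeks is not None else 4) * _W
        n_trans = len(seq) - 1
        if n_trans == 0:
            if tweeks is not None:
                raise CatalogError(f"scenario {base} has no transition")
            return ScenarioSpec(scenario_id, ((models[seq[0]], _VALID_TOTAL),), ())
        transitions = tuple(tdays for _ in range(n_trans))
        if n_trans == 1:
            last = _VALID_TOTAL - _SEG - tdays
            segments = ((models[seq[0]], _SEG), (models[seq[1]], last))
        else:
            last = _VALID_TOTAL - 2 * _SEG - 2 * tdays
            segments = (
                (models[seq[0]], _SEG),
                (models[seq[1]], _SEG),
                (models[seq[2]], last),
            )
        return ScenarioSpec(scenario_id, segments, transitions)

    raise CatalogError(
        f"unknown scenario {scenario_id!r}; valid ids: {', '.join(catalog_ids())}"
    )


def load_catalog_config(path):
    """Load a catalog override from a plain YAML mapping.

    Recognized keys (all optional):

    * ``models``: name -> {mu, sigma}; merged over the built-in models;
    * ``rate``: {poisson_mean, cap} -> a :class:`MeasurementRate`;
    * ``scenarios``: id -> {segments: [[model, weeks], ...],
      transitions: [weeks, ...]} -> custom :class:`ScenarioSpec` entries.

    Returns ``(scenarios, models, rate)`` where ``scenarios`` maps custom ids
    to specs and ``rate`` is None unless given.
    """
    import pathlib

    import yaml

    raw = yaml.safe_load(pathlib.Path(path).read_text()) or {}
    unknown = set(raw) - {"models", "rate", "scenarios"}
    if unknown:
        raise ParameterError(f"unknown catalog config keys: {sorted(unknown)}")
    models = dict(MODELS)
    for name, kv in (raw.get("models") or {}).items():
        models[name] = GaitModel(mu=float(kv["mu"]), sigma=float(kv["sigma"]),
                                 label=name)
    rate = None
    if "rate" in raw:
        rate = MeasurementRate(
            poisson_mean=float(raw["rate"].get("poisson_mean", 5.0)),
            cap=raw["rate"].get("cap", _AUTO),
        )
    scenarios = {}
    for sid, kv in (raw.get("scenarios") or {}).items():
        segments = tuple(
            (models[m], int(weeks) * DAYS_PER_WEEK) for m, weeks in kv["segments"]
        )
        transitions = tuple(
            int(w) * DAYS_PER_WEEK for w in kv.get("transitions", [])
        )
        scenarios[sid] = ScenarioSpec(sid, segments, transitions)
    return scenarios, models, rate
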