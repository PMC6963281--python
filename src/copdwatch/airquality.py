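"""Indoor air quality indices and the stringent-combination rule.

Two composite indices are computed from per-pollutant readings:

* a descending 0-100 index (higher is better) with categories
  good (100-76), normal (75-51), unhealthy (50-26), hazardous (25-0);
  the overall value is the *minimum* (worst) pollutant sub-index;
* an ascending EPA-AQI-style index (higher is worse) whose overall value
  is the *maximum* pollutant sub-index, with a 150-point health-protection
  threshold for respiratory patients.

Neither source publishes its sub-index formula, so both are implemented
as piecewise-linear interpolations anchored at the shipped per-pollutant
alarm limits: a concentration of zero scores 100 (descending) / 0
(ascending), the alarm limit scores 50 / 100, and twice the limit is the
hazardous node. Because the two scales run in opposite directions, "most
stringent" is implemented as an OR over their alarm conditions.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

SAAD_CATEGORIES = ("good", "normal", "unhealthy", "hazardous")
WANG_ALARM_POINTS = 150.0


@dataclass(frozen=True)
class PollutantReading:
    """One pollutant concentration in its canonical unit."""

    name: str
    concentration: float
    units: str | None = None

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError(f"{self.name}: concentration must be >= 0")


@dataclass(frozen=True)
class IaqiResult:
    saad_index: float  # 0-100, higher is better
    saad_category: str
    aqi_index: float  # >= 0, higher is worse
    alarm: bool
    worst_pollutant: str


@functools.lru_cache(maxsize=1)
def default_breakpoints() -> dict:
    text = resources.files("copdwatch.data").joinpath("iaqi_breakpoints.yaml").read_text()
    return yaml.safe_load(text)


def _limit_for(name: str, breakpoints: dict | None) -> tuple[float, float]:
    table = breakpoints if breakpoints is not None else default_breakpoints()
    limits = table["limits"]
    if name not in limits:
        raise KeyError(f"no breakpoints registered for pollutant {name!r}")
    entry = limits[name]
    if isinstance(entry, dict):
        limit = float(entry["limit"])
    else:
        limit = float(entry)
    return limit, float(table.get("hazardous_multiple", 2.0))


def saad_subindex(reading: PollutantReading, breakpoints: dict | None = None) -> float:
    """Descending 0-100 sub-index for one pollutant.

    Piecewise linear: 0 concentration -> 100, alarm limit -> 50
    (unhealthy boundary), hazardous node (2x limit) -> 25, 3x limit -> 0;
    clamped to [0, 100]; monotone non-increasing in concentration.
    """
    limit, haz_mult = _limit_for(reading.name, breakpoints)
    nodes = [0.0, limit, haz_mult * limit, (haz_mult + 1.0) * limit]
    scores = [100.0, 50.0, 25.0, 0.0]
    value = float(np.interp(reading.concentration, nodes, scores))
    return float(np.clip(value, 0.0, 100.0))


def wang_subindex(reading: PollutantReading, breakpoints: dict | None = None) -> float:
    """Ascending AQI-style sub-index: linear, alarm limit -> 100 points."""
    limit, _ = _limit_for(reading.name, breakpoints)
    return 100.0 * reading.concentration / limit


def categorize(saad_index: float) -> str:
    """Map a 0-100 descending index to its category.

    Boundary values belong to the better category's closed range:
    76 -> good, 51 -> normal, 26 -> unhealthy.
    """
    if not 0.0 <= saad_index <= 100.0:
        raise ValueError(f"index {saad_index} outside [0, 100]")
    if saad_index >= 76.0:
        return "good"
    if saad_index >= 51.0:
        return "normal"
    if saad_index >= 26.0:
        return "unhealthy"
    return "hazardous"


def iaqi(
    readings: list[PollutantReading] | tuple[PollutantReading, ...],
    breakpoints: dict | None = None,
) -> IaqiResult:
    """Combine pollutant readings into the stringent composite index.

    The descending index takes the worst (minimum) sub-index; the
    ascending index takes the worst (maximum); the alarm fires when the
    descending category is worse than "normal" OR the ascending index
    exceeds the 150-point protection threshold.
    """
    if not readings:
        raise ValueError("iaqi requires at least one pollutant reading")
    saad_scores = {r.name: saad_subindex(r, breakpoints) for r in readings}
    wang_scores = {r.name: wang_subindex(r, breakpoints) for r in readings}
    worst = min(saad_scores, key=saad_scores.__getitem__)
    saad = saad_scores[worst]
    aqi = max(wang_scores.values())
    category = categorize(saad)
    alarm = category in {"unhealthy", "hazardous"} or aqi > WANG_ALARM_POINTS
    return IaqiResult(
        saad_index=saad,
        saad_category=category,
        aqi_index=aqi,
        alarm=alarm,
        worst_pollutant=worst,
    )


IAQI_SUGGESTIONS: dict[str, str] = {
    "good": "Air quality is good; no action needed.",
    "normal": "Air quality is acceptable; keep ventilation steady.",
    "unhealthy": "Air quality is unhealthy for respiratory patients: ventilate, "
    "run filtration, and limit exertion indoors.",
    "hazardous": "Hazardous indoor air: leave the room or use supplemental "
    "filtration/oxygen and contact your care team.",
}
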