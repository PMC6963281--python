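"""Declarative rulepacks: representation, serialization and validation.

A :class:`Rule` is one safe-band or relational constraint over a monitored
parameter, together with the context it applies in (activity intensity,
location, season, daypart), an optional temporal exposure window, optional
guard conditions on other parameters, a dynamic-threshold schedule, the
severity groups it protects, and the suggestion text attached to its
alarms. A :class:`Rulepack` groups rules of one family; the four shipped
packs (``vitals``, ``pollution``, ``weather``, ``activity``) encode the
published alarm/constraint tables verbatim.

The printed relational notation "a < X > b" is interpreted as: alarm when
X leaves the closed band [a, b].
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Literal, Optional, Sequence

import yaml
from pydantic import BaseModel, Field, model_validator

from copdwatch.profiles import (
    ACTIVITY_CATEGORIES,
    VITAL_UNITS,
    Band,
    PatientProfile,
    SeverityGroup,
    activity_band,
    severity_group,
)

RULE_CATEGORIES = ("vital", "pollution", "weather", "activity")
LOCATIONS = ("bedroom", "living_room", "indoor", "outdoor")
SEASONS = ("winter", "spring", "summer", "autumn")
ALL_SEVERITIES = [s.value for s in SeverityGroup]

#: Registered unit per rule parameter (vitals plus environment/nutrition).
PARAMETER_UNITS: dict[str, str] = {
    **VITAL_UNITS,
    "spo2_6mwt": "%",
    "indoor_temperature": "degC",
    "indoor_humidity": "%",
    "indoor_pressure": "hPa",
    "outdoor_temperature": "degC",
    "outdoor_humidity": "%",
    "outdoor_pressure": "kPa",
    "wind_speed_mph": "mph",
    "rainfall_cm": "cm",
    "snowfall_cm": "cm",
    "co": "ppm",
    "hcho": "ppm",
    "voc": "ppm",
    "co2": "ppm",
    "pm10": "ug/m3",
    "pm2_5": "ug/m3",
    "pm10_mg": "mg/m3",
    "o3": "ppm",
    "bacteria": "CFU/m3",
    "fungi": "CFU/m3",
    "no2": "ppm",
    "so2": "ppm",
    "h2s": "ppm",
    "no": "ppm",
    "nox": "ppm",
    "trs": "ppm",
    "altitude": "m",
    "aerobic_training_min": "min",
    "sodium_mg": "mg",
    "fructose_g": "g",
    "glucose_mg": "mg",
    "calcium_mg": "mg",
    "vitamin_d_iu": "IU",
    "vitamin_c_mg": "mg",
    "vitamin_a_mcg": "mcg",
    "vitamin_e_iu": "IU",
    "vitamin_b12_mcg": "mcg",
    "iron_mg": "mg",
    "zinc_mg": "mg",
    "magnesium_mg": "mg",
    "carbohydrate_g": "g",
    "protein_g": "g",
    "fat_g": "g",
    "fiber_g": "g",
}


class RulepackError(ValueError):
    """Raised on structural problems; names the offending rule ids."""


class Limit(BaseModel):
    """Relational threshold: alarm when the value crosses ``value``."""

    direction: Literal["above", "below"]
    value: float


class ScheduleStep(BaseModel):
    """One node of a dynamic-threshold schedule."""

    exposure_minutes: float = Field(ge=0)
    value: float


class Guard(BaseModel):
    """Side condition on another parameter: satisfied when low < v < high."""

    parameter: str
    low: Optional[float] = None
    high: Optional[float] = None

    def satisfied(self, value: float) -> bool:
        if self.low is not None and not value > self.low:
            return False
        if self.high is not None and not value < self.high:
            return False
        return True


class RuleContext(BaseModel):
    """Context predicate; ``None`` fields match anything."""

    activity: Optional[str] = None
    location: Optional[str] = None
    season: Optional[str] = None
    daypart: Optional[str] = None

    @model_validator(mode="after")
    def _known(self) -> "RuleContext":
        if self.activity is not None and self.activity not in ACTIVITY_CATEGORIES:
            raise ValueError(f"unknown activity category {self.activity!r}")
        if self.location is not None and self.location not in LOCATIONS:
            raise ValueError(f"unknown location {self.location!r}")
        if self.season is not None and self.season not in SEASONS:
            raise ValueError(f"unknown season {self.season!r}")
        return self


class Rule(BaseModel):
    id: str
    category: Literal["vital", "pollution", "weather", "activity"]
    parameter: str
    context: RuleContext = Field(default_factory=RuleContext)
    band: Optional[Band] = None
    limit: Optional[Limit] = None
    schedule: Optional[list[ScheduleStep]] = None
    exposure_minutes: Optional[float] = Field(default=None, gt=0)
    window: Literal["continuous", "rolling"] = "continuous"
    severity: list[str] = Field(default_factory=lambda: list(ALL_SEVERITIES))
    guards: list[Guard] = Field(default_factory=list)
    suggestion: str = ""

    @model_validator(mode="after")
    def _well_formed(self) -> "Rule":
        if (self.band is None) == (self.limit is None):
            raise ValueError(f"rule {self.id}: exactly one of band/limit required")
        if self.schedule is not None:
            if self.limit is None:
                raise ValueError(f"rule {self.id}: schedule requires a relational limit")
            nodes = [s.exposure_minutes for s in self.schedule]
            if nodes != sorted(nodes):
                raise ValueError(f"rule {self.id}: schedule nodes must be ascending")
        unknown = set(self.severity) - set(ALL_SEVERITIES)
        if unknown:
            raise ValueError(f"rule {self.id}: unknown severity levels {sorted(unknown)}")
        return self

    def violates(self, value: float, effective: Optional[float] = None) -> bool:
        """True when ``value`` breaks this rule's band or limit.

        ``effective`` overrides the static limit value (dynamic thresholds).
        """
        if self.band is not None:
            return not self.band.contains(value)
        assert self.limit is not None
        threshold = self.limit.value if effective is None else effective
        if self.limit.direction == "above":
            return value > threshold
        return value < threshold

    def describe_bound(self, effective: Optional[float] = None) -> str:
        if self.band is not None:
            return f"[{self.band.low}, {self.band.high}]"
        assert self.limit is not None
        threshold = self.limit.value if effective is None else effective
        return f"{self.limit.direction} {threshold}"


class Rulepack(BaseModel):
    name: str
    version: str = "1.0"
    rules: list[Rule] = Field(default_factory=list)

    @model_validator(mode="after")
    def _validate_pack(self) -> "Rulepack":
        seen: set[str] = set()
        duplicates: list[str] = []
        unknown_params: list[str] = []
        for rule in self.rules:
            if rule.id in seen:
                duplicates.append(rule.id)
            seen.add(rule.id)
            if rule.parameter not in PARAMETER_UNITS:
                unknown_params.append(rule.id)
        problems = []
        if duplicates:
            problems.append(f"duplicate rule ids: {sorted(set(duplicates))}")
        if unknown_params:
            problems.append(f"unregistered parameters in rules: {sorted(unknown_params)}")
        if problems:
            raise ValueError("; ".join(problems))
        return self

    def by_id(self, rule_id: str) -> Rule:
        for rule in self.rules:
            if rule.id == rule_id:
                return rule
        raise KeyError(rule_id)


def load_rulepack(path: str | Path) -> Rulepack:
    """Load and validate a rulepack from a YAML file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = yaml.safe_load(path.read_text())
    try:
        return Rulepack(**data)
    except ValueError as exc:
        raise RulepackError(f"{path}: {exc}") from exc


def save_rulepack(pack: Rulepack, path: str | Path) -> None:
    """Serialize a rulepack to YAML (lossless round-trip)."""
    Path(path).write_text(
        yaml.safe_dump(pack.model_dump(exclude_none=True), sort_keys=False)
    )


def default_rulepack(name: str) -> Rulepack:
    """Load one of the shipped packs: vitals, pollution, weather, activity."""
    if name not in {"vitals", "pollution", "weather", "activity"}:
        raise KeyError(f"no shipped rulepack named {name!r}")
    text = resources.files("copdwatch.data.rules").joinpath(f"{name}.yaml").read_text()
    return Rulepack(**yaml.safe_load(text))


def default_rulepacks() -> list[Rulepack]:
    """All four shipped packs."""
    return [default_rulepack(n) for n in ("vitals", "pollution", "weather", "activity")]


def expand_rulepack(pack: Rulepack, profile: PatientProfile) -> Rulepack:
    """Specialize a pack to one patient.

    Vital-sign rules with an activity context get their band replaced by
    the profile's own band for that (vital, intensity) pair when one is
    available or derivable from the baselines; rules whose severity
    applicability excludes the profile's group are dropped. Idempotent:
    expanding an already-expanded pack changes nothing.
    """
    level = severity_group(profile).value
    out: list[Rule] = []
    for rule in pack.rules:
        if level not in rule.severity:
            continue
        new = rule
        if (
            rule.category == "vital"
            and rule.band is not None
            and rule.context.activity is not None
            and rule.parameter in VITAL_UNITS
        ):
            try:
                band = activity_band(profile, rule.parameter, rule.context.activity)
            except KeyError:
                band = None
            if band is not None:
                new = rule.model_copy(update={"band": band})
        out.append(new)
    return Rulepack(name=f"{pack.name}", version=pack.version, rules=out)


def expand_cohort(
    packs: Sequence[Rulepack], profiles: Sequence[PatientProfile]
) -> dict[str, list[Rulepack]]:
    """Expand every pack for every profile; returns per-patient pack lists."""
    return {p.id: [expand_rulepack(pack, p) for pack in packs] for p in profiles}
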