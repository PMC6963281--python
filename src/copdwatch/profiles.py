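"""COPD patient medical records: typed schema, I/O and severity grouping.

A :class:`PatientProfile` mirrors the information a pulmonology clinic
records at diagnosis: demographics, GOLD stage, comorbidities, medications,
baseline values for the monitored vital signs, and per-activity-intensity
safe bands obtained from exercise testing (incremental cycle test / 6MWT).

Profiles are the anchor of personalization: the rule engine specializes its
generic safe bands with the bands stored here, and the severity group
derived from a profile selects which protection rules apply.
"""

from __future__ import annotations

import csv
import json
import math
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from pydantic import BaseModel, Field, field_validator, model_validator

#: The monitored vital signs (plus FEV1, tracked like a vital).
VITALS: tuple[str, ...] = (
    "body_temperature",
    "dbp",
    "sbp",
    "heart_rate",
    "pao2",
    "spo2",
    "paco2",
    "vo2",
    "respiration_rate",
    "ph",
    "hco3",
    "fev1",
)

#: Canonical unit per vital. Units are fixed; no inference is performed.
VITAL_UNITS: dict[str, str] = {
    "body_temperature": "degC",
    "dbp": "mmHg",
    "sbp": "mmHg",
    "heart_rate": "bpm",
    "pao2": "mmHg",
    "spo2": "%",
    "paco2": "mmHg",
    "vo2": "mL/kg/min",
    "respiration_rate": "breaths/min",
    "ph": "pH",
    "hco3": "mmol/L",
    "fev1": "L",
}

#: Activity-intensity categories used for banded vitals.
ACTIVITY_CATEGORIES: tuple[str, ...] = ("sedentary", "light", "moderate", "vigorous")

COMORBIDITIES: frozenset[str] = frozenset(
    {"CHF", "HBP", "anemia", "IHD", "PH", "GERD", "asthma"}
)

GOLD_STAGES: tuple[str, ...] = ("I", "II", "III", "IV")


class Band(BaseModel):
    """A closed safe interval [low, high] in the parameter's own units."""

    low: float
    high: float

    @model_validator(mode="after")
    def _ordered(self) -> "Band":
        if not (math.isfinite(self.low) and math.isfinite(self.high)):
            raise ValueError("band bounds must be finite")
        if self.low > self.high:
            raise ValueError(f"band low {self.low} exceeds high {self.high}")
        return self

    def contains(self, value: float) -> bool:
        return self.low <= value <= self.high

    @property
    def mid(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def width(self) -> float:
        return self.high - self.low


class SeverityGroup(str, Enum):
    """Four levels of protection derived from the medical profile."""

    low = "low"
    moderate = "moderate"
    high = "high"
    very_high = "very_high"

    @property
    def rank(self) -> int:
        return ("low", "moderate", "high", "very_high").index(self.value)


# Additive offsets relative to the baseline used to synthesize a missing
# activity band.  The values reproduce the band geometry of a published
# example record (baseline HR 60 -> light 60-97, moderate 98-120,
# vigorous 121-130, and analogous rows for the other vitals).
_BAND_OFFSETS: dict[str, dict[str, tuple[float, float]]] = {
    "heart_rate": {
        "sedentary": (-6.0, 8.0),
        "light": (0.0, 37.0),
        "moderate": (38.0, 60.0),
        "vigorous": (61.0, 70.0),
    },
    "body_temperature": {
        "sedentary": (-0.5, 0.6),
        "light": (0.2, 0.9),
        "moderate": (0.5, 1.2),
        "vigorous": (1.0, 1.7),
    },
    "spo2": {
        "sedentary": (-1.0, 0.5),
        "light": (-0.8, 0.0),
        "moderate": (-2.9, -1.0),
        "vigorous": (-4.7, -3.4),
    },
    "pao2": {
        "sedentary": (-3.0, 3.0),
        "light": (-3.0, 4.0),
        "moderate": (5.0, 10.0),
        "vigorous": (11.0, 17.0),
    },
    "paco2": {
        "sedentary": (-2.0, 2.0),
        "light": (-1.0, 2.0),
        "moderate": (-5.0, 0.0),
        "vigorous": (-7.0, 0.0),
    },
    "dbp": {
        "sedentary": (-5.0, 3.0),
        "light": (-1.0, 2.0),
        "moderate": (3.0, 6.0),
        "vigorous": (7.0, 14.0),
    },
    "sbp": {
        "sedentary": (-9.0, 10.0),
        "light": (1.0, 20.0),
        "moderate": (21.0, 25.0),
        "vigorous": (26.0, 35.0),
    },
    "respiration_rate": {
        "sedentary": (-2.0, 2.0),
        "light": (0.0, 5.0),
        "moderate": (6.0, 16.0),
        "vigorous": (17.0, 36.0),
    },
    "vo2": {
        "sedentary": (-0.5, 0.5),
        "light": (0.0, 3.8),
        "moderate": (3.9, 6.8),
        "vigorous": (7.0, 9.3),
    },
    "ph": {
        "sedentary": (-0.05, 0.05),
        "light": (-0.08, 0.02),
        "moderate": (-0.12, 0.0),
        "vigorous": (-0.18, -0.02),
    },
    "hco3": {
        "sedentary": (-3.0, 3.0),
        "light": (-2.0, 4.0),
        "moderate": (-4.0, 2.0),
        "vigorous": (-5.0, 1.0),
    },
    "fev1": {
        "sedentary": (-0.15, 0.15),
        "light": (-0.2, 0.1),
        "moderate": (-0.3, 0.05),
        "vigorous": (-0.4, 0.0),
    },
}


class PatientProfile(BaseModel):
    """One patient medical record.

    ``baselines`` maps every monitored vital to its stable resting value;
    ``activity_bands`` maps ``(vital, category)`` keys (encoded as
    ``"vital|category"`` in serialized form) to safe :class:`Band` objects.
    Columns/keys that are not part of the typed schema (e.g. extended
    spirometry such as FEF25-75 or TLC) are preserved in ``extras``.
    """

    id: str
    age: int = Field(ge=18, le=110)
    gender: str
    height: float = Field(gt=50, lt=260, description="cm")
    weight: float = Field(gt=20, lt=350, description="kg")
    bmi: float = Field(gt=5, lt=90, description="kg/m2")
    smoker: bool = False
    gold_stage: str
    mmrc: int = Field(ge=0, le=4, default=1)
    comorbidities: set[str] = Field(default_factory=set)
    medications: set[str] = Field(default_factory=set)
    baselines: dict[str, float] = Field(default_factory=dict)
    activity_bands: dict[str, Band] = Field(default_factory=dict)
    extras: dict[str, str] = Field(default_factory=dict)

    @field_validator("gender")
    @classmethod
    def _gender(cls, v: str) -> str:
        v = v.strip().lower()
        if v not in {"male", "female"}:
            raise ValueError(f"gender must be male/female, got {v!r}")
        return v

    @field_validator("gold_stage")
    @classmethod
    def _stage(cls, v: str) -> str:
        v = v.strip().upper()
        if v not in GOLD_STAGES:
            raise ValueError(f"gold_stage must be one of {GOLD_STAGES}, got {v!r}")
        return v

    @field_validator("comorbidities")
    @classmethod
    def _comorb(cls, v: set[str]) -> set[str]:
        unknown = v - COMORBIDITIES
        if unknown:
            raise ValueError(f"unknown comorbidities: {sorted(unknown)}")
        return v

    @field_validator("baselines")
    @classmethod
    def _baselines(cls, v: dict[str, float]) -> dict[str, float]:
        for vital, value in v.items():
            if vital not in VITAL_UNITS:
                raise ValueError(f"unknown vital {vital!r} in baselines")
            if not math.isfinite(value):
                raise ValueError(f"baseline {vital} is not finite")
        return v

    @model_validator(mode="after")
    def _bmi_consistent(self) -> "PatientProfile":
        computed = self.weight / (self.height / 100.0) ** 2
        if abs(computed - self.bmi) > 0.5:
            raise ValueError(
                f"bmi {self.bmi} inconsistent with weight/height ({computed:.2f})"
            )
        return self

    @staticmethod
    def band_key(vital: str, category: str) -> str:
        return f"{vital}|{category}"

    def band(self, vital: str, category: str) -> Band | None:
        return self.activity_bands.get(self.band_key(vital, category))


def severity_group(profile: PatientProfile) -> SeverityGroup:
    """Classify a profile into one of the four levels of protection.

    Monotone in GOLD stage and in comorbidity count: a higher stage, or an
    added comorbidity, never yields a lower level.
    """
    n_comorb = len(profile.comorbidities)
    if profile.gold_stage == "IV":
        return SeverityGroup.very_high
    if profile.gold_stage == "III":
        return SeverityGroup.very_high if n_comorb >= 1 else SeverityGroup.high
    # GOLD I-II
    if n_comorb >= 1 or profile.age >= 65:
        return SeverityGroup.moderate
    return SeverityGroup.low


def synthesize_band(profile: PatientProfile, vital: str, category: str) -> Band:
    """Derive an activity band from the baseline using fixed offsets.

    The offsets reproduce the geometry of the published example record's
    per-exercise bands; the sedentary band always brackets the baseline.
    """
    if vital not in _BAND_OFFSETS:
        raise KeyError(f"no band offsets registered for vital {vital!r}")
    if vital not in profile.baselines:
        raise KeyError(f"profile {profile.id} has no baseline for {vital!r}")
    base = profile.baselines[vital]
    lo_off, hi_off = _BAND_OFFSETS[vital][category]
    return Band(low=base + lo_off, high=base + hi_off)


def activity_band(profile: PatientProfile, vital: str, category: str) -> Band:
    """Safe band for ``vital`` during an activity of the given intensity.

    Uses the profile's own measured band when available, otherwise
    synthesizes one from the baseline. Raises ``KeyError`` for unknown
    vitals or categories.
    """
    if vital not in VITAL_UNITS:
        raise KeyError(f"unknown vital {vital!r}")
    if category not in ACTIVITY_CATEGORIES:
        raise KeyError(f"unknown activity category {category!r}")
    band = profile.band(vital, category)
    if band is not None:
        return band
    return synthesize_band(profile, vital, category)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_MANDATORY = ("id", "age", "gender", "height", "weight", "bmi", "gold_stage")


class ProfileSchemaError(ValueError):
    """A mandatory field is missing or a value cannot be parsed."""


def _profile_to_flat(profile: PatientProfile) -> dict[str, str]:
    row: dict[str, str] = {
        "id": profile.id,
        "age": str(profile.age),
        "gender": profile.gender,
        "height": repr(profile.height),
        "weight": repr(profile.weight),
        "bmi": repr(profile.bmi),
        "smoker": "yes" if profile.smoker else "no",
        "gold_stage": profile.gold_stage,
        "mmrc": str(profile.mmrc),
        "comorbidities": ";".join(sorted(profile.comorbidities)),
        "medications": ";".join(sorted(profile.medications)),
    }
    for vital, value in profile.baselines.items():
        row[f"baseline_{vital}"] = repr(value)
    for key, band in profile.activity_bands.items():
        vital, category = key.split("|")
        row[f"band_{vital}_{category}"] = f"{band.low!r}-{band.high!r}"
    row.update(profile.extras)
    return row


def _flat_to_profile(row: Mapping[str, str], row_id: str) -> PatientProfile:
    for field in _MANDATORY:
        if field not in row or str(row[field]).strip() == "":
            raise ProfileSchemaError(f"row {row_id}: missing mandatory field {field!r}")
    kwargs: dict[str, object] = {}
    baselines: dict[str, float] = {}
    bands: dict[str, Band] = {}
    extras: dict[str, str] = {}
    for key, raw in row.items():
        value = str(raw).strip()
        if key in {"id", "gender", "gold_stage"}:
            kwargs[key] = value
        elif key in {"age", "mmrc"}:
            kwargs[key] = int(float(value)) if value else 0
        elif key in {"height", "weight", "bmi"}:
            try:
                kwargs[key] = float(value)
            except ValueError as exc:
                raise ProfileSchemaError(f"row {row_id}: non-numeric {key}={value!r}") from exc
        elif key == "smoker":
            kwargs[key] = value.lower() in {"yes", "true", "1"}
        elif key in {"comorbidities", "medications"}:
            kwargs[key] = {t for t in value.split(";") if t}
        elif key.startswith("baseline_"):
            vital = key[len("baseline_"):]
            if value:
                try:
                    baselines[vital] = float(value)
                except ValueError as exc:
                    raise ProfileSchemaError(
                        f"row {row_id}: non-numeric vital {vital}={value!r}"
                    ) from exc
        elif key.startswith("band_"):
            stem = key[len("band_"):]
            vital, _, category = stem.rpartition("_")
            if value:
                lo, _, hi = value.rpartition("-")
                # guard against negative lows encoded with a leading minus
                if lo.endswith("-"):
                    lo = lo[:-1]
                    hi = "-" + hi
                try:
                    bands[PatientProfile.band_key(vital, category)] = Band(
                        low=float(lo), high=float(hi)
                    )
                except ValueError as exc:
                    raise ProfileSchemaError(
                        f"row {row_id}: bad band {key}={value!r}"
                    ) from exc
        else:
            if value:
                extras[key] = value
    kwargs["baselines"] = baselines
    kwargs["activity_bands"] = bands
    kwargs["extras"] = extras
    return PatientProfile(**kwargs)


def load_profiles(path: str | Path, format: str | None = None) -> list[PatientProfile]:
    """Load validated patient profiles from a CSV or JSON file.

    CSV has one row per patient with snake_case column labels; banded
    fields are encoded ``"low-high"``. JSON is a list of flat objects with
    the same keys. Unknown columns are preserved in ``extras``.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format not in {"csv", "json"}:
        raise ValueError(f"format must be csv or json, got {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    rows: list[Mapping[str, str]]
    if format == "json":
        data = json.loads(path.read_text())
        if not isinstance(data, list):
            raise ProfileSchemaError("JSON profile file must contain a list")
        rows = data
    else:
        with path.open(newline="") as fh:
            rows = list(csv.DictReader(fh))
    return [_flat_to_profile(row, row_id=str(row.get("id", i))) for i, row in enumerate(rows)]


def write_profiles(
    profiles: Sequence[PatientProfile], path: str | Path, format: str | None = None
) -> None:
    """Write profiles to CSV or JSON (inverse of :func:`load_profiles`)."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    flats = [_profile_to_flat(p) for p in profiles]
    if format == "json":
        path.write_text(json.dumps(flats, indent=1))
        return
    fields: list[str] = []
    for flat in flats:
        for key in flat:
            if key not in fields:
                fields.append(key)
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        writer.writerows(flats)


def iter_band_checks(profiles: Iterable[PatientProfile]) -> Iterable[tuple[str, str, Band]]:
    """Yield (profile id, band key, band) for every stored activity band."""
    for profile in profiles:
        for key, band in profile.activity_bands.items():
            yield profile.id, key, band
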