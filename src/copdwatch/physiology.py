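"""Closed-form physiological and atmospheric relations.

The rules that protect a COPD patient outdoors lean on a small set of
published regressions and physical laws:

* the hypsometric (barometric) formula relating altitude to pressure,
* Dalton partial pressures of the fixed atmospheric gas fractions,
* a regression predicting arterial PaO2 at altitude from sea-level PaO2
  and FEV1,
* per-degree-Celsius shifts of heart rate and blood pressure outside a
  thermal comfort zone,
* the cold-weather decline of FEV1/FVC per degree of outdoor cooling,
* a stage/age/profile-conditioned expected resting heart rate.

All tabulated parameters ship as a versioned YAML data file
(``data/heart_rate_table.yaml``) and may be overridden by the caller.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass
from importlib import resources

import yaml

from copdwatch.profiles import PatientProfile

# Atmospheric constants
SEA_LEVEL_PRESSURE_MMHG = 760.0
HYPSOMETRIC_CONSTANT_M = 44330.76923
HYPSOMETRIC_EXPONENT = 5.255876
O2_FRACTION = 0.21
N2_FRACTION = 0.78
CO2_FRACTION = 0.00038

# Thermal comfort zone: cold effects accrue below 22 degC, hot effects
# above 27 degC; inside the zone all deltas are zero.
COLD_THRESHOLD_C = 22.0
HOT_THRESHOLD_C = 27.0
COLD_COEF = {"heart_rate": 0.063, "sbp": 0.129, "dbp": 0.065}  # per degC below
HOT_COEF = {"heart_rate": 0.133, "sbp": 0.605, "dbp": 0.128}  # per degC above

FEV1_COLD_SLOPE_ML_PER_C = 2.20
FVC_COLD_SLOPE_ML_PER_C = 3.64

# Hypertension-prevalence multiplier: +2% per 100 m of altitude, used for
# advisories only (never applied to vitals).
HYPERTENSION_PER_100M = 0.02


@dataclass(frozen=True)
class VitalDeltas:
    """Ambient-temperature-driven shifts of HR and blood pressure."""

    d_hr: float  # beats/min
    d_sbp: float  # mmHg
    d_dbp: float  # mmHg


@dataclass(frozen=True)
class AtmosphereState:
    """Pressure and gas partial pressures at a given altitude (mmHg, m)."""

    altitude: float
    pressure: float
    po2: float
    pn2: float
    pco2: float


def barometric_pressure(
    altitude: float, constant: float = HYPSOMETRIC_CONSTANT_M
) -> float:
    """Barometric pressure (mmHg) at ``altitude`` metres, 0..11,000 m.

    P = 760 * (1 - h/C)^5.255876. The default scale constant C reproduces
    the standard atmosphere (exactly 760 mmHg at sea level, ~670 mmHg at
    1050 m); strictly decreasing on its domain.
    """
    if not 0.0 <= altitude <= 11_000.0:
        raise ValueError(f"altitude {altitude} m outside [0, 11000]")
    return SEA_LEVEL_PRESSURE_MMHG * (1.0 - altitude / constant) ** HYPSOMETRIC_EXPONENT


def partial_pressures(pressure: float) -> dict[str, float]:
    """Partial pressures (mmHg) of N2, O2 and CO2 at total ``pressure``.

    Fixed dry-air fractions: 78% N2, 21% O2, 0.038% CO2. At 760 mmHg this
    gives 592.8 / 159.6 / 0.289 mmHg (593 / 160 when rounded).
    """
    if pressure <= 0:
        raise ValueError(f"pressure must be positive, got {pressure}")
    return {
        "pn2": N2_FRACTION * pressure,
        "po2": O2_FRACTION * pressure,
        "pco2": CO2_FRACTION * pressure,
    }


def atmosphere_at(altitude: float) -> AtmosphereState:
    """Full atmospheric state (pressure + partial pressures) at altitude."""
    pressure = barometric_pressure(altitude)
    gases = partial_pressures(pressure)
    return AtmosphereState(altitude=altitude, pressure=pressure, **gases)


def pao2_at_altitude(pao2_sea: float, fev1: float) -> float:
    """Predicted arterial PaO2 (mmHg) at high altitude.

    Regression on ground-level PaO2 and FEV1 (litres):
    PaO2_alt = 0.5196 * PaO2_sea + 11.856 * FEV1 - 1.76.
    Intended for pre-travel screening of patients with FEV1 < 1.5 L.
    """
    if pao2_sea < 0 or fev1 < 0:
        raise ValueError("pao2_sea and fev1 must be non-negative")
    return 0.5196 * pao2_sea + 11.856 * fev1 - 1.76


def temperature_vital_deltas(mean_temp: float) -> VitalDeltas:
    """HR/BP shifts (beats/min, mmHg) driven by ambient temperature.

    Piecewise linear with a dead zone between the cold threshold (22 degC)
    and the hot threshold (27 degC): each degree below 22 adds the cold
    coefficients, each degree above 27 adds the hot coefficients, and the
    deltas are zero inside the zone.
    """
    cold = max(0.0, COLD_THRESHOLD_C - mean_temp)
    hot = max(0.0, mean_temp - HOT_THRESHOLD_C)
    return VitalDeltas(
        d_hr=COLD_COEF["heart_rate"] * cold + HOT_COEF["heart_rate"] * hot,
        d_sbp=COLD_COEF["sbp"] * cold + HOT_COEF["sbp"] * hot,
        d_dbp=COLD_COEF["dbp"] * cold + HOT_COEF["dbp"] * hot,
    )


def fev1_cold_decline(t_warm: float, t_cold: float, slope: float = FEV1_COLD_SLOPE_ML_PER_C) -> float:
    """Expected FEV1 decline (mL) between a warm and a cold period.

    (t_warm - t_cold) * 2.20 mL/degC outdoors; use
    ``slope=FVC_COLD_SLOPE_ML_PER_C`` (3.64) for the FVC analogue.
    """
    if t_warm < t_cold:
        raise ValueError("t_warm must be >= t_cold")
    return (t_warm - t_cold) * slope


def hypertension_multiplier(altitude: float) -> float:
    """Reported-prevalence multiplier for hypertension at altitude.

    1 + 0.02 per 100 m; attached to advisories, never applied to vitals.
    """
    if altitude < 0:
        raise ValueError("altitude must be non-negative")
    return 1.0 + HYPERTENSION_PER_100M * (altitude / 100.0)


# ---------------------------------------------------------------------------
# Expected resting heart rate
# ---------------------------------------------------------------------------


@functools.lru_cache(maxsize=1)
def heart_rate_table() -> dict:
    """The shipped stage x age-decade HR reference table (parsed YAML)."""
    text = resources.files("copdwatch.data").joinpath("heart_rate_table.yaml").read_text()
    return yaml.safe_load(text)


def _decade_index(age: int, decades: list[int]) -> int:
    lo, hi = decades[0], decades[-1] + 10
    if age < lo or age > hi:
        warnings.warn(
            f"age {age} outside the reference range [{lo}, {hi}]; clamped",
            stacklevel=3,
        )
    age = min(max(age, lo), hi - 1)
    for i, edge in enumerate(decades):
        if age < edge + 10:
            return i
    return len(decades) - 1


def _hr_modifiers(profile: PatientProfile, table: dict) -> float:
    mods = table["modifiers"]
    total = 0.0
    if profile.smoker:
        total += mods["smoker"]
    if profile.bmi >= 30:
        total += mods["obese"]
    if any("inhaler" in m.lower() for m in profile.medications):
        total += mods["inhaler"]
    for comorbidity in ("CHF", "anemia", "PH", "asthma"):
        if comorbidity in profile.comorbidities:
            total += mods[comorbidity]
    return total


def expected_resting_hr(
    profile: PatientProfile, category: str = "resting", table: dict | None = None
) -> float:
    """Expected heart rate (beats/min) for a profile and activity category.

    ``category="resting"`` returns the stage x age-decade reference cell
    plus additive modifiers (smoker +6.6, obese +9, inhaler +7, CHF +9.6,
    anemia +7, PH +10, asthma +8) and a +3 offset for female patients.
    Exercise categories replace the cell with the stage-I exercise mean
    scaled by the profile's cell / stage-I-cell ratio, modifiers and
    gender offset still added. Non-decreasing in GOLD stage.
    """
    tbl = table if table is not None else heart_rate_table()
    decades: list[int] = tbl["decades"]
    idx = _decade_index(profile.age, decades)
    cell = float(tbl["stages"][profile.gold_stage]["mean"][idx])
    extra = _hr_modifiers(profile, tbl)
    if profile.gender == "female":
        extra += float(tbl["female_offset"])
    if category == "resting":
        return cell + extra
    if category not in tbl["exercise"]:
        raise KeyError(f"unknown activity category {category!r}")
    stage1 = float(tbl["stages"]["I"]["mean"][idx])
    scaled = float(tbl["exercise"][category]["mean"]) * (cell / stage1)
    return scaled + extra


def resting_hr_sd(profile: PatientProfile, category: str = "resting") -> float:
    """Reference spread (SD, beats/min) paired with :func:`expected_resting_hr`."""
    tbl = heart_rate_table()
    if category in tbl["exercise"]:
        return float(tbl["exercise"][category]["sd"])
    idx = _decade_index(profile.age, tbl["decades"])
    return float(tbl["stages"][profile.gold_stage]["sd"][idx])
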