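"""Synthetic cohort generation: activities, environment, vitals.

Three coupled generators reproduce the structure of a year-long
telemonitoring dataset at one-minute resolution:

* **Activities** — a first-order Markov chain over 18 activities of daily
  living, with six daypart-specific transition matrices (4-hour blocks
  starting at 06:00), per-activity duration and daily-frequency bounds,
  and an ICF-style physical-capacity filter that removes activities a
  patient cannot perform (GOLD I-II: all intensities; GOLD III: up to
  moderate; GOLD IV or mMRC >= 3: up to light).
* **Environment** — indoor and outdoor series (temperature, humidity,
  wind, precipitation, pressure, and the pollutant panel) generated by
  mean-reverting AR(1) processes around seasonal means. The defaults are
  chosen to be consistent with published sample readings from a cold
  Canadian climate and a monitored apartment.
* **Vitals** — profile-conditioned draws centred on the patient's own
  activity bands (resting heart rate centred on the stage/age reference),
  shifted by ambient-temperature and altitude physiology, with Gaussian
  noise truncated at +/-4 sigma and an optional anomaly-injection rate
  that produces out-of-band episodes (the evaluation ground truth).

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from copdwatch import physiology
from copdwatch.profiles import (
    ACTIVITY_CATEGORIES,
    VITALS,
    Band,
    PatientProfile,
    activity_band,
)

# ---------------------------------------------------------------------------
# Activities of daily living
# ---------------------------------------------------------------------------

#: activity -> (intensity category, typical location, duration bounds min,
#: max daily frequency)
ACTIVITY_INFO: dict[str, tuple[str, str, tuple[int, int], int]] = {
    "sleeping": ("sedentary", "bedroom", (240, 540), 3),
    "resting": ("sedentary", "living_room", (10, 60), 10),
    "watching_tv": ("sedentary", "living_room", (20, 120), 6),
    "reading": ("sedentary", "living_room", (10, 60), 5),
    "telephone_use": ("sedentary", "living_room", (3, 15), 8),
    "taking_medication": ("sedentary", "living_room", (2, 5), 4),
    "driving": ("sedentary", "outdoor", (15, 60), 4),
    "traveling": ("sedentary", "outdoor", (30, 120), 2),
    "eating": ("light", "living_room", (15, 45), 5),
    "dressing": ("light", "bedroom", (5, 15), 4),
    "washing": ("light", "indoor", (5, 25), 4),
    "toileting": ("light", "indoor", (3, 10), 10),
    "cooking": ("light", "indoor", (10, 45), 4),
    "walking": ("light", "outdoor", (10, 45), 6),
    "housekeeping": ("moderate", "indoor", (15, 60), 3),
    "laundry": ("moderate", "indoor", (10, 40), 2),
    "jogging": ("vigorous", "outdoor", (10, 40), 2),
    "running": ("vigorous", "outdoor", (10, 30), 2),
}

ACTIVITIES: tuple[str, ...] = tuple(ACTIVITY_INFO)
DAYPARTS: tuple[str, ...] = (
    "morning", "midday", "afternoon", "evening", "night", "late_night",
)

# Relative next-activity weights per daypart; rows of the transition
# matrices are these weights renormalized (with the current activity's own
# weight damped to discourage immediate repeats). The morning block gives
# commuting (driving) high probability and the afternoon block makes lunch
# (eating) dominant, matching the intended daily structure.
_DAYPART_WEIGHTS: dict[str, dict[str, float]] = {
    "morning": {
        "dressing": 2.0, "washing": 2.0, "eating": 2.5, "driving": 3.0,
        "toileting": 1.0, "taking_medication": 1.0, "walking": 1.0,
        "cooking": 1.0, "reading": 0.5, "telephone_use": 0.5, "resting": 0.5,
        "watching_tv": 0.5, "housekeeping": 0.5, "laundry": 0.3,
        "jogging": 0.5, "running": 0.3, "traveling": 0.5, "sleeping": 0.3,
    },
    "midday": {
        "housekeeping": 2.0, "laundry": 1.5, "walking": 2.0, "cooking": 1.5,
        "eating": 1.0, "resting": 1.0, "reading": 1.0, "telephone_use": 1.0,
        "toileting": 1.0, "watching_tv": 1.0, "driving": 1.0,
        "traveling": 0.5, "jogging": 0.7, "running": 0.4, "washing": 0.5,
        "dressing": 0.3, "taking_medication": 0.5, "sleeping": 0.2,
    },
    "afternoon": {
        "eating": 3.0, "resting": 1.5, "walking": 1.5, "watching_tv": 1.5,
        "reading": 1.0, "telephone_use": 1.0, "toileting": 1.0,
        "cooking": 1.0, "housekeeping": 0.7, "laundry": 0.5, "driving": 1.0,
        "traveling": 0.5, "jogging": 0.5, "running": 0.3, "washing": 0.3,
        "dressing": 0.2, "taking_medication": 0.5, "sleeping": 0.3,
    },
    "evening": {
        "cooking": 2.0, "eating": 2.0, "watching_tv": 3.0, "reading": 1.5,
        "telephone_use": 1.0, "toileting": 1.0, "resting": 1.0,
        "walking": 0.7, "washing": 1.0, "dressing": 0.5,
        "taking_medication": 1.0, "housekeeping": 0.3, "laundry": 0.3,
        "driving": 0.5, "traveling": 0.3, "jogging": 0.2, "running": 0.1,
        "sleeping": 1.0,
    },
    "night": {
        "sleeping": 8.0, "toileting": 0.7, "reading": 0.5,
        "watching_tv": 0.5, "resting": 0.3,
    },
    "late_night": {
        "sleeping": 10.0, "toileting": 0.5, "resting": 0.2,
    },
}
_BACKGROUND_WEIGHT = 0.02  # floor so every matrix stays strictly positive


@dataclass(frozen=True)
class ActivityEvent:
    start_minute: int  # minute of day, 0..1439
    end_minute: int  # exclusive
    activity: str
    category: str
    location: str


@dataclass
class TransitionModel:
    """Daypart-specific Markov model over the 18 activities."""

    activities: tuple[str, ...] = ACTIVITIES
    dayparts: tuple[str, ...] = DAYPARTS
    matrices: dict[str, np.ndarray] = field(default_factory=dict)
    duration_bounds: dict[str, tuple[int, int]] = field(default_factory=dict)
    freq_bounds: dict[str, tuple[int, int]] = field(default_factory=dict)

    def validate(self) -> None:
        for label in self.dayparts:
            matrix = self.matrices[label]
            sums = matrix.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError(f"matrix {label!r} rows are not stochastic")
            if (matrix < 0).any():
                raise ValueError(f"matrix {label!r} has negative entries")
        mean_minutes = sum(
            self.freq_bounds[a][0] * np.mean(self.duration_bounds[a])
            for a in self.activities
        )
        if mean_minutes > 1440:
            raise ValueError("frequency/duration bounds are unsatisfiable in one day")


def daypart_of_minute(minute: int) -> str:
    """Daypart label for a minute of day; blocks of 4 h starting 06:00."""
    return DAYPARTS[((minute // 60 - 6) % 24) // 4]


def default_transition_model() -> TransitionModel:
    matrices: dict[str, np.ndarray] = {}
    n = len(ACTIVITIES)
    for label in DAYPARTS:
        weights = np.array(
            [_DAYPART_WEIGHTS[label].get(a, 0.0) + _BACKGROUND_WEIGHT for a in ACTIVITIES]
        )
        matrix = np.tile(weights, (n, 1))
        # damp self-transitions: durations are modelled explicitly
        np.fill_diagonal(matrix, matrix.diagonal() * 0.25)
        matrix /= matrix.sum(axis=1, keepdims=True)
        matrices[label] = matrix
    model = TransitionModel(
        matrices=matrices,
        duration_bounds={a: ACTIVITY_INFO[a][2] for a in ACTIVITIES},
        freq_bounds={a: (0, ACTIVITY_INFO[a][3]) for a in ACTIVITIES},
    )
    model.validate()
    return model


def icf_capacity(profile: PatientProfile) -> str:
    """Highest activity intensity the profile can perform (ICF-style)."""
    if profile.gold_stage == "IV" or profile.mmrc >= 3:
        return "light"
    if profile.gold_stage == "III":
        return "moderate"
    return "vigorous"


def _allowed_mask(model: TransitionModel, capacity: str) -> np.ndarray:
    max_rank = ACTIVITY_CATEGORIES.index(capacity)
    return np.array(
        [ACTIVITY_CATEGORIES.index(ACTIVITY_INFO[a][0]) <= max_rank for a in model.activities]
    )


def generate_activity_day(
    model: TransitionModel,
    profile: PatientProfile,
    seed: int | np.random.Generator,
) -> list[ActivityEvent]:
    """One day of activity events tiling exactly 1440 minutes.

    Activities beyond the profile's ICF capacity never appear; daily
    frequencies respect the model's upper bounds; identical seeds yield
    identical sequences.
    """
    model.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    allowed = _allowed_mask(model, icf_capacity(profile))
    if not allowed.any():
        raise ValueError("capacity filter excludes every activity")
    index = {a: i for i, a in enumerate(model.activities)}
    counts = {a: 0 for a in model.activities}
    events: list[ActivityEvent] = []
    t = 0
    current = "sleeping"  # days start at midnight, asleep
    while t < 1440:
        lo, hi = model.duration_bounds[current]
        duration = int(rng.integers(lo, hi + 1))
        end = min(t + duration, 1440)
        cat, loc, _, _ = ACTIVITY_INFO[current]
        events.append(ActivityEvent(t, end, current, cat, loc))
        counts[current] += 1
        t = end
        if t >= 1440:
            break
        row = model.matrices[daypart_of_minute(t)][index[current]].copy()
        row[~allowed] = 0.0
        for a, cnt in counts.items():
            if cnt >= model.freq_bounds[a][1]:
                row[index[a]] = 0.0
        if row.sum() <= 0:  # everything capped: fall back to resting/sleeping
            row = np.zeros_like(row)
            row[index["sleeping"]] = 1.0
        row /= row.sum()
        current = model.activities[int(rng.choice(len(row), p=row))]
    assert events[-1].end_minute == 1440
    return events


# ---------------------------------------------------------------------------
# Environment
# ---------------------------------------------------------------------------

#: field -> (annual mean, seasonal amplitude, stationary SD, clip_low, clip_high)
DEFAULT_SEASON_PROFILE: dict[str, tuple[float, float, float, float | None, float | None]] = {
    "outdoor_temperature": (8.0, 14.0, 3.0, None, None),
    "outdoor_humidity": (70.0, 8.0, 5.0, 5.0, 100.0),
    "wind_speed": (1.0, 0.3, 0.35, 0.0, None),  # m/s
    "wind_direction": (180.0, 0.0, 60.0, 0.0, 360.0),
    "precipitation": (0.3, 0.1, 0.07, 0.0, None),  # mm
    "outdoor_pressure": (101.6, 0.4, 0.3, None, None),  # kPa
    "aqhi": (2.5, 0.5, 0.4, 0.0, None),
    "co": (0.14, 0.03, 0.02, 0.0, None),
    "h2s": (0.25, 0.05, 0.05, 0.0, None),
    "no": (0.5, 0.1, 0.1, 0.0, None),
    "no2": (1.5, 0.3, 0.3, 0.0, None),
    "nox": (2.0, 0.4, 0.4, 0.0, None),
    "o3": (34.0, 5.0, 3.0, 0.0, None),
    "pm10": (26.0, 6.0, 4.0, 0.0, None),
    "pm2_5": (6.0, 1.5, 1.2, 0.0, None),
    "so2": (0.12, 0.02, 0.02, 0.0, None),
    "trs": (0.5, 0.1, 0.1, 0.0, None),
    "indoor_temperature": (21.5, 0.8, 0.8, None, None),
    "indoor_humidity": (45.0, 6.0, 4.0, 5.0, 95.0),
    "indoor_pressure": (1015.5, 1.0, 0.8, None, None),  # hPa
    "co2": (695.0, 40.0, 40.0, 350.0, None),
    "voc": (0.062, 0.01, 0.008, 0.0, None),
    "indoor_pm2_5": (8.0, 1.5, 1.5, 0.0, None),
    "indoor_pm10": (9.5, 2.0, 1.8, 0.0, None),
}

_AR_PHI = 0.98  # per-minute persistence of the mean-reverting noise


def generate_environment(
    days: int,
    season_profile: Optional[dict] = None,
    seed: int | np.random.Generator = 0,
    start: str = "2021-01-01",
) -> pd.DataFrame:
    """Per-minute indoor + outdoor environmental series.

    Every field follows ``x_t = mu(day) + AR1 noise``, with a sinusoidal
    seasonal mean (coldest around mid-January) and stationary noise SD as
    configured. Wind speed is also exported in mph and precipitation split
    into rainfall/snowfall (cm) by the sign of the outdoor temperature.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    profile_cfg = season_profile or DEFAULT_SEASON_PROFILE
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = days * 1440
    idx = pd.date_range(start=start, periods=n, freq="min")
    doy = idx.dayofyear.to_numpy()
    frame: dict[str, np.ndarray] = {}
    seasonal_shape = -np.cos(2.0 * np.pi * (doy - 15) / 365.0)
    for name, (base, amp, sd, lo, hi) in profile_cfg.items():
        mu = base + amp * seasonal_shape
        sigma = sd * np.sqrt(1.0 - _AR_PHI**2)
        eps = rng.standard_normal(n) * sigma
        noise = lfilter([1.0], [1.0, -_AR_PHI], eps)
        x = mu + noise
        if lo is not None or hi is not None:
            x = np.clip(x, lo, hi)
        frame[name] = x
    df = pd.DataFrame(frame, index=idx)
    df.index.name = "timestamp"
    df["wind_speed_mph"] = df["wind_speed"] * 2.23694
    rain = df["outdoor_temperature"] > 0
    df["rainfall_cm"] = np.where(rain, df["precipitation"] / 10.0, 0.0)
    df["snowfall_cm"] = np.where(rain, 0.0, df["precipitation"])
    return df


# ---------------------------------------------------------------------------
# Vitals
# ---------------------------------------------------------------------------

_HR_ALT_BPM_PER_M = 1.0 / 600.0  # HR rises, SpO2 falls, with altitude
_SPO2_ALT_PCT_PER_M = 1.0 / 500.0


def _vital_center_sd(
    profile: PatientProfile, vital: str, category: str
) -> tuple[float, float]:
    band_cat = "sedentary" if category == "resting" else category
    band: Band = activity_band(profile, vital, band_cat)
    if vital == "heart_rate":
        if category in ("resting", "sedentary"):
            center = physiology.expected_resting_hr(profile, "resting")
        else:
            center = band.mid
        sd = physiology.resting_hr_sd(
            profile, "resting" if category == "resting" else band_cat
        )
        return center, sd
    return band.mid, max(band.width / 4.0, 1e-3)


def generate_vitals(
    profile: PatientProfile,
    category: str,
    env: Optional[dict] = None,
    seed: int | np.random.Generator = 0,
    n: int = 1,
    anomaly_rate: float = 0.0,
) -> pd.DataFrame:
    """Draw ``n`` per-minute vitals samples for one activity category.

    Each vital is Gaussian around its profile band midpoint (resting heart
    rate around the stage/age reference value) with noise truncated at
    +/-4 sigma. ``env`` may carry ``outdoor_temperature`` (degC; shifts
    HR/SBP/DBP through the thermal-response coefficients) and ``altitude``
    (m; lowers SpO2 and raises HR). With ``anomaly_rate`` > 0, a random
    subset of samples has one vital pushed outside its safe band; the
    ``anomaly`` and ``hospital`` columns flag them (``hospital`` marks
    excursions beyond one full band width: the evaluation ground truth).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    env = env or {}
    deltas = physiology.temperature_vital_deltas(env["outdoor_temperature"]) \
        if "outdoor_temperature" in env else None
    altitude = float(env.get("altitude", 0.0))
    out: dict[str, np.ndarray] = {}
    for vital in VITALS:
        center, sd = _vital_center_sd(profile, vital, category)
        if deltas is not None:
            if vital == "heart_rate":
                center += deltas.d_hr
            elif vital == "sbp":
                center += deltas.d_sbp
            elif vital == "dbp":
                center += deltas.d_dbp
        if altitude > 0:
            if vital == "heart_rate":
                center += altitude * _HR_ALT_BPM_PER_M
            elif vital == "spo2":
                center -= altitude * _SPO2_ALT_PCT_PER_M
        noise = np.clip(rng.standard_normal(n), -4.0, 4.0) * sd
        out[vital] = center + noise
    anomaly = rng.random(n) < anomaly_rate
    hospital = np.zeros(n, dtype=bool)
    if anomaly.any():
        band_cat = "sedentary" if category == "resting" else category
        idx = np.flatnonzero(anomaly)
        which = rng.integers(0, len(VITALS), size=len(idx))
        magnitude = rng.uniform(0.3, 2.0, size=len(idx))  # band widths past the edge
        direction = rng.choice([-1.0, 1.0], size=len(idx))
        for j, (i, w) in enumerate(zip(idx, which)):
            vital = VITALS[w]
            band = activity_band(profile, vital, band_cat)
            width = max(band.width, 1e-3)
            if direction[j] > 0:
                out[vital][i] = band.high + magnitude[j] * width
            else:
                out[vital][i] = band.low - magnitude[j] * width
            hospital[i] = magnitude[j] > 1.0
    df = pd.DataFrame(out)
    df["anomaly"] = anomaly
    df["hospital"] = hospital
    return df


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

STAGE_PROBS = {"I": 0.30, "II": 0.30, "III": 0.25, "IV": 0.15}
_BASELINE_FEV1 = {"I": 2.8, "II": 2.1, "III": 1.3, "IV": 0.8}


def generate_profiles(n: int, seed: int | np.random.Generator = 0) -> list[PatientProfile]:
    """Sample ``n`` synthetic patient profiles spanning stages I-IV."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stages = list(STAGE_PROBS)
    probs = np.array(list(STAGE_PROBS.values()))
    profiles: list[PatientProfile] = []
    for i in range(n):
        stage = stages[int(rng.choice(4, p=probs))]
        stage_idx = stages.index(stage)
        age = int(rng.integers(40, 91))
        gender = "female" if rng.random() < 0.5 else "male"
        height = float(np.round(rng.normal(170 if gender == "male" else 160, 8), 1))
        height = float(np.clip(height, 140, 205))
        bmi = float(np.clip(rng.normal(26, 4), 17, 42))
        weight = float(np.round(bmi * (height / 100.0) ** 2, 1))
        bmi = round(weight / (height / 100.0) ** 2, 2)
        smoker = bool(rng.random() < 0.4)
        mmrc = int(np.clip(stage_idx + rng.integers(-1, 2), 0, 4))
        comorbidities = {
            c for c in ("CHF", "HBP", "anemia", "IHD", "PH", "GERD", "asthma")
            if rng.random() < 0.15
        }
        medications = {
            m for m, p in (("SABA", 0.5), ("LABA", 0.4), ("inhaler", 0.45))
            if rng.random() < p
        }
        baselines = {
            "heart_rate": float(np.round(rng.normal(72 + 3 * stage_idx, 6), 1)),
            "body_temperature": float(np.round(rng.normal(36.6, 0.2), 2)),
            "spo2": float(np.round(np.clip(rng.normal(97 - 1.2 * stage_idx, 0.7), 85, 99), 1)),
            "pao2": float(np.round(rng.normal(82 - 4 * stage_idx, 3), 1)),
            "paco2": float(np.round(rng.normal(38 + 1.5 * stage_idx, 2), 1)),
            "dbp": float(np.round(rng.normal(75, 5), 1)),
            "sbp": float(np.round(rng.normal(118, 8), 1)),
            "respiration_rate": float(np.round(rng.normal(14 + stage_idx, 1.5), 1)),
            "vo2": float(np.round(np.clip(rng.normal(2.5, 0.4), 1.0, 5.0), 2)),
            "ph": float(np.round(rng.normal(7.38, 0.02), 3)),
            "hco3": float(np.round(rng.normal(25, 2), 1)),
            "fev1": float(np.round(np.clip(
                rng.normal(_BASELINE_FEV1[stage], 0.15), 0.4, 4.0), 2)),
        }
        profile = PatientProfile(
            id=f"P{i:04d}",
            age=age,
            gender=gender,
            height=height,
            weight=weight,
            bmi=bmi,
            smoker=smoker,
            gold_stage=stage,
            mmrc=mmrc,
            comorbidities=comorbidities,
            medications=medications,
            baselines=baselines,
        )
        bands = {
            PatientProfile.band_key(v, c): activity_band(profile, v, c)
            for v in VITALS
            for c in ACTIVITY_CATEGORIES
        }
        profile.activity_bands.update(bands)
        profiles.append(profile)
    return profiles


@dataclass
class ObservationRecord:
    """One joined per-minute observation (engine input)."""

    timestamp: datetime
    activity: str
    activity_category: str
    location: str
    altitude: float
    environment: dict[str, float]
    vitals: dict[str, float]


@dataclass
class CohortDataset:
    profiles: list[PatientProfile]
    streams: dict[str, pd.DataFrame]  # patient id -> joined per-minute frame


_ENV_COLUMNS = list(DEFAULT_SEASON_PROFILE) + ["wind_speed_mph", "rainfall_cm", "snowfall_cm"]


def generate_patient_stream(
    profile: PatientProfile,
    days: int,
    seed: int | np.random.Generator,
    anomaly_rate: float = 0.002,
    start: str = "2021-01-01",
    model: Optional[TransitionModel] = None,
) -> pd.DataFrame:
    """Joined per-minute stream for one patient: activity + environment + vitals."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    model = model or default_transition_model()
    env = generate_environment(days, seed=rng, start=start)
    n = days * 1440
    activity = np.empty(n, dtype=object)
    category = np.empty(n, dtype=object)
    location = np.empty(n, dtype=object)
    for day in range(days):
        for ev in generate_activity_day(model, profile, rng):
            s, e = day * 1440 + ev.start_minute, day * 1440 + ev.end_minute
            activity[s:e] = ev.activity
            category[s:e] = ev.category
            location[s:e] = ev.location
    df = env.reset_index()
    df["activity"] = activity
    df["activity_category"] = category
    df["location"] = location
    df["altitude"] = 50.0
    # vitals drawn per category block, temperature shift applied to
    # outdoor minutes afterwards (vectorized)
    vit = pd.DataFrame(index=df.index, columns=list(VITALS), dtype=float)
    anomaly = np.zeros(n, dtype=bool)
    hospital = np.zeros(n, dtype=bool)
    for cat in ACTIVITY_CATEGORIES:
        mask = (df["activity_category"] == cat).to_numpy()
        k = int(mask.sum())
        if k == 0:
            continue
        draws = generate_vitals(profile, cat, seed=rng, n=k, anomaly_rate=anomaly_rate)
        for v in VITALS:
            vit.loc[mask, v] = draws[v].to_numpy()
        anomaly[mask] = draws["anomaly"].to_numpy()
        hospital[mask] = draws["hospital"].to_numpy()
    outdoor = (df["location"] == "outdoor").to_numpy()
    if outdoor.any():
        t = df.loc[outdoor, "outdoor_temperature"].to_numpy()
        cold = np.maximum(0.0, physiology.COLD_THRESHOLD_C - t)
        hot = np.maximum(0.0, t - physiology.HOT_THRESHOLD_C)
        vit.loc[outdoor, "heart_rate"] += (
            physiology.COLD_COEF["heart_rate"] * cold + physiology.HOT_COEF["heart_rate"] * hot
        )
        vit.loc[outdoor, "sbp"] += (
            physiology.COLD_COEF["sbp"] * cold + physiology.HOT_COEF["sbp"] * hot
        )
        vit.loc[outdoor, "dbp"] += (
            physiology.COLD_COEF["dbp"] * cold + physiology.HOT_COEF["dbp"] * hot
        )
    for v in VITALS:
        df[v] = vit[v]
    df["anomaly"] = anomaly
    df["hospital"] = hospital
    return df


def generate_cohort(
    n_patients: int,
    days: int,
    seed: int = 0,
    anomaly_rate: float = 0.002,
    start: str = "2021-01-01",
) -> CohortDataset:
    """Full synthetic cohort: profiles plus one joined stream per patient."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if days < 1:
        raise ValueError("days must be >= 1")
    seq = np.random.SeedSequence(seed)
    profile_seed, *patient_seeds = seq.spawn(n_patients + 1)
    profiles = generate_profiles(n_patients, np.random.default_rng(profile_seed))
    streams = {
        p.id: generate_patient_stream(
            p, days, np.random.default_rng(s), anomaly_rate=anomaly_rate, start=start
        )
        for p, s in zip(profiles, patient_seeds)
    }
    return CohortDataset(profiles=profiles, streams=streams)


def iter_records(stream: pd.DataFrame) -> Iterator[ObservationRecord]:
    """Yield engine-ready records from a joined per-minute frame."""
    env_cols = [c for c in _ENV_COLUMNS if c in stream.columns]
    vital_cols = [v for v in VITALS if v in stream.columns]
    env_idx = [stream.columns.get_loc(c) for c in env_cols]
    vit_idx = [stream.columns.get_loc(c) for c in vital_cols]
    ts_i = stream.columns.get_loc("timestamp")
    act_i = stream.columns.get_loc("activity")
    cat_i = stream.columns.get_loc("activity_category")
    loc_i = stream.columns.get_loc("location")
    alt_i = stream.columns.get_loc("altitude") if "altitude" in stream.columns else None
    for row in stream.itertuples(index=False, name=None):
        yield ObservationRecord(
            timestamp=row[ts_i].to_pydatetime() if hasattr(row[ts_i], "to_pydatetime") else row[ts_i],
            activity=row[act_i],
            activity_category=row[cat_i],
            location=row[loc_i],
            altitude=row[alt_i] if alt_i is not None else 0.0,
            environment={c: row[i] for c, i in zip(env_cols, env_idx)},
            vitals={v: row[i] for v, i in zip(vital_cols, vit_idx)},
        )
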