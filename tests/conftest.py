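from __future__ import annotations

import pytest

from copdwatch.profiles import Band, PatientProfile


@pytest.fixture
def example_profile() -> PatientProfile:
    """A GOLD I patient mirroring a published example record.

    Age 51 male, BMI 23, GERD, baseline PaO2 78 mmHg, FEV1 1.73 L, with
    measured per-exercise bands (baseline HR 60 -> light 60-97 etc.).
    """
    profile = PatientProfile(
        id="example",
        age=51,
        gender="male",
        height=178,
        weight=72.9,
        bmi=23.0,
        smoker=False,
        gold_stage="I",
        mmrc=2,
        comorbidities={"GERD"},
        medications={"SABA", "LABA"},
        baselines={
            "heart_rate": 60.0,
            "body_temperature": 36.39,
            "spo2": 96.01,
            "pao2": 78.0,
            "paco2": 39.0,
            "dbp": 75.9,
            "sbp": 120.0,
            "respiration_rate": 14.0,
            "vo2": 2.53,
            "ph": 7.3,
            "hco3": 25.0,
            "fev1": 1.73,
        },
    )
    measured = {
        ("heart_rate", "light"): Band(low=60, high=97),
        ("heart_rate", "moderate"): Band(low=98, high=120),
        ("heart_rate", "vigorous"): Band(low=121, high=130),
        ("spo2", "light"): Band(low=95.21, high=96.01),
        ("spo2", "moderate"): Band(low=93.10, high=95.0),
        ("spo2", "vigorous"): Band(low=91.30, high=92.6),
        ("pao2", "light"): Band(low=75, high=82),
        ("pao2", "moderate"): Band(low=83, high=88),
        ("pao2", "vigorous"): Band(low=89, high=95),
        ("paco2", "light"): Band(low=38, high=41),
        ("paco2", "moderate"): Band(low=34, high=39),
        ("paco2", "vigorous"): Band(low=32, high=39),
        ("dbp", "light"): Band(low=75, high=78),
        ("dbp", "moderate"): Band(low=79, high=82),
        ("dbp", "vigorous"): Band(low=83, high=90),
        ("sbp", "light"): Band(low=121, high=140),
        ("sbp", "moderate"): Band(low=141, high=145),
        ("sbp", "vigorous"): Band(low=146, high=155),
        ("respiration_rate", "light"): Band(low=14, high=19),
        ("respiration_rate", "moderate"): Band(low=20, high=30),
        ("respiration_rate", "vigorous"): Band(low=31, high=50),
        ("vo2", "light"): Band(low=2.5, high=6.34),
        ("vo2", "moderate"): Band(low=6.4, high=9.36),
        ("vo2", "vigorous"): Band(low=9.5, high=11.79),
    }
    profile.activity_bands.update(
        {PatientProfile.band_key(v, c): b for (v, c), b in measured.items()}
    )
    return profile


def make_plain_profile(
    stage: str = "I",
    age: int = 45,
    gender: str = "male",
    smoker: bool = False,
    comorbidities: set[str] | None = None,
    medications: set[str] | None = None,
    bmi: float = 25.0,
    mmrc: int = 1,
) -> PatientProfile:
    """A minimal valid profile with standard baselines and no modifiers."""
    height = 175.0
    weight = round(bmi * (height / 100.0) ** 2, 1)
    return PatientProfile(
        id=f"plain-{stage}-{age}",
        age=age,
        gender=gender,
        height=height,
        weight=weight,
        bmi=round(weight / (height / 100.0) ** 2, 2),
        smoker=smoker,
        gold_stage=stage,
        mmrc=mmrc,
        comorbidities=comorbidities or set(),
        medications=medications or set(),
        baselines={
            "heart_rate": 72.0,
            "body_temperature": 36.6,
            "spo2": 95.0,
            "pao2": 78.0,
            "paco2": 40.0,
            "dbp": 75.0,
            "sbp": 118.0,
            "respiration_rate": 15.0,
            "vo2": 2.5,
            "ph": 7.38,
            "hco3": 25.0,
            "fev1": 1.4,
        },
    )


@pytest.fixture
def plain_profile() -> PatientProfile:
    return make_plain_profile()
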