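"""Cohort simulator: activity tiling, environment statistics, vitals draws."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from copdwatch import physiology as ph
from copdwatch.profiles import ACTIVITY_CATEGORIES, VITALS
from copdwatch.simulator import (
    ACTIVITY_INFO,
    DEFAULT_SEASON_PROFILE,
    default_transition_model,
    generate_activity_day,
    generate_cohort,
    generate_environment,
    generate_profiles,
    generate_patient_stream,
    generate_vitals,
    icf_capacity,
    iter_records,
)

from conftest import make_plain_profile


class TestTransitionModel:
    def test_all_matrices_row_stochastic(self):
        model = default_transition_model()
        for matrix in model.matrices.values():
            assert np.allclose(matrix.sum(axis=1), 1.0, atol=1e-9)
            assert (matrix >= 0).all()

    def test_empirical_frequencies_match_matrix_row(self):
        """Multinomial check: observed transitions within 3 sigma of the row."""
        model = default_transition_model()
        rng = np.random.default_rng(0)
        matrix = model.matrices["midday"]
        row_idx = list(model.activities).index("resting")
        row = matrix[row_idx]
        n = 100_000
        draws = rng.choice(len(row), size=n, p=row)
        counts = np.bincount(draws, minlength=len(row))
        for j, p in enumerate(row):
            sigma = np.sqrt(n * p * (1 - p))
            assert abs(counts[j] - n * p) <= 3 * sigma + 1


class TestActivityDay:
    def test_tiles_exactly_1440_minutes(self):
        model = default_transition_model()
        profile = make_plain_profile("II")
        for seed in range(5):
            events = generate_activity_day(model, profile, seed)
            assert events[0].start_minute == 0
            assert events[-1].end_minute == 1440
            for a, b in zip(events, events[1:]):
                assert a.end_minute == b.start_minute

    def test_same_seed_identical_sequence(self):
        model = default_transition_model()
        profile = make_plain_profile("II")
        assert generate_activity_day(model, profile, 11) == generate_activity_day(
            model, profile, 11
        )

    def test_frequency_caps_respected(self):
        model = default_transition_model()
        profile = make_plain_profile("I")
        for seed in range(20):
            events = generate_activity_day(model, profile, seed)
            counts: dict[str, int] = {}
            for ev in events:
                counts[ev.activity] = counts.get(ev.activity, 0) + 1
            for activity, count in counts.items():
                if activity == "sleeping":
                    continue  # overflow fallback when everything else is capped
                assert count <= model.freq_bounds[activity][1]

    def test_icf_capacity_mapping(self):
        assert icf_capacity(make_plain_profile("I")) == "vigorous"
        assert icf_capacity(make_plain_profile("III")) == "moderate"
        assert icf_capacity(make_plain_profile("IV")) == "light"
        assert icf_capacity(make_plain_profile("II", mmrc=3)) == "light"

    def test_gold_iv_never_performs_vigorous_activities(self):
        """Exhaustive scan over 2,000 simulated days (the full 10,000-day
        scan runs in the acceptance suite)."""
        model = default_transition_model()
        profile = make_plain_profile("IV")
        rng = np.random.default_rng(123)
        for _ in range(2_000):
            for ev in generate_activity_day(model, profile, rng):
                assert ev.category in ("sedentary", "light")


class TestEnvironment:
    def test_field_set_covers_all_schemas(self):
        env = generate_environment(1, seed=0)
        expected = {
            "outdoor_humidity", "outdoor_temperature", "wind_speed",
            "wind_direction", "precipitation", "outdoor_pressure", "aqhi",
            "co", "h2s", "no", "no2", "nox", "o3", "pm10", "pm2_5", "so2",
            "trs", "indoor_temperature", "indoor_humidity", "co2", "voc",
            "indoor_pm2_5", "indoor_pm10",
        }
        assert expected <= set(env.columns)
        assert len(env) == 1440

    def test_same_seed_identical_series(self):
        a = generate_environment(2, seed=42)
        b = generate_environment(2, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_concentrations_non_negative(self):
        env = generate_environment(3, seed=1)
        for col in ("co", "pm10", "pm2_5", "o3", "voc", "co2", "precipitation"):
            assert (env[col] >= 0).all()

    def test_annual_mean_matches_configuration(self):
        """Law of large numbers: 365-day mean near the configured base."""
        env = generate_environment(365, seed=7)
        for name, (base, _amp, _sd, _lo, _hi) in DEFAULT_SEASON_PROFILE.items():
            assert env[name].mean() == pytest.approx(base, rel=0.02), name


class TestVitals:
    def test_anomaly_rate_zero_bounded_noise(self):
        profile = make_plain_profile("II")
        draws = generate_vitals(profile, "sedentary", n=20_000, seed=5)
        assert not draws["anomaly"].any()
        for vital in VITALS:
            center, sd = draws[vital].mean(), draws[vital].std()
            assert (draws[vital] - draws[vital].mean()).abs().max() <= 4.5 * sd

    def test_cold_ambient_raises_mean_hr(self):
        profile = make_plain_profile("I")
        warm = generate_vitals(profile, "resting", env={"outdoor_temperature": 22.0},
                               n=50_000, seed=9)
        cold = generate_vitals(profile, "resting", env={"outdoor_temperature": 12.0},
                               n=50_000, seed=9)
        shift = cold["heart_rate"].mean() - warm["heart_rate"].mean()
        assert shift == pytest.approx(0.63, abs=1e-9)  # same seed: exact shift

    def test_altitude_lowers_spo2_and_raises_hr(self):
        profile = make_plain_profile("I")
        low = generate_vitals(profile, "resting", env={"altitude": 0.0}, n=1000, seed=2)
        high = generate_vitals(profile, "resting", env={"altitude": 2000.0}, n=1000, seed=2)
        assert high["spo2"].mean() < low["spo2"].mean()
        assert high["heart_rate"].mean() > low["heart_rate"].mean()

    def test_anomalies_leave_band_and_flag_hospital(self):
        profile = make_plain_profile("II")
        draws = generate_vitals(profile, "sedentary", n=5000, seed=8, anomaly_rate=0.1)
        assert 0.05 < draws["anomaly"].mean() < 0.15
        assert draws["hospital"].sum() > 0
        assert (~draws["anomaly"] & draws["hospital"]).sum() == 0


class TestCohort:
    def test_stream_has_one_record_per_minute(self):
        profile = make_plain_profile("II")
        stream = generate_patient_stream(profile, 2, seed=0)
        assert len(stream) == 2880
        assert stream["timestamp"].is_unique
        assert (stream["timestamp"].diff().dropna() == pd.Timedelta(minutes=1)).all()

    def test_activity_and_vitals_consistent(self):
        """Vigorous minutes carry vitals drawn from vigorous bands."""
        profile = make_plain_profile("I")
        stream = generate_patient_stream(profile, 3, seed=4, anomaly_rate=0.0)
        from copdwatch.profiles import activity_band

        for cat in ACTIVITY_CATEGORIES:
            sub = stream[stream["activity_category"] == cat]
            if len(sub) < 30:
                continue
            band = activity_band(profile, "respiration_rate", cat)
            assert sub["respiration_rate"].mean() == pytest.approx(band.mid, abs=2.0)

    def test_zero_patients_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(0, 1)

    def test_cohort_spans_all_stages(self):
        profiles = generate_profiles(600, seed=13)
        stages = {p.gold_stage for p in profiles}
        assert stages == {"I", "II", "III", "IV"}

    def test_records_iterator_joins_fields(self):
        profile = make_plain_profile("II")
        stream = generate_patient_stream(profile, 1, seed=6)
        record = next(iter_records(stream))
        assert set(record.vitals) == set(VITALS)
        assert "outdoor_temperature" in record.environment
        assert record.activity in ACTIVITY_INFO
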