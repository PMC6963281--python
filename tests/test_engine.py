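"""Rule engine: exposure windows, dynamic thresholds, one-shot checks.

The core property test replays random 24 h single-parameter streams
through both the incremental engine and an independent O(n*W) oracle that
rescans the violation history at every minute.
"""

from __future__ import annotations

from datetime import datetime, timedelta

import numpy as np
import pytest

from copdwatch.engine import (
    Alarm,
    ExposureState,
    SequencingError,
    altitude_travel_check,
    dynamic_threshold,
    evaluate_minute,
    nutrition_check,
    ottawa_risk,
)
from copdwatch.profiles import Band
from copdwatch.rulepack import Rule, Rulepack, default_rulepack
from copdwatch.simulator import ObservationRecord

from conftest import make_plain_profile

T0 = datetime(2021, 1, 1, 0, 0)


def hr_record(i: int, hr: float, category: str = "light") -> ObservationRecord:
    return ObservationRecord(
        timestamp=T0 + timedelta(minutes=i),
        activity="walking",
        activity_category=category,
        location="outdoor",
        altitude=0.0,
        environment={},
        vitals={"heart_rate": hr},
    )


def indoor_record(i: int, env: dict) -> ObservationRecord:
    return ObservationRecord(
        timestamp=T0 + timedelta(minutes=i),
        activity="resting",
        activity_category="sedentary",
        location="living_room",
        altitude=0.0,
        environment=env,
        vitals={},
    )


class TestDynamicThreshold:
    def test_pm10_schedule_steps(self):
        rule = default_rulepack("pollution").by_id("pm10_dynamic_low")
        assert dynamic_threshold(rule, "low", 0) == pytest.approx(0.150)
        assert dynamic_threshold(rule, "low", 540) == pytest.approx(0.020)

    def test_static_rule_returns_printed_limit(self):
        rule = default_rulepack("pollution").by_id("co_1h")
        for exposure in (0, 100, 10_000):
            assert dynamic_threshold(rule, "low", exposure) == 2

    def test_limit_non_increasing_in_exposure(self):
        rule = default_rulepack("pollution").by_id("pm10_dynamic_low")
        limits = [dynamic_threshold(rule, "low", e) for e in range(0, 1500, 10)]
        assert all(a >= b for a, b in zip(limits, limits[1:]))


class TestEvaluateMinute:
    def test_immediate_vital_alarm(self, plain_profile):
        state = ExposureState()
        alarms, _ = evaluate_minute(
            plain_profile, hr_record(0, 120.0), state, [default_rulepack("vitals")]
        )
        assert [a.rule_id for a in alarms] == ["hr_light"]

    def test_co_fires_at_minute_61(self, plain_profile):
        pack = default_rulepack("pollution")
        state = ExposureState()
        fired_at = []
        for i in range(70):
            alarms, state = evaluate_minute(
                plain_profile, indoor_record(i, {"co": 2.5}), state, [pack]
            )
            fired_at += [i for a in alarms if a.rule_id == "co_1h"]
        assert fired_at == [60]  # the 61st consecutive violating minute

    def test_in_band_stream_emits_nothing_and_resets(self, plain_profile):
        state = ExposureState()
        for i in range(30):
            alarms, state = evaluate_minute(
                plain_profile, hr_record(i, 90.0), state, [default_rulepack("vitals")]
            )
            assert alarms == []
        assert all(v == 0 for v in state.continuous.values())

    def test_out_of_order_timestamp_rejected(self, plain_profile):
        state = ExposureState()
        evaluate_minute(plain_profile, hr_record(5, 90.0), state, [])
        with pytest.raises(SequencingError):
            evaluate_minute(plain_profile, hr_record(4, 90.0), state, [])

    def test_missing_value_freezes_accumulator(self, plain_profile):
        pack = default_rulepack("pollution")
        state = ExposureState()
        # 30 violating minutes, 5 missing, then 31 more: fires only after
        # the full continuous hour of *observed* violation
        fired = []
        for i in range(66):
            env = {} if 30 <= i < 35 else {"co": 2.5}
            alarms, state = evaluate_minute(plain_profile, indoor_record(i, env), state, [pack])
            fired += [i for a in alarms if a.rule_id == "co_1h"]
        assert fired == [65]

    def test_rearm_after_five_clear_minutes(self, plain_profile):
        pack = default_rulepack("vitals")
        values = [120.0] * 3 + [90.0] * 5 + [120.0] * 3
        state = ExposureState()
        fired = []
        for i, hr in enumerate(values):
            alarms, state = evaluate_minute(plain_profile, hr_record(i, hr), state, [pack])
            fired += [i for a in alarms if a.rule_id == "hr_light"]
        assert fired == [0, 8]

    def test_dynamic_pm10_tightens_after_8h_indoors(self):
        profile = make_plain_profile("I", age=50)  # low severity
        pack = default_rulepack("pollution")
        state = ExposureState()
        fired = []
        # indoor PM10 held at 0.050 mg/m3: safe against 0.150, unsafe
        # against the tightened 0.020 limit after 8 h of indoor exposure
        for i in range(500):
            alarms, state = evaluate_minute(
                profile, indoor_record(i, {"indoor_pm10": 50.0}), state, [pack]
            )
            fired += [i for a in alarms if a.rule_id == "pm10_dynamic_low"]
        assert fired == [479]  # exposure reaches 480 min at the 480th record

    def test_emitted_alarm_values_actually_violate(self, plain_profile):
        rng = np.random.default_rng(0)
        pack = default_rulepack("vitals")
        state = ExposureState()
        for i in range(300):
            record = hr_record(i, float(rng.uniform(50, 150)))
            alarms, state = evaluate_minute(plain_profile, record, state, [pack])
            for alarm in alarms:
                rule = pack.by_id(alarm.rule_id)
                assert rule.violates(alarm.value)


def oracle_alarm_minutes(
    violated: list[bool], window: int, rearm: int = 5
) -> list[int]:
    """Independent recomputation: rescan the history at every minute."""
    fired_minutes: list[int] = []
    suppressed = False
    for i, bad in enumerate(violated):
        if not bad:
            # re-armed once the trailing `rearm` minutes are all compliant
            if i + 1 >= rearm and not any(violated[i + 1 - rearm : i + 1]):
                suppressed = False
            continue
        run = 0
        j = i
        while j >= 0 and violated[j]:
            run += 1
            j -= 1
        if run - 1 >= window and not suppressed:
            fired_minutes.append(i)
            suppressed = True
    return fired_minutes


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    @pytest.mark.parametrize("window", [0, 15, 60])
    def test_matches_brute_force_on_random_day(self, seed, window):
        rng = np.random.default_rng(seed)
        profile = make_plain_profile()
        rule = Rule(
            id="test_hr",
            category="vital",
            parameter="heart_rate",
            band=Band(low=77, high=113),
            exposure_minutes=window or None,
        )
        pack = Rulepack(name="test", rules=[rule])
        # bursty violations: random walk crossing the band edges
        values = 95 + np.cumsum(rng.normal(0, 8, size=1440))
        violated = [bool(v < 77 or v > 113) for v in values]
        state = ExposureState()
        engine_fired = []
        for i, value in enumerate(values):
            alarms, state = evaluate_minute(profile, hr_record(i, float(value)), state, [pack])
            engine_fired += [i for a in alarms if a.rule_id == "test_hr"]
        assert engine_fired == oracle_alarm_minutes(violated, window)

    def test_determinism_same_stream_same_log(self):
        rng = np.random.default_rng(3)
        values = [float(v) for v in 95 + np.cumsum(rng.normal(0, 8, size=720))]
        profile = make_plain_profile()
        pack = default_rulepack("vitals")

        def run() -> list[tuple]:
            state = ExposureState()
            log = []
            for i, value in enumerate(values):
                alarms, state = evaluate_minute(profile, hr_record(i, value), state, [pack])
                log += [(a.timestamp, a.rule_id, a.value) for a in alarms]
            return log

        assert run() == run()


class TestAltitudeTravel:
    def test_altitude_above_1050_alarms(self, plain_profile):
        advisory = altitude_travel_check(plain_profile, 1200.0)
        assert advisory.alarm

    def test_low_pao2_means_cannot_travel(self, plain_profile):
        advisory = altitude_travel_check(plain_profile, 800.0, observed_pao2=49.0)
        assert advisory.alarm and not advisory.can_travel

    def test_sea_level_baseline_no_alarm(self, plain_profile):
        advisory = altitude_travel_check(plain_profile, 0.0)
        assert not advisory.alarm and advisory.can_travel

    def test_prediction_included_for_low_fev1(self, plain_profile):
        # baseline FEV1 1.4 L < 1.5 L: prediction from the regression
        advisory = altitude_travel_check(plain_profile, 500.0)
        assert advisory.predicted_pao2 == pytest.approx(
            0.5196 * 78.0 + 11.856 * 1.4 - 1.76
        )

    def test_six_mwt_lowers_spo2_threshold(self, plain_profile):
        assert altitude_travel_check(plain_profile, 0.0, observed_spo2=90.0).alarm
        assert not altitude_travel_check(
            plain_profile, 0.0, observed_spo2=90.0, six_mwt=True
        ).alarm


class TestNutrition:
    def test_fructose_over_limit_alarms(self):
        alarms = nutrition_check({"fructose_g": 30.0})
        assert [a.rule_id for a in alarms] == ["fructose_24h"]

    def test_fiber_inside_band_is_silent(self):
        assert nutrition_check({"fiber_g": 20.0}) == []

    def test_zero_intake_fires_only_minimum_rules(self):
        """Brute force at zero intake over every nutrient rule."""
        pack = default_rulepack("activity")
        nutrient_rules = [r for r in pack.rules if r.id.endswith("_24h")]
        totals = {r.parameter: 0.0 for r in nutrient_rules}
        fired = {a.rule_id for a in nutrition_check(totals)}
        expected = {r.id for r in nutrient_rules if r.violates(0.0)}
        assert fired == expected
        assert "calcium_24h" in fired
        assert "sodium_24h" not in fired

    def test_negative_totals_rejected(self):
        with pytest.raises(ValueError):
            nutrition_check({"iron_mg": -1.0})


class TestOttawaRisk:
    @pytest.mark.parametrize(
        "items, dangerous, band",
        [([5], True, "dangerous"), ([], False, "safe"), ([1, 1], False, "safe"),
         ([3], True, "dangerous"), ([9], True, "dangerous"), ([10], False, "critical")],
    )
    def test_danger_band_boundaries(self, items, dangerous, band):
        assessment = ottawa_risk(items)
        assert assessment.dangerous is dangerous
        assert assessment.band == band

    def test_boundary_enumeration(self):
        for total in range(0, 13):
            assessment = ottawa_risk([1] * total)
            assert assessment.total == total
            assert assessment.dangerous == (3 <= total <= 9)

    def test_negative_scores_rejected(self):
        with pytest.raises(ValueError):
            ottawa_risk([-1])
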