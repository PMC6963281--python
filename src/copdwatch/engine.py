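"""Stateful forward evaluation of rulepacks over per-minute observations.

The engine walks a chronologically ordered stream of per-minute records
and, for every applicable rule, tracks how long its constraint has been
violated. Rules with an exposure window fire only once the violation has
persisted for the window's duration (continuously for the hourly limits,
cumulatively within a rolling 24 h window for the daily ones); rules
without a window fire immediately. Dynamic rules tighten their limit as
the patient's cumulative exposure to the rule's context grows. A rule
that has fired stays silent until it has been back in the safe zone for a
re-arm period (default 5 min), which keeps per-minute repeats from
flooding the alarm log.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Any, Iterable, Optional, Sequence

import math

from copdwatch import physiology
from copdwatch.profiles import Band, PatientProfile, SeverityGroup, severity_group
from copdwatch.rulepack import Rule, Rulepack, default_rulepack

ROLLING_WINDOW_MIN = 1440  # the rolling accumulators span one calendar day
DEFAULT_REARM_MIN = 5


class SequencingError(ValueError):
    """Observation timestamps must be strictly increasing."""


@dataclass
class Alarm:
    timestamp: datetime
    category: str  # vital | weather | pollution | activity
    parameter: str
    value: float
    bound: str  # human-readable violated band/limit
    rule_id: str
    suggestion: str


@dataclass
class ExposureState:
    """Per-stream accumulators carried between minutes.

    ``continuous`` counts consecutive violating minutes per rule;
    ``rolling`` keeps the violating minute timestamps of the trailing 24 h;
    ``context_minutes`` keeps the trailing-24 h minutes spent inside each
    dynamic rule's context (the exposure driving its threshold schedule);
    ``clear_minutes`` counts consecutive compliant minutes used to re-arm
    a rule after it fired.
    """

    last: Optional[datetime] = None
    continuous: dict[str, int] = field(default_factory=dict)
    rolling: dict[str, deque] = field(default_factory=dict)
    context_minutes: dict[str, deque] = field(default_factory=dict)
    fired: set[str] = field(default_factory=set)
    clear_minutes: dict[str, int] = field(default_factory=dict)


def dynamic_threshold(
    rule: Rule, severity: SeverityGroup | str, exposure_minutes: float
) -> Band | float:
    """Effective band/limit for a rule at the given cumulative exposure.

    Static rules return their printed band or limit unchanged. Dynamic
    rules return the schedule step whose exposure node is the largest one
    not exceeding ``exposure_minutes``; for upper limits the schedule is
    non-increasing, so longer exposure never loosens the constraint.
    """
    if rule.band is not None:
        return rule.band
    assert rule.limit is not None
    if not rule.schedule:
        return rule.limit.value
    value = rule.schedule[0].value
    for step in rule.schedule:
        if step.exposure_minutes <= exposure_minutes:
            value = step.value
        else:
            break
    return value


def _matches_location(rule_loc: Optional[str], record_loc: Optional[str]) -> bool:
    if rule_loc is None:
        return True
    if record_loc is None:
        return False
    if rule_loc == "indoor":
        return record_loc in {"indoor", "bedroom", "living_room"}
    return record_loc == rule_loc


def season_of(ts: datetime) -> str:
    month = ts.month
    if month in (12, 1, 2):
        return "winter"
    if month in (3, 4, 5):
        return "spring"
    if month in (6, 7, 8):
        return "summer"
    return "autumn"


def _context_matches(rule: Rule, record: Any) -> bool:
    ctx = rule.context
    if ctx.activity is not None and getattr(record, "activity_category", None) != ctx.activity:
        return False
    if not _matches_location(ctx.location, getattr(record, "location", None)):
        return False
    if ctx.season is not None and season_of(record.timestamp) != ctx.season:
        return False
    return True


def _lookup(parameter: str, record: Any) -> Optional[float]:
    vitals = getattr(record, "vitals", None) or {}
    env = getattr(record, "environment", None) or {}
    if parameter in vitals:
        return vitals[parameter]
    if parameter in env:
        return env[parameter]
    if parameter == "altitude":
        return getattr(record, "altitude", None)
    if parameter == "pm10_mg":  # derived: indoor PM10 in mg/m3
        pm10 = env.get("indoor_pm10", env.get("pm10"))
        return None if pm10 is None else pm10 / 1000.0
    return None


def _prune(window: deque, now: datetime) -> None:
    horizon = now - timedelta(minutes=ROLLING_WINDOW_MIN)
    while window and window[0] <= horizon:
        window.popleft()


def evaluate_minute(
    profile: PatientProfile,
    record: Any,
    state: ExposureState,
    packs: Sequence[Rulepack],
    rearm_minutes: int = DEFAULT_REARM_MIN,
) -> tuple[list[Alarm], ExposureState]:
    """Evaluate one per-minute record against the packs; update state.

    Returns the alarms emitted at this minute and the advanced state (the
    same object, mutated). Records must arrive in strictly increasing
    timestamp order; missing (None/NaN) sensor values are skipped with
    their accumulators frozen.
    """
    ts: datetime = record.timestamp
    if state.last is not None and ts <= state.last:
        raise SequencingError(f"record at {ts} not after previous {state.last}")
    level = severity_group(profile)
    alarms: list[Alarm] = []
    for pack in packs:
        for rule in pack.rules:
            if level.value not in rule.severity:
                continue
            in_context = _context_matches(rule, record)
            if rule.schedule is not None:
                window = state.context_minutes.setdefault(rule.id, deque())
                if in_context:
                    window.append(ts)
                _prune(window, ts)
            if not in_context:
                state.continuous[rule.id] = 0
                state.clear_minutes[rule.id] = state.clear_minutes.get(rule.id, 0) + 1
                if state.clear_minutes[rule.id] >= rearm_minutes:
                    state.fired.discard(rule.id)
                continue
            if any(
                not g.satisfied(v)
                for g in rule.guards
                if (v := _lookup(g.parameter, record)) is not None
            ):
                continue
            value = _lookup(rule.parameter, record)
            if value is None or (isinstance(value, float) and math.isnan(value)):
                continue  # frozen accumulators
            exposure = float(len(state.context_minutes.get(rule.id, ())))
            effective = dynamic_threshold(rule, level, exposure)
            eff_limit = None if isinstance(effective, Band) else effective
            violated = rule.violates(value, effective=eff_limit)
            if violated:
                state.clear_minutes[rule.id] = 0
                if rule.window == "rolling":
                    window = state.rolling.setdefault(rule.id, deque())
                    window.append(ts)
                    _prune(window, ts)
                    exposure_now = len(window)
                else:
                    state.continuous[rule.id] = state.continuous.get(rule.id, 0) + 1
                    # elapsed minutes since the violation began: the first
                    # violating minute contributes zero exposure
                    exposure_now = state.continuous[rule.id] - 1
                needed = rule.exposure_minutes or 0
                if exposure_now >= needed and rule.id not in state.fired:
                    alarms.append(
                        Alarm(
                            timestamp=ts,
                            category=rule.category,
                            parameter=rule.parameter,
                            value=value,
                            bound=rule.describe_bound(effective=eff_limit),
                            rule_id=rule.id,
                            suggestion=rule.suggestion,
                        )
                    )
                    state.fired.add(rule.id)
            else:
                state.continuous[rule.id] = 0
                if rule.window == "rolling":
                    _prune(state.rolling.setdefault(rule.id, deque()), ts)
                state.clear_minutes[rule.id] = state.clear_minutes.get(rule.id, 0) + 1
                if state.clear_minutes[rule.id] >= rearm_minutes:
                    state.fired.discard(rule.id)
    state.last = ts
    return alarms, state


# ---------------------------------------------------------------------------
# One-shot checks
# ---------------------------------------------------------------------------


@dataclass
class TravelAdvisory:
    alarm: bool
    can_travel: bool
    predicted_pao2: Optional[float]
    hypertension_multiplier: float
    messages: list[str]


def altitude_travel_check(
    profile: PatientProfile,
    altitude: float,
    observed_pao2: Optional[float] = None,
    observed_spo2: Optional[float] = None,
    six_mwt: bool = False,
) -> TravelAdvisory:
    """Screen a profile for a mountain trip / high-altitude exposure.

    Alarms when the altitude exceeds 1050 m, when the (observed or
    predicted) PaO2 falls below 50 mmHg, or when SpO2 falls below 92%
    (84% under the six-minute walking test). The PaO2 prediction is
    computed for patients with baseline FEV1 below 1.5 L.
    """
    messages: list[str] = []
    fev1 = profile.baselines.get("fev1")
    pao2_base = profile.baselines.get("pao2")
    predicted = None
    if fev1 is not None and pao2_base is not None and fev1 < 1.5:
        predicted = physiology.pao2_at_altitude(pao2_base, fev1)
        messages.append(f"Predicted PaO2 at altitude: {predicted:.1f} mmHg")
    pao2 = observed_pao2 if observed_pao2 is not None else predicted
    spo2 = observed_spo2 if observed_spo2 is not None else profile.baselines.get("spo2")
    alarm = False
    can_travel = True
    if altitude > 1050:
        alarm = True
        messages.append("Altitude above 1050 m: descend or use supplemental oxygen.")
    if pao2 is not None and pao2 < 50:
        alarm = True
        can_travel = False
        messages.append("PaO2 below 50 mmHg: cannot travel without supplemental oxygen.")
    spo2_limit = 84.0 if six_mwt else 92.0
    if spo2 is not None and spo2 < spo2_limit:
        alarm = True
        messages.append(
            f"SpO2 below {spo2_limit:.0f}%: hypoxia risk; pre-flight assessment required."
        )
    multiplier = physiology.hypertension_multiplier(max(altitude, 0.0))
    if altitude > 0:
        messages.append(
            f"Hypertension-prevalence multiplier at this altitude: {multiplier:.2f}"
        )
    return TravelAdvisory(
        alarm=alarm,
        can_travel=can_travel,
        predicted_pao2=predicted,
        hypertension_multiplier=multiplier,
        messages=messages,
    )


def nutrition_check(
    daily_totals: dict[str, float], pack: Optional[Rulepack] = None
) -> list[Alarm]:
    """Check 24 h nutrient totals against the shipped intake rules.

    Band rules (fiber, vitamin D) alarm outside the band; relational rules
    alarm past their limit, including minimum-type rules (e.g. calcium)
    that fire at zero intake. Totals must be non-negative.
    """
    for nutrient, amount in daily_totals.items():
        if amount < 0:
            raise ValueError(f"negative 24 h total for {nutrient}")
    if pack is None:
        pack = default_rulepack("activity")
    now = datetime.now()
    alarms: list[Alarm] = []
    for rule in pack.rules:
        if rule.parameter not in daily_totals:
            continue
        value = daily_totals[rule.parameter]
        if rule.violates(value):
            alarms.append(
                Alarm(
                    timestamp=now,
                    category="activity",
                    parameter=rule.parameter,
                    value=value,
                    bound=rule.describe_bound(),
                    rule_id=rule.id,
                    suggestion=rule.suggestion,
                )
            )
    return alarms


@dataclass
class RiskAssessment:
    total: int
    dangerous: bool
    band: str  # safe | dangerous | critical


def ottawa_risk(item_scores: Iterable[int]) -> RiskAssessment:
    """Total a COPD risk-score item list and flag the 3-9 danger band.

    Totals above 9 map to the highest (critical) band; the individual item
    definitions are not modelled, only the aggregate danger band.
    """
    scores = list(item_scores)
    if any(s < 0 for s in scores):
        raise ValueError("item scores must be >= 0")
    total = int(sum(scores))
    if total > 9:
        band = "critical"
    elif total >= 3:
        band = "dangerous"
    else:
        band = "safe"
    return RiskAssessment(total=total, dangerous=(3 <= total <= 9), band=band)
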