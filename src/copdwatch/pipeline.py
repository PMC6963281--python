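"""End-to-end orchestration: simulate -> monitor -> aggregate -> evaluate.

The pipeline drives the rule engine over simulated cohort streams,
aggregates the resulting alarm logs by month/season/category, and scores
alarm performance against a hospitalization reference with the standard
confusion-matrix metric set (accuracy, sensitivity, specificity, the
false-positive and false-negative fractions, PPV, NPV and F1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import math

import pandas as pd

from copdwatch.engine import Alarm, ExposureState, evaluate_minute, season_of
from copdwatch.profiles import PatientProfile
from copdwatch.rulepack import Rulepack, default_rulepack, default_rulepacks, expand_rulepack
from copdwatch.simulator import CohortDataset, iter_records

logger = logging.getLogger(__name__)

ALARM_CATEGORIES = ("vital", "weather", "pollution", "activity")
SEASONS = ("winter", "spring", "summer", "autumn")


@dataclass
class AlarmLog:
    patient_id: str
    alarms: list[Alarm]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": [a.timestamp for a in self.alarms],
                "category": [a.category for a in self.alarms],
                "parameter": [a.parameter for a in self.alarms],
                "value": [a.value for a in self.alarms],
                "bound": [a.bound for a in self.alarms],
                "rule_id": [a.rule_id for a in self.alarms],
                "suggestion": [a.suggestion for a in self.alarms],
            }
        )


def run_monitoring(
    profile: PatientProfile,
    stream: pd.DataFrame,
    packs: Optional[Sequence[Rulepack]] = None,
    expand: bool = True,
    progress_every: int = 0,
) -> AlarmLog:
    """Stream a joined per-minute frame through the rule engine.

    Packs default to the four shipped families, expanded (personalized) for
    the profile. Deterministic given the stream.
    """
    if packs is None:
        packs = default_rulepacks()
    if expand:
        packs = [expand_rulepack(p, profile) for p in packs]
    required = {"timestamp", "activity", "activity_category", "location"}
    missing = required - set(stream.columns)
    if missing:
        raise ValueError(f"stream is missing mandatory columns: {sorted(missing)}")
    state = ExposureState()
    alarms: list[Alarm] = []
    for i, record in enumerate(iter_records(stream)):
        out, state = evaluate_minute(profile, record, state, packs)
        alarms.extend(out)
        if progress_every and (i + 1) % progress_every == 0:
            logger.info("patient %s: %d minutes, %d alarms", profile.id, i + 1, len(alarms))
    return AlarmLog(patient_id=profile.id, alarms=alarms)


def run_cohort_monitoring(
    dataset: CohortDataset, packs: Optional[Sequence[Rulepack]] = None
) -> dict[str, AlarmLog]:
    """Monitor every patient stream independently (no cross-talk)."""
    logs: dict[str, AlarmLog] = {}
    for profile in dataset.profiles:
        logs[profile.id] = run_monitoring(profile, dataset.streams[profile.id], packs)
    return logs


def aggregate_alarms(log: AlarmLog | Iterable[Alarm], by: str = "season") -> pd.DataFrame:
    """Count alarms by category crossed with month or season.

    Seasons: Dec-Feb winter, Mar-May spring, Jun-Aug summer, Sep-Nov
    autumn. The counts partition the log exactly; a Total row/column is
    appended.
    """
    alarms = log.alarms if isinstance(log, AlarmLog) else list(log)
    if by not in {"season", "month", "category"}:
        raise ValueError("by must be season, month or category")
    if by == "category":
        counts = pd.Series([a.category for a in alarms]).value_counts()
        return counts.reindex(ALARM_CATEGORIES, fill_value=0).to_frame("count")
    if by == "season":
        cols = list(SEASONS)
        keys = [season_of(a.timestamp) for a in alarms]
    else:
        cols = list(range(1, 13))
        keys = [a.timestamp.month for a in alarms]
    table = pd.DataFrame(0, index=list(ALARM_CATEGORIES), columns=cols)
    for alarm, key in zip(alarms, keys):
        table.loc[alarm.category, key] += 1
    table.loc["Total"] = table.sum(axis=0)
    table["Total"] = table.sum(axis=1)
    return table


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def build_confusion(
    alarm_outcomes: Iterable[tuple[bool, bool]]
) -> tuple[int, int, int, int]:
    """Count (TP, FP, TN, FN) from (alarm, hospitalization-reference) pairs.

    TP: alarm with hospitalization; FP: alarm without; TN: neither;
    FN: hospitalization without alarm.
    """
    tp = fp = tn = fn = 0
    for alarm, reference in alarm_outcomes:
        if alarm and reference:
            tp += 1
        elif alarm and not reference:
            fp += 1
        elif not alarm and not reference:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """Standard diagnostic metric set, in percent.

    accuracy = (TP+TN)/total; sensitivity = TP/(TP+FN);
    FNF = FN/(TP+FN); specificity = TN/(TN+FP); FPF = FP/(TN+FP);
    PPV = TP/(TP+FP); NPV = TN/(FN+TN); F1 = harmonic mean of PPV and
    sensitivity. A zero denominator yields NaN for that metric rather
    than an exception.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("counts must be non-negative")
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("at least one outcome required")

    def ratio(num: float, den: float) -> float:
        return 100.0 * num / den if den > 0 else math.nan

    sensitivity = ratio(tp, tp + fn)
    ppv = ratio(tp, tp + fp)
    if math.isnan(sensitivity) or math.isnan(ppv) or (sensitivity + ppv) == 0:
        f1 = math.nan
    else:
        f1 = 2.0 * ppv * sensitivity / (ppv + sensitivity)
    return {
        "accuracy": ratio(tp + tn, total),
        "sensitivity": sensitivity,
        "fnf": ratio(fn, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "fpf": ratio(fp, tn + fp),
        "ppv": ppv,
        "npv": ratio(tn, fn + tn),
        "f1": f1,
    }


def evaluate_daily_alarms(
    log: AlarmLog, stream: pd.DataFrame, category: Optional[str] = None
) -> tuple[int, int, int, int]:
    """Pair daily alarm presence with the stream's hospitalization truth.

    Each calendar day is one case: alarm = any matching alarm that day;
    reference = any hospitalization-worthy anomaly injected that day.
    """
    alarms = [a for a in log.alarms if category is None or a.category == category]
    alarm_days = {a.timestamp.date() for a in alarms}
    truth = stream.groupby(stream["timestamp"].dt.date)["hospital"].any()
    pairs = [(day in alarm_days, bool(flag)) for day, flag in truth.items()]
    return build_confusion(pairs)


EXPERIMENTS = {
    "vitals": "vitals",
    "pollution": "pollution",
    "weather": "weather",
    "activity": "activity",
}


def run_experiment(
    name: str, profile: PatientProfile, stream: pd.DataFrame
) -> AlarmLog:
    """Run one rule family in isolation over a stream (the four scenarios)."""
    if name not in EXPERIMENTS:
        raise KeyError(f"unknown experiment {name!r}; choose from {sorted(EXPERIMENTS)}")
    pack = default_rulepack(EXPERIMENTS[name])
    return run_monitoring(profile, stream, packs=[pack])
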