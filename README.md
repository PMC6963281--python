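# copdwatch

Personalized, rule-based telemonitoring for patients with chronic
obstructive pulmonary disease (COPD).

People living with COPD are vulnerable to triggers that healthy people
barely notice: cold or hot weather, indoor and outdoor air pollution,
humidity extremes, altitude, over-exertion, and diet. `copdwatch`
implements a clinical-decision-support engine that watches a per-minute
stream of vital signs and environmental readings and raises alarms when a
personalized safe band is violated — where "safe" depends on the
patient's medical profile (GOLD stage, age, comorbidities, medications),
the intensity of the current activity, the location, and how long the
exposure has lasted. It is aimed at researchers prototyping
telemonitoring rules and at engineers who need a testable, declarative
alternative to ontology-based rule stacks.

## What is inside

* **profiles** — typed patient medical records (demographics, GOLD stage
  I–IV, comorbidities, baseline vitals, per-activity-intensity safe
  bands), CSV/JSON I/O, and a four-level severity grouping
  (low / moderate / high / very high) that is monotone in stage and
  comorbidity count.
* **physiology** — the closed forms behind the outdoor rules:
  the hypsometric formula `P = 760·(1 − h/44330.76923)^5.255876` (mmHg, m);
  Dalton partial pressures for 78 % N₂ / 21 % O₂ / 0.038 % CO₂;
  the altitude PaO₂ regression
  `PaO₂_alt = 0.5196·PaO₂_sea + 11.856·FEV1 − 1.76`;
  heart-rate/blood-pressure shifts per °C outside the 22–27 °C comfort
  zone (cold: 0.063 / 0.129 / 0.065; hot: 0.133 / 0.605 / 0.128 per °C
  for HR/SBP/DBP); the cold-weather FEV1 decline (2.20 mL·°C⁻¹, FVC
  3.64 mL·°C⁻¹); and a stage × age-decade expected resting heart rate
  with additive profile modifiers.
* **airquality** — descending 0–100 indoor air-quality index
  (good 100–76, normal 75–51, unhealthy 50–26, hazardous 25–0) and an
  ascending EPA-AQI-style index with a 150-point protection threshold,
  combined by the stringent rule (worst sub-index; alarm on either
  scale).
* **rulepack** — declarative YAML rule families (`vitals`, `pollution`,
  `weather`, `activity`) with safe bands, relational limits, exposure
  windows, guard conditions, severity applicability and suggestion
  texts, plus per-patient expansion that swaps in the profile's own
  bands.
* **engine** — stateful per-minute evaluation: continuous-violation and
  rolling 24 h exposure windows, dynamic thresholds that tighten with
  cumulative exposure (e.g. indoor PM10 drops from 0.150 to
  0.020 mg/m³ after 8 h), alarm de-duplication with a 5-minute re-arm,
  altitude-travel screening, nutrient-intake checks, and a risk-score
  danger band (3–9).
* **simulator** — a synthetic cohort: Markov-chain activity days over 18
  activities of daily living with six daypart transition matrices and an
  ICF capacity filter; mean-reverting seasonal indoor/outdoor
  environment series; profile-conditioned vitals with anomaly injection
  (the evaluation ground truth).
* **pipeline / cli** — simulate → monitor → aggregate → evaluate
  orchestration, seasonal alarm tables, and confusion-matrix metrics.

## Worked example

```python
from copdwatch.pipeline import run_monitoring, aggregate_alarms, confusion_metrics
from copdwatch.simulator import generate_cohort

dataset = generate_cohort(n_patients=1, days=14, seed=42)
profile = dataset.profiles[0]          # P0000: male, 69, GOLD IV
log = run_monitoring(profile, dataset.streams[profile.id])
print(len(log.alarms))                 # 1777
print(aggregate_alarms(log, by="category"))
```

```
           count
vital       1441
weather      306
pollution     30
activity       0
```

Two winter weeks of a severe (GOLD IV) patient produce mostly
vital-sign alarms (his personalized bands are narrow relative to his
heart-rate variability) plus weather alarms from indoor-pressure and
cold-weather excursions. Each alarm carries the violated band and a
suggestion, e.g. `indoor_pressure 1012.95 ∉ [1013, 1018] hPa — "Indoor
pressure outside the 1013-1018 hPa comfort band; check the ventilation
system."`.

Scoring alarms against a hospitalization reference uses the standard
confusion-matrix metric set, in percent:

```python
>>> confusion_metrics(tp=512, fp=88, tn=544, fn=56)
{'accuracy': 88.0, 'sensitivity': 90.14, 'fnf': 9.86, 'specificity': 86.08,
 'fpf': 13.92, 'ppv': 85.33, 'npv': 90.67, 'f1': 87.67}
```

A command-line interface mirrors the library:

```bash
copdwatch simulate data/ --patients 5 --days 30 --seed 1
copdwatch monitor data/ --out alarms.csv
copdwatch aggregate alarms.csv --by season
copdwatch airquality "PM10=80,CO=1.2"
```

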