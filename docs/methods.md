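# Methods

This note documents the models, parameters and design choices behind
`copdwatch`, and what the synthetic cohort does and does not show about
real telemonitoring data.

## Patient profiles and severity grouping

A profile is a diagnostic-time snapshot: demographics, GOLD stage
(I–IV), mMRC dyspnea grade, smoking status, comorbidities (CHF, HBP,
anemia, IHD, PH, GERD, asthma), medications, baseline values for the 12
monitored parameters (body temperature °C, DBP/SBP mmHg, heart rate
bpm, PaO₂ mmHg, SpO₂ %, PaCO₂ mmHg, VO₂ mL/kg/min, respiration rate
breaths/min, pH, HCO₃ mmol/L, FEV1 L), and per-activity-intensity safe
bands measured in exercise testing. Units are fixed per vital and
validated on load; no unit inference is attempted. Extended spirometry
columns (FEF25–75, TLC, RV, …) are carried as untyped extras because no
rule consumes them.

The four protection levels are derived deterministically:

* **low** — GOLD I–II, no comorbidities, age < 65;
* **moderate** — GOLD I–II with ≥ 1 comorbidity or age ≥ 65;
* **high** — GOLD III;
* **very high** — GOLD IV, or GOLD III with ≥ 1 comorbidity.

The mapping is monotone in stage and in comorbidity count (verified by
enumeration in the tests). It is a design choice: the source material
requires four profile-driven levels but does not print the assignment.

Missing activity bands are synthesized from the baseline with fixed
additive offsets per (vital, intensity) whose geometry reproduces a
published example record (baseline HR 60 → light 60–97, moderate
98–120, vigorous 121–130, and analogous rows for the other vitals). The
sedentary offsets straddle zero, so a synthesized sedentary band always
contains the baseline.

## Physiology

* **Barometric pressure.** `P(h) = 760·(1 − h/C)^5.255876` mmHg on
  0–11,000 m with `C = 44330.76923` m. A variant of this constant with
  one digit fewer circulates in print but yields physically impossible
  pressures (≈183 mmHg at 1050 m); the standard value reproduces
  textbook numbers (760.0 at 0 m, ≈670 mmHg at 1050 m) and both agree
  exactly at sea level. The constant is an argument for callers who
  need the literal variant.
* **Partial pressures.** Fixed dry-air fractions 78 % N₂ / 21 % O₂ /
  0.038 % CO₂. At 760 mmHg: 592.8 / 159.6 / 0.289 mmHg. The CO₂ value
  is the computed one; a printed figure of 0.02 mmHg is inconsistent
  with the stated fraction and is not used.
* **Altitude PaO₂.** `0.5196·PaO₂_sea + 11.856·FEV1 − 1.76` (mmHg, L),
  intended for pre-travel screening when baseline FEV1 < 1.5 L.
* **Thermal response.** HR/SBP/DBP shift linearly with ambient
  temperature outside a dead zone: cold coefficients 0.063 / 0.129 /
  0.065 per °C below 22 °C, hot coefficients 0.133 / 0.605 / 0.128 per
  °C above 27 °C, zero in between. The underlying report attaches the
  22 °C threshold to HR and 27 °C to BP but does not define the
  opposite side of either; using one shared dead zone [22, 27] °C keeps
  the response continuous, piecewise linear with exactly two knots, and
  zero between the thresholds, and matches every printed anchor (e.g.
  +0.63 bpm at 12 °C, +0.605 mmHg SBP at 28 °C).
* **Cold-season spirometry.** FEV1 declines at 2.20 mL·°C⁻¹ (FVC at
  3.64 mL·°C⁻¹) between a warm and a cold period; the function returns
  the slope product (44.70 mL for a 21.1 → 0.78 °C contrast).
* **Expected resting heart rate.** A stage × age-decade reference grid
  for male patients (72.6 bpm at stage I, ages 40–50, rising to
  84.9 bpm at stage IV) ships as versioned YAML with additive
  modifiers: smoker +6.6, obese (BMI ≥ 30) +9, inhaler medication +7,
  CHF +9.6, anemia +7, PH +10, asthma +8 bpm. The female offset is a
  constant +3 bpm (the published age curve is graphical only) and is
  configurable. Exercise categories replace the resting cell with the
  stage-I exercise mean (sedentary 76.3, light 85.5, moderate 125.6,
  vigorous 145.3 bpm) scaled by the profile's cell / stage-I-cell
  ratio. Ages outside 40–90 are clamped with a warning. Where the grid
  and its accompanying prose disagree on two stage-I cells, the grid is
  authoritative.

## Indoor air quality

Neither source index publishes its sub-index formula, so both are
EPA-AQI-style piecewise-linear interpolations anchored on the shipped
per-pollutant alarm limits (CO 2 ppm, HCHO 0.04 ppm, TVOC 0.9 ppm, CO₂
600 ppm, PM10 60 µg/m³, PM2.5 45 µg/m³, O₃ 0.03 ppm, bacteria
600 CFU/m³, NO₂ 5 ppm, SO₂ 0.06 ppm, H₂S 1 ppm, NO 25 ppm, NOx 10 ppm,
TRS 10 ppm; fungi, which has no printed limit, defaults to a common
500 CFU/m³ guideline). The descending index maps 0 → 100, the limit →
50 (the unhealthy boundary), 2× the limit → 25 and 3× → 0; boundary
scores belong to the better category (76 → good, 51 → normal, 26 →
unhealthy). The ascending index is linear with the limit at 100
points. Because the two scales run in opposite directions, "adopt the
most stringent" is implemented as an OR: alarm when the descending
category is worse than normal **or** the ascending index exceeds 150
points.

## Rule semantics

* `a < X > b` notation is read as: alarm when X leaves [a, b]. A
  literal reading is unsatisfiable, and the bands bracket the example
  profile's normal ranges.
* Blood-pressure rows joined by AND are split into independent SBP and
  DBP rules (safety-first: either component leaving its band alarms).
* The living-room temperature rule alarms on rooms *colder* than 21 °C
  (the respiratory optimum is at and above 21 °C); the literal
  direction is available by editing the pack.
* The indoor pressure band is treated as 1013–1018 hPa; kPa values of
  that magnitude are impossible.
* Exposure windows on hourly/8 h/4 h limits are continuous-violation
  windows: the accumulator counts elapsed minutes since the violation
  began and resets on any compliant minute, so a 1 h rule fires at the
  61st consecutive violating minute. The 24 h particulate and nutrient
  windows are rolling calendar windows. The source says "exposure
  limit" without reset semantics; this is the package's choice.
* Dynamic thresholds are step schedules over cumulative in-context
  exposure (largest node ≤ exposure wins). The shipped example: indoor
  PM10 for the low-severity group starts at 0.150 mg/m³ and tightens
  to 0.020 mg/m³ once indoor exposure exceeds 8 h. Upper limits are
  non-increasing in exposure by construction.
* A rule that fired is suppressed until it has been compliant for 5
  consecutive minutes (configurable). Reported daily alarm counts of
  2–8 imply some such suppression of per-minute repeats.
* Missing sensor values freeze the rule's accumulators (no alarm, no
  reset).
* The encoded sodium limit (180 mg/24 h) is far below dietary norms but
  is kept as published; the travel thresholds encode both the tabular
  (SpO₂ < 92 %, < 84 % with 6MWT, PaO₂ < 50 mmHg) and the narrative
  variant, with the tabular ones taking precedence.
* Only the 3–9 danger band of the COPD risk score is modelled; the
  item definitions are not published in the source material.

## Synthetic cohort

The simulator replaces the original study's non-redistributable data
sources (provincial air-quality archives, a commercial indoor monitor,
hospital medical records) with parametric generators; it reproduces
their *structure*, not their measurements.

* **Activities.** 18 activities of daily living (the published list
  enumerates 17; "resting" completes it). Days are tiled by a
  first-order Markov chain with six daypart matrices (4 h blocks from
  06:00); rows are daypart activity-preference weights renormalized
  with damped self-transitions, hand-authored so that commuting peaks
  in the morning block and lunch in the early-afternoon block (the
  published matrix is graphical only). Durations are uniform within
  per-activity bounds; daily frequencies are capped; activities beyond
  the patient's capacity never appear. The capacity mapping — GOLD
  I–II all intensities, GOLD III up to moderate, GOLD IV or mMRC ≥ 3
  up to light — instantiates the stated ICF principle.
* **Environment.** Every field is `x_t = μ(day) + AR(1) noise` at
  one-minute resolution with per-minute persistence φ = 0.98, a
  sinusoidal seasonal mean (coldest mid-January) and configured
  stationary SD; non-negative fields are clipped at zero with means
  ≥ ~4 SD so the clipping bias is negligible. Defaults (e.g. outdoor
  temperature 8 ± 14 °C seasonal swing, indoor 21.5 °C, CO₂ ≈ 695 ppm,
  indoor humidity ≈ 45 %) are consistent with the published sample
  rows from a cold-climate station and a monitored apartment. Wind is
  also exported in mph and precipitation split into rainfall/snowfall
  (cm) by the sign of the temperature, matching the rule parameters.
* **Vitals.** Per minute, each vital is Gaussian around the profile's
  band midpoint for the current intensity — resting heart rate around
  the stage/age reference value, with the reference SDs (12–14 bpm at
  rest, up to 25 bpm for vigorous exercise); other vitals use SD =
  band width / 4. Noise is truncated at ±4 σ. Outdoor minutes add the
  thermal HR/BP deltas; altitude lowers SpO₂ (−1 %/500 m) and raises
  HR (+1 bpm/600 m) — deliberately modest linear surrogates for the
  reported directional effects. An anomaly-injection rate (default
  0.002/min) pushes one random vital outside its band by 0.3–2 band
  widths; excursions beyond one full width are flagged
  hospitalization-worthy and form the evaluation ground truth, since
  the original physician panel is unavailable.

One patient-year at one-minute resolution is exactly 525,600 joined
records and generates in a few seconds (the per-minute rule engine over
such a stream is minutes; tests and examples use days-to-weeks).

What passing tests show: the engine's temporal semantics are exact
(proved against a brute-force oracle), the generators are calibrated to
their configured means, and the whole pipeline is deterministic under
seeds. What they do not show: real sensor noise is neither Gaussian nor
stationary, real activity sequences are far more structured, and the
injected-anomaly ground truth is much cleaner than physician-labelled
hospitalizations — so the confusion-matrix numbers obtained on
synthetic streams say nothing about clinical accuracy on real patients.

## Evaluation metrics

`confusion_metrics` applies the standard formulas — accuracy
(TP+TN)/total, sensitivity TP/(TP+FN), FNF FN/(TP+FN), specificity
TN/(TN+FP), FPF FP/(TN+FP), PPV TP/(TP+FP), NPV TN/(FN+TN), F1 the
harmonic mean of PPV and sensitivity — in percent, with NaN for empty
denominators. On the published counts (TP 512, FP 88, TN 544, FN 56)
the formulas give sensitivity 90.14 %, consistent with the published
FNF of 9.85 % but not with the published sensitivity of 91.14 %; the
implementation returns the formula value, and F1 is accordingly 87.67 %
rather than the published 88.13 %.

## Numerical and degenerate-input choices

* Band bounds are closed intervals; values exactly on a bound are safe.
* Air-quality category boundaries belong to the better category.
* Profile BMI must agree with weight/height within 0.5 kg/m².
* Out-of-order timestamps raise a sequencing error; the engine assumes
  a one-minute cadence.
* Zero patients/days, inverted bands, negative concentrations and
  negative nutrient totals are rejected with descriptive errors.
* All randomness flows through `numpy.random.Generator`; cohort
  generation spawns independent child seeds per patient via
  `SeedSequence`, so patient streams are independent and reproducible.
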