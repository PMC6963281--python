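# Resting heart-rate reference for male COPD patients (beats/min),
# stage x age-decade grid of mean +/- SD, with additive modifier means and
# exercise-category means. Overridable by user config.
decades: [40, 50, 60, 70, 80]   # lower edge of each 10-year band
stages:
  I:
    mean: [72.6, 69.2, 70.1, 68.70, 67.20]
    sd:   [12, 11, 8, 7, 9]
  II:
    mean: [74.6, 72.3, 71.3, 70.3, 69.3]
    sd:   [13, 12, 11, 10, 12]
  III:
    mean: [77.5, 75.2, 74.2, 73.6, 72.6]
    sd:   [13, 12, 11, 11, 10]
  IV:
    mean: [84.9, 82.2, 81.2, 80.2, 79.2]
    sd:   [14, 13, 12, 10, 11]
# Mean additive change in resting HR (beats/min) per influencing factor.
modifiers:
  smoker: 6.6
  obese: 9.0          # BMI >= 30
  inhaler: 7.0        # inhaler medication
  CHF: 9.6
  anemia: 7.0
  PH: 10.0
  asthma: 8.0
# Mean HR during exercise categories for the stage-I reference population,
# scaled by (stage cell / stage-I cell) when applied to other stages.
exercise:
  sedentary: {mean: 76.3, sd: 10}
  light:     {mean: 85.5, sd: 15}
  moderate:  {mean: 125.6, sd: 18}
  vigorous:  {mean: 145.3, sd: 25}
# Constant female offset added to the male grid (the underlying age curve
# is published only graphically).
female_offset: 3.0
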