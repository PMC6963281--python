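# Activity and lifestyle alarms: exercise endurance, air travel and
# mountain-trip screening, and 24-hour nutrient intake limits. Nutrient
# rules are evaluated over rolling 24 h totals. The encoded sodium limit
# (180 mg/24 h) is far below dietary norms but is kept as published.
name: activity
version: "1.0"
rules:
  - {id: aerobic_training, category: activity, parameter: aerobic_training_min,
     limit: {direction: above, value: 30},
     suggestion: "Aerobic training longer than the 30 min endurance limit; stop and rest."}
  - {id: travel_spo2, category: activity, parameter: spo2,
     limit: {direction: below, value: 92},
     suggestion: "Oxygen saturation below 92%: air travel requires a hypoxia altitude simulation test."}
  - {id: travel_spo2_6mwt, category: activity, parameter: spo2_6mwt,
     limit: {direction: below, value: 84},
     suggestion: "Oxygen saturation below 84% on the six-minute walking test; do not fly without supplemental oxygen."}
  - {id: travel_pao2, category: activity, parameter: pao2,
     limit: {direction: below, value: 50},
     suggestion: "Arterial oxygen pressure below 50 mmHg; travel is unsafe without supplemental oxygen."}
  - {id: mountain_altitude, category: activity, parameter: altitude,
     limit: {direction: above, value: 1050},
     suggestion: "Altitude above 1050 m; descend or use supplemental oxygen."}
  - {id: sodium_24h, category: activity, parameter: sodium_mg, window: rolling,
     limit: {direction: above, value: 180},
     suggestion: "Sodium intake above the 24 h limit; reduce salty foods."}
  - {id: fructose_24h, category: activity, parameter: fructose_g, window: rolling,
     limit: {direction: above, value: 25},
     suggestion: "Fructose intake above 25 g/24 h; reduce sweetened foods."}
  - {id: glucose_24h, category: activity, parameter: glucose_mg, window: rolling,
     limit: {direction: above, value: 20},
     suggestion: "Glucose intake above the 24 h limit; reduce sugary foods."}
  - {id: calcium_24h, category: activity, parameter: calcium_mg, window: rolling,
     limit: {direction: below, value: 1200},
     suggestion: "Calcium intake below 1200 mg/24 h; add calcium-rich foods."}
  - {id: vitamin_d_24h, category: activity, parameter: vitamin_d_iu, window: rolling,
     band: {low: 800, high: 2000},
     suggestion: "Vitamin D outside the 800-2000 IU daily band; adjust supplementation."}
  - {id: vitamin_c_24h, category: activity, parameter: vitamin_c_mg, window: rolling,
     limit: {direction: above, value: 1000},
     suggestion: "Vitamin C above 1000 mg/24 h; reduce supplementation."}
  - {id: vitamin_a_24h, category: activity, parameter: vitamin_a_mcg, window: rolling,
     limit: {direction: above, value: 850},
     suggestion: "Vitamin A above 850 mcg/24 h; reduce supplementation."}
  - {id: vitamin_e_24h, category: activity, parameter: vitamin_e_iu, window: rolling,
     limit: {direction: above, value: 900},
     suggestion: "Vitamin E above 900 IU/24 h; reduce supplementation."}
  - {id: vitamin_b12_24h, category: activity, parameter: vitamin_b12_mcg, window: rolling,
     limit: {direction: above, value: 2.2},
     suggestion: "Vitamin B12 above 2.2 mcg/24 h; reduce supplementation."}
  - {id: iron_24h, category: activity, parameter: iron_mg, window: rolling,
     limit: {direction: above, value: 35},
     suggestion: "Iron above 35 mg/24 h; reduce supplementation."}
  - {id: zinc_24h, category: activity, parameter: zinc_mg, window: rolling,
     limit: {direction: above, value: 40},
     suggestion: "Zinc above 40 mg/24 h; reduce supplementation."}
  - {id: magnesium_24h, category: activity, parameter: magnesium_mg, window: rolling,
     limit: {direction: above, value: 435},
     suggestion: "Magnesium above 435 mg/24 h; reduce supplementation."}
  - {id: carbohydrate_24h, category: activity, parameter: carbohydrate_g, window: rolling,
     limit: {direction: above, value: 380},
     suggestion: "Carbohydrate above 380 g/24 h; rebalance the diet."}
  - {id: protein_24h, category: activity, parameter: protein_g, window: rolling,
     limit: {direction: above, value: 80},
     suggestion: "Protein above 80 g/24 h; rebalance the diet."}
  - {id: fat_24h, category: activity, parameter: fat_g, window: rolling,
     limit: {direction: above, value: 75},
     suggestion: "Fat above 75 g/24 h; rebalance the diet."}
  - {id: fiber_24h, category: activity, parameter: fiber_g, window: rolling,
     band: {low: 15, high: 30},
     suggestion: "Fiber outside the 15-30 g daily band; adjust the diet."}
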