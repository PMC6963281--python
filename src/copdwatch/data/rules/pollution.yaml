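# Indoor pollutant alarms and constraints: relational limits with temporal
# exposure windows. Hourly/8-hour/4-hour limits use continuous-violation
# windows; 24-hour particulate limits use rolling calendar windows. The
# dynamic PM10 rule tightens its safe limit once the low-severity patient's
# indoor exposure exceeds 8 hours.
name: pollution
version: "1.0"
rules:
  - {id: co_1h, category: pollution, parameter: co, context: {location: indoor},
     limit: {direction: above, value: 2}, exposure_minutes: 60,
     suggestion: "Carbon monoxide above 2 ppm for 1 h; ventilate immediately and check fuel appliances."}
  - {id: hcho_1h, category: pollution, parameter: hcho, context: {location: indoor},
     limit: {direction: above, value: 0.04}, exposure_minutes: 60,
     suggestion: "Formaldehyde above 0.04 ppm for 1 h; ventilate and remove the emission source."}
  - {id: tvoc_1h, category: pollution, parameter: voc, context: {location: indoor},
     limit: {direction: above, value: 0.9}, exposure_minutes: 60,
     suggestion: "Volatile organic compounds above 0.9 ppm for 1 h; ventilate the room."}
  - {id: co2_8h, category: pollution, parameter: co2, context: {location: indoor},
     limit: {direction: above, value: 600}, exposure_minutes: 480,
     suggestion: "CO2 above 600 ppm for 8 h; increase fresh-air supply."}
  - {id: pm10_24h, category: pollution, parameter: pm10, context: {location: indoor},
     limit: {direction: above, value: 60}, exposure_minutes: 1440, window: rolling,
     suggestion: "PM10 above 60 ug/m3 over 24 h; run air filtration."}
  - {id: pm2_5_24h, category: pollution, parameter: pm2_5, context: {location: indoor},
     limit: {direction: above, value: 45}, exposure_minutes: 1440, window: rolling,
     suggestion: "PM2.5 above 45 ug/m3 over 24 h; run air filtration."}
  - {id: o3_8h, category: pollution, parameter: o3, context: {location: indoor},
     limit: {direction: above, value: 0.03}, exposure_minutes: 480,
     suggestion: "Ozone above 0.03 ppm for 8 h; switch off ozone sources and ventilate."}
  - {id: bacteria_now, category: pollution, parameter: bacteria, context: {location: indoor},
     limit: {direction: above, value: 600},
     suggestion: "Airborne bacteria above 600 CFU/m3; clean and disinfect the room."}
  - {id: no2_8h, category: pollution, parameter: no2, context: {location: indoor},
     limit: {direction: above, value: 5}, exposure_minutes: 480,
     suggestion: "Nitrogen dioxide above 5 ppm for 8 h; ventilate and check combustion sources."}
  - {id: so2_8h, category: pollution, parameter: so2, context: {location: indoor},
     limit: {direction: above, value: 0.06}, exposure_minutes: 480,
     suggestion: "Sulfur dioxide above 0.06 ppm for 8 h; ventilate."}
  - {id: h2s_8h, category: pollution, parameter: h2s, context: {location: indoor},
     limit: {direction: above, value: 1}, exposure_minutes: 480,
     suggestion: "Hydrogen sulfide above 1 ppm for 8 h; ventilate and find the source."}
  - {id: no_8h, category: pollution, parameter: "no", context: {location: indoor},
     limit: {direction: above, value: 25}, exposure_minutes: 480,
     suggestion: "Nitric oxide above 25 ppm for 8 h; ventilate."}
  - {id: nox_8h, category: pollution, parameter: nox, context: {location: indoor},
     limit: {direction: above, value: 10}, exposure_minutes: 480,
     suggestion: "Nitrogen oxides above 10 ppm for 8 h; ventilate."}
  - {id: trs_4h, category: pollution, parameter: trs, context: {location: indoor},
     limit: {direction: above, value: 10}, exposure_minutes: 240,
     suggestion: "Total reduced sulfur above 10 ppm for 4 h; ventilate."}
  - {id: pm10_dynamic_low, category: pollution, parameter: pm10_mg, context: {location: indoor},
     limit: {direction: above, value: 0.150},
     schedule: [{exposure_minutes: 0, value: 0.150}, {exposure_minutes: 480, value: 0.020}],
     severity: [low],
     suggestion: "PM10 above the exposure-adjusted safe limit; leave the room or filter the air."}
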