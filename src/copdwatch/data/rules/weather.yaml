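# Weather alarms and constraints, indoor climate and outdoor conditions.
# Indoor pressure is expressed in hPa. The living-room rule alarms on cold
# rooms (below the 21 degC respiratory optimum).
name: weather
version: "1.0"
rules:
  - {id: bedroom_night_temp, category: weather, parameter: indoor_temperature,
     context: {location: bedroom}, band: {low: 18, high: 18.5}, exposure_minutes: 540,
     suggestion: "Bedroom temperature outside 18-18.5 degC for 9 h overnight; adjust heating."}
  - {id: living_room_temp, category: weather, parameter: indoor_temperature,
     context: {location: living_room}, limit: {direction: below, value: 21},
     suggestion: "Living room colder than 21 degC; raise the thermostat."}
  - {id: indoor_humidity, category: weather, parameter: indoor_humidity,
     context: {location: indoor}, band: {low: 30, high: 50},
     suggestion: "Indoor humidity outside 30-50%; humidify or dehumidify."}
  - {id: indoor_pressure, category: weather, parameter: indoor_pressure,
     context: {location: indoor}, band: {low: 1013, high: 1018},
     suggestion: "Indoor pressure outside the 1013-1018 hPa comfort band; check the ventilation system."}
  - {id: outdoor_humidity, category: weather, parameter: outdoor_humidity,
     context: {location: outdoor}, limit: {direction: above, value: 75},
     guards: [{parameter: outdoor_temperature, high: 30}],
     suggestion: "Outdoor humidity above 75%; shorten outdoor exposure."}
  - {id: outdoor_temp_hot, category: weather, parameter: outdoor_temperature,
     context: {location: outdoor}, limit: {direction: above, value: 27}, exposure_minutes: 30,
     suggestion: "Hot weather above 27 degC for 30 min; move to shade and hydrate."}
  - {id: outdoor_temp_cold, category: weather, parameter: outdoor_temperature,
     context: {location: outdoor}, limit: {direction: below, value: 14}, exposure_minutes: 30,
     suggestion: "Cold weather below 14 degC for 30 min; go indoors and cover the mouth and nose."}
  - {id: outdoor_temp_very_cold, category: weather, parameter: outdoor_temperature,
     context: {location: outdoor}, limit: {direction: below, value: 5}, exposure_minutes: 15,
     suggestion: "Very cold weather below 5 degC for 15 min; go indoors now."}
  - {id: outdoor_pressure, category: weather, parameter: outdoor_pressure,
     context: {location: outdoor}, limit: {direction: below, value: 89.325},
     guards: [{parameter: outdoor_temperature, low: 15, high: 25}],
     suggestion: "Low atmospheric pressure below 89.325 kPa; limit exertion outdoors."}
  - {id: wind_fresh_15min, category: weather, parameter: wind_speed_mph,
     context: {location: outdoor}, limit: {direction: above, value: 12}, exposure_minutes: 15,
     suggestion: "Wind above 12 mph for 15 min; avoid exposed areas."}
  - {id: wind_moderate_1h, category: weather, parameter: wind_speed_mph,
     context: {location: outdoor}, limit: {direction: above, value: 7}, exposure_minutes: 60,
     suggestion: "Wind above 7 mph for 1 h; consider returning indoors."}
  - {id: rainfall, category: weather, parameter: rainfall_cm,
     context: {location: outdoor}, limit: {direction: above, value: 0.2},
     suggestion: "Rainfall above 0.2 cm; stay indoors or use rain protection."}
  - {id: snowfall, category: weather, parameter: snowfall_cm,
     context: {location: outdoor}, limit: {direction: above, value: 5},
     suggestion: "Snowfall above 5 cm; avoid outdoor activity."}
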