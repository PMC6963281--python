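# Indoor pollutant alarm limits used as the 50-point (unhealthy-boundary)
# anchor of the descending 0-100 sub-index and as the 100-point anchor of
# the ascending AQI-style sub-index. Units are the pollutant's canonical
# reporting unit. Overridable by config.
limits:
  CO:       {limit: 2.0,    units: ppm}
  HCHO:     {limit: 0.04,   units: ppm}
  TVOC:     {limit: 0.9,    units: ppm}
  CO2:      {limit: 600.0,  units: ppm}
  PM10:     {limit: 60.0,   units: ug/m3}
  PM2.5:    {limit: 45.0,   units: ug/m3}
  O3:       {limit: 0.03,   units: ppm}
  bacteria: {limit: 600.0,  units: CFU/m3}
  fungi:    {limit: 500.0,  units: CFU/m3}
  NO2:      {limit: 5.0,    units: ppm}
  SO2:      {limit: 0.06,   units: ppm}
  H2S:      {limit: 1.0,    units: ppm}
  "NO":     {limit: 25.0,   units: ppm}
  NOx:      {limit: 10.0,   units: ppm}
  TRS:      {limit: 10.0,   units: ppm}
# Multiple of the limit treated as the hazardous node (sub-index 25).
hazardous_multiple: 2.0
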