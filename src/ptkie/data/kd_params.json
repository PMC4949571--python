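{
  "kd0": 3.7,
  "kd0_err": 0.4,
  "dV": -15.9,
  "dV_err": 3.6,
  "dBeta": 12.5,
  "dBeta_err": 2.5,
  "temperature_K": 298.15,
  "units": {
    "kd0": "uM",
    "dV": "cm^3/mol",
    "dBeta": "cm^3/(mol*kbar)"
  }
}
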