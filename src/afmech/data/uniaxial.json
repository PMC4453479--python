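{
  "label": "uniaxial",
  "c10_mpa": 0.035,
  "k1_mpa": 0.296,
  "k2": 65.0,
  "kappa": 0.0,
  "fiber_angle_deg": 30.0
}
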