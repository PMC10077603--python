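model_type: lms
outcome: fev1
sex: F
model_id: truth_fev1_F
m:
  b0: -7.370636
  b1: 1.95
  b2: -0.402365
s:
  b0: -3.598
  b1: 0.409
L: 1.0
age_range:
- 20.0
- 90.0
m_spline: null
s_spline: null
provenance:
  tool: spirolms
  version: 0.1.0
  seed: 0
  config_sha256: f0ec4f552e40c9b3
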