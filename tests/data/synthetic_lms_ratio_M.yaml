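model_type: lms
outcome: ratio
sex: M
model_id: truth_ratio_M
m:
  b0: 0.9864440000000005
  b1: -0.15000000000000013
  b2: -0.12305000000000002
s:
  b0: -4.2248
  b1: 0.4135
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
  config_sha256: 2b8b6f22cead0abc
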