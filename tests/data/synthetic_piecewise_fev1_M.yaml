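model_type: piecewise
outcome: fev1
sex: M
model_id: olin_like
reference_height: 170.0
segments:
- age_interval:
  - 20.0
  - 50.0
  mean_terms:
  - - 0
    - 0
    - 0.5
  - - 1
    - 0
    - 0.02
  - - 2
    - 0
    - -0.0003
  - - 3
    - 0
    - 1.0e-06
  - - 0
    - 1
    - 0.01
  sd_terms:
  - - 0
    - 0
    - 0.4
- age_interval:
  - 50.0
  - 90.0
  mean_terms:
  - - 0
    - 0
    - 0.0
  - - 1
    - 0
    - 0.04
  - - 2
    - 0
    - -0.0005
  - - 3
    - 0
    - 1.0e-06
  - - 0
    - 1
    - 0.01
  sd_terms:
  - - 0
    - 0
    - 0.4
provenance:
  tool: spirolms
  version: 0.1.0
  seed: 0
  config_sha256: 6f35831d99708913
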