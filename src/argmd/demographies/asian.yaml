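# Asian demography — APPROXIMATE calibration.
# Same event scaffold as the European model with a somewhat stronger
# founder bottleneck; values are round approximations, not a fit.
name: asian
description: >
  Asian population: expansion to 100k at 400 generations, founder
  bottleneck (N_e 1000 for 100 generations) at 2000 generations,
  out-of-Africa merge into the African ancestor at 3500 generations.
  Approximate values.
populations:
  - id: ASN
    initial_size: 100000
  - id: AFR
    initial_size: 100000
events:
  - {time: 200, type: size_change, population: AFR, size: 24000}
  - {time: 400, type: size_change, population: ASN, size: 7700}
  - {time: 2000, type: bottleneck, population: ASN, size: 1000, duration: 100}
  - {time: 3500, type: split, population: ASN, into: AFR}
  - {time: 17000, type: size_change, population: AFR, size: 12500}
sampling:
  ASN: 1.0
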