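# European demography — APPROXIMATE calibration.
# Recent expansion, founder bottleneck, out-of-Africa split (backward
# merge into AFR), and the deep ancestral size increase carried by the
# African ancestor.  Values are round approximations, not a fit.
name: european
description: >
  European population: expansion to 100k at 350 generations, founder
  bottleneck (N_e 1500 for 100 generations) at 2000 generations,
  out-of-Africa merge into the African ancestor at 3500 generations.
  Approximate values.
populations:
  - id: EUR
    initial_size: 100000
  - id: AFR
    initial_size: 100000
events:
  - {time: 200, type: size_change, population: AFR, size: 24000}
  - {time: 350, type: size_change, population: EUR, size: 7700}
  - {time: 2000, type: bottleneck, population: EUR, size: 1500, duration: 100}
  - {time: 3500, type: split, population: EUR, into: AFR}
  - {time: 17000, type: size_change, population: AFR, size: 12500}
sampling:
  EUR: 1.0
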