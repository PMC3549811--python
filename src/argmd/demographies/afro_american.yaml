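# Afro-American demography — APPROXIMATE calibration.
# Recently admixed population: going backward, each sampled lineage moves
# to the African source with probability 0.8 and the European source with
# probability 0.2 at 13 generations ago.  The sources carry the African
# and European histories of the other shipped configs.  Values are round
# approximations, not a fit.
name: afro_american
description: >
  Admixed Afro-American population (80% African / 20% European ancestry,
  admixture 13 generations ago) over the African and European source
  histories.  Approximate values.
populations:
  - id: AA
    initial_size: 100000
  - id: AFR
    initial_size: 100000
  - id: EUR
    initial_size: 100000
events:
  - {time: 13, type: admixture, population: AA, sources: {AFR: 0.8, EUR: 0.2}}
  - {time: 200, type: size_change, population: AFR, size: 24000}
  - {time: 350, type: size_change, population: EUR, size: 7700}
  - {time: 2000, type: bottleneck, population: EUR, size: 1500, duration: 100}
  - {time: 3500, type: split, population: EUR, into: AFR}
  - {time: 17000, type: size_change, population: AFR, size: 12500}
sampling:
  AA: 1.0
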