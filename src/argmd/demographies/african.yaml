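# African demography — APPROXIMATE calibration.
# Human-like piecewise model assembled from the standard event types
# (recent effective-size increase, ancient effective-size increase).
# Parameter values are round literature-style figures, not a fitted
# calibration; times are generations before present, sizes are haploid-
# lineage effective sizes N_e as used by the coalescent rate 1/(2 N_e).
name: african
description: >
  Single African population: present-day expansion to 100k at 200
  generations ago, long-term size 24k, ancestral size 12.5k beyond 17k
  generations.  Approximate values.
populations:
  - id: AFR
    initial_size: 100000
events:
  - {time: 200, type: size_change, population: AFR, size: 24000}
  - {time: 17000, type: size_change, population: AFR, size: 12500}
sampling:
  AFR: 1.0
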