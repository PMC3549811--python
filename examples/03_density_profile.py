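"""History density and estimable density as functions of depth.

Binning node ages into epochs (in generations) gives the history density
N_d — how many genetic events fall in each depth range — and the estimable
density f_d = Ñ_d / N_d, the per-epoch share of events the minimal
descriptor retains.  Event density decays roughly exponentially with depth,
so logarithmic epochs keep the bins informative.
"""

from argmd import (
    EpochGrid,
    SimulationConfig,
    density_profile,
    load_demography,
    minimal_descriptor,
    simulate_topology,
)

config = SimulationConfig(
    demography=load_demography("african"),
    sample_size=60,
    sequence_length_bp=30_000,
    recombination_rate=2.1,
    topology_seed=21,
)
arg = simulate_topology(config)
md = minimal_descriptor(arg)
grid = EpochGrid.logarithmic(arg.max_age(), bins=12)
profile = density_profile(arg, md, grid)

frame = profile.to_frame()
frame["epoch_lo"] = frame["epoch_lo"].round(0)
frame["epoch_hi"] = frame["epoch_hi"].round(0)
print(frame.to_string(index=False, na_rep=".", float_format=lambda v: f"{v:.3f}"))
print(f"\ntotals: N = {profile.n_d.sum()}, Ñ = {profile.n_md_d.sum()} "
      "(per-epoch counts sum exactly to the global ones)")
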