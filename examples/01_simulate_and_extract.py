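"""Simulate one ARG under the European demography and bound its estimability.

The penetrable fraction f = Ñ/N compares the node count of the minimal
descriptor (the structure- and samples-preserving core) with that of the
full ARG: no reconstruction method, however clever, can recover more than
the fraction f of the history's nodes, so 1 - f of the common genetic
history is impenetrable.
"""

from collections import Counter

from argmd import (
    SimulationConfig,
    count_nodes,
    estimable_fraction,
    load_demography,
    minimal_descriptor,
    simulate,
)

config = SimulationConfig(
    demography=load_demography("european"),
    sample_size=30,          # haploid sequences
    sequence_length_bp=30_000,
    mutation_rate=1.5e-8,    # per bp per generation
    recombination_rate=1.3,  # cM/Mb, the human genome-wide average
    topology_seed=11,
    mutation_seed=12,
)
arg = simulate(config)
md = minimal_descriptor(arg)
f = estimable_fraction(arg, md)

print(f"simulated ARG: {len(arg.nodes)} nodes, {len(arg.edges)} edges, "
      f"{len(arg.breakpoints)} nonmixing segments, {arg.num_mutations()} mutations")
print(f"history nodes N = {count_nodes(arg)}, minimal descriptor Ñ = {count_nodes(md.arg)}")
reasons = Counter(r.reason for r in md.removal_log)
print(f"removed: {reasons['not_t_coalescent']} sterile coalescences, {reasons['chain']} chains")
print(f"penetrable fraction f = {f:.3f}  ->  at least {1 - f:.1%} of this history "
      "is beyond any reconstruction method")
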