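# Methods

## The measure of genetic history

An ancestral recombination graph (ARG) over n sampled haploid sequences is
a dated DAG: leaves are the samples (age 0), internal nodes are genetic
events (common-ancestor or recombination), edges point toward the present
and carry the half-open intervals of sequence — normalized to [0, 1] —
that flow through them and are ancestral to at least one sample.  The
amount of relevant history is measured by the node count N (non-leaf nodes
by default; see *Counting rule*).  Crossover positions partition the
sequence into nonmixing segments; the genealogy of each segment (its
marginal tree) is embedded in the graph.

The minimal descriptor G′ of an ARG G is a substructure that preserves the
topology and branch lengths of every marginal tree and the genotype
patterns of the samples.  Writing Ñ for its node count, f = Ñ/N bounds
from above the fraction of history any reconstruction method can recover,
and 1 − f bounds the impenetrable remainder from below.

## Extraction algorithm

1. **Classification.**  Node labels are pure degree functions counting
   edges (parallel edges count separately): leaf (out-degree 0),
   exchange (in ≥ 2, out 1), chain (in ≤ 1, out 1), coalescent (in ≤ 1,
   out ≥ 2), hybrid (in ≥ 2, out ≥ 2).
2. **t-coalescent test.**  A coalescent (or hybrid) node branches in some
   marginal tree iff two of its child edges carry overlapping material —
   an interval sweep, no tree construction needed.  The status is cached
   the first time a node is tested: removals preserve every marginal tree,
   so it can never change.
3. **Removal.**  To remove a single-parent node v, each child edge
   v→w is replaced by u→w (u the parent) with the same material;
   mutations on u→v are pushed down onto every new edge whose material
   contains their position, and mutations on v→w stay put.  When
   rewiring leaves two parallel edges between one (u, w) pair they are
   merged and their materials united.  Multi-parent nodes are never
   removed.
4. **Fixpoint.**  Sweeps alternate — all current single-parent coalescent
   nodes failing the t-coalescent test (youngest first, ties by id), then
   all current chains — until neither applies.  Parallel-edge merging is
   the one mechanism by which degrees shrink, so a node that began as an
   exchange node can surface later as a removable coalescent node or
   chain; this is why a resolved recombination "diamond" (a crossover
   whose products immediately re-coalesce) collapses out entirely, and why
   single passes are not enough.  A node that is a chain with no parent
   (a local root that stopped branching) is deleted outright.

Removal-phase semantics use *current* degrees: the exemption for
coalescent-and-exchange (hybrid) nodes applies while the node actually has
two or more parents, which is exactly when the removal step is undefined
for it.  The final node set is empirically independent of sweep order
(property-tested by running youngest-first against oldest-first), though
uniqueness of minimal descriptors is not a theorem: any one of them yields
a valid upper bound f.

Correctness is enforced by a master oracle, `verify_structure_preserving`:
for every nonmixing segment of G, the marginal trees of G and G′ must
agree in topology, node ids and ages exactly, and the genotype matrices
must coincide (sites compared by position and carrier pattern — extraction
may re-home a mutation onto a rewired edge without changing who carries
it).

## The simulator

Backward-time Hudson coalescent with recombination, continuous time in
generations.

* **Coalescence.**  Within a population of current effective size N_e,
  each lineage pair merges at rate 1/(2 N_e); k lineages give total rate
  k(k−1)/(4 N_e).  For a pair of samples this yields E[TMRCA] = 2 N_e
  generations, the calibration the analytic tests pin down.
* **Recombination.**  A lineage recombines at rate r·(bp span of its
  ancestral-material hull), r the per-bp per-generation crossover rate
  (1 cM/Mb = 10⁻⁸).  The crossover position is uniform on the hull.  A
  position strictly inside the hull always separates two non-empty
  lineages and is accepted — including positions inside interior gaps of
  trapped (non-ancestral) material, which is the standard Hudson
  behaviour: such events rearrange linkage but leave no mark in the
  material annotations, so they create an exchange node without a new
  nonmixing-segment boundary.  Proposals that would split off an empty
  lineage (possible only at the hull's endpoints, a measure-zero event)
  are rejected, so no dead lineages ever enter the graph.
* **Fixation.**  Lineage material carries per-interval sample counts; a
  stretch whose count reaches n has found its local MRCA and is dropped.
  The run ends when all material has fixed — no events are generated above
  segment MRCAs, so every node in the output is on some sample's ancestral
  path.  A hard event cap (default 10⁶) aborts pathological configurations
  with a resource error naming the cap.
* **Demography.**  Piecewise model compiled from four event types:
  size change, bottleneck (a size drop for a stated duration, then
  restoration to the pre-bottleneck size), split (backward merge of one
  population into another), and admixture (each lineage of the admixed
  population moves independently to a source population with the stated
  probabilities).  Event times are generations before present, strictly
  positive and sorted; sizes positive; admixture proportions in (0, 1)
  summing to 1.  Size changes scheduled inside a bottleneck window are
  overridden by the restoration — place none there.
* **Mutations.**  A second pass, seeded independently of the topology,
  drops a Poisson number of mutations on each edge with mean
  μ · L · (edge length) · (material width), positions uniform within the
  edge's material.  Because topology and mutation streams are decoupled,
  f is *bit-identical* across mutation rates at a fixed topology seed — an
  exact property, tested as such, rather than a statistical one.

Sampling weights in a demography are relative and rescaled to the
requested sample size by largest remainder, so one demography file serves
every point of a sample-size sweep.

### Shipped demographies

Four single-focal-population configurations approximate a calibrated human
demography (times in generations; sizes are N_e):

| name | key events |
|---|---|
| african | growth to 100k at 200; 24k long-term; 12.5k beyond 17,000 |
| european | growth to 100k at 350; 7.7k; bottleneck (1.5k × 100 gen) at 2,000; merges into the African ancestor at 3,500 |
| asian | as european with a stronger bottleneck (1k × 100 gen at 2,000) |
| afro_american | 80/20 African/European admixture at 13; source histories as above |

The values are round, literature-style approximations chosen once — not a
fitted calibration — and the YAML files say so.  Published calibrations of
this kind are tuned to linkage-disequilibrium patterns of real data;
nothing here depends on that level of fidelity, but absolute levels of f
do depend on the effective sizes through the population-scaled
recombination rate.

## Estimability statistics

* **Counting rule.**  N and Ñ count non-leaf nodes: leaves are the extant
  samples, present in both graphs by construction, and counting them would
  only dilute f toward 1.  Every counting function takes
  ``include_leaves`` (CLI: ``--count-leaves``) to flip the rule.
* **Epoch grids.**  Depth bins covering [0, max age], linear or
  logarithmic (default 25 log bins; event density decays roughly
  exponentially with depth, so log bins stay informative).  The log grid's
  first bin starts at 0 and its geometric part starts at max age / 1000.
  The last bin is closed so the oldest node is always counted.  Empty
  epochs report f_d as missing (NaN / "." in TSV), never a coerced 0, and
  per-epoch counts sum exactly to N and Ñ.
* **Sweeps.**  One row per (demography, μ, L, n, r) × replicate.  Cell
  statistics aggregate replicates (mean, standard error across replicates
  only).  The marginal curve for one parameter averages the *cell means*
  over all values of the other parameters — cells weigh equally regardless
  of replicate imbalance.  Per-replicate seeds derive from
  SeedSequence(master, cell index, replicate), so any cell can be re-run
  alone; identical grids produce byte-identical TSVs.  Cells exceeding the
  event cap are recorded as skipped with their reason.

## What the generator does and does not emulate

It emulates the features that drive estimability: a structured, piecewise
human-like demography; genome-scale recombination with trapped-material
crossovers; per-position coalescence to local MRCAs; decoupled mutation
overlay.  It does not model gene conversion, continuous migration,
variable recombination maps, or selection — and it emits *only
consequential* nodes: every node in its output lies on an ancestral path
of some sample.  Full event logs of generation-stepping simulators can
additionally contain bookkeeping structure (dead lineages, events above
local MRCAs, migration way-points) that a minimal-descriptor extraction
would strip; measured on such logs, f is systematically lower than on the
clean graphs produced here.  Passing tests therefore demonstrate the
behaviour of the bound on exact Hudson-model ARGs, not on any particular
simulator's log dialect, and absolute f levels quoted anywhere in this
package are tied to the shipped demographies and the stated parameter
ranges.

At the settings the acceptance script runs (n = 120, L = 30 kb,
r = 1.3 cM/Mb, four demographies × 10 replicates), it measures a
large-sample plateau of f ≈ 0.83; an independent Hudson implementation
(msprime with full-ARG recording, converted to this package's format and
run through the same extraction) reproduces the same level at matched
parameters, which localizes any discrepancy with log-derived estimates in
the input ARGs, not in the extraction.

## Numerical choices, determinism, degenerate inputs

* Coordinates are floats copied, never recomputed, so exact comparisons of
  breakpoints and material endpoints are sound; crossover collisions have
  probability zero and hand fixtures avoid them.
* Removal candidates sort by (age, node id) — youngest first — making runs
  reproducible; ages tie only in hand-built graphs.
* Mutation columns order by (position, carrying edge's child id).
* `validate_arg` returns a list of named violations instead of raising:
  parsers raise on malformed documents, the validator reports on
  well-formed but inconsistent graphs (age inversions, material outside
  breakpoint boundaries, ambiguous upward paths, missing per-position
  MRCAs).  Graphs whose genomic sectors fix in different lineages have
  several zero-in-degree nodes; validation requires a unique MRCA per
  position, not a unique global root.
* Degenerate inputs: sample sizes below 2 and empty-material edges are
  configuration errors; a single-sample graph has no countable history and
  f is undefined (raised, not returned as 0/0).

## Problem sizes

Test-suite simulations run at desk scale, chosen as reductions that keep
every qualitative contrast measurable: the structure-preservation corpus
covers 200 seeds at the corners of the parameter grid up to 50 kb and 60
samples; trend sweeps use a 3×3×3 grid (5–75 kb, 5–120 samples,
0.5–2.5 cM/Mb) with 10 replicates per cell; analytic calibrations use
2,000 replicates.  The full published-scale design (hundreds of cells, up
to 200 kb) is expressible in the same GridSpec YAML for larger machines.
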