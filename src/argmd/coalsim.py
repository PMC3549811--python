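"""Backward-time coalescent-with-recombination simulator with piecewise demography.

Generates complete ARGs (topology, node ages, edge ancestral material) for a
sample of haploid sequences under a structured, piecewise-constant population
model, then drops mutations in a second, independently seeded pass.  The
model is the standard Hudson coalescent with recombination:

* within a population of current effective size ``N_e``, each pair of
  lineages coalesces at rate ``1 / (2 N_e)`` per generation, so ``k``
  lineages coalesce at total rate ``k (k-1) / (4 N_e)``;
* a lineage recombines at rate (per-bp crossover rate) x (bp span of the
  hull of its ancestral material), with the crossover position uniform on
  the hull; a crossover strictly inside the hull always separates two
  non-empty lineages and is accepted — including crossovers falling in
  interior gaps of trapped (non-ancestral) material, which rearrange
  linkage without leaving a trace in the material annotations — while
  proposals that would split off an empty lineage are rejected, so no dead
  lineages are ever created;
* the demography is a time-ordered schedule of size changes, bottlenecks,
  backward-merging splits, and admixture events;
* per genomic position the process halts at that position's local MRCA:
  fixed material is dropped from lineages, and the run ends when every
  position has fixed.  No events above segment MRCAs are generated.

Time is continuous and reported in generations; sequence coordinates are
normalized to [0, 1].  Two RNG streams (``topology_seed``,
``mutation_seed``) decouple the graph from its mutation annotation, making
"the penetrable fraction is invariant to the mutation rate" an exact
property of the implementation rather than a statistical one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from . import intervals as iv
from .arg import Arg, ArgEdge, ArgNode, material_breakpoints

#: 1 centimorgan per megabase, expressed as crossover probability per bp per generation.
CM_PER_MB = 1.0e-8

EVENT_TYPES = ("size_change", "bottleneck", "split", "admixture")


class ConfigError(ValueError):
    """Invalid simulation or demography configuration."""


class ResourceError(RuntimeError):
    """The simulation exceeded its event cap before completing."""


# -- demography ------------------------------------------------------------


@dataclass(frozen=True)
class DemographyEvent:
    """One demographic transition, dated in generations before present.

    ``size_change``: ``population`` takes effective size ``size`` for all
    older times (until an older event overrides it).
    ``bottleneck``: ``population`` drops to ``size`` for ``duration``
    generations, then returns to its pre-bottleneck size.
    ``split``: going backward, all lineages of ``population`` merge into
    ``into`` (forward in time, ``population`` was founded from ``into``).
    ``admixture``: going backward, each lineage of ``population`` moves to
    source population ``p`` with probability ``sources[p]``.
    """

    time: float
    type: str
    population: str
    size: Optional[float] = None
    duration: Optional[float] = None
    into: Optional[str] = None
    sources: Optional[dict[str, float]] = None


@dataclass(frozen=True)
class DemographyConfig:
    """Piecewise population model: initial sizes, events, sampling weights."""

    name: str
    populations: tuple[tuple[str, float], ...]  # (id, present-day size)
    events: tuple[DemographyEvent, ...] = ()
    sampling: tuple[tuple[str, float], ...] = ()  # (population, relative weight)
    description: str = ""

    def population_ids(self) -> list[str]:
        return [p for p, _ in self.populations]

    def validate(self) -> None:
        pops = self.population_ids()
        if not pops:
            raise ConfigError("demography has no populations")
        if len(set(pops)) != len(pops):
            raise ConfigError("duplicate population ids")
        for p, size in self.populations:
            if size <= 0:
                raise ConfigError(f"population {p}: non-positive size {size}")
        times = [e.time for e in self.events]
        if any(t <= 0 for t in times):
            raise ConfigError("event times must be strictly positive")
        if times != sorted(times):
            raise ConfigError("events must be sorted by time")
        for e in self.events:
            if e.type not in EVENT_TYPES:
                raise ConfigError(f"unknown event type {e.type!r}")
            if e.population not in pops:
                raise ConfigError(f"event at t={e.time} names unknown population {e.population!r}")
            if e.type in ("size_change", "bottleneck"):
                if e.size is None or e.size <= 0:
                    raise ConfigError(f"{e.type} at t={e.time}: size must be positive")
            if e.type == "bottleneck" and (e.duration is None or e.duration <= 0):
                raise ConfigError(f"bottleneck at t={e.time}: duration must be positive")
            if e.type == "split":
                if e.into not in pops:
                    raise ConfigError(f"split at t={e.time}: unknown destination {e.into!r}")
                if e.into == e.population:
                    raise ConfigError(f"split at t={e.time}: population cannot merge into itself")
            if e.type == "admixture":
                if not e.sources:
                    raise ConfigError(f"admixture at t={e.time}: no sources")
                props = list(e.sources.values())
                if any(not (0.0 < p < 1.0) for p in props):
                    raise ConfigError(f"admixture at t={e.time}: proportions must be in (0, 1)")
                if abs(sum(props) - 1.0) > 1e-9:
                    raise ConfigError(f"admixture at t={e.time}: proportions must sum to 1")
                for src in e.sources:
                    if src not in pops:
                        raise ConfigError(f"admixture at t={e.time}: unknown source {src!r}")
        weights = dict(self.sampling) or {pops[0]: 1.0}
        for p, w in weights.items():
            if p not in pops:
                raise ConfigError(f"sampling names unknown population {p!r}")
            if w < 0:
                raise ConfigError(f"sampling weight for {p} is negative")
        if sum(weights.values()) <= 0:
            raise ConfigError("sampling weights sum to zero")

    def sample_counts(self, sample_size: int) -> dict[str, int]:
        """Distribute ``sample_size`` haploid samples by the sampling weights.

        Weights are relative; counts are assigned by largest remainder so the
        total is exact, with ties broken by population order.
        """
        weights = dict(self.sampling) or {self.population_ids()[0]: 1.0}
        total = sum(weights.values())
        quota = {p: sample_size * w / total for p, w in weights.items()}
        counts = {p: int(math.floor(q)) for p, q in quota.items()}
        leftover = sample_size - sum(counts.values())
        order = sorted(quota, key=lambda p: (-(quota[p] - counts[p]), p))
        for p in order[:leftover]:
            counts[p] += 1
        return {p: c for p, c in counts.items() if c > 0}

    @classmethod
    def from_dict(cls, doc: dict) -> "DemographyConfig":
        try:
            pops = tuple((str(p["id"]), float(p["initial_size"])) for p in doc["populations"])
            events = tuple(
                DemographyEvent(
                    time=float(e["time"]),
                    type=str(e["type"]),
                    population=str(e["population"]),
                    size=float(e["size"]) if "size" in e else None,
                    duration=float(e["duration"]) if "duration" in e else None,
                    into=str(e["into"]) if "into" in e else None,
                    sources={str(k): float(v) for k, v in e["sources"].items()} if "sources" in e else None,
                )
                for e in doc.get("events", [])
            )
            sampling = tuple((str(k), float(v)) for k, v in (doc.get("sampling") or {}).items())
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"malformed demography: {exc}") from exc
        cfg = cls(
            name=str(doc.get("name", "unnamed")),
            populations=pops,
            events=events,
            sampling=sampling,
            description=str(doc.get("description", "")),
        )
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        out = {
            "name": self.name,
            "description": self.description,
            "populations": [{"id": p, "initial_size": s} for p, s in self.populations],
            "events": [],
            "sampling": dict(self.sampling),
        }
        for e in self.events:
            doc = {"time": e.time, "type": e.type, "population": e.population}
            if e.size is not None:
                doc["size"] = e.size
            if e.duration is not None:
                doc["duration"] = e.duration
            if e.into is not None:
                doc["into"] = e.into
            if e.sources is not None:
                doc["sources"] = dict(e.sources)
            out["events"].append(doc)
        return out


def constant_demography(effective_size: float = 10_000.0, name: str = "constant") -> DemographyConfig:
    """A single panmictic population of constant effective size."""
    return DemographyConfig(name=name, populations=(("POP", float(effective_size)),), sampling=(("POP", 1.0),))


def load_demography(source: Union[str, Path, dict]) -> DemographyConfig:
    """Load a demography from a dict, a YAML file path, or a shipped name."""
    if isinstance(source, dict):
        return DemographyConfig.from_dict(source)
    path = Path(source)
    if path.suffix in (".yaml", ".yml") or path.exists():
        with open(path) as fh:
            return DemographyConfig.from_dict(yaml.safe_load(fh))
    if source == "constant":
        return constant_demography()
    pkg_file = resources.files("argmd").joinpath(f"demographies/{source}.yaml")
    if pkg_file.is_file():
        return DemographyConfig.from_dict(yaml.safe_load(pkg_file.read_text()))
    raise ConfigError(f"unknown demography {source!r}")


def bestfit_like_demographies() -> dict[str, DemographyConfig]:
    """The four shipped human-like demographies, keyed by population name.

    Approximations to a calibrated human model built from four event types:
    recent effective-size increase, founder bottleneck, out-of-Africa split,
    and ancient effective-size increase, plus recent admixture for the
    Afro-American configuration.  Parameter values live in the shipped
    ``demographies/*.yaml`` files and are documented there as approximate.
    """
    return {name: load_demography(name) for name in ("african", "european", "asian", "afro_american")}


# -- simulation configuration ---------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """One simulation run: demography, rates, sizes, and the two seeds."""

    demography: DemographyConfig
    sequence_length_bp: int = 30_000
    mutation_rate: float = 1.5e-8  # per bp per generation
    recombination_rate: float = 1.3  # cM/Mb
    sample_size: int = 30
    topology_seed: int = 1
    mutation_seed: int = 1
    event_cap: int = 1_000_000

    def validate(self) -> None:
        self.demography.validate()
        if self.sequence_length_bp < 1:
            raise ConfigError("sequence_length_bp must be >= 1")
        if self.sample_size < 2:
            raise ConfigError("sample_size must be >= 2")
        if self.mutation_rate < 0 or self.recombination_rate < 0:
            raise ConfigError("rates must be non-negative")
        if self.event_cap < 1:
            raise ConfigError("event_cap must be positive")

    def provenance(self) -> dict:
        return {
            "sequence_length_bp": self.sequence_length_bp,
            "demography": self.demography.name,
            "mutation_rate": self.mutation_rate,
            "recombination_rate_cM_Mb": self.recombination_rate,
            "sample_size": self.sample_size,
            "topology_seed": self.topology_seed,
            "mutation_seed": self.mutation_seed,
        }


# -- compiled demographic schedule -----------------------------------------


def _compile_schedule(demog: DemographyConfig) -> list[tuple[float, str, tuple]]:
    """Flatten the demography into dated instructions for the event loop.

    Bottlenecks expand into a size drop plus a restoration to the size in
    effect when the bottleneck began (size changes scheduled *inside* a
    bottleneck window are overridden by the restoration).
    """
    sizes = {p: s for p, s in demog.populations}
    sched: list[tuple[float, str, tuple]] = []
    current: dict[str, float] = dict(sizes)
    for e in demog.events:
        if e.type == "size_change":
            sched.append((e.time, "size", (e.population, e.size)))
            current[e.population] = e.size
        elif e.type == "bottleneck":
            restore = current[e.population]
            sched.append((e.time, "size", (e.population, e.size)))
            sched.append((e.time + e.duration, "size", (e.population, restore)))
        elif e.type == "split":
            sched.append((e.time, "move_all", (e.population, e.into)))
        elif e.type == "admixture":
            dests = sorted(e.sources.items())
            sched.append((e.time, "admix", (e.population, tuple(dests))))
    sched.sort(key=lambda item: item[0])
    return sched


# -- counted-segment algebra ----------------------------------------------

# A lineage's ancestral material is a sorted disjoint list of
# (start, end, count) triples: `count` is the number of samples descending
# from the lineage on that stretch of sequence.  A stretch fixes (reaches its
# local MRCA) when the count hits the total sample size.


def _merge_counted(a: list, b: list, n_total: int) -> list:
    """Sum two counted-segment lists, dropping stretches that fix at n_total."""
    pts = sorted({x for s, e, _ in a for x in (s, e)} | {x for s, e, _ in b for x in (s, e)})
    out: list[tuple[float, float, int]] = []
    ia = ib = 0
    for lo, hi in zip(pts, pts[1:]):
        c = 0
        while ia < len(a) and a[ia][1] <= lo:
            ia += 1
        if ia < len(a) and a[ia][0] <= lo < a[ia][1]:
            c += a[ia][2]
        while ib < len(b) and b[ib][1] <= lo:
            ib += 1
        if ib < len(b) and b[ib][0] <= lo < b[ib][1]:
            c += b[ib][2]
        if 0 < c < n_total:
            if out and out[-1][1] == lo and out[-1][2] == c:
                out[-1] = (out[-1][0], hi, c)
            else:
                out.append((lo, hi, c))
    return out


def _segments_to_material(segs: Sequence[tuple[float, float, int]]) -> iv.IntervalList:
    """Forget the counts; coalesce abutting stretches into plain intervals."""
    return iv.canonical((s, e) for s, e, _ in segs)


@dataclass
class _Lineage:
    node: int
    pop: str
    segs: list  # counted segments


# -- the simulator ---------------------------------------------------------


def simulate_topology(config: SimulationConfig) -> Arg:
    """Simulate the ARG topology: nodes, ages, edges and ancestral material.

    Deterministic given ``config.topology_seed``; carries no mutations (see
    :func:`drop_mutations`).  Raises :class:`ResourceError` if the event
    count exceeds ``config.event_cap``.
    """
    config.validate()
    rng = np.random.default_rng(config.topology_seed)
    demog = config.demography
    sched = _compile_schedule(demog)
    sizes = {p: float(s) for p, s in demog.populations}
    n_total = config.sample_size
    r_per_gen = config.recombination_rate * CM_PER_MB * config.sequence_length_bp

    nodes: list[ArgNode] = []
    edges: list[ArgEdge] = []
    n_crossovers = 0
    n_material_crossovers = 0
    lineages: list[_Lineage] = []
    counts = demog.sample_counts(n_total)
    for pop in demog.population_ids():
        for _ in range(counts.get(pop, 0)):
            nid = len(nodes)
            nodes.append(ArgNode(nid, 0.0, True))
            lineages.append(_Lineage(nid, pop, [(0.0, 1.0, 1)]))
    samples = [n.id for n in nodes]

    t = 0.0
    sched_i = 0
    n_events = 0
    while lineages:
        n_events += 1
        if n_events > config.event_cap:
            raise ResourceError(
                f"simulation exceeded the event cap of {config.event_cap} events "
                f"at t={t:.1f} with {len(lineages)} open lineages"
            )
        by_pop: dict[str, list[int]] = {}
        for i, lin in enumerate(lineages):
            by_pop.setdefault(lin.pop, []).append(i)
        coal_rates = []
        for pop in sorted(by_pop):
            k = len(by_pop[pop])
            if k >= 2:
                coal_rates.append((pop, k * (k - 1) / 2.0 / (2.0 * sizes[pop])))
        hull_widths = [lin.segs[-1][1] - lin.segs[0][0] for lin in lineages]
        recomb_rate = r_per_gen * sum(hull_widths)
        total = sum(r for _, r in coal_rates) + recomb_rate

        next_sched = sched[sched_i][0] if sched_i < len(sched) else math.inf
        wait = rng.exponential(1.0 / total) if total > 0 else math.inf
        if t + wait >= next_sched:
            t = next_sched
            _, kind, payload = sched[sched_i]
            sched_i += 1
            if kind == "size":
                pop, size = payload
                sizes[pop] = float(size)
            elif kind == "move_all":
                src, dst = payload
                for lin in lineages:
                    if lin.pop == src:
                        lin.pop = dst
            elif kind == "admix":
                src, dests = payload
                pops = [d for d, _ in dests]
                probs = np.array([p for _, p in dests])
                probs = probs / probs.sum()
                for lin in lineages:
                    if lin.pop == src:
                        lin.pop = pops[rng.choice(len(pops), p=probs)]
            continue

        t += wait
        u = rng.uniform(0.0, total)
        acc = 0.0
        chosen_pop = None
        for pop, r in coal_rates:
            acc += r
            if u < acc:
                chosen_pop = pop
                break
        if chosen_pop is not None:
            idxs = by_pop[chosen_pop]
            i = int(rng.integers(len(idxs)))
            j = int(rng.integers(len(idxs) - 1))
            if j >= i:
                j += 1
            a, b = lineages[idxs[i]], lineages[idxs[j]]
            nid = len(nodes)
            nodes.append(ArgNode(nid, t, False))
            edges.append(ArgEdge(nid, a.node, _segments_to_material(a.segs)))
            edges.append(ArgEdge(nid, b.node, _segments_to_material(b.segs)))
            merged = _merge_counted(a.segs, b.segs, n_total)
            for idx in sorted((idxs[i], idxs[j]), reverse=True):
                lineages.pop(idx)
            if merged:
                lineages.append(_Lineage(nid, chosen_pop, merged))
        else:
            # recombination: pick a lineage weighted by its hull width
            w = u - sum(r for _, r in coal_rates)
            target = w / r_per_gen
            acc_w = 0.0
            li = len(lineages) - 1
            for i, hw in enumerate(hull_widths):
                acc_w += hw
                if target < acc_w:
                    li = i
                    break
            lin = lineages[li]
            lo, hi = lin.segs[0][0], lin.segs[-1][1]
            x = rng.uniform(lo, hi)
            material = _segments_to_material(lin.segs)
            if not (lo < x < hi):
                continue  # would split off an empty lineage: rejected
            n_crossovers += 1
            if iv.strictly_inside(material, x):
                n_material_crossovers += 1  # x becomes a nonmixing-segment boundary
            nid = len(nodes)
            nodes.append(ArgNode(nid, t, False))
            edges.append(ArgEdge(nid, lin.node, material))
            left = [(s, min(e, x), c) for s, e, c in lin.segs if s < x]
            right = [(max(s, x), e, c) for s, e, c in lin.segs if e > x]
            lineages[li] = _Lineage(nid, lin.pop, left)
            lineages.append(_Lineage(nid, lin.pop, right))

    prov = config.provenance()
    prov["n_crossovers"] = n_crossovers
    prov["n_material_crossovers"] = n_material_crossovers
    return Arg(nodes, edges, samples, material_breakpoints(edges), prov)


def drop_mutations(
    arg: Arg,
    mutation_rate: float,
    sequence_length_bp: int,
    mutation_seed: int,
) -> Arg:
    """Place mutations on the edges of a mutation-free ARG.

    Each edge receives a Poisson number of mutations with mean
    ``mutation_rate x sequence_length_bp x edge length x material width``,
    positioned uniformly within the edge's ancestral material.  Deterministic
    given ``mutation_seed``; the topology is untouched.
    """
    if mutation_rate < 0:
        raise ConfigError("mutation_rate must be non-negative")
    if arg.num_mutations() > 0:
        raise ConfigError("ARG already carries mutations")
    rng = np.random.default_rng(mutation_seed)
    new_edges = []
    for e in arg.edges:
        length = arg.nodes[e.parent].age - arg.nodes[e.child].age
        width = iv.total_width(e.material)
        lam = mutation_rate * sequence_length_bp * length * width
        k = int(rng.poisson(lam)) if lam > 0 else 0
        if k == 0:
            new_edges.append(e)
            continue
        offsets = np.sort(rng.uniform(0.0, width, size=k))
        positions = []
        base = 0.0
        oi = 0
        for a, b in e.material:
            span = b - a
            while oi < k and offsets[oi] < base + span:
                positions.append(a + (offsets[oi] - base))
                oi += 1
            base += span
        new_edges.append(ArgEdge(e.parent, e.child, e.material, tuple(positions)))
    prov = dict(arg.provenance)
    prov.update(mutation_rate=mutation_rate, mutation_seed=mutation_seed)
    return Arg(arg.nodes.values(), new_edges, arg.samples, arg.breakpoints, prov)


def simulate(config: SimulationConfig) -> Arg:
    """Topology plus mutations: the full simulation entry point."""
    arg = simulate_topology(config)
    return drop_mutations(arg, config.mutation_rate, config.sequence_length_bp, config.mutation_seed)
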