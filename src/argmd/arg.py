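"""Ancestral recombination graph (ARG) data model and queries.

An ARG records the complete genetic history relevant to a set of sampled
haploid sequences: each internal node is a dated genetic event (a common
ancestor or a recombination), and each edge carries the genomic intervals of
*sample-ancestral* material flowing from an older node (the parent) to a
younger one (the child), optionally annotated with mutations.

Coordinates are normalized to [0, 1] with half-open interval semantics.  The
recombination crossover positions partition the sequence into *nonmixing
segments*; within one segment every sample has a single unbroken line of
descent, so a single genealogy — the *marginal tree* — applies.

The module provides structural validation, the breakpoint partition, marginal
tree extraction (per position and for all segments at once), and the sample
genotype matrix implied by the mutations.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from . import intervals as iv
from .intervals import Interval, IntervalList


@dataclass(frozen=True)
class ArgNode:
    """A dated event in the ARG.  Samples (extant units) have age zero."""

    id: int
    age: float
    is_sample: bool = False


@dataclass(frozen=True)
class ArgEdge:
    """Flow of sequence material from ``parent`` (older) to ``child`` (younger).

    ``material`` is a canonical list of half-open [a, b) intervals ancestral
    to at least one sample; ``mutations`` are positions, each inside the
    material.  Edge length is ``age(parent) - age(child)``.
    """

    parent: int
    child: int
    material: IntervalList
    mutations: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "material", tuple((float(a), float(b)) for a, b in self.material))
        object.__setattr__(self, "mutations", tuple(float(m) for m in self.mutations))


NODE_KINDS = ("leaf", "coalescent", "exchange", "chain", "hybrid")


class Arg:
    """An ancestral recombination graph.

    Parallel edges between the same (parent, child) pair are permitted: they
    arise when both products of a recombination coalesce back with each other
    immediately, and the degree rules that classify nodes count *edges*, not
    distinct neighbours.
    """

    def __init__(
        self,
        nodes: Iterable[ArgNode],
        edges: Iterable[ArgEdge],
        samples: Iterable[int],
        breakpoints: Iterable[float],
        provenance: Optional[dict] = None,
    ) -> None:
        self.nodes: dict[int, ArgNode] = {n.id: n for n in nodes}
        self.edges: list[ArgEdge] = list(edges)
        self.samples: list[int] = list(samples)
        self.breakpoints: list[float] = [float(b) for b in breakpoints]
        self.provenance: dict = dict(provenance or {})
        self._children: Optional[dict[int, list[ArgEdge]]] = None
        self._parents: Optional[dict[int, list[ArgEdge]]] = None

    # -- adjacency ---------------------------------------------------------

    def _index(self) -> None:
        children: dict[int, list[ArgEdge]] = {n: [] for n in self.nodes}
        parents: dict[int, list[ArgEdge]] = {n: [] for n in self.nodes}
        for e in self.edges:
            children.setdefault(e.parent, []).append(e)
            parents.setdefault(e.child, []).append(e)
        self._children, self._parents = children, parents

    def children_edges(self, v: int) -> list[ArgEdge]:
        """Outgoing edges of ``v`` (toward the present)."""
        if self._children is None:
            self._index()
        return self._children[v]

    def parent_edges(self, v: int) -> list[ArgEdge]:
        """Incoming edges of ``v`` (from older ancestors)."""
        if self._parents is None:
            self._index()
        return self._parents[v]

    def out_degree(self, v: int) -> int:
        return len(self.children_edges(v))

    def in_degree(self, v: int) -> int:
        return len(self.parent_edges(v))

    def kind_of(self, v: int) -> str:
        """Degree-derived label of node ``v``.

        leaf: no outgoing edges; exchange: >=2 incoming, single outgoing;
        chain: one incoming (or none) and one outgoing; coalescent: <=1
        incoming and >=2 outgoing; hybrid: >=2 incoming and >=2 outgoing.
        """
        outd, ind = self.out_degree(v), self.in_degree(v)
        if outd == 0:
            return "leaf"
        if ind >= 2:
            return "hybrid" if outd >= 2 else "exchange"
        return "coalescent" if outd >= 2 else "chain"

    def max_age(self) -> float:
        return max(n.age for n in self.nodes.values())

    def num_mutations(self) -> int:
        return sum(len(e.mutations) for e in self.edges)

    def copy(self) -> "Arg":
        return Arg(self.nodes.values(), self.edges, self.samples, self.breakpoints, self.provenance)


# -- validation ------------------------------------------------------------


def validate_arg(arg: Arg) -> list[str]:
    """Check every structural invariant; return human-readable violations.

    An empty list means the ARG is well formed: ages strictly increase along
    edges, samples sit at age zero, material is canonical and mutation
    positions lie inside it, material boundaries align with the breakpoint
    partition, and at every position each sample has a unique upward path
    meeting the other samples at a single most recent common ancestor.
    """
    v: list[str] = []
    bp = arg.breakpoints
    if not bp or bp[-1] != 1.0:
        v.append("breakpoints must end at 1.0")
    if any(not (0.0 < b <= 1.0) for b in bp):
        v.append("breakpoints must lie in (0, 1]")
    if any(b1 >= b2 for b1, b2 in zip(bp, bp[1:])):
        v.append("breakpoints must be strictly increasing")

    sample_set = set(arg.samples)
    for n in arg.nodes.values():
        if n.age < 0:
            v.append(f"node {n.id}: negative age {n.age}")
        if n.is_sample and n.age != 0.0:
            v.append(f"node {n.id}: sample with nonzero age {n.age}")
        if n.is_sample and n.id not in sample_set:
            v.append(f"node {n.id}: flagged is_sample but missing from samples list")
    for s in arg.samples:
        if s not in arg.nodes:
            v.append(f"samples list names unknown node {s}")
        elif not arg.nodes[s].is_sample:
            v.append(f"node {s}: listed as sample but not flagged is_sample")

    boundary_ok = set(bp) | {0.0, 1.0}
    for i, e in enumerate(arg.edges):
        tag = f"edge {e.parent}->{e.child} (#{i})"
        if e.parent not in arg.nodes or e.child not in arg.nodes:
            v.append(f"{tag}: endpoint not in node set")
            continue
        if arg.nodes[e.parent].age <= arg.nodes[e.child].age:
            v.append(f"{tag}: parent age {arg.nodes[e.parent].age} not greater than child age {arg.nodes[e.child].age}")
        if not e.material:
            v.append(f"{tag}: empty material")
        elif not iv.is_canonical(e.material):
            v.append(f"{tag}: material not sorted/disjoint")
        if e.material and (e.material[0][0] < 0.0 or e.material[-1][1] > 1.0):
            v.append(f"{tag}: material outside [0, 1]")
        for a, b in e.material:
            if a not in boundary_ok or b not in boundary_ok:
                v.append(f"{tag}: material boundary inside a nonmixing segment ({a}, {b})")
        for m in e.mutations:
            if not iv.contains(e.material, m):
                v.append(f"{tag}: mutation at {m} outside edge material")

    for n in arg.nodes.values():
        if arg.out_degree(n.id) == 0 and not n.is_sample:
            v.append(f"node {n.id}: leaf that is not a sample (extraneous)")
        if n.is_sample and arg.out_degree(n.id) > 0:
            v.append(f"node {n.id}: sample with outgoing edges")

    if v:  # path tracing assumes the basics hold
        return v

    for lo, hi in breakpoint_partition(arg):
        x = 0.5 * (lo + hi)
        up: dict[int, Optional[int]] = {}
        ambiguous = False
        for node in arg.nodes:
            carriers = [e for e in arg.parent_edges(node) if iv.contains(e.material, x)]
            if len(carriers) > 1:
                v.append(f"node {node}: {len(carriers)} upward paths carry position {x}")
                ambiguous = True
            up[node] = carriers[0].parent if carriers else None
        if ambiguous:
            continue
        tops = set()
        for s in arg.samples:
            cur, steps = s, 0
            while up[cur] is not None and steps <= len(arg.nodes):
                cur = up[cur]
                steps += 1
            tops.add(cur)
        if len(tops) != 1:
            v.append(f"segment [{lo}, {hi}): samples do not share a single MRCA (tops {sorted(tops)})")
    return v


# -- breakpoints -----------------------------------------------------------


def breakpoint_partition(arg: Arg) -> list[Interval]:
    """The M nonmixing segments [0, l_1), [l_1, l_2), ..., [l_{M-1}, 1)."""
    lo = 0.0
    out: list[Interval] = []
    for b in arg.breakpoints:
        out.append((lo, b))
        lo = b
    return out


def material_breakpoints(edges: Iterable[ArgEdge]) -> list[float]:
    """Breakpoint list implied by the material annotations themselves.

    The distinct crossover positions appearing as interval endpoints, plus the
    terminal 1.0.  Used by the simulator and by minimal-descriptor extraction
    to (re)derive the partition.
    """
    return iv.boundaries(e.material for e in edges) + [1.0]


# -- marginal trees --------------------------------------------------------


@dataclass
class MarginalTree:
    """The genealogy of the samples on one nonmixing segment.

    Tree nodes keep their ARG node ids; ``parent`` maps every non-root tree
    node to its tree parent, ``ages`` gives depths in generations, and branch
    lengths are age differences.  Lineages above the segment's MRCA are not
    part of the tree.
    """

    interval: Interval
    root: int
    parent: dict[int, int]
    ages: dict[int, float]
    samples: tuple[int, ...]

    def branch_length(self, v: int) -> float:
        return self.ages[self.parent[v]] - self.ages[v]

    def node_ids(self) -> set[int]:
        return set(self.ages)

    def children(self) -> dict[int, list[int]]:
        ch: dict[int, list[int]] = {v: [] for v in self.ages}
        for c, p in self.parent.items():
            ch[p].append(c)
        for v in ch:
            ch[v].sort()
        return ch

    def internal_nodes(self) -> set[int]:
        return self.node_ids() - set(self.samples)

    def same_genealogy(self, other: "MarginalTree") -> bool:
        """Identical topology, node ids and (hence) branch lengths."""
        return self.parent == other.parent and self.ages == other.ages and self.root == other.root

    def newick(self, precision: int = 9) -> str:
        ch = self.children()

        def fmt(v: int) -> str:
            label = str(v)
            if ch[v]:
                label = "(" + ",".join(fmt(c) for c in ch[v]) + ")" + label
            if v == self.root:
                return label
            return f"{label}:{self.branch_length(v):.{precision}g}"

        return fmt(self.root) + ";"


def _tree_from_edges(arg: Arg, seg: Interval, seg_edges: list[ArgEdge]) -> MarginalTree:
    """Assemble the marginal tree of one segment from the edges carrying it."""
    up: dict[int, ArgEdge] = {}
    n_child: dict[int, int] = {}
    for e in seg_edges:
        if e.child in up:
            raise ValueError(f"segment {seg}: node {e.child} has two upward paths")
        up[e.child] = e
        n_child[e.parent] = n_child.get(e.parent, 0) + 1
    branching = {v for v, c in n_child.items() if c >= 2}
    tree_nodes = list(arg.samples) + sorted(branching)
    parent: dict[int, int] = {}
    roots = []
    for v in tree_nodes:
        e = up.get(v)
        while e is not None and e.parent not in branching:
            e = up.get(e.parent)
        if e is None:
            roots.append(v)
        else:
            parent[v] = e.parent
    if len(roots) != 1:
        raise ValueError(f"segment {seg}: expected a single MRCA, found {sorted(roots)}")
    ages = {v: arg.nodes[v].age for v in tree_nodes}
    return MarginalTree(seg, roots[0], parent, ages, tuple(arg.samples))


def all_marginal_trees(arg: Arg) -> list[tuple[Interval, MarginalTree]]:
    """One (segment, marginal tree) pair per nonmixing segment, in genome order."""
    segs = breakpoint_partition(arg)
    bp = arg.breakpoints
    per_seg: list[list[ArgEdge]] = [[] for _ in segs]
    for e in arg.edges:
        for a, b in e.material:
            for si in range(bisect_right(bp, a), bisect_left(bp, b) + 1):
                per_seg[si].append(e)
    return [(seg, _tree_from_edges(arg, seg, seg_edges)) for seg, seg_edges in zip(segs, per_seg)]


def marginal_tree(arg: Arg, x: float) -> MarginalTree:
    """The genealogy of the samples at position ``x`` in [0, 1)."""
    if not (0.0 <= x < 1.0):
        raise ValueError(f"position {x} outside [0, 1)")
    si = iv.segment_index(arg.breakpoints, x)
    segs = breakpoint_partition(arg)
    seg = segs[si]
    seg_edges = [e for e in arg.edges if iv.overlaps(e.material, *seg)]
    return _tree_from_edges(arg, seg, seg_edges)


# -- genotypes -------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Sample-by-site presence/absence matrix of the ARG's mutations.

    Columns are ordered by (position, child id of the carrying edge); rows
    follow the ARG's sample order.  Equality compares samples, positions and
    the matrix — not the carrying edges, which extraction may legitimately
    rewire while leaving the variation patterns untouched.
    """

    samples: tuple[int, ...]
    positions: tuple[float, ...]
    child_ids: tuple[int, ...]
    matrix: np.ndarray  # shape (n_samples, n_sites), dtype uint8

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.positions == other.positions
            and np.array_equal(self.matrix, other.matrix)
        )

    @property
    def n_sites(self) -> int:
        return len(self.positions)


def sample_genotypes(arg: Arg) -> GenotypeMatrix:
    """Presence/absence of every mutation in every sample.

    A sample carries a mutation iff the mutation's edge lies on the sample's
    upward path at the mutation's position; equivalently, the sample is
    reachable downward from the edge's child through edges whose material
    contains the position.
    """
    sites: list[tuple[float, int, set[int]]] = []
    sample_set = set(arg.samples)
    for e in arg.edges:
        for m in e.mutations:
            carriers: set[int] = set()
            stack = [e.child]
            while stack:
                v = stack.pop()
                if v in sample_set:
                    carriers.add(v)
                for ce in arg.children_edges(v):
                    if iv.contains(ce.material, m):
                        stack.append(ce.child)
            sites.append((m, e.child, carriers))
    sites.sort(key=lambda t: (t[0], t[1]))
    mat = np.zeros((len(arg.samples), len(sites)), dtype=np.uint8)
    row = {s: i for i, s in enumerate(arg.samples)}
    for j, (_, _, carriers) in enumerate(sites):
        for s in carriers:
            mat[row[s], j] = 1
    return GenotypeMatrix(
        samples=tuple(arg.samples),
        positions=tuple(s[0] for s in sites),
        child_ids=tuple(s[1] for s in sites),
        matrix=mat,
    )
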