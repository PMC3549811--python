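"""Minimal-descriptor extraction: the estimable core of an ARG.

A *minimal descriptor* (mdARG) of an ARG G is a structure- and
samples-preserving substructure: the topology and branch lengths of every
marginal tree, and the genotype patterns of the samples, are identical to
those of G.  Its node count Ñ upper-bounds the number of history nodes any
reconstruction method could recover, so f = Ñ/N bounds the penetrable
fraction of the population's genetic history.

Extraction proceeds in two phases:

1. every coalescent node that is *not t-coalescent* — that branches in none
   of the marginal trees — is removed by the node-removal procedure, which
   reconnects its parent directly to each of its children and pushes the
   annotations down; nodes that are simultaneously coalescent and exchange
   (hybrids) are exempt and always retained;
2. chain nodes (single path-through nodes) are removed the same way, to a
   fixpoint, since resolving a removal can expose new chains.

When rewiring creates two parallel edges between the same pair of nodes they
are merged, their materials united: this is what lets a fully resolved
recombination "diamond" (a crossover whose two products immediately
re-coalesce with each other) collapse out of the graph, and it is the only
mechanism by which a node's degree can shrink during extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from . import intervals as iv
from .arg import (
    Arg,
    ArgEdge,
    ArgNode,
    all_marginal_trees,
    material_breakpoints,
    sample_genotypes,
)

REMOVAL_REASONS = ("not_t_coalescent", "chain")


def classify_nodes(arg: Arg) -> dict[int, str]:
    """Label every node by its degree: leaf / coalescent / exchange / chain / hybrid.

    Labels are a function of in/out edge counts only (parallel edges count
    separately).  A zero-in-degree node with two or more outgoing edges — a
    local grand MRCA — is a coalescent node.
    """
    return {v: arg.kind_of(v) for v in arg.nodes}


def is_t_coalescent(arg: Arg, v: int) -> bool:
    """Does node ``v`` branch in at least one marginal tree?

    True iff two or more of ``v``'s child edges carry overlapping material —
    equivalently, some nonmixing segment flows to two distinct children, so
    ``v`` is an internal (coalescent) node of that segment's genealogy.
    """
    kind = arg.kind_of(v)
    if kind in ("leaf", "exchange"):
        raise ValueError(f"node {v} is a {kind} node; the t-coalescent test applies to coalescent nodes")
    return iv.max_coverage_at_least([e.material for e in arg.children_edges(v)], 2)


@dataclass(frozen=True)
class RemovalRecord:
    node: int
    age: float
    reason: str  # one of REMOVAL_REASONS
    iteration: int


@dataclass
class MinimalDescriptor:
    """An mdARG together with its provenance in the source ARG.

    Node ids (and ages) of the descriptor are a subset of the source ARG's;
    ``node_map`` makes that identification explicit, and ``removal_log``
    records every deletion in order.
    """

    arg: Arg
    node_map: dict[int, int]
    removal_log: list[RemovalRecord] = field(default_factory=list)

    def removed_nodes(self) -> list[int]:
        return [r.node for r in self.removal_log]


# -- mutable working graph -------------------------------------------------


class _Working:
    """Adjacency-dict view of an ARG that supports node removal in place."""

    def __init__(self, arg: Arg) -> None:
        self.nodes: dict[int, ArgNode] = dict(arg.nodes)
        self.children: dict[int, list[ArgEdge]] = {v: [] for v in self.nodes}
        self.parents: dict[int, list[ArgEdge]] = {v: [] for v in self.nodes}
        for e in arg.edges:
            self.children[e.parent].append(e)
            self.parents[e.child].append(e)
        self.samples = list(arg.samples)
        self._sample_set = set(self.samples)
        self.provenance = dict(arg.provenance)

    def _detach(self, e: ArgEdge) -> None:
        self.children[e.parent].remove(e)
        self.parents[e.child].remove(e)

    def _attach(self, e: ArgEdge) -> None:
        self.children[e.parent].append(e)
        self.parents[e.child].append(e)

    def _merge_parallel(self, u: int) -> None:
        """Coalesce parallel edges out of ``u`` into single edges."""
        by_child: dict[int, list[ArgEdge]] = {}
        for e in self.children[u]:
            by_child.setdefault(e.child, []).append(e)
        for child, group in by_child.items():
            if len(group) > 1:
                merged = ArgEdge(
                    u,
                    child,
                    iv.union(*(e.material for e in group)),
                    tuple(sorted(m for e in group for m in e.mutations)),
                )
                for e in group:
                    self._detach(e)
                self._attach(merged)

    def remove(self, v: int) -> None:
        """The node-removal procedure.

        Reconnects ``v``'s parent ``u`` to each child ``w`` with the former
        ``v -> w`` material; mutations on ``u -> v`` are pushed down onto
        every new edge whose material contains them.  A parentless ``v``
        (a chain-equivalent local root) is simply deleted with its edge.
        All other nodes keep their ages and edges.
        """
        if v in self._sample_set or not self.children[v]:
            raise ValueError(f"node {v} is a leaf/sample and cannot be removed")
        n_parents = len(self.parents[v])
        if n_parents >= 2:
            raise ValueError(
                f"node {v} has {n_parents} parents; exchange nodes continue to belong to the minimal descriptor"
            )
        up = self.parents[v][0] if n_parents == 1 else None
        child_edges = list(self.children[v])
        for e in child_edges:
            self._detach(e)
        if up is not None:
            self._detach(up)
            for e in child_edges:
                inherited = tuple(m for m in up.mutations if iv.contains(e.material, m))
                self._attach(ArgEdge(up.parent, e.child, e.material, tuple(sorted(e.mutations + inherited))))
            self._merge_parallel(up.parent)
        del self.nodes[v], self.children[v], self.parents[v]

    def in_degree(self, v: int) -> int:
        return len(self.parents[v])

    def out_degree(self, v: int) -> int:
        return len(self.children[v])

    def is_chain(self, v: int) -> bool:
        return v not in self._sample_set and self.out_degree(v) == 1 and self.in_degree(v) <= 1

    def to_arg(self) -> Arg:
        edges = [e for v in sorted(self.children) for e in self.children[v]]
        return Arg(self.nodes.values(), edges, self.samples, material_breakpoints(edges), self.provenance)


# -- public operations -----------------------------------------------------


def remove_node(arg: Arg, v: int) -> Arg:
    """Remove a single-parent, non-leaf node; return the rewired ARG.

    Functional form of the node-removal procedure used by extraction;
    refuses leaves and multi-parent (exchange) nodes.
    """
    if v not in arg.nodes:
        raise KeyError(f"no node {v}")
    w = _Working(arg)
    w.remove(v)
    return w.to_arg()


def minimal_descriptor(arg: Arg, order: str = "youngest") -> MinimalDescriptor:
    """Extract a minimal descriptor of ``arg``.

    Alternates two sweeps to a global fixpoint: remove every current
    single-parent coalescent node that fails the t-coalescent test
    (youngest-first, ties by node id; ``order="oldest"`` reverses the
    sweep order, which must not change the surviving node set), then
    remove chain nodes likewise.
    Multi-parent nodes — exchange nodes and hybrids, even hybrids that fail
    the t-coalescent test — are never removed; but a node's *degrees* can
    shrink when rewiring merges parallel edges, so a former exchange node
    may later surface as a removable coalescent node or chain, which is why
    the sweeps iterate.  The t-coalescent status itself is cached the first
    time a node is tested: removal preserves every marginal tree, so whether
    a node branches in one of them can never change.
    """
    if order not in ("youngest", "oldest"):
        raise ValueError(f"unknown candidate order {order!r}")
    reverse = order == "oldest"
    w = _Working(arg)
    log: list[RemovalRecord] = []
    t_cache: dict[int, bool] = {}

    def fails_t(v: int) -> bool:
        if v not in t_cache:
            t_cache[v] = iv.max_coverage_at_least([e.material for e in w.children[v]], 2)
        return not t_cache[v]

    def is_candidate(v: int) -> bool:
        return (
            v in w.nodes
            and v not in w._sample_set
            and w.in_degree(v) == 1
            and w.out_degree(v) >= 2
            and fails_t(v)
        )

    iteration = 0
    while True:
        iteration += 1
        removed_this_round = 0
        candidates = sorted(
            (v for v in w.nodes if is_candidate(v)), key=lambda v: (w.nodes[v].age, v), reverse=reverse
        )
        for v in candidates:
            if is_candidate(v):  # degrees may shift within a sweep
                w.remove(v)
                log.append(RemovalRecord(v, arg.nodes[v].age, "not_t_coalescent", iteration))
                removed_this_round += 1
        while True:
            iteration += 1
            chains = sorted(
                (v for v in w.nodes if w.is_chain(v)), key=lambda v: (w.nodes[v].age, v), reverse=reverse
            )
            if not chains:
                break
            for v in chains:
                if v in w.nodes and w.is_chain(v):
                    w.remove(v)
                    log.append(RemovalRecord(v, arg.nodes[v].age, "chain", iteration))
                    removed_this_round += 1
        if removed_this_round == 0:
            break

    out = w.to_arg()
    out.provenance["derived_from"] = arg.provenance.get("topology_seed")
    out.provenance["minimal_descriptor"] = True
    return MinimalDescriptor(arg=out, node_map={v: v for v in out.nodes}, removal_log=log)


def verify_structure_preserving(arg: Arg, md: MinimalDescriptor) -> bool:
    """Master correctness oracle: is ``md`` structure- and samples-preserving?

    Checks that on every nonmixing segment of ``arg`` the marginal trees of
    G and G' are identical in topology, node ids and branch lengths (ages
    are compared exactly), and that the genotype matrices coincide.
    """
    md_trees = all_marginal_trees(md.arg)
    md_bp = md.arg.breakpoints
    for seg, tree in all_marginal_trees(arg):
        mid = 0.5 * (seg[0] + seg[1])
        md_tree = md_trees[iv.segment_index(md_bp, mid)][1]
        if not tree.same_genealogy(md_tree):
            return False
    return sample_genotypes(arg) == sample_genotypes(md.arg)
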