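"""Deterministic hand-built ARG fixtures.

Five small graphs whose extraction behaviour was worked out by hand before
any code existed; they pin down the corner cases of the algorithm:

(a) ``recombination_free_tree`` — a plain 3-leaf genealogy: nothing is
    removable, f = 1.
(b) ``figure1_style`` — 3 samples, 2 crossovers, 3 nonmixing segments, and
    exactly two coalescent nodes that branch in no marginal tree (each
    re-joins disjoint fragments of a single sample's sequence).
(c) ``figure2_style`` — a resolved recombination "diamond" plus a
    pre-existing chain: extraction removes one non-t-coalescent node, after
    which the crossover node collapses to a chain; the removal log is
    exactly one ``not_t_coalescent`` plus two ``chain`` records.
(d) ``f1`` — 8 non-leaf nodes of which a hand-run of the algorithm removes
    exactly 3, so f = 5/8 (see the README written next to the JSON files).
(e) ``hybrid_retained`` — a node that is coalescent *and* exchange (two
    parents, two children) and fails the t-coalescent test, yet must be
    retained: the extraction log is empty and f = 1.
"""

from __future__ import annotations

from pathlib import Path
from typing import Callable

from .arg import Arg, ArgEdge, ArgNode
from .io import write_arg_json


def _mk(nodes, edges, samples, breakpoints, name: str) -> Arg:
    return Arg(
        [ArgNode(i, age, i in samples) for i, age in nodes],
        [ArgEdge(p, c, tuple(mat), tuple(muts)) for p, c, mat, muts in edges],
        samples,
        breakpoints,
        {"sequence_length_bp": 1000, "fixture": name},
    )


def recombination_free_tree() -> Arg:
    """((0,1),2): two coalescences, one marginal tree, no removable nodes."""
    return _mk(
        nodes=[(0, 0.0), (1, 0.0), (2, 0.0), (3, 1.0), (4, 2.0)],
        edges=[
            (3, 0, [(0.0, 1.0)], [0.25]),
            (3, 1, [(0.0, 1.0)], []),
            (4, 3, [(0.0, 1.0)], [0.8]),
            (4, 2, [(0.0, 1.0)], [0.6]),
        ],
        samples=[0, 1, 2],
        breakpoints=[1.0],
        name="recombination_free_tree",
    )


def figure1_style() -> Arg:
    """Two nested crossovers on sample 2's lineage; both re-joins are sterile.

    Sample 2 recombines at 0.6 (node 3) and its left product again at 0.3
    (node 4).  Node 5 re-joins the two products of node 4, node 6 re-joins
    that with the right product of node 3: both merge *disjoint* fragments
    of the same ancestral sequence, so neither branches in any of the three
    marginal trees — they are the two non-t-coalescent nodes.
    """
    return _mk(
        nodes=[(0, 0.0), (1, 0.0), (2, 0.0), (3, 1.0), (4, 1.5), (5, 2.0), (6, 2.5), (7, 3.0), (8, 4.0)],
        edges=[
            (3, 2, [(0.0, 1.0)], [0.45]),
            (4, 3, [(0.0, 0.6)], []),
            (5, 4, [(0.0, 0.3)], []),
            (5, 4, [(0.3, 0.6)], []),
            (6, 5, [(0.0, 0.6)], []),
            (6, 3, [(0.6, 1.0)], []),
            (7, 6, [(0.0, 1.0)], []),
            (7, 0, [(0.0, 1.0)], [0.1]),
            (8, 7, [(0.0, 1.0)], [0.8]),
            (8, 1, [(0.0, 1.0)], []),
        ],
        samples=[0, 1, 2],
        breakpoints=[0.3, 0.6, 1.0],
        name="figure1_style",
    )


def figure2_style() -> Arg:
    """One sterile re-join (node 5) over a crossover (node 4), plus chain 3.

    Removing node 5 merges its two parallel edges onto node 4, which
    collapses to a chain; node 3 is a chain from the outset.  Extraction
    log: [5: not_t_coalescent, 3: chain, 4: chain].
    """
    return _mk(
        nodes=[(0, 0.0), (1, 0.0), (2, 0.0), (3, 0.5), (4, 1.0), (5, 2.0), (6, 3.0), (7, 4.0)],
        edges=[
            (4, 2, [(0.0, 1.0)], [0.7]),
            (5, 4, [(0.0, 0.5)], []),
            (5, 4, [(0.5, 1.0)], []),
            (6, 5, [(0.0, 1.0)], []),
            (6, 0, [(0.0, 1.0)], [0.2]),
            (7, 6, [(0.0, 1.0)], []),
            (7, 3, [(0.0, 1.0)], []),
            (3, 1, [(0.0, 1.0)], [0.9]),
        ],
        samples=[0, 1, 2],
        breakpoints=[0.5, 1.0],
        name="figure2_style",
    )


def f1() -> Arg:
    """Hand-verified fixture: 8 non-leaf nodes, 3 removed by hand-execution, f = 5/8.

    Node 6 re-joins the two products of crossover node 4 (not t-coalescent);
    its removal exposes node 4 as a chain; node 5 is a chain from the start.
    Crossover node 8 at 0.7 genuinely separates the genealogies of segments
    [0, 0.7) and [0.7, 1) and survives, as do coalescences 7, 9, 10, 11.
    """
    return _mk(
        nodes=[
            (0, 0.0), (1, 0.0), (2, 0.0), (3, 0.0),
            (4, 1.0), (5, 0.5), (6, 2.0), (7, 3.0),
            (8, 3.5), (9, 4.0), (10, 5.0), (11, 6.0),
        ],
        edges=[
            (4, 2, [(0.0, 1.0)], [0.25]),
            (5, 3, [(0.0, 1.0)], []),
            (6, 4, [(0.0, 0.5)], []),
            (6, 4, [(0.5, 1.0)], []),
            (7, 6, [(0.0, 1.0)], []),
            (7, 0, [(0.0, 1.0)], []),
            (8, 7, [(0.0, 1.0)], []),
            (9, 8, [(0.0, 0.7)], [0.6]),
            (9, 1, [(0.0, 1.0)], []),
            (10, 8, [(0.7, 1.0)], []),
            (10, 5, [(0.0, 1.0)], [0.9]),
            (11, 9, [(0.0, 1.0)], [0.1]),
            (11, 10, [(0.0, 1.0)], []),
        ],
        samples=[0, 1, 2, 3],
        breakpoints=[0.5, 0.7, 1.0],
        name="f1",
    )


def hybrid_retained() -> Arg:
    """Node 4 has two parents and two children: coalescent *and* exchange.

    Its child edges carry disjoint halves of sample 2's sequence, so it
    fails the t-coalescent test — but hybrid nodes continue to belong to
    the minimal descriptor, so extraction removes nothing and f = 1.
    """
    return _mk(
        nodes=[(0, 0.0), (1, 0.0), (2, 0.0), (3, 1.0), (4, 2.0), (5, 3.0), (6, 4.0), (7, 5.0)],
        edges=[
            (3, 2, [(0.0, 1.0)], [0.4]),
            (4, 3, [(0.0, 0.5)], []),
            (4, 3, [(0.5, 1.0)], []),
            (5, 4, [(0.0, 0.5)], []),
            (5, 0, [(0.0, 1.0)], []),
            (6, 4, [(0.5, 1.0)], []),
            (6, 1, [(0.0, 1.0)], []),
            (7, 5, [(0.0, 1.0)], []),
            (7, 6, [(0.0, 1.0)], []),
        ],
        samples=[0, 1, 2],
        breakpoints=[0.5, 1.0],
        name="hybrid_retained",
    )


BUILDERS: dict[str, Callable[[], Arg]] = {
    "recombination_free_tree": recombination_free_tree,
    "figure1_style": figure1_style,
    "figure2_style": figure2_style,
    "f1": f1,
    "hybrid_retained": hybrid_retained,
}

_F1_README = """\
# Fixture ARGs

Deterministic hand-built ARGs used by the test suite; see
`argmd.fixtures` for the builders.

## Hand-execution of the extraction algorithm on fixture `f1`

Non-leaf nodes (N = 8): 4 (crossover at 0.5), 5 (chain), 6, 7, 8 (crossover
at 0.7), 9, 10, 11.

1. t-coalescent classification: node 6's two child edges carry [0,0.5) and
   [0.5,1) — disjoint, so node 6 branches in no marginal tree.  Nodes 7, 9,
   10, 11 each have child edges with overlapping material, so they are
   t-coalescent.  Nodes 4 and 8 are exchange nodes (two incoming edges);
   node 5 is a chain.
2. Remove node 6 (not t-coalescent): its parent 7 gains two parallel edges
   to node 4, which merge into a single edge 7->4 carrying [0,1).
3. Chain removal: node 5 (one parent, one child) goes first (youngest);
   then node 4, which after step 2 has a single parent (7) and its single
   child (2) — a chain.  No further chains appear.

Removed: {6, 5, 4}.  Surviving non-leaf nodes (Ñ = 5): 7, 8, 9, 10, 11.
Penetrable fraction f = Ñ/N = 5/8.
"""


def make_fixtures(out_dir) -> dict[str, Path]:
    """Write all fixture ARGs as ARG-JSON files plus a README; return the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, build in BUILDERS.items():
        p = out / f"{name}.json"
        write_arg_json(build(), p)
        paths[name] = p
    (out / "README.md").write_text(_F1_README)
    return paths
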