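"""Brute-force reference implementations, independent of the library's
interval algebra: per-position lineage tracing by naive membership tests.

These deliberately re-derive marginal trees and genotypes from first
principles (walk each sample upward through whichever edges carry the
position) so that the fast implementations have something honest to be
checked against.
"""

from __future__ import annotations

import numpy as np


def _carries(material, x: float) -> bool:
    return any(a <= x < b for a, b in material)


def trace_path(arg, sample: int, x: float):
    """Edge-index path of ``sample`` upward at position ``x``."""
    path = []
    cur = sample
    while True:
        nxt = [
            i
            for i, e in enumerate(arg.edges)
            if e.child == cur and _carries(e.material, x)
        ]
        if not nxt:
            return path
        assert len(nxt) == 1, f"ambiguous path at node {cur}, position {x}"
        path.append(nxt[0])
        cur = arg.edges[nxt[0]].parent


def tree_at(arg, x: float):
    """(root, parent-map, ages) of the genealogy at ``x``, by path tracing."""
    paths = {s: [s] + [arg.edges[i].parent for i in trace_path(arg, s, x)] for s in arg.samples}
    preds: dict[int, set[int]] = {}
    for p in paths.values():
        for child, parent in zip(p, p[1:]):
            preds.setdefault(parent, set()).add(child)
    branching = {v for v, ch in preds.items() if len(ch) >= 2}
    tree_nodes = set(arg.samples) | branching
    parent = {}
    root = None
    for v in sorted(tree_nodes):
        path = next(p for p in paths.values() if v in p)
        above = path[path.index(v) + 1:]
        anc = next((u for u in above if u in branching), None)
        if anc is None:
            root = v
        else:
            parent[v] = anc
    ages = {v: arg.nodes[v].age for v in tree_nodes}
    return root, parent, ages


def genotypes(arg) -> tuple[tuple, np.ndarray]:
    """(sorted site keys, matrix) by upward path tracing per sample."""
    sites = []
    for i, e in enumerate(arg.edges):
        for m in e.mutations:
            sites.append((m, e.child, i))
    sites.sort(key=lambda t: (t[0], t[1]))
    mat = np.zeros((len(arg.samples), len(sites)), dtype=np.uint8)
    for si, s in enumerate(arg.samples):
        for j, (m, _, ei) in enumerate(sites):
            if ei in trace_path(arg, s, m):
                mat[si, j] = 1
    return tuple((m, c) for m, c, _ in sites), mat


def t_coalescent_nodes(arg) -> set[int]:
    """Nodes that branch in at least one marginal tree, via tree_at."""
    out: set[int] = set()
    bp = [0.0] + list(arg.breakpoints)
    for lo, hi in zip(bp, bp[1:]):
        _, parent, ages = tree_at(arg, (lo + hi) / 2)
        out |= set(ages) - set(arg.samples)
    return out
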