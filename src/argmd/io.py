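"""ARG-JSON interchange format and newick export.

ARG-JSON (format tag ``argmd-arg/1``) is a plain-text, self-contained
serialization of an ARG: node ages, edge ancestral-material intervals in
normalized [0, 1] coordinates, mutation positions, recombination breakpoints
and a free-form provenance object echoing the simulation configuration.
Readers reject unknown major versions; writers emit keys in a fixed order so
outputs are byte-reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, TextIO, Union

from .arg import Arg, ArgEdge, ArgNode, MarginalTree

FORMAT = "argmd-arg/1"
_MAJOR = 1


class FormatError(ValueError):
    """Raised when a document cannot be parsed as supported ARG-JSON."""


def arg_to_dict(arg: Arg) -> dict:
    provenance = dict(arg.provenance)
    seq_len = int(provenance.pop("sequence_length_bp", 0))
    return {
        "format": FORMAT,
        "sequence_length_bp": seq_len,
        "samples": list(arg.samples),
        "nodes": [
            {"id": n.id, "age": n.age, "is_sample": n.is_sample}
            for n in sorted(arg.nodes.values(), key=lambda n: (n.age, n.id))
        ],
        "edges": [
            {
                "parent": e.parent,
                "child": e.child,
                "material": [[a, b] for a, b in e.material],
                "mutations": list(e.mutations),
            }
            for e in arg.edges
        ],
        "breakpoints": list(arg.breakpoints),
        "provenance": provenance,
    }


def arg_from_dict(doc: dict) -> Arg:
    if not isinstance(doc, dict):
        raise FormatError("ARG-JSON document must be an object")
    tag = doc.get("format")
    if not isinstance(tag, str) or "/" not in tag or tag.split("/", 1)[0] != "argmd-arg":
        raise FormatError(f"not an ARG-JSON document (format tag {tag!r})")
    try:
        major = int(tag.split("/", 1)[1].split(".")[0])
    except ValueError as exc:
        raise FormatError(f"malformed format tag {tag!r}") from exc
    if major != _MAJOR:
        raise FormatError(f"unsupported ARG-JSON major version {major} (supported: {_MAJOR})")
    try:
        nodes = [ArgNode(int(n["id"]), float(n["age"]), bool(n.get("is_sample", False))) for n in doc["nodes"]]
        edges = [
            ArgEdge(
                int(e["parent"]),
                int(e["child"]),
                tuple((float(a), float(b)) for a, b in e["material"]),
                tuple(float(m) for m in e.get("mutations", [])),
            )
            for e in doc["edges"]
        ]
        samples = [int(s) for s in doc["samples"]]
        breakpoints = [float(b) for b in doc["breakpoints"]]
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"malformed ARG-JSON: {exc}") from exc
    provenance = dict(doc.get("provenance") or {})
    if "sequence_length_bp" in doc:
        provenance["sequence_length_bp"] = int(doc["sequence_length_bp"])
    return Arg(nodes, edges, samples, breakpoints, provenance)


def write_arg_json(arg: Arg, path: Union[str, Path, TextIO]) -> None:
    doc = arg_to_dict(arg)
    if hasattr(path, "write"):
        json.dump(doc, path, indent=1)
        path.write("\n")
    else:
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")


def read_arg_json(path: Union[str, Path, TextIO]) -> Arg:
    if hasattr(path, "read"):
        doc = json.load(path)
    else:
        with open(path) as fh:
            doc = json.load(fh)
    return arg_from_dict(doc)


def trees_to_newick(trees: Iterable[tuple[tuple[float, float], MarginalTree]]) -> str:
    """Marginal trees as newick, one per line, tagged with their segment.

    Each line is ``[&interval=a,b] <newick>`` with branch lengths in
    generations and ARG node ids as labels.
    """
    lines = []
    for (a, b), tree in trees:
        lines.append(f"[&interval={a:.9g},{b:.9g}] {tree.newick()}")
    return "\n".join(lines) + "\n"


def write_newick(trees, path: Union[str, Path]) -> None:
    Path(path).write_text(trees_to_newick(trees))
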