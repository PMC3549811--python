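"""Estimability statistics: penetrable fraction f and density profiles.

The amount of relevant genetic history in an ARG is measured by its node
count N; the minimal descriptor's count Ñ <= N bounds what is recoverable,
giving the penetrable fraction f = Ñ/N and the impenetrable lower bound
1 - f.  Binning node ages into epochs yields the history density N_d, the
estimable count Ñ_d, and the estimable density f_d = Ñ_d / N_d as functions
of depth.  Sweep aggregation averages f over a parameter grid with the
marginal-mean convention: the curve for one parameter averages over all
values of the others, replicates included.

By default N and Ñ count non-leaf nodes only: leaves are the extant samples,
present in both graphs by construction, and counting them would dilute f.
Every function takes ``include_leaves`` to flip that rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .arg import Arg
from .mdarg import MinimalDescriptor

SWEEP_PARAMS = ("demography", "mutation_rate", "sequence_length", "sample_size", "recombination_rate")


def count_nodes(arg: Arg, include_leaves: bool = False) -> int:
    """Number of history nodes in the ARG (non-leaf nodes by default)."""
    if include_leaves:
        return len(arg.nodes)
    return sum(1 for n in arg.nodes.values() if arg.out_degree(n.id) > 0)


def estimable_fraction(arg: Arg, md: MinimalDescriptor, include_leaves: bool = False) -> float:
    """The penetrable fraction f = Ñ/N in [0, 1]; 1 - f bounds the impenetrable part."""
    n = count_nodes(arg, include_leaves)
    if n == 0:
        raise ValueError("ARG has no countable nodes; f is undefined")
    return count_nodes(md.arg, include_leaves) / n


# -- epoch grids and density profiles --------------------------------------


@dataclass(frozen=True)
class EpochGrid:
    """Contiguous depth bins [edges[i], edges[i+1]) covering [0, max age].

    The last bin is closed on the right so the oldest node always falls in
    a bin.  ``logarithmic`` grids start at 0 and continue geometrically from
    ``min_age`` (default: max_age / 1000), which suits the roughly
    exponential decay of event density with depth.
    """

    edges: tuple[float, ...]
    mode: str = "linear"

    def __post_init__(self) -> None:
        e = self.edges
        if len(e) < 2 or e[0] != 0.0 or any(a >= b for a, b in zip(e, e[1:])):
            raise ValueError("epoch edges must start at 0 and increase strictly")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @classmethod
    def linear(cls, max_age: float, bins: int = 25) -> "EpochGrid":
        return cls(tuple(np.linspace(0.0, float(max_age), bins + 1)), "linear")

    @classmethod
    def logarithmic(cls, max_age: float, bins: int = 25, min_age: Optional[float] = None) -> "EpochGrid":
        if min_age is None:
            min_age = max_age / 1000.0
        inner = np.geomspace(min_age, float(max_age), bins)
        return cls((0.0,) + tuple(inner), "logarithmic")

    def covers(self, age: float) -> bool:
        return 0.0 <= age <= self.edges[-1]

    def bin_of(self, age: float) -> int:
        if not self.covers(age):
            raise ValueError(f"age {age} outside epoch grid [0, {self.edges[-1]}]")
        if age == self.edges[-1]:
            return self.n_bins - 1
        return int(np.searchsorted(self.edges, age, side="right")) - 1

    def counts(self, ages: Iterable[float]) -> np.ndarray:
        out = np.zeros(self.n_bins, dtype=np.int64)
        for a in ages:
            out[self.bin_of(a)] += 1
        return out


@dataclass
class DensityProfile:
    """Per-epoch node counts N_d, Ñ_d and the estimable density f_d.

    Conservation holds by construction: the bin counts sum to N and Ñ.
    Empty epochs report f_d as NaN (missing), never a coerced 0.
    """

    grid: EpochGrid
    n_d: np.ndarray
    n_md_d: np.ndarray

    @property
    def f_d(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_d > 0, self.n_md_d / np.maximum(self.n_d, 1), np.nan)

    def to_frame(self) -> pd.DataFrame:
        e = self.grid.edges
        return pd.DataFrame(
            {
                "epoch_lo": e[:-1],
                "epoch_hi": e[1:],
                "N_d": self.n_d,
                "Nmd_d": self.n_md_d,
                "f_d": self.f_d,
            }
        )


def density_profile(
    arg: Arg,
    md: MinimalDescriptor,
    grid: EpochGrid,
    include_leaves: bool = False,
) -> DensityProfile:
    """Bin the node ages of G and G' into the epoch grid."""

    def ages(a: Arg) -> list[float]:
        return [
            n.age
            for n in a.nodes.values()
            if include_leaves or a.out_degree(n.id) > 0
        ]

    arg_ages = ages(arg)
    if arg_ages and not grid.covers(max(arg_ages)):
        raise ValueError(
            f"epoch grid ends at {grid.edges[-1]} but the oldest node has age {max(arg_ages)}"
        )
    return DensityProfile(grid, grid.counts(arg_ages), grid.counts(ages(md.arg)))


# -- sweep aggregation -----------------------------------------------------


@dataclass
class SweepResult:
    """Per-replicate rows plus per-cell and marginal summaries of f.

    ``table`` has one row per (parameter cell, replicate) with columns
    ``SWEEP_PARAMS + (replicate, N, N_md, f)``.  ``cell_means`` aggregates
    replicates within each cell (mean, standard error across replicates).
    ``marginal_mean(param)`` averages the cell means over every value of the
    other parameters, the convention used for summary curves.
    """

    table: pd.DataFrame
    skipped: pd.DataFrame

    @property
    def cell_means(self) -> pd.DataFrame:
        g = self.table.groupby(list(SWEEP_PARAMS), sort=True)["f"]
        out = g.agg(mean_f="mean", sd_f="std", n_replicates="count").reset_index()
        out["sd_f"] = out["sd_f"].fillna(0.0)
        out["stderr_f"] = out["sd_f"] / np.sqrt(out["n_replicates"])
        return out.drop(columns=["sd_f"])

    def marginal_mean(self, param: str) -> pd.DataFrame:
        if param not in SWEEP_PARAMS:
            raise ValueError(f"unknown sweep parameter {param!r}")
        cells = self.cell_means
        g = cells.groupby(param, sort=True)
        out = g.agg(
            mean_f=("mean_f", "mean"),
            n_cells=("mean_f", "count"),
            stderr_f=("stderr_f", lambda s: float(np.sqrt(np.sum(np.square(s))) / len(s))),
        ).reset_index()
        return out

    def marginals(self) -> pd.DataFrame:
        frames = []
        for p in SWEEP_PARAMS:
            m = self.marginal_mean(p).rename(columns={p: "value"})
            m.insert(0, "parameter", p)
            frames.append(m)
        return pd.concat(frames, ignore_index=True)


def aggregate_sweep(rows: Union[pd.DataFrame, Sequence[dict]], skipped: Union[pd.DataFrame, Sequence[dict], None] = None) -> SweepResult:
    """Assemble per-replicate rows into a SweepResult.

    Each row must carry the five sweep parameters plus ``replicate``, ``N``,
    ``N_md`` and ``f`` (``f`` is recomputed as N_md/N if absent).
    """
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no sweep rows to aggregate")
    missing = [c for c in SWEEP_PARAMS + ("replicate", "N", "N_md") if c not in table.columns]
    if missing:
        raise ValueError(f"sweep rows missing columns: {missing}")
    if "f" not in table.columns:
        table["f"] = table["N_md"] / table["N"]
    if ((table["f"] < 0) | (table["f"] > 1)).any():
        raise ValueError("f outside [0, 1]")
    skipped_df = pd.DataFrame(skipped) if skipped is not None else pd.DataFrame(
        columns=list(SWEEP_PARAMS) + ["replicate", "reason"]
    )
    return SweepResult(table=table.reset_index(drop=True), skipped=skipped_df)
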