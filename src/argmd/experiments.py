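"""Parameter-grid experiments: reproducible sweeps of the penetrable fraction.

A :class:`GridSpec` lists values for the four swept simulation parameters
(mutation rate, sequence length, sample size, recombination rate) plus the
demographies and a replicate count.  :func:`run_grid` simulates every cell x
replicate, extracts the minimal descriptor, measures N, Ñ and f, and
aggregates the rows; per-replicate seeds are derived from the master seed by
a counter-based scheme so any single cell can be re-run in isolation.
Failing cells (for instance runs that exceed the event cap) are recorded as
skipped with their reason, never silently dropped.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .coalsim import (
    ConfigError,
    DemographyConfig,
    ResourceError,
    SimulationConfig,
    load_demography,
    simulate,
)
from .estimability import SweepResult, aggregate_sweep, count_nodes, estimable_fraction
from .io import write_arg_json
from .mdarg import minimal_descriptor

log = logging.getLogger("argmd")


def derive_seeds(master_seed: int, cell_index: int, replicate: int) -> tuple[int, int]:
    """Topology and mutation seeds for one (cell, replicate) of a sweep.

    Counter-based: the master seed and the two counters feed a
    ``numpy.random.SeedSequence``, whose first two output words (masked to
    31 bits) become the seeds.  Deterministic, collision-resistant, and
    independent of execution order.
    """
    ss = np.random.SeedSequence([int(master_seed), int(cell_index), int(replicate)])
    a, b = ss.generate_state(2)
    return int(a) & 0x7FFFFFFF, int(b) & 0x7FFFFFFF


@dataclass(frozen=True)
class GridSpec:
    """A sweep grid: parameter values, demographies, replicates, master seed."""

    demographies: tuple[str, ...] = ("constant",)
    mutation_rates: tuple[float, ...] = (1.5e-8,)
    sequence_lengths_bp: tuple[int, ...] = (30_000,)
    sample_sizes: tuple[int, ...] = (30,)
    recombination_rates: tuple[float, ...] = (1.3,)
    replicates: int = 10
    master_seed: int = 1
    event_cap: int = 1_000_000

    def validate(self) -> None:
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        for group in (
            self.demographies,
            self.mutation_rates,
            self.sequence_lengths_bp,
            self.sample_sizes,
            self.recombination_rates,
        ):
            if not group:
                raise ConfigError("every grid dimension needs at least one value")

    def cells(self) -> list[tuple[int, tuple]]:
        """Enumerated (demography, mu, L, n, r) tuples in a fixed order."""
        prod = itertools.product(
            self.demographies,
            self.mutation_rates,
            self.sequence_lengths_bp,
            self.sample_sizes,
            self.recombination_rates,
        )
        return list(enumerate(prod))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "GridSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        try:
            spec = cls(
                demographies=tuple(doc.get("demographies", ["constant"])),
                mutation_rates=tuple(doc.get("mutation_rates", [1.5e-8])),
                sequence_lengths_bp=tuple(int(x) for x in doc.get("sequence_lengths_bp", [30_000])),
                sample_sizes=tuple(int(x) for x in doc.get("sample_sizes", [30])),
                recombination_rates=tuple(doc.get("recombination_rates", [1.3])),
                replicates=int(doc.get("replicates", 10)),
                master_seed=int(doc.get("master_seed", 1)),
                event_cap=int(doc.get("event_cap", 1_000_000)),
            )
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"malformed grid spec: {exc}") from exc
        spec.validate()
        return spec


def run_grid(
    grid: GridSpec,
    include_leaves: bool = False,
    keep_args: Optional[Union[str, Path]] = None,
) -> SweepResult:
    """Simulate, extract and measure every cell x replicate of the grid.

    Returns a :class:`SweepResult`; cells that exceed the event cap (or fail
    for any other reason) land in ``result.skipped`` with their reason.  If
    ``keep_args`` names a directory, every simulated ARG is retained there
    as ARG-JSON.
    """
    grid.validate()
    demogs: dict[str, DemographyConfig] = {name: load_demography(name) for name in grid.demographies}
    rows: list[dict] = []
    skipped: list[dict] = []
    for cell_index, (dem, mu, length, n, r) in grid.cells():
        for rep in range(grid.replicates):
            tseed, mseed = derive_seeds(grid.master_seed, cell_index, rep)
            coords = {
                "demography": dem,
                "mutation_rate": mu,
                "sequence_length": length,
                "sample_size": n,
                "recombination_rate": r,
                "replicate": rep,
            }
            config = SimulationConfig(
                demography=demogs[dem],
                sequence_length_bp=length,
                mutation_rate=mu,
                recombination_rate=r,
                sample_size=n,
                topology_seed=tseed,
                mutation_seed=mseed,
                event_cap=grid.event_cap,
            )
            try:
                arg = simulate(config)
                log.info("simulate cell=%d %s: %d nodes", cell_index, coords, len(arg.nodes))
                md = minimal_descriptor(arg)
                log.info("extract cell=%d rep=%d: removed %d", cell_index, rep, len(md.removal_log))
                f = estimable_fraction(arg, md, include_leaves)
                rows.append(
                    {
                        **coords,
                        "N": count_nodes(arg, include_leaves),
                        "N_md": count_nodes(md.arg, include_leaves),
                        "f": f,
                    }
                )
                if keep_args is not None:
                    out = Path(keep_args)
                    out.mkdir(parents=True, exist_ok=True)
                    write_arg_json(arg, out / f"cell{cell_index:05d}_rep{rep:03d}.json")
            except (ResourceError, ConfigError, ValueError) as exc:
                log.warning("skip cell=%d rep=%d: %s", cell_index, rep, exc)
                skipped.append({**coords, "reason": str(exc)})
    log.info(
        "grid done: attempted=%d completed=%d skipped=%d",
        len(rows) + len(skipped), len(rows), len(skipped),
    )
    if not rows:
        raise ResourceError("every cell of the grid failed; see the skipped table")
    return aggregate_sweep(rows, skipped)


# -- plain-text output ------------------------------------------------------


def write_sweep_tsv(result: SweepResult, path: Union[str, Path]) -> Path:
    """Write per-replicate rows as TSV plus a `*_marginals.tsv` companion."""
    path = Path(path)
    result.table.to_csv(path, sep="\t", index=False, float_format="%.10g")
    marg_path = path.with_name(path.stem + "_marginals" + (path.suffix or ".tsv"))
    result.marginals().to_csv(marg_path, sep="\t", index=False, float_format="%.10g")
    if len(result.skipped):
        skip_path = path.with_name(path.stem + "_skipped" + (path.suffix or ".tsv"))
        result.skipped.to_csv(skip_path, sep="\t", index=False, float_format="%.10g")
    return marg_path


def write_profile_tsv(profile, path: Union[str, Path]) -> None:
    """Density profile as TSV; empty epochs report f_d as '.' (missing)."""
    frame = profile.to_frame().copy()
    frame["f_d"] = [f"{v:.10g}" if np.isfinite(v) else "." for v in frame["f_d"]]
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_removal_log_tsv(md, path: Union[str, Path]) -> None:
    """Extraction removal log: node_id, age, reason, iteration."""
    pd.DataFrame(
        [
            {"node_id": r.node, "age": r.age, "reason": r.reason, "iteration": r.iteration}
            for r in md.removal_log
        ],
        columns=["node_id", "age", "reason", "iteration"],
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")
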