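"""Shared fixtures: hand-built ARGs and a small simulated corpus."""

from __future__ import annotations

import itertools

import pytest

from argmd import SimulationConfig, simulate
from argmd.coalsim import constant_demography, load_demography
from argmd import fixtures as fx


@pytest.fixture(scope="session")
def hand_args():
    return {name: build() for name, build in fx.BUILDERS.items()}


def corpus_configs(n_seeds: int = 12):
    """Small mixed corpus: varied L, n, r, mu over two demographies."""
    demogs = {
        "constant": constant_demography(10_000),
        "european": load_demography("european"),
    }
    cells = list(
        itertools.product(
            [5_000, 30_000],
            [5, 30],
            [0.5, 2.5],
            sorted(demogs),
        )
    )
    configs = []
    for seed in range(n_seeds):
        L, n, r, dem = cells[seed % len(cells)]
        configs.append(
            SimulationConfig(
                demography=demogs[dem],
                sequence_length_bp=L,
                sample_size=n,
                recombination_rate=r,
                mutation_rate=1.5e-8,
                topology_seed=1_000 + seed,
                mutation_seed=2_000 + seed,
            )
        )
    return configs


@pytest.fixture(scope="session")
def sim_corpus():
    """A dozen simulated ARGs with mutations, spanning the small grid."""
    return [simulate(cfg) for cfg in corpus_configs()]
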