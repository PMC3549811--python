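"""Simulator: structure, determinism, demography handling, scaling."""

import numpy as np
import pytest

from argmd import (
    ConfigError,
    DemographyConfig,
    DemographyEvent,
    ResourceError,
    SimulationConfig,
    bestfit_like_demographies,
    drop_mutations,
    simulate,
    simulate_topology,
    validate_arg,
)
from argmd.coalsim import constant_demography
from argmd.io import arg_to_dict


def cfg(**kw):
    base = dict(
        demography=constant_demography(10_000),
        sample_size=10,
        sequence_length_bp=20_000,
        recombination_rate=1.0,
        topology_seed=11,
        mutation_seed=12,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestTopology:
    def test_zero_recombination_gives_binary_tree(self):
        for n in (2, 5, 17):
            arg = simulate_topology(cfg(sample_size=n, recombination_rate=0.0, topology_seed=n))
            internal = [v for v in arg.nodes if not arg.nodes[v].is_sample]
            assert len(internal) == n - 1
            assert all(arg.kind_of(v) == "coalescent" for v in internal)
            assert arg.breakpoints == [1.0]

    def test_same_seed_is_bit_identical(self):
        a, b = simulate(cfg()), simulate(cfg())
        assert arg_to_dict(a) == arg_to_dict(b)

    def test_topology_invariant_to_mutation_settings(self):
        a = simulate(cfg(mutation_rate=0.7e-8, mutation_seed=1))
        b = simulate(cfg(mutation_rate=3.0e-8, mutation_seed=2))
        strip = lambda arg: [(e.parent, e.child, e.material) for e in arg.edges]
        assert strip(a) == strip(b)
        assert {v: n.age for v, n in a.nodes.items()} == {v: n.age for v, n in b.nodes.items()}

    def test_event_cap_raises_resource_error(self):
        with pytest.raises(ResourceError, match="event cap of 40"):
            simulate_topology(cfg(sample_size=60, recombination_rate=5.0, event_cap=40))

    def test_exchange_nodes_increase_with_recombination_and_length(self):
        from scipy.stats import spearmanr

        def mean_exchanges(r, L):
            out = []
            for seed in range(6):
                arg = simulate_topology(cfg(recombination_rate=r, sequence_length_bp=L, topology_seed=100 + seed))
                out.append(sum(1 for v in arg.nodes if arg.kind_of(v) == "exchange"))
            return np.mean(out)

        by_r = [mean_exchanges(r, 20_000) for r in (0.1, 0.9, 2.1, 5.1)]
        by_l = [mean_exchanges(1.3, L) for L in (5_000, 20_000, 50_000)]
        assert spearmanr(range(len(by_r)), by_r).statistic > 0
        assert spearmanr(range(len(by_l)), by_l).statistic > 0

    def test_corpus_validates(self, sim_corpus):
        for arg in sim_corpus:
            assert validate_arg(arg) == []


class TestMutations:
    def test_zero_rate_means_zero_mutations(self):
        arg = simulate_topology(cfg())
        assert drop_mutations(arg, 0.0, 20_000, 5).num_mutations() == 0

    def test_identical_seed_identical_mutations(self):
        arg = simulate_topology(cfg())
        m1 = drop_mutations(arg, 1.5e-8, 20_000, 99)
        m2 = drop_mutations(arg, 1.5e-8, 20_000, 99)
        assert arg_to_dict(m1) == arg_to_dict(m2)

    def test_refuses_already_mutated_arg(self):
        arg = simulate(cfg())
        with pytest.raises(ConfigError, match="already carries"):
            drop_mutations(arg, 1.5e-8, 20_000, 1)

    def test_mutations_lie_inside_material(self, sim_corpus):
        for arg in sim_corpus:
            assert validate_arg(arg) == []  # includes the mutation-in-material check


class TestDemographies:
    def test_four_shipped_configs(self):
        demogs = bestfit_like_demographies()
        assert set(demogs) == {"african", "european", "asian", "afro_american"}
        for d in demogs.values():
            d.validate()

    def test_split_structure_of_shipped_configs(self):
        demogs = bestfit_like_demographies()
        kinds = {name: {e.type for e in d.events} for name, d in demogs.items()}
        assert "split" not in kinds["african"]
        assert "split" in kinds["european"] and "split" in kinds["asian"]
        assert "admixture" in kinds["afro_american"]
        # out-of-Africa populations carry a founder bottleneck
        assert "bottleneck" in kinds["european"] and "bottleneck" in kinds["asian"]

    def test_each_shipped_demography_simulates(self):
        for i, (name, d) in enumerate(sorted(bestfit_like_demographies().items())):
            arg = simulate_topology(cfg(demography=d, sample_size=8, topology_seed=300 + i))
            assert validate_arg(arg) == [], name

    def test_sampling_weights_largest_remainder(self):
        d = DemographyConfig(
            name="two", populations=(("A", 1e4), ("B", 1e4)),
            sampling=(("A", 2.0), ("B", 1.0)),
        )
        assert d.sample_counts(9) == {"A": 6, "B": 3}
        assert d.sample_counts(10) == {"A": 7, "B": 3}

    @pytest.mark.parametrize("bad", [
        dict(populations=(("A", -5.0),)),
        dict(events=(DemographyEvent(time=-1.0, type="size_change", population="A", size=10.0),)),
        dict(events=(
            DemographyEvent(time=5.0, type="size_change", population="A", size=10.0),
            DemographyEvent(time=1.0, type="size_change", population="A", size=10.0),
        )),
        dict(events=(DemographyEvent(time=1.0, type="admixture", population="A",
                                     sources={"A": 0.5, "Z": 0.5}),)),
    ])
    def test_invalid_demographies_rejected(self, bad):
        base = dict(name="x", populations=(("A", 1e4),), sampling=(("A", 1.0),))
        base.update(bad)
        with pytest.raises(ConfigError):
            DemographyConfig(**base).validate()

    def test_invalid_simulation_configs_rejected(self):
        with pytest.raises(ConfigError):
            cfg(sample_size=1).validate()
        with pytest.raises(ConfigError):
            cfg(mutation_rate=-1e-8).validate()

    def test_bottleneck_restores_previous_size(self):
        from argmd.coalsim import _compile_schedule

        d = DemographyConfig(
            name="bn",
            populations=(("A", 10_000.0),),
            events=(
                DemographyEvent(time=100.0, type="size_change", population="A", size=5_000.0),
                DemographyEvent(time=500.0, type="bottleneck", population="A", size=800.0, duration=50.0),
            ),
            sampling=(("A", 1.0),),
        )
        sched = _compile_schedule(d)
        assert (500.0, "size", ("A", 800.0)) in sched
        assert (550.0, "size", ("A", 5_000.0)) in sched
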