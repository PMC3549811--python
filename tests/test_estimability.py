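"""Node counting, f, epoch grids, density profiles, sweep aggregation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from argmd import (
    Arg,
    ArgNode,
    DensityProfile,
    EpochGrid,
    aggregate_sweep,
    count_nodes,
    density_profile,
    estimable_fraction,
    minimal_descriptor,
)
from argmd import fixtures as fx


class TestCounting:
    def test_tree_counts_internal_nodes(self):
        arg = fx.recombination_free_tree()
        assert count_nodes(arg) == 2
        assert count_nodes(arg, include_leaves=True) == 5

    def test_f1_has_eight_history_nodes(self):
        assert count_nodes(fx.f1()) == 8

    def test_fraction_of_identity_descriptor_is_one(self):
        arg = fx.recombination_free_tree()
        md = minimal_descriptor(arg)
        assert estimable_fraction(arg, md) == 1.0
        assert estimable_fraction(arg, md, include_leaves=True) == 1.0

    def test_degenerate_arg_raises(self):
        lonely = Arg([ArgNode(0, 0.0, True)], [], [0], [1.0])
        md = minimal_descriptor(fx.recombination_free_tree())
        with pytest.raises(ValueError, match="undefined"):
            estimable_fraction(lonely, md)


class TestEpochGrid:
    def test_linear_and_log_modes(self):
        lin = EpochGrid.linear(100.0, 4)
        assert lin.edges == (0.0, 25.0, 50.0, 75.0, 100.0)
        log = EpochGrid.logarithmic(1000.0, bins=10)
        assert log.edges[0] == 0.0 and log.edges[-1] == 1000.0
        assert len(log.edges) == 11
        widths = np.diff(log.edges[1:])
        assert (np.diff(widths) > 0).all()  # geometric: widths grow with depth

    def test_bin_of_boundaries(self):
        g = EpochGrid.linear(10.0, 5)
        assert g.bin_of(0.0) == 0
        assert g.bin_of(2.0) == 1
        assert g.bin_of(10.0) == 4  # closed last bin
        with pytest.raises(ValueError):
            g.bin_of(10.5)

    def test_invalid_edges_rejected(self):
        with pytest.raises(ValueError):
            EpochGrid((1.0, 2.0))
        with pytest.raises(ValueError):
            EpochGrid((0.0, 2.0, 2.0))


class TestDensityProfile:
    def test_single_epoch_degenerates_to_totals(self, sim_corpus):
        arg = sim_corpus[0]
        md = minimal_descriptor(arg)
        grid = EpochGrid.linear(arg.max_age(), 1)
        prof = density_profile(arg, md, grid)
        assert prof.n_d.sum() == count_nodes(arg)
        assert prof.f_d[0] == pytest.approx(estimable_fraction(arg, md))

    def test_recombination_free_profile_is_flat_one(self):
        arg = fx.recombination_free_tree()
        md = minimal_descriptor(arg)
        prof = density_profile(arg, md, EpochGrid.linear(arg.max_age(), 4))
        f = prof.f_d
        assert np.all((f == 1.0) | np.isnan(f))

    def test_conservation_and_bruteforce_counts(self, sim_corpus):
        for arg in sim_corpus[:5]:
            md = minimal_descriptor(arg)
            for grid in (EpochGrid.linear(arg.max_age(), 7), EpochGrid.logarithmic(arg.max_age(), 13)):
                prof = density_profile(arg, md, grid)
                assert prof.n_d.sum() == count_nodes(arg)
                assert prof.n_md_d.sum() == count_nodes(md.arg)
                assert (prof.n_md_d <= prof.n_d).all()
                ages = [n.age for n in arg.nodes.values() if arg.out_degree(n.id) > 0]
                for i, (lo, hi) in enumerate(zip(grid.edges, grid.edges[1:])):
                    expect = sum(lo <= a < hi or (a == hi == grid.edges[-1]) for a in ages)
                    assert prof.n_d[i] == expect

    def test_empty_epochs_are_missing_not_zero(self):
        arg = fx.recombination_free_tree()  # internal ages 1 and 2
        md = minimal_descriptor(arg)
        prof = density_profile(arg, md, EpochGrid.linear(4.0, 8))
        assert np.isnan(prof.f_d[0])  # epoch [0, 0.5): no nodes
        assert prof.n_d[0] == 0

    def test_grid_must_cover_oldest_node(self, sim_corpus):
        arg = sim_corpus[0]
        md = minimal_descriptor(arg)
        with pytest.raises(ValueError, match="oldest node"):
            density_profile(arg, md, EpochGrid.linear(arg.max_age() / 2, 5))


class TestSweepAggregation:
    @staticmethod
    def row(dem="c", mu=1.5e-8, L=1000, n=10, r=1.0, rep=0, N=10, N_md=5):
        return dict(demography=dem, mutation_rate=mu, sequence_length=L,
                    sample_size=n, recombination_rate=r, replicate=rep,
                    N=N, N_md=N_md, f=N_md / N)

    def test_single_row_marginal_is_that_row(self):
        res = aggregate_sweep([self.row()])
        m = res.marginal_mean("sample_size")
        assert list(m["mean_f"]) == [0.5]

    def test_equal_cells_average_arithmetically(self):
        rows = [self.row(r=0.5, N_md=4, rep=i) for i in range(3)]
        rows += [self.row(r=2.0, N_md=6, rep=i) for i in range(3)]
        res = aggregate_sweep(rows)
        m = res.marginal_mean("sample_size")
        assert m["mean_f"][0] == pytest.approx(0.5)  # mean of 0.4 and 0.6
        by_r = res.marginal_mean("recombination_rate")
        assert list(by_r["mean_f"]) == [pytest.approx(0.4), pytest.approx(0.6)]

    def test_marginals_match_bruteforce_groupby(self):
        rng = np.random.default_rng(5)
        rows = []
        for dem, r, n in itertools.product(["a", "b"], [0.5, 1.5], [5, 30]):
            for rep in range(4):
                nmd = int(rng.integers(3, 10))
                rows.append(self.row(dem=dem, r=r, n=n, rep=rep, N=10, N_md=nmd))
        res = aggregate_sweep(rows)
        for param in ("demography", "recombination_rate", "sample_size"):
            got = dict(zip(res.marginal_mean(param)[param], res.marginal_mean(param)["mean_f"]))
            values = sorted({row[param] for row in rows})
            for v in values:
                cells = {}
                for row in rows:
                    if row[param] != v:
                        continue
                    key = tuple(row[p] for p in
                                ("demography", "mutation_rate", "sequence_length",
                                 "sample_size", "recombination_rate"))
                    cells.setdefault(key, []).append(row["f"])
                expect = np.mean([np.mean(fs) for fs in cells.values()])
                assert got[v] == pytest.approx(expect)

    def test_empty_input_and_bad_f_rejected(self):
        with pytest.raises(ValueError):
            aggregate_sweep([])
        bad = self.row()
        bad["f"] = 1.5
        with pytest.raises(ValueError, match="outside"):
            aggregate_sweep([bad])
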