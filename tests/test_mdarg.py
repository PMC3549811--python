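"""Minimal-descriptor extraction: classification, removal, preservation."""

from collections import Counter

import pytest

import oracles
from argmd import (
    classify_nodes,
    count_nodes,
    estimable_fraction,
    is_t_coalescent,
    minimal_descriptor,
    remove_node,
    sample_genotypes,
    validate_arg,
    verify_structure_preserving,
)
from argmd import fixtures as fx
from argmd.mdarg import MinimalDescriptor, _Working


class TestClassification:
    def test_pure_tree_is_all_coalescent(self):
        labels = classify_nodes(fx.recombination_free_tree())
        assert labels == {0: "leaf", 1: "leaf", 2: "leaf", 3: "coalescent", 4: "coalescent"}

    def test_figure2_style_labels(self):
        labels = classify_nodes(fx.figure2_style())
        assert labels[5] == "coalescent"  # the sterile re-join
        assert labels[4] == "exchange"
        assert labels[3] == "chain"

    def test_two_parents_two_children_is_hybrid(self):
        assert classify_nodes(fx.hybrid_retained())[4] == "hybrid"


class TestTCoalescent:
    def test_figure1_style_has_exactly_two_failures(self):
        arg = fx.figure1_style()
        labels = classify_nodes(arg)
        failing = [
            v for v, lab in labels.items()
            if lab in ("coalescent", "hybrid") and not is_t_coalescent(arg, v)
        ]
        assert sorted(failing) == [5, 6]

    def test_root_of_tree_is_t_coalescent(self):
        arg = fx.recombination_free_tree()
        assert is_t_coalescent(arg, 4) and is_t_coalescent(arg, 3)

    def test_leaf_and_exchange_raise(self):
        arg = fx.figure2_style()
        with pytest.raises(ValueError):
            is_t_coalescent(arg, 0)
        with pytest.raises(ValueError):
            is_t_coalescent(arg, 4)

    def test_matches_marginal_tree_membership_oracle(self, sim_corpus):
        for arg in sim_corpus:
            branching = oracles.t_coalescent_nodes(arg)
            for v, lab in classify_nodes(arg).items():
                if lab in ("coalescent", "hybrid"):
                    assert is_t_coalescent(arg, v) == (v in branching)
                elif lab in ("exchange", "chain"):
                    assert v not in branching  # single child edge cannot branch


class TestRemoveNode:
    def test_figure2_removal_of_sterile_join_merges_parallel_edges(self):
        arg = fx.figure2_style()
        out = remove_node(arg, 5)
        assert 5 not in out.nodes
        assert validate_arg(out) == []
        # the two halves reunite on a single edge 6 -> 4, exposing 4 as a chain
        mats = [e.material for e in out.children_edges(6) if e.child == 4]
        assert mats == [((0.0, 1.0),)]
        assert out.kind_of(4) == "chain"

    def test_chain_removal_adds_edge_lengths(self):
        arg = fx.figure2_style()
        out = remove_node(arg, 3)  # chain at age 0.5 between nodes 7 and 1
        (edge,) = [e for e in out.children_edges(7) if e.child == 1]
        assert out.nodes[7].age - out.nodes[1].age == 4.0
        assert edge.mutations == (0.9,)  # chain's mutation pushed down

    def test_refuses_multi_parent_and_leaf(self):
        arg = fx.figure2_style()
        with pytest.raises(ValueError, match="minimal descriptor"):
            remove_node(arg, 4)  # exchange node
        with pytest.raises(ValueError):
            remove_node(arg, 0)  # leaf

    def test_genotypes_preserved_under_algorithmic_removals(self, sim_corpus):
        # candidates the extraction would delete: chains, and coalescent
        # nodes that branch in no marginal tree (removing a t-coalescent
        # node instead would split a site across two carrying edges)
        for arg in sim_corpus[:6]:
            labels = classify_nodes(arg)
            removable = [
                v for v, lab in labels.items()
                if arg.in_degree(v) == 1
                and (lab == "chain" or (lab == "coalescent" and not is_t_coalescent(arg, v)))
            ]
            for v in removable[:10]:
                out = remove_node(arg, v)
                assert sample_genotypes(out) == sample_genotypes(arg)


class TestMinimalDescriptor:
    def test_figure2_removal_log(self):
        md = minimal_descriptor(fx.figure2_style())
        assert [(r.node, r.reason) for r in md.removal_log] == [
            (5, "not_t_coalescent"), (3, "chain"), (4, "chain"),
        ]

    def test_recombination_free_arg_is_its_own_descriptor(self):
        arg = fx.recombination_free_tree()
        md = minimal_descriptor(arg)
        assert md.removal_log == []
        assert set(md.arg.nodes) == set(arg.nodes)
        assert estimable_fraction(arg, md) == 1.0

    def test_hybrid_failing_t_test_is_retained(self):
        arg = fx.hybrid_retained()
        assert not is_t_coalescent(arg, 4)
        md = minimal_descriptor(arg)
        assert md.removal_log == [] and 4 in md.arg.nodes

    def test_f1_fixture_hand_count(self):
        arg = fx.f1()
        md = minimal_descriptor(arg)
        assert sorted(md.removed_nodes()) == [4, 5, 6]
        assert estimable_fraction(arg, md) == 5 / 8

    def test_idempotent_on_corpus(self, sim_corpus):
        for arg in sim_corpus:
            md = minimal_descriptor(arg)
            assert minimal_descriptor(md.arg).removal_log == []

    def test_descriptor_is_valid_arg_with_source_ages(self, sim_corpus):
        for arg in sim_corpus:
            md = minimal_descriptor(arg)
            assert validate_arg(md.arg) == []
            assert set(md.arg.nodes) <= set(arg.nodes)
            for v, n in md.arg.nodes.items():
                assert n.age == arg.nodes[v].age
            assert set(arg.samples) <= set(md.arg.nodes)

    def test_removal_order_does_not_change_surviving_set(self, hand_args, sim_corpus):
        for arg in list(hand_args.values()) + sim_corpus:
            a = minimal_descriptor(arg, order="youngest")
            b = minimal_descriptor(arg, order="oldest")
            assert set(a.arg.nodes) == set(b.arg.nodes)

    def test_counting_identity_and_bound(self, sim_corpus):
        for arg in sim_corpus:
            md = minimal_descriptor(arg)
            assert count_nodes(md.arg) <= count_nodes(arg)
            assert count_nodes(arg) - count_nodes(md.arg) == len(md.removal_log)

    def test_no_leaf_or_multi_parent_node_is_ever_removed(self, sim_corpus):
        for arg in sim_corpus:
            md = minimal_descriptor(arg)
            removed = set(md.removed_nodes())
            assert removed.isdisjoint(arg.samples)
            reasons = Counter(r.reason for r in md.removal_log)
            assert set(reasons) <= {"not_t_coalescent", "chain"}


class TestStructurePreservation:
    def test_corpus_is_preserved(self, sim_corpus):
        for arg in sim_corpus:
            md = minimal_descriptor(arg)
            assert verify_structure_preserving(arg, md)

    def test_detects_an_overzealous_deletion(self, sim_corpus):
        for arg in sim_corpus:
            md = minimal_descriptor(arg)
            labels = classify_nodes(md.arg)
            victims = [
                v for v, lab in labels.items()
                if lab == "coalescent" and md.arg.in_degree(v) == 1
            ]
            if not victims:
                continue
            w = _Working(md.arg)
            w.remove(victims[0])  # deletes a t-coalescent node: trees must differ
            broken = MinimalDescriptor(arg=w.to_arg(), node_map={})
            assert not verify_structure_preserving(arg, broken)
            return
        pytest.fail("corpus produced no removable t-coalescent node")
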