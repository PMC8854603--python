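"""Synteny blocks, pairwise event calls, and parsimony branch assignment."""

import itertools

import numpy as np
import pytest

from karyoz.karyotype import MarkerGenome
from karyoz.simulate import random_ancestor, simulate_karyotype_evolution
from karyoz.synteny import (
    AdjacencyCharacter,
    MACRO_MACRO,
    MICRO_MACRO,
    MICRO_MICRO,
    assign_events_to_branches,
    call_pairwise_events,
    chain_anchors,
    classify_fusion_sizes,
    find_anchors,
    fitch_assign,
    fusion_operand_sizes,
)
from karyoz.trees import RootedTree


def genome(chrom_map, marker_bp=1_000_000):
    markers = {m for row in chrom_map.values() for m, _ in row}
    return MarkerGenome(chrom_map, {m: marker_bp for m in markers})


class TestAnchors:
    def test_identical_genomes_anchor_every_marker_concordantly(self, toy_genome):
        anchors = find_anchors(toy_genome, toy_genome)
        assert len(anchors) == 8
        assert all(a.relative_orient == 1 for a in anchors)

    def test_disjoint_marker_sets_give_no_anchors(self):
        a = genome({"1": [("a", 1), ("b", 1)]})
        b = genome({"1": [("x", 1), ("y", 1)]})
        assert find_anchors(a, b) == []

    def test_reversed_chromosome_flips_relative_orientation(self, toy_genome):
        rev = MarkerGenome(
            {
                "chr1": [("c", -1), ("b", -1), ("a", -1)],
                "chr2": [("d", 1), ("e", 1)],
                "chr3": [("f", 1), ("g", 1), ("h", 1)],
            },
            toy_genome.marker_lengths,
        )
        anchors = {a.marker: a for a in find_anchors(toy_genome, rev)}
        assert all(anchors[m].relative_orient == -1 for m in "abc")
        assert all(anchors[m].relative_orient == 1 for m in "defgh")


def chainable(prev, anc, max_gap):
    """Can anc extend a run ending at prev? (independent statement of the
    collinearity/gap contract)"""
    return (
        prev.chrom_a == anc.chrom_a
        and prev.chrom_b == anc.chrom_b
        and prev.relative_orient == anc.relative_orient
        and anc.index_a - prev.index_a - 1 <= max_gap
        and 0 < (anc.index_b - prev.index_b) * prev.relative_orient <= max_gap + 1
    )


def assert_valid_and_maximal(anchors, blocks, max_gap):
    """Oracle by property: blocks partition the anchors into valid collinear
    runs that cannot be extended by merging consecutive same-pair blocks."""
    seen = [a for bl in blocks for a in bl.anchors]
    assert sorted(a.marker for a in seen) == sorted(a.marker for a in anchors)
    for bl in blocks:
        for prev, anc in zip(bl.anchors, bl.anchors[1:]):
            assert chainable(prev, anc, max_gap)
    from collections import defaultdict

    by_pair = defaultdict(list)
    for bl in blocks:
        by_pair[(bl.chrom_a, bl.chrom_b)].append(bl)
    for group in by_pair.values():
        group.sort(key=lambda b: b.a_start)
        for left, right in zip(group, group[1:]):
            assert not chainable(left.anchors[-1], right.anchors[0], max_gap)


class TestChaining:
    def test_collinear_anchors_form_single_block(self, toy_genome):
        anchors = find_anchors(toy_genome, toy_genome)
        blocks = chain_anchors(anchors, max_gap=0, min_block=1)
        assert len(blocks) == 3  # one per chromosome
        assert {b.n_anchors for b in blocks} == {2, 3}

    def test_gap_larger_than_max_splits_block(self):
        # B genome drops marker 'c', creating a gap of 1 in genome-B indices
        a = genome({"1": [("a", 1), ("b", 1), ("c", 1), ("d", 1), ("e", 1)]})
        b = genome({"1": [("a", 1), ("b", 1), ("d", 1), ("e", 1)]})
        anchors = find_anchors(a, b)
        assert len(chain_anchors(anchors, max_gap=1, min_block=1)) == 1
        assert len(chain_anchors(anchors, max_gap=0, min_block=1)) == 2

    def test_min_block_discards_short_runs(self):
        a = genome({"1": [("a", 1), ("b", 1), ("c", 1), ("d", 1), ("e", 1)]})
        b = genome({"1": [("a", 1), ("b", 1), ("c", 1), ("d", 1), ("e", -1)],
                    })
        # orientation flip at 'e' creates blocks of sizes {4, 1}
        blocks = chain_anchors(find_anchors(a, b), max_gap=0, min_block=3)
        assert [bl.n_anchors for bl in blocks] == [4]

    def test_matches_brute_force_runs_on_random_shuffles(self, rng):
        markers = [f"m{i}" for i in range(12)]
        a = genome({"1": [(m, 1) for m in markers]})
        for trial in range(25):
            perm = rng.permutation(12)
            split = int(rng.integers(4, 9))
            b = genome(
                {
                    "1": [(markers[i], int(rng.choice([1, -1]))) for i in perm[:split]],
                    "2": [(markers[i], 1) for i in perm[split:]],
                }
            )
            anchors = find_anchors(a, b)
            for max_gap in (0, 1, 2):
                got = chain_anchors(anchors, max_gap=max_gap, min_block=1)
                assert_valid_and_maximal(anchors, got, max_gap)


class TestPairwiseEvents:
    def test_fusion_called_when_two_ref_chroms_map_to_one_qry(self):
        ref = genome({"1": [("a", 1), ("b", 1)], "2": [("c", 1), ("d", 1)]})
        qry = genome({"1": [("a", 1), ("b", 1), ("c", 1), ("d", 1)]})
        calls = call_pairwise_events(ref, qry, chain_anchors(find_anchors(ref, qry)))
        assert [(e.kind, e.ref_chroms) for e in calls.events] == [("fusion", ("1", "2"))]

    def test_fission_called_when_ref_chrom_splits(self):
        ref = genome({"1": [("a", 1), ("b", 1), ("c", 1), ("d", 1)]})
        qry = genome({"1": [("a", 1), ("b", 1)], "2": [("c", 1), ("d", 1)]})
        calls = call_pairwise_events(ref, qry, chain_anchors(find_anchors(ref, qry)))
        assert [(e.kind, e.ref_chroms) for e in calls.events] == [("fission", ("1",))]

    def test_identical_genomes_give_zero_events(self, toy_genome):
        calls = call_pairwise_events(
            toy_genome, toy_genome, chain_anchors(find_anchors(toy_genome, toy_genome))
        )
        assert calls.events == []

    def test_fusion_and_reciprocal_fission_share_junction(self):
        ref = genome({"1": [("a", 1), ("b", 1)], "2": [("c", 1), ("d", 1)]})
        qry = genome({"1": [("a", 1), ("b", 1), ("c", -1), ("d", -1)]})
        fwd = call_pairwise_events(ref, qry, chain_anchors(find_anchors(ref, qry)))
        rev = call_pairwise_events(qry, ref, chain_anchors(find_anchors(qry, ref)))
        assert fwd.events[0].kind == "fusion" and rev.events[0].kind == "fission"
        assert fwd.events[0].junction == rev.events[0].junction

    def test_inversions_reported_separately_not_as_events(self):
        ref = genome({"1": [("a", 1), ("b", 1), ("c", 1), ("d", 1)]})
        qry = genome({"1": [("a", 1), ("c", -1), ("b", -1), ("d", 1)]})
        calls = call_pairwise_events(ref, qry, chain_anchors(find_anchors(ref, qry)))
        assert calls.events == []
        assert len(calls.inversions) == 1


def exhaustive_min_changes(char: AdjacencyCharacter, tree: RootedTree) -> int:
    """Oracle: minimum changes over every internal-state labeling."""
    internals = [n.label for n in tree.preorder() if not n.is_leaf]
    best = None
    for states in itertools.product((0, 1), repeat=len(internals)):
        lab = dict(zip(internals, states))
        if lab[tree.root.label] != char.root_state:
            continue
        lab.update(char.tip_states)
        changes = sum(
            1
            for n in tree.preorder()
            if n.parent is not None and lab[n.label] != lab[n.parent.label]
        )
        best = changes if best is None else min(best, changes)
    return best


class TestFitch:
    @pytest.mark.parametrize("root_state", [0, 1])
    def test_matches_exhaustive_enumeration_on_all_patterns(self, root_state):
        tree = RootedTree.from_newick("(((A,B),(C,D)),(E,F));")
        tips = tree.leaf_labels()
        for bits in itertools.product((0, 1), repeat=len(tips)):
            char = AdjacencyCharacter(
                junction=frozenset({"x.h", "y.t"}),
                tip_states=dict(zip(tips, bits)),
                root_state=root_state,
            )
            _, changes, _ = fitch_assign(char, tree)
            assert changes == exhaustive_min_changes(char, tree)

    def test_sister_pair_gain_lands_on_stem_branch(self, eight_tip_tree):
        tips = eight_tip_tree.leaf_labels()
        char = AdjacencyCharacter(
            junction=frozenset({"x.h", "y.t"}),
            tip_states={t: int(t in ("A", "B")) for t in tips},
            root_state=0,
        )
        events, changes, unique = fitch_assign(char, eight_tip_tree)
        assert changes == 1 and unique
        [ev] = events
        assert ev.kind == "fusion"
        assert eight_tip_tree.clade_leaves(ev.branch) == {"A", "B"}

    def test_private_tip_state_assigned_to_terminal_branch(self, eight_tip_tree):
        tips = eight_tip_tree.leaf_labels()
        char = AdjacencyCharacter(
            junction=frozenset({"x.h", "y.t"}),
            tip_states={t: int(t == "G") for t in tips},
            root_state=0,
        )
        events, _, _ = fitch_assign(char, eight_tip_tree)
        assert [(e.kind, e.branch) for e in events] == [("fusion", "G")]

    def test_universal_adjacency_triggers_no_events(self, eight_tip_tree):
        char = AdjacencyCharacter(
            junction=frozenset({"x.h", "y.t"}),
            tip_states={t: 1 for t in eight_tip_tree.leaf_labels()},
            root_state=1,
        )
        events, changes, unique = fitch_assign(char, eight_tip_tree)
        assert events == [] and changes == 0 and unique


class TestRecovery:
    def test_events_recovered_with_perfect_precision_and_recall(self, eight_tip_tree):
        anc = random_ancestor()
        tips, log = simulate_karyotype_evolution(anc, eight_tip_tree, seed=11, n_events=38)
        ba = assign_events_to_branches(tips, anc, eight_tip_tree)
        truth = {(e.kind, e.branch, e.junction) for e in log if not e.skipped}
        recovered = {(e.kind, e.branch, e.junction) for e in ba.events}
        assert recovered == truth

    def test_chromosome_count_change_equals_fission_minus_fusion(self, eight_tip_tree):
        anc = random_ancestor(n_macro=4, n_micro=8)
        tips, log = simulate_karyotype_evolution(anc, eight_tip_tree, seed=5, n_events=25)
        for tip, g in tips.items():
            path = set(eight_tip_tree.path_to(tip))
            n_fis = sum(1 for e in log if e.branch in path and e.kind == "fission")
            n_fus = sum(1 for e in log if e.branch in path and e.kind == "fusion")
            assert len(g) - len(anc) == n_fis - n_fus


class TestSizeClasses:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (5_000_000, 60_000_000, MICRO_MACRO),
            (5_000_000, 8_000_000, MICRO_MICRO),
            (20_000_000, 30_000_000, MACRO_MACRO),  # boundary: 20 Mb is macro
            (19_999_999, 20_000_000, MICRO_MACRO),
        ],
    )
    def test_size_class_assignment(self, a, b, expected):
        assert classify_fusion_sizes([(a, b)])[expected] == 1

    def test_operand_sizes_reflect_prior_events(self, eight_tip_tree):
        anc = random_ancestor(n_macro=2, n_micro=4)
        tips, log = simulate_karyotype_evolution(anc, eight_tip_tree, seed=9, n_events=15)
        sizes = fusion_operand_sizes(anc, eight_tip_tree, log)
        n_fusions = sum(1 for e in log if e.kind == "fusion" and not e.skipped)
        assert len(sizes) == n_fusions
        total = sum(classify_fusion_sizes(sizes).values())
        assert total == n_fusions
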