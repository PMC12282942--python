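"""The SHM-ordered inheritance tree algorithm: root selection, dummy
roots, the inheritance test, edge weights and exact-recovery oracles."""

import itertools
import random

import pytest

from shmtree.clonotype_shm import CloneNode
from shmtree.inheritance_tree import (build_tree, edge_weight, inherits,
                                      levenshtein, make_dummy_root,
                                      select_root)
from shmtree.simulator import SimParams, sim_to_lineage, simulate_tree

R = "cdrh3"
GERMLINE = "ACGTACGTAC"


def mknode(muts, isotype="IgG", size=1, germline=GERMLINE, shm=None):
    """Clonotype node from a mutation set, sequence derived by applying
    the mutations to a nominal germline."""
    seq = list(germline)
    for _, pos, base in muts:
        seq[pos] = base
    muts = frozenset(muts)
    return CloneNode(node_name="", clonotype_seq="".join(seq), size=size,
                     isotype_counts={isotype: size}, node_isotype=isotype,
                     shm_rate=len(muts) / len(germline) if shm is None
                     else shm, cdr_mutations=muts)


class TestDummyRoot:
    def test_disagreement_becomes_d(self):
        assert make_dummy_root(["AGC", "CGC"]) == "DGC"

    def test_full_agreement_keeps_bases(self):
        assert make_dummy_root(["AAA", "AAA"]) == "AAA"

    def test_multiple_disagreements(self):
        assert make_dummy_root(["AGT", "CGA"]) == "DGD"

    def test_unequal_lengths_raise(self):
        with pytest.raises(ValueError):
            make_dummy_root(["AG", "AGC"])

    def test_single_candidate_raises(self):
        with pytest.raises(ValueError):
            make_dummy_root(["AGC"])


class TestSelectRoot:
    def test_unique_minimum_shm_wins(self):
        nodes = [mknode({(R, 0, "T")}, shm=0.05),
                 mknode(set(), shm=0.01),
                 mknode({(R, 1, "T")}, shm=0.02)]
        root, is_dummy = select_root(nodes)
        assert root is nodes[1] and not is_dummy

    def test_unswitched_isotype_breaks_tie(self):
        igm = mknode({(R, 0, "T")}, isotype="IgM", shm=0.0)
        igg = mknode({(R, 1, "T")}, isotype="IgG", shm=0.0)
        root, is_dummy = select_root([igg, igm])
        assert root is igm and not is_dummy

    def test_remaining_tie_builds_dummy_consensus(self):
        a = mknode({(R, 0, "A")}, germline="GGC", shm=0.0)  # AGC
        b = mknode({(R, 0, "C")}, germline="GGC", shm=0.0)  # CGC
        root, is_dummy = select_root([a, b])
        assert is_dummy
        assert root.clonotype_seq == "DGC"
        assert root.shm_rate == 0.0
        assert root.cdr_mutations == frozenset()  # intersection
        assert root.size == 0 and root.node_isotype == "dummy"

    def test_dummy_mutations_are_candidate_intersection(self):
        shared = (R, 5, "G")
        a = mknode({shared, (R, 0, "A")}, shm=0.2)
        b = mknode({shared, (R, 1, "T")}, shm=0.2)
        root, is_dummy = select_root([a, b])
        assert is_dummy and root.cdr_mutations == {shared}
        assert inherits(root.cdr_mutations, a.cdr_mutations)
        assert inherits(root.cdr_mutations, b.cdr_mutations)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            select_root([])


class TestInherits:
    def test_empty_set_is_always_inherited(self):
        assert inherits(frozenset(), frozenset({(R, 3, "T")}))

    def test_subset_holds(self):
        assert inherits(frozenset({(R, 3, "T")}),
                        frozenset({(R, 3, "T"), ("cdrh1", 0, "G")}))

    def test_same_position_different_base_is_not_inherited(self):
        assert not inherits(frozenset({(R, 3, "T")}),
                            frozenset({(R, 3, "A"), ("cdrh1", 0, "G")}))


class TestEdgeWeight:
    @pytest.mark.parametrize("parent,child,expected", [
        ("ACGT", "ACGT", 0.0),
        ("ACGT", "ACTT", 0.25),
        ("AAAA", "AAAAA", 0.25),  # one insertion over parent length 4
    ])
    def test_normalized_levenshtein(self, parent, child, expected):
        assert edge_weight(parent, child) == pytest.approx(expected)

    def test_dummy_base_mismatches_every_nucleotide(self):
        assert levenshtein("DGC", "AGC") == 1
        assert levenshtein("DGC", "CGC") == 1

    def test_empty_parent_raises(self):
        with pytest.raises(ValueError):
            edge_weight("", "ACGT")


def _chain_nodes():
    m1, m2, m3 = (R, 0, "T"), (R, 3, "A"), (R, 7, "C")
    return [mknode(set()), mknode({m1}), mknode({m1, m2}),
            mknode({m1, m2, m3})]


def _star_nodes():
    return [mknode(set()), mknode({(R, 0, "T")}), mknode({(R, 3, "A")}),
            mknode({(R, 7, "C")})]


def _edge_seqs(tree):
    return {(tree.nodes[e.parent].clonotype_seq,
             tree.nodes[e.child].clonotype_seq) for e in tree.edges}


def _brute_force_best_parents(nodes):
    """Independent oracle: for every node, enumerate all inheritance-valid
    lower-SHM parents and keep those at minimum Levenshtein distance."""
    best = {}
    for child in nodes:
        valid = [p for p in nodes if p is not child
                 and p.shm_rate <= child.shm_rate
                 and p.cdr_mutations <= child.cdr_mutations
                 and p.cdr_mutations != child.cdr_mutations]
        if not valid:
            continue
        dists = [levenshtein(p.clonotype_seq, child.clonotype_seq)
                 for p in valid]
        dmin = min(dists)
        best[child.clonotype_seq] = {p.clonotype_seq
                                     for p, d in zip(valid, dists)
                                     if d == dmin}
    return best


class TestBuildTree:
    def test_chain_recovered_exactly(self):
        nodes = _chain_nodes()
        truth = {(nodes[i].clonotype_seq, nodes[i + 1].clonotype_seq)
                 for i in range(3)}
        tree = build_tree(nodes)
        assert _edge_seqs(tree) == truth
        # oracle: the generating parent is the unique minimum-distance
        # valid parent of every non-root node
        for child_seq, parents in _brute_force_best_parents(nodes).items():
            assert len(parents) == 1
            assert (next(iter(parents)), child_seq) in truth

    def test_star_recovered_exactly(self):
        nodes = _star_nodes()
        root_seq = nodes[0].clonotype_seq
        tree = build_tree(nodes)
        assert _edge_seqs(tree) == {(root_seq, n.clonotype_seq)
                                    for n in nodes[1:]}
        for parents in _brute_force_best_parents(nodes).values():
            assert parents == {root_seq}

    def test_single_node_tree(self):
        tree = build_tree([mknode(set())])
        assert len(tree.nodes) == 1 and tree.edges == []
        assert tree.root == "R"

    def test_root_named_r_and_children_numbered_by_shm(self):
        tree = build_tree(_chain_nodes())
        assert tree.root == "R"
        names = [e.child for e in tree.edges]
        assert names == ["1", "2", "3"]
        shms = [tree.nodes[n].shm_rate for n in names]
        assert shms == sorted(shms)

    def test_structure_count_invariant(self):
        tree = build_tree(_star_nodes())
        assert len(tree.edges) == len(tree.nodes) - 1

    def test_deterministic_under_input_shuffling(self):
        make = lambda: sim_to_lineage(simulate_tree(
            SimParams(L=50, N=20, lambda_c=2, lambda_m=1, seed=5)))
        base = _edge_seqs(build_tree(make()))
        for seed in range(5):
            shuffled = make()
            random.Random(seed).shuffle(shuffled)
            assert _edge_seqs(build_tree(shuffled)) == base

    def test_conflicting_branches_both_attach_to_root(self):
        # contradictory bases at one site: neither mutated node can be
        # the other's ancestor, so both hang off the germline root
        nodes = [mknode(set()),
                 mknode({(R, 0, "T"), (R, 3, "A")}),
                 mknode({(R, 0, "G"), (R, 3, "A"), (R, 5, "T")})]
        tree = build_tree(nodes)
        assert len(tree.edges) == 2
        assert all(e.parent == "R" and not e.fallback for e in tree.edges)
        for e in tree.edges:
            assert inherits(tree.nodes[e.parent].cdr_mutations,
                            tree.nodes[e.child].cdr_mutations)

    def test_fallback_flagged_when_root_set_not_inherited(self):
        # root has a mutation the child contradicts -> only the universal
        # root fallback can attach the child
        root = mknode({(R, 0, "T")}, isotype="IgM", shm=0.0)
        child = mknode({(R, 0, "G"), (R, 3, "A")}, shm=0.2)
        tree = build_tree([root, child])
        assert len(tree.edges) == 1
        assert tree.edges[0].fallback is True

    @pytest.mark.parametrize("params", [
        SimParams(L=60, N=25, lambda_c=2, lambda_m=1, seed=s)
        for s in range(8)])
    def test_simulated_lineages_obey_ordering_and_inheritance(self, params):
        tree = build_tree(sim_to_lineage(simulate_tree(params)))
        for e in tree.edges:
            parent, child = tree.nodes[e.parent], tree.nodes[e.child]
            assert child.shm_rate >= parent.shm_rate
            assert not e.fallback  # germline-rooted: no fallback needed
            assert inherits(parent.cdr_mutations, child.cdr_mutations)
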