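"""Tree structure: newick round-trips, bipartitions, NNI, consensus, RF."""

import dendropy
import numpy as np
import pytest

from mitopart.trees import (Tree, TreeError, all_topologies,
                            majority_rule_consensus, nni_neighbors,
                            random_nni, random_topology, rf_distance,
                            star_tree, topology_key)

TAXA6 = ["a", "b", "c", "d", "e", "f"]


class TestNewick:
    def test_roundtrip_preserves_topology_and_lengths(self, rng):
        t = random_topology(TAXA6, rng)
        back = Tree.from_newick(t.to_newick(), taxa=TAXA6)
        assert topology_key(back) == topology_key(t)
        assert back.total_length() == pytest.approx(t.total_length())

    def test_dendropy_agrees_on_roundtrip(self, rng):
        """Cross-check our writer with an independent newick parser."""
        t = random_topology(TAXA6, rng)
        dt = dendropy.Tree.get(data=t.to_newick(), schema="newick")
        assert sorted(lf.taxon.label for lf in dt.leaf_node_iter()) == TAXA6
        assert dt.length() == pytest.approx(t.total_length())

    def test_taxon_mismatch_rejected(self):
        with pytest.raises(TreeError):
            Tree.from_newick("((a,b),(c,d));", taxa=["a", "b", "c", "x"])


class TestTopologyKey:
    def test_rotation_invariant(self):
        k1 = topology_key(Tree.from_newick("((a,b),(c,d),e);"))
        k2 = topology_key(Tree.from_newick("(e,(d,c),(b,a));"))
        assert k1 == k2

    def test_branch_lengths_ignored(self):
        k1 = topology_key(Tree.from_newick("((a:1,b:2):3,(c:4,d:5):6,e:7);"))
        k2 = topology_key(Tree.from_newick("((a,b),(c,d),e);"))
        assert k1 == k2

    def test_nni_alternatives_differ(self):
        k1 = topology_key(Tree.from_newick("((a,b),(c,d));"))
        k2 = topology_key(Tree.from_newick("((a,c),(b,d));"))
        assert k1 != k2

    def test_caterpillar_has_n_minus_3_nontrivial_splits(self):
        t = Tree.from_newick("(a,(b,(c,(d,(e,f)))));")
        assert len(t.bipartitions()) == 3


class TestRfDistance:
    def test_identical_trees(self, rng):
        t = random_topology(TAXA6, rng)
        assert rf_distance(t, t.copy()) == 0

    def test_four_taxon_nni_neighbors_at_distance_two(self):
        t1 = Tree.from_newick("((a,b),(c,d));")
        t2 = Tree.from_newick("((a,c),(b,d));")
        assert rf_distance(t1, t2) == 2
        assert rf_distance(t2, t1) == 2

    def test_agrees_with_dendropy(self, rng):
        """Independent oracle: dendropy's symmetric difference."""
        ns = dendropy.TaxonNamespace(TAXA6)
        for _ in range(10):
            t1 = random_topology(TAXA6, rng)
            t2 = random_topology(TAXA6, rng)
            d1 = dendropy.Tree.get(data=t1.to_newick(), schema="newick",
                                   taxon_namespace=ns)
            d2 = dendropy.Tree.get(data=t2.to_newick(), schema="newick",
                                   taxon_namespace=ns)
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            expect = dendropy.calculate.treecompare.symmetric_difference(
                d1, d2)
            assert rf_distance(t1, t2) == expect

    def test_taxon_mismatch_rejected(self, rng):
        t1 = random_topology(TAXA6, rng)
        t2 = random_topology(["x"] + TAXA6[1:], rng)
        with pytest.raises(TreeError):
            rf_distance(t1, t2)


class TestEnumerationAndNni:
    def test_topology_counts_follow_double_factorial(self):
        assert len(list(all_topologies(["a", "b", "c", "d"]))) == 3
        assert len(list(all_topologies(TAXA6[:5]))) == 15
        assert len(list(all_topologies(TAXA6))) == 105

    def test_enumeration_yields_distinct_topologies(self):
        keys = {topology_key(t) for t in all_topologies(TAXA6[:5])}
        assert len(keys) == 15

    def test_refuses_above_guard(self):
        with pytest.raises(TreeError):
            list(all_topologies([f"t{i}" for i in range(10)]))

    def test_four_taxon_nni_reaches_both_alternatives_evenly(self, rng):
        t = Tree.from_newick("((a,b),(c,d));")
        base = topology_key(t)
        seen = {}
        for _ in range(4000):
            k = topology_key(random_nni(t, rng))
            assert k != base
            seen[k] = seen.get(k, 0) + 1
        assert len(seen) == 2
        freqs = np.array(list(seen.values())) / 4000
        assert np.abs(freqs - 0.5).max() < 3 * 0.5 / np.sqrt(4000)

    def test_nni_neighbors_are_valid_binary_trees(self, rng):
        t = random_topology(TAXA6, rng)
        for nbr in nni_neighbors(t):
            assert nbr.is_binary()
            assert sorted(nbr.taxa) == sorted(t.taxa)
            assert set(nbr.lengths.values()) == set(t.lengths.values())


class TestConsensus:
    def test_identical_trees_return_that_topology(self, rng):
        t = random_topology(TAXA6, rng)
        cons = majority_rule_consensus([t.copy() for _ in range(5)])
        assert topology_key(cons) == topology_key(t)

    def test_one_nni_disagreement_collapses_one_node(self):
        t1 = Tree.from_newick("(((a,b),c),(d,(e,f)));")
        t2 = Tree.from_newick("(((a,c),b),(d,(e,f)));")
        cons = majority_rule_consensus([t1, t2])
        shared = t1.bipartitions() & t2.bipartitions()
        assert cons.bipartitions() == shared

    def test_threshold_one_is_strict_consensus(self):
        t1 = Tree.from_newick("(((a,b),c),(d,(e,f)));")
        t2 = Tree.from_newick("(((a,c),b),(d,(e,f)));")
        strict = majority_rule_consensus([t1, t1, t2], threshold=1.0)
        assert strict.bipartitions() == t1.bipartitions() & t2.bipartitions()

    def test_majority_agrees_with_dendropy(self, rng):
        """Independent oracle: dendropy majority-rule consensus."""
        trees = [random_topology(TAXA6, rng) for _ in range(7)]
        ours = majority_rule_consensus(trees)
        ns = dendropy.TaxonNamespace(TAXA6)
        tl = dendropy.TreeList(
            [dendropy.Tree.get(data=t.to_newick(), schema="newick",
                               taxon_namespace=ns) for t in trees])
        dcons = tl.consensus(min_freq=0.5)
        dcons.is_rooted = False
        theirs = Tree.from_newick(dcons.as_string(schema="newick"),
                                  taxa=None)
        assert ours.bipartitions() == theirs.bipartitions()
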