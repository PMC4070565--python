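"""Parsimony and ML cross-checks: Fitch, searches, bootstrap."""

import numpy as np
import pytest

from mitopart.alt_inference import (InferenceError, bootstrap, fitch_score,
                                    fitch_score_brute_force, ml_search,
                                    mp_search)
from mitopart.seqdata import Alignment, GeneEntry, GeneMap
from mitopart.simulate import SimSpec, simulate_alignment, simulate_tree
from mitopart.trees import (Tree, majority_rule_consensus, random_topology,
                            rf_distance, topology_key)


def _sim(n_taxa=6, n_sites=500, seed=0, height=0.25):
    gm = GeneMap([GeneEntry("g1", 0, n_sites, "rRNA", None, "+")])
    spec = SimSpec(n_taxa=n_taxa, tree_height=height, gene_map=gm, seed=seed,
                   ambiguity_rate=0.0, class_freqs=None,
                   class_rates={"rRNA": 1.0})
    tree = simulate_tree(spec)
    aln, _ = simulate_alignment(tree, spec)
    return tree, aln


class TestFitch:
    def test_invariant_alignment_scores_zero(self, rng):
        taxa = [f"t{i}" for i in range(5)]
        tree = random_topology(taxa, rng)
        aln = Alignment(taxa, np.tile(np.array(list("ACGT")), (5, 1)))
        assert fitch_score(tree, aln) == 0

    def test_hand_worked_four_taxon_column(self):
        aln = Alignment.from_sequences(
            [("a1", "A"), ("a2", "A"), ("t1", "T"), ("t2", "T")])
        taxa = ["a1", "a2", "t1", "t2"]
        good = Tree.from_newick("((a1,a2),(t1,t2));", taxa=taxa)
        bad = Tree.from_newick("((a1,t1),(a2,t2));", taxa=taxa)
        assert fitch_score(good, aln) == 1
        assert fitch_score(bad, aln) == 2

    def test_matches_enumeration_on_random_instances(self, rng):
        for _ in range(8):
            n = int(rng.integers(4, 7))
            taxa = [f"t{i}" for i in range(n)]
            tree = random_topology(taxa, rng)
            aln = Alignment(taxa, rng.choice(list("ACGTR-?"), size=(n, 5)))
            assert fitch_score(tree, aln) == fitch_score_brute_force(tree, aln)

    def test_additive_over_concatenation(self, rng):
        taxa = [f"t{i}" for i in range(6)]
        tree = random_topology(taxa, rng)
        a = Alignment(taxa, rng.choice(list("ACGT"), size=(6, 10)))
        b = Alignment(taxa, rng.choice(list("ACGT"), size=(6, 7)))
        concat = Alignment(taxa, np.hstack([a.matrix, b.matrix]))
        assert fitch_score(tree, concat) == (fitch_score(tree, a)
                                             + fitch_score(tree, b))

    def test_taxon_mismatch_rejected(self, rng):
        tree = random_topology(["a", "b", "c", "d"], rng)
        aln = Alignment.from_sequences([("a", "A"), ("b", "A"), ("c", "A"),
                                        ("x", "A")])
        with pytest.raises(InferenceError):
            fitch_score(tree, aln)


class TestMpSearch:
    def test_single_informative_column_gives_unique_mp_tree(self):
        aln = Alignment.from_sequences(
            [("a1", "AA"), ("a2", "AA"), ("t1", "TA"), ("t2", "TA")])
        res = mp_search(aln, mode="exhaustive")
        assert res.complete
        assert len(res.trees) == 1
        expect = topology_key(Tree.from_newick(
            "((a1,a2),(t1,t2));", taxa=["a1", "a2", "t1", "t2"]))
        assert topology_key(res.trees[0]) == expect

    def test_two_conflicting_columns_tie_two_trees(self):
        # column 1 groups (a1,a2); column 2 groups (a1,t1)
        aln = Alignment.from_sequences(
            [("a1", "AC"), ("a2", "AG"), ("t1", "TC"), ("t2", "TG")])
        res = mp_search(aln, mode="exhaustive")
        assert len(res.trees) == 2
        cons = majority_rule_consensus(res.trees)
        assert cons.bipartitions() == set()  # fully unresolved consensus

    def test_result_invariant_to_taxon_input_order(self, rng):
        taxa = [f"t{i}" for i in range(5)]
        m = rng.choice(list("ACGT"), size=(5, 20))
        aln1 = Alignment(taxa, m)
        perm = rng.permutation(5)
        aln2 = Alignment([taxa[i] for i in perm], m[perm])
        r1 = mp_search(aln1, mode="exhaustive")
        r2 = mp_search(aln2, mode="exhaustive")
        assert r1.score == r2.score
        assert ({topology_key(t) for t in r1.trees}
                == {topology_key(t) for t in r2.trees})

    def test_exhaustive_refused_above_guard(self, rng):
        taxa = [f"t{i}" for i in range(10)]
        aln = Alignment(taxa, rng.choice(list("ACGT"), size=(10, 8)))
        with pytest.raises(InferenceError):
            mp_search(aln, mode="exhaustive")

    def test_heuristic_flagged_incomplete(self, rng):
        tree, aln = _sim(6, 200, seed=5)
        res = mp_search(aln, mode="heuristic-NNI")
        assert not res.complete
        assert res.trees


class TestMlSearch:
    def test_recovers_generating_topology_from_wrong_start(self):
        hits = 0
        for seed in range(3):
            tree, aln = _sim(5, 800, seed=seed, height=0.3)
            start = random_topology(sorted(aln.taxa),
                                    np.random.default_rng(999))
            best, lnl = ml_search(aln, start=start, n_categories=2)
            hits += rf_distance(best, tree) == 0
        assert hits >= 2

    def test_generating_tree_is_a_fixed_point_on_clean_data(self):
        tree, aln = _sim(5, 1000, seed=11, height=0.3)
        best, lnl = ml_search(aln, start=tree, n_categories=2)
        assert rf_distance(best, tree) == 0


class TestBootstrap:
    def test_supports_are_percentages_and_reproducible(self, rng):
        tree, aln = _sim(5, 120, seed=2)
        r1 = bootstrap(aln, method="MP", n_replicates=20, seed=4)
        r2 = bootstrap(aln, method="MP", n_replicates=20, seed=4)
        assert r1.n_replicates == 20
        assert r1.support == r2.support
        assert all(0 <= v <= 100 for v in r1.support.values())
        assert len(r1.replicate_trees) == 20

    def test_replicates_keep_original_column_count(self, rng):
        tree, aln = _sim(5, 90, seed=3)
        res = bootstrap(aln, method="MP", n_replicates=3, seed=1)
        # replicate trees exist for every replicate; column count is fixed by
        # construction (resampling size = alignment length)
        assert len(res.replicate_trees) == 3

    def test_strong_signal_gives_high_support_for_true_splits(self):
        tree, aln = _sim(5, 900, seed=7, height=0.3)
        res = bootstrap(aln, method="MP", n_replicates=40, seed=9)
        for mask in tree.bipartitions():
            assert res.support.get(mask, 0.0) >= 95.0
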