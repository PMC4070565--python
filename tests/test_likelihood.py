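"""Pruning likelihood vs closed forms and the enumeration oracle."""

import numpy as np
import pytest

from mitopart.likelihood import (LikelihoodEngine, LikelihoodError,
                                 brute_force_log_likelihood,
                                 compress_patterns, leaf_vector)
from mitopart.models import PartitionedModel, SubstitutionModel
from mitopart.partitions import CharSet, PartitionScheme, single_partition
from mitopart.seqdata import Alignment
from mitopart.trees import Tree, random_topology, star_tree


def random_instance(rng, n_taxa, n_sites=8, gamma=True, ambig=True):
    taxa = [f"t{i}" for i in range(n_taxa)]
    tree = random_topology(taxa, rng)
    symbols = list("ACGT") + (["R", "N", "-", "?"] if ambig else [])
    p = ([0.22] * 4 + [0.03] * 4) if ambig else [0.25] * 4
    aln = Alignment(taxa, rng.choice(symbols, p=p, size=(n_taxa, n_sites)))
    model = SubstitutionModel(
        "GTR", tuple(rng.random(6) + 0.2), tuple(rng.dirichlet([6] * 4)),
        gamma_shape=float(rng.uniform(0.3, 2.0)) if gamma else None,
        n_gamma_categories=3)
    pm = PartitionedModel([model], np.ones(1), np.ones(1))
    return tree, aln, pm


class TestPatternCompression:
    def test_identical_columns_collapse_with_weights(self):
        aln = Alignment.from_sequences([("a", "AAAA"), ("b", "CCCC")])
        table = compress_patterns(aln)
        assert table.n_patterns == 1
        assert table.weights.tolist() == [4]

    def test_partitions_keep_identical_columns_separate(self):
        aln = Alignment.from_sequences([("a", "AA"), ("b", "CC")])
        scheme = PartitionScheme("x", [CharSet("l", (0,)), CharSet("r", (1,))],
                                 2)
        table = compress_patterns(aln, scheme)
        assert table.n_patterns == 2
        assert table.part_index.tolist() == [0, 1]

    def test_lnl_unchanged_by_compression(self, rng):
        tree, aln, pm = random_instance(rng, 5, n_sites=30)
        # uncompressed route: every column its own partition-of-one pattern
        eng = LikelihoodEngine.for_alignment(aln, None, n_categories=3)
        total = eng.log_likelihood(tree, pm)
        per_site = 0.0
        for j in range(aln.length):
            sub = aln.subset_columns([j])
            e = LikelihoodEngine.for_alignment(sub, None, n_categories=3)
            per_site += e.log_likelihood(tree, pm)
        assert total == pytest.approx(per_site, abs=1e-9)


class TestPruningVsClosedForms:
    def test_two_taxa_single_matching_site_jc(self):
        taxa = ["a", "b"]
        tree = Tree(("a", "b"), {0: [1], 1: [0]}, {(0, 1): 0.1})
        aln = Alignment.from_sequences([("a", "A"), ("b", "A")])
        pm = PartitionedModel([SubstitutionModel.jc()], np.ones(1), np.ones(1))
        eng = LikelihoodEngine.for_alignment(aln, None, 1)
        expect = np.log(0.25 * (0.25 + 0.75 * np.exp(-4 * 0.1 / 3)))
        assert eng.log_likelihood(tree, pm) == pytest.approx(expect, abs=1e-12)

    def test_zero_length_star_identical_sequences(self):
        taxa = [f"t{i}" for i in range(5)]
        tree = star_tree(taxa, branch_length=0.0)
        aln = Alignment.from_sequences([(t, "ACG") for t in taxa])
        m = SubstitutionModel("GTR", (1.0,) * 6, (0.4, 0.2, 0.2, 0.2))
        pm = PartitionedModel([m], np.ones(1), np.ones(1))
        eng = LikelihoodEngine.for_alignment(aln, None, 1)
        expect = np.log(0.4) + np.log(0.2) + np.log(0.2)
        assert eng.log_likelihood(tree, pm) == pytest.approx(expect, abs=1e-9)

    def test_all_missing_columns_contribute_zero(self, rng):
        taxa = [f"t{i}" for i in range(4)]
        tree = random_topology(taxa, rng)
        aln = Alignment(taxa, np.full((4, 6), "?"))
        pm = PartitionedModel([SubstitutionModel.jc(0.5)], np.ones(1),
                              np.ones(1))
        eng = LikelihoodEngine.for_alignment(aln, None, 4)
        assert eng.log_likelihood(tree, pm) == pytest.approx(0.0, abs=1e-12)


class TestEnumerationOracle:
    @pytest.mark.parametrize("n_taxa", [2, 3, 4, 5, 6])
    def test_matches_brute_force(self, n_taxa):
        rng = np.random.default_rng(100 + n_taxa)
        for _ in range(4):
            tree, aln, pm = random_instance(rng, n_taxa)
            eng = LikelihoodEngine.for_alignment(aln, None, n_categories=3)
            a = eng.log_likelihood(tree, pm)
            b = brute_force_log_likelihood(tree, pm, aln)
            assert a == pytest.approx(b, abs=1e-8)

    def test_oracle_refuses_large_trees(self, rng):
        tree, aln, pm = random_instance(rng, 7)
        with pytest.raises(LikelihoodError):
            brute_force_log_likelihood(tree, pm, aln)


class TestInvariances:
    def test_rerooting_invariance(self, rng):
        """Pulley principle: lnL identical whatever internal node the
        pruning pass happens to start from (forced by permuting the internal
        node ids, which decide the traversal root)."""
        tree, aln, pm = random_instance(rng, 6)
        eng = LikelihoodEngine.for_alignment(aln, None, n_categories=3)
        base = eng.log_likelihood(tree, pm)
        internals = tree.internal_nodes()
        vals = [base]
        for _ in range(5):
            perm = dict(zip(internals, rng.permutation(internals)))
            remap = lambda v: perm.get(v, v)
            t2 = Tree(tree.taxa,
                      {remap(v): [remap(u) for u in nbrs]
                       for v, nbrs in tree.adj.items()},
                      {tuple(sorted((remap(a), remap(b)))): bl
                       for (a, b), bl in tree.lengths.items()})
            vals.append(eng.log_likelihood(t2, pm))
        assert np.ptp(vals) < 1e-9

    def test_rate_multiplier_equals_branch_scaling(self, rng):
        """Doubling a partition's multiplier == doubling its branch lengths."""
        taxa = [f"t{i}" for i in range(5)]
        tree = random_topology(taxa, rng)
        aln = Alignment(taxa, rng.choice(list("ACGT"), size=(5, 12)))
        scheme = PartitionScheme("x", [CharSet("a", tuple(range(6))),
                                       CharSet("b", tuple(range(6, 12)))], 12)
        m = SubstitutionModel("GTR", tuple(rng.random(6) + 0.2),
                              tuple(rng.dirichlet([6] * 4)), 0.8, 4)
        eng = LikelihoodEngine.for_alignment(aln, scheme, 4)
        pm1 = PartitionedModel([m, m], np.array([4 / 3, 2 / 3]),
                               np.array([6.0, 6.0]))
        v1 = eng.per_partition_log_likelihood(tree, pm1)
        doubled = tree.copy()
        for key in doubled.lengths:
            doubled.lengths[key] *= 4 / 3
        pm2 = PartitionedModel([m, m], np.ones(2), np.array([6.0, 6.0]))
        v2 = eng.per_partition_log_likelihood(doubled, pm2)
        assert v1[0] == pytest.approx(v2[0], abs=1e-9)

    def test_incremental_partition_evaluation_matches_full(self, rng):
        taxa = [f"t{i}" for i in range(6)]
        tree = random_topology(taxa, rng)
        aln = Alignment(taxa, rng.choice(list("ACGT"), size=(6, 20)))
        scheme = PartitionScheme("x", [CharSet("a", tuple(range(8))),
                                       CharSet("b", tuple(range(8, 20)))], 20)
        models = [SubstitutionModel("GTR", tuple(rng.random(6) + 0.2),
                                    tuple(rng.dirichlet([6] * 4)), 1.0, 4)
                  for _ in range(2)]
        pm = PartitionedModel(models, np.ones(2), np.array([8.0, 12.0]))
        eng = LikelihoodEngine.for_alignment(aln, scheme, 4)
        full = eng.per_partition_log_likelihood(tree, pm)
        for p in (0, 1):
            part = eng.per_partition_log_likelihood(tree, pm, only=[p])
            assert part[p] == pytest.approx(full[p], abs=1e-10)


class TestLeafVectors:
    @pytest.mark.parametrize("sym,states", [
        ("A", "A"), ("R", "AG"), ("N", "ACGT"), ("-", "ACGT"), ("?", "ACGT"),
        ("B", "CGT"),
    ])
    def test_possibility_vectors(self, sym, states):
        v = leaf_vector(sym)
        expect = np.array([1.0 if b in states else 0.0 for b in "ACGT"])
        assert (v == expect).all()
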