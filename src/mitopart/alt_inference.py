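"""Maximum-likelihood hill climbing and Fitch parsimony with bootstrap.

These are the cross-method checks run alongside the Bayesian analyses: a
Fitch-length parsimony criterion with exhaustive search at small taxon counts
(and an NNI heuristic above), an ML search alternating NNI rearrangements with
per-branch Brent optimization, and a nonparametric bootstrap resampling
columns with replacement and reporting bipartition support percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .likelihood import LikelihoodEngine
from .models import PartitionedModel
from .partitions import PartitionScheme, single_partition
from .seqdata import IUPAC, Alignment
from .trees import (Tree, all_topologies,
                    majority_rule_consensus, nni_neighbors, topology_key)

_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}


class InferenceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# parsimony
# ---------------------------------------------------------------------------

def _state_sets(alignment: Alignment) -> np.ndarray:
    """(n_taxa, n_sites) bitmask state sets; gaps/'?' are the full set."""
    out = np.zeros(alignment.matrix.shape, dtype=np.uint8)
    for sym, states in IUPAC.items():
        if not states:
            states = "ACGT"  # gap enters parsimony as the full state set
        mask = sum(_BIT[s] for s in states)
        out[alignment.matrix == sym] = mask
    return out


def fitch_score(tree: Tree, alignment: Alignment) -> int:
    """Minimal number of state changes over the tree, summed over sites."""
    if sorted(tree.taxa) != sorted(alignment.taxa):
        raise InferenceError("tree and alignment taxa differ")
    sets = _state_sets(alignment)
    row = {lf: alignment.taxa.index(tree.taxa[lf]) for lf in tree.leaves()}
    # root along the edge at leaf 0 so every internal node is binary
    order = tree.postorder(root=0)
    node_set: dict[int, np.ndarray] = {}
    score = np.zeros(alignment.length, dtype=np.int64)
    for nd, par in order:
        if nd < tree.n_taxa:
            node_set[nd] = sets[row[nd]].copy()
        kids = [ch for ch in tree.adj[nd] if ch != par]
        if nd < tree.n_taxa and not kids:
            continue
        acc = node_set.get(nd)
        for ch in kids:
            child = node_set[ch]
            if acc is None:
                acc = child.copy()
                continue
            inter = acc & child
            empty = inter == 0
            score += empty
            acc = np.where(empty, acc | child, inter)
        node_set[nd] = acc
    return int(score.sum())


def fitch_score_brute_force(tree: Tree, alignment: Alignment,
                            max_taxa: int = 6) -> int:
    """Minimum changes by explicit enumeration of internal state assignments."""
    import itertools

    if tree.n_taxa > max_taxa:
        raise InferenceError("enumeration refused above the taxon guard")
    sets = _state_sets(alignment)
    row = {lf: alignment.taxa.index(tree.taxa[lf]) for lf in tree.leaves()}
    order = tree.postorder(root=0)
    internals = [nd for nd, _ in order if nd >= tree.n_taxa]
    edges = [(nd, par) for nd, par in order if par is not None]
    total = 0
    for site in range(alignment.length):
        best = None
        leaf_opts = {lf: [b for b in range(4) if sets[row[lf], site] >> b & 1]
                     for lf in tree.leaves()}
        for assign in itertools.product(range(4), repeat=len(internals)):
            st = dict(zip(internals, assign))
            # choose each leaf's compatible state greedily is not valid in
            # general, so enumerate leaf options too
            for leaf_assign in itertools.product(
                    *[leaf_opts[lf] for lf in tree.leaves()]):
                st.update(dict(zip(tree.leaves(), leaf_assign)))
                changes = sum(st[a] != st[b] for a, b in edges)
                best = changes if best is None else min(best, changes)
        total += best
    return total


@dataclass
class MpResult:
    trees: list[Tree]
    score: int
    complete: bool  # True when the search provably saw every topology


def mp_search(alignment: Alignment, mode: str = "auto",
              max_exhaustive_taxa: int = 9,
              start: Tree | None = None,
              rng: np.random.Generator | None = None) -> MpResult:
    """Most-parsimonious tree search.

    ``exhaustive`` enumerates all unrooted topologies (refused above 9 taxa)
    and returns every minimal tree; ``heuristic-NNI`` hill-climbs and returns
    the best set found (flagged incomplete).
    """
    n = alignment.n_taxa
    if n < 4:
        raise InferenceError("tree search needs >= 4 taxa")
    if mode == "auto":
        mode = "exhaustive" if n <= max_exhaustive_taxa else "heuristic-NNI"
    if mode == "exhaustive":
        if n > max_exhaustive_taxa:
            raise InferenceError(
                f"exhaustive search refused for {n} > {max_exhaustive_taxa} "
                "taxa")
        best: list[Tree] = []
        best_score = None
        for t in all_topologies(sorted(alignment.taxa)):
            s = fitch_score(t, alignment)
            if best_score is None or s < best_score:
                best, best_score = [t], s
            elif s == best_score:
                best.append(t)
        return MpResult(best, int(best_score), True)
    if mode != "heuristic-NNI":
        raise InferenceError(f"unknown search mode {mode!r}")
    if start is None:
        from .modelselect import nj_tree
        start = nj_tree(alignment)
    current = start
    score = fitch_score(current, alignment)
    ties = {topology_key(current): current}
    improved = True
    while improved:
        improved = False
        for nbr in nni_neighbors(current):
            s = fitch_score(nbr, alignment)
            if s < score:
                current, score = nbr, s
                ties = {topology_key(nbr): nbr}
                improved = True
                break
            if s == score:
                ties.setdefault(topology_key(nbr), nbr)
    return MpResult(list(ties.values()), score, False)


# ---------------------------------------------------------------------------
# maximum likelihood
# ---------------------------------------------------------------------------

def optimize_branch_lengths(tree: Tree, engine: LikelihoodEngine,
                            models: PartitionedModel, n_passes: int = 2,
                            tol: float = 1e-6,
                            max_bl: float = 20.0) -> tuple[Tree, float]:
    """Cycle Brent 1-D maximization over every branch until improvement < tol."""
    t = tree.copy()
    lnl = engine.log_likelihood(t, models)
    for _ in range(n_passes * 5):
        before = lnl
        for key in list(t.lengths):
            def neg(x: float, key=key) -> float:
                t.lengths[key] = x
                return -engine.log_likelihood(t, models)
            res = minimize_scalar(neg, bounds=(1e-8, max_bl),
                                  method="bounded",
                                  options={"xatol": 1e-6})
            t.lengths[key] = float(res.x)
            lnl = -float(res.fun)
        if lnl - before < tol:
            break
    return t, lnl


def ml_search(alignment: Alignment, scheme: PartitionScheme | None = None,
              models: PartitionedModel | None = None,
              start: Tree | None = None,
              n_categories: int = 4,
              optimize_every: bool = False) -> tuple[Tree, float]:
    """NNI hill climbing with branch-length optimization; lnL never decreases.

    With *optimize_every* the branch lengths are re-optimized for each NNI
    candidate (slower, more thorough); otherwise candidates are screened at
    current lengths and only accepted improvements are re-optimized.
    """
    from .models import uniform_partitioned_model

    if scheme is None:
        scheme = single_partition(alignment.length)
    if models is None:
        models = uniform_partitioned_model(scheme, "GTR", gamma_shape=1.0,
                                           n_gamma_categories=n_categories)
    engine = LikelihoodEngine.for_alignment(alignment, scheme, n_categories)
    if start is None:
        from .modelselect import nj_tree
        start = nj_tree(alignment)
    current, lnl = optimize_branch_lengths(start, engine, models)
    improved = True
    while improved and current.internal_edges():
        improved = False
        for nbr in nni_neighbors(current):
            if optimize_every:
                cand, cand_lnl = optimize_branch_lengths(nbr, engine, models)
            else:
                cand, cand_lnl = nbr, engine.log_likelihood(nbr, models)
            if cand_lnl > lnl + 1e-9:
                cand, cand_lnl = optimize_branch_lengths(cand, engine, models)
            if cand_lnl > lnl + 1e-9:
                current, lnl = cand, cand_lnl
                improved = True
                break
    return current, lnl


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    replicate_trees: list[Tree]
    support: dict[int, float] = field(default_factory=dict)  # split -> percent
    n_replicates: int = 0

    def support_on(self, tree: Tree) -> dict[int, float]:
        return {m: self.support.get(m, 0.0) for m in tree.bipartitions()}


def bootstrap(alignment: Alignment, method: str = "MP",
              n_replicates: int = 100, seed: int = 0,
              scheme: PartitionScheme | None = None,
              models: PartitionedModel | None = None) -> BootstrapResult:
    """Nonparametric bootstrap: resample columns, re-infer, count splits."""
    if n_replicates < 1:
        raise InferenceError("need at least one bootstrap replicate")
    rng = np.random.default_rng(seed)
    counts: dict[int, int] = {}
    trees: list[Tree] = []
    for _ in range(n_replicates):
        cols = rng.integers(alignment.length, size=alignment.length)
        rep = alignment.subset_columns(list(cols))
        if method == "MP":
            result = mp_search(rep, mode="heuristic-NNI"
                               if rep.n_taxa > 9 else "exhaustive")
            rep_tree = result.trees[0] if len(result.trees) == 1 else \
                majority_rule_consensus(result.trees)
        elif method == "ML":
            rep_tree, _ = ml_search(rep, models=models)
        else:
            raise InferenceError(f"unknown bootstrap method {method!r}")
        trees.append(rep_tree)
        for m in rep_tree.bipartitions():
            counts[m] = counts.get(m, 0) + 1
    support = {m: 100.0 * c / n_replicates for m, c in counts.items()}
    return BootstrapResult(trees, support, n_replicates)
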