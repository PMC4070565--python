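"""Partitioned phylogenetic log-likelihood by Felsenstein pruning.

Site columns are compressed to distinct patterns within each partition; the
pruning pass runs vectorized over all patterns of all partitions at once, with
per-(partition, gamma-category) transition matrices and per-node scaling in
log space so mitogenome-sized matrices do not underflow.

Leaf conditionals for IUPAC ambiguity codes are possibility vectors (1 on each
compatible state); gaps and '?' are all-ones, so an all-missing column
contributes exactly 0 to the log-likelihood.

A brute-force enumeration oracle (explicit sum over internal-node state
assignments) is provided for small trees and is deliberately written without
reusing the pruning machinery.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.special import logsumexp

from .models import PartitionedModel, SubstitutionModel
from .partitions import PartitionScheme, single_partition
from .seqdata import IUPAC, Alignment
from .trees import Tree

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


class LikelihoodError(ValueError):
    pass


def leaf_vector(symbol: str) -> np.ndarray:
    """Possibility vector over (A, C, G, T) for one alignment symbol."""
    states = IUPAC[symbol.upper()]
    if symbol == "-":
        states = "ACGT"  # gap treated as missing in likelihood
    v = np.zeros(4)
    for s in states:
        v[_BASE_INDEX[s]] = 1.0
    return v


@dataclass
class PatternTable:
    """Compressed site patterns, grouped contiguously by partition."""

    taxa: list[str]
    patterns: np.ndarray        # (n_patterns, n_taxa) symbol codes into table
    weights: np.ndarray         # (n_patterns,) multiplicities
    part_index: np.ndarray      # (n_patterns,) partition id per pattern
    part_sizes: np.ndarray      # (n_partitions,) site counts
    leaf_partials: np.ndarray   # (n_taxa, n_patterns, 4)

    @property
    def n_patterns(self) -> int:
        return len(self.weights)

    @property
    def n_partitions(self) -> int:
        return len(self.part_sizes)


def compress_patterns(alignment: Alignment,
                      scheme: PartitionScheme | None = None) -> PatternTable:
    """Collapse identical columns within each partition, keeping weights."""
    if scheme is None:
        scheme = single_partition(alignment.length)
    m = alignment.matrix
    pats: list[np.ndarray] = []
    weights: list[int] = []
    part_index: list[int] = []
    sizes: list[int] = []
    for p, cs in enumerate(scheme.charsets):
        block = m[:, list(cs.sites)]
        cols, counts = np.unique(block, axis=1, return_counts=True)
        for j in range(cols.shape[1]):
            pats.append(cols[:, j])
            weights.append(int(counts[j]))
            part_index.append(p)
        sizes.append(len(cs.sites))
    patterns = np.array(pats)  # (n_pat, n_taxa)
    lut = {sym: leaf_vector(sym) for sym in IUPAC}
    leaf_partials = np.zeros((alignment.n_taxa, len(pats), 4))
    for t in range(alignment.n_taxa):
        for k in range(len(pats)):
            leaf_partials[t, k] = lut[patterns[k, t]]
    return PatternTable(list(alignment.taxa), patterns,
                        np.array(weights), np.array(part_index),
                        np.array(sizes), leaf_partials)


class LikelihoodEngine:
    """Reusable pruning engine bound to one pattern table."""

    def __init__(self, table: PatternTable, n_categories: int = 4):
        self.table = table
        self.n_categories = n_categories

    @classmethod
    def for_alignment(cls, alignment: Alignment,
                      scheme: PartitionScheme | None = None,
                      n_categories: int = 4) -> "LikelihoodEngine":
        return cls(compress_patterns(alignment, scheme), n_categories)

    # -- transition matrices --------------------------------------------
    def _edge_matrices(self, models: PartitionedModel, blens: np.ndarray,
                       part_ids: "list[int] | None" = None) -> np.ndarray:
        """(n_sel_part, n_cat, n_edges, 4, 4) transition matrices."""
        if part_ids is None:
            part_ids = list(range(self.table.n_partitions))
        ncat = self.n_categories
        P = np.empty((len(part_ids), ncat, len(blens), 4, 4))
        for p, pid in enumerate(part_ids):
            model = models.models[pid]
            lam, U, Uinv = model._eigen
            rates = np.ones(ncat)
            if model.gamma_shape is not None:
                if model.n_gamma_categories != ncat:
                    raise LikelihoodError(
                        "model category count differs from engine setting")
                rates = model.category_rates
            t_eff = blens[None, :] * rates[:, None] * models.multipliers[pid]
            expo = np.exp(lam[None, None, :] * t_eff[:, :, None])  # (c,e,4)
            Pp = np.einsum("ik,cek,kj->ceij", U, expo, Uinv)
            np.clip(Pp, 0.0, None, out=Pp)
            P[p] = Pp / Pp.sum(axis=3, keepdims=True)
        return P

    # -- pruning ---------------------------------------------------------
    def per_partition_log_likelihood(self, tree: Tree,
                                     models: PartitionedModel,
                                     only: "list[int] | None" = None
                                     ) -> np.ndarray:
        """Per-partition log-likelihood contributions.

        With *only*, restricts the computation to those partitions' patterns
        (other entries return 0) — used for incremental MCMC updates.
        """
        tab = self.table
        if sorted(tree.taxa) != sorted(tab.taxa):
            raise LikelihoodError("tree and alignment taxa differ")
        if models.n_partitions != tab.n_partitions:
            raise LikelihoodError("model count does not match partitions")
        # map tree leaf index -> table taxon row
        row_of_leaf = [tab.taxa.index(lab) for lab in tree.taxa]

        order = tree.postorder()
        nodes = [nd for nd, _ in order]
        node_pos = {nd: i for i, nd in enumerate(nodes)}
        blens = np.array([tree.branch_length(nd, par) if par is not None else 0.0
                          for nd, par in order])
        if only is None:
            part_ids = list(range(tab.n_partitions))
            sel = slice(None)
            pidx_local = tab.part_index
        else:
            part_ids = sorted(set(only))
            sel = np.isin(tab.part_index, part_ids)
            remap = {pid: i for i, pid in enumerate(part_ids)}
            pidx_local = np.array([remap[p] for p in tab.part_index[sel]])
        P = self._edge_matrices(models, blens, part_ids)  # (p,c,e,4,4)
        leaf_partials = tab.leaf_partials[:, sel, :]
        weights = tab.weights[sel]
        pidx_global = tab.part_index[sel]
        ncat = self.n_categories
        npat = leaf_partials.shape[1]

        partial = np.empty((len(nodes), ncat, npat, 4))
        logscale = np.zeros((ncat, npat))
        for i, (nd, par) in enumerate(order):
            if nd < tree.n_taxa:
                partial[i] = leaf_partials[row_of_leaf[nd]][None, :, :]
            else:
                prod = np.ones((ncat, npat, 4))
                for ch in tree.adj[nd]:
                    if ch == (par if par is not None else -1):
                        continue
                    ci = node_pos[ch]
                    Pc = P[pidx_local, :, ci]  # (npat, ncat, 4, 4)
                    prod *= np.einsum("pcij,cpj->cpi", Pc, partial[ci])
                scale = prod.max(axis=2)
                safe = np.where(scale > 0, scale, 1.0)
                prod /= safe[:, :, None]
                with np.errstate(divide="ignore"):
                    logscale += np.where(scale > 0, np.log(safe), -np.inf)
                partial[i] = prod
        root_i = len(nodes) - 1
        root = nodes[root_i]
        root_partial = partial[root_i]
        if root < tree.n_taxa:  # 2-3 taxa: root ended up a leaf
            # fold the remaining edge(s) into the root leaf's vector
            prod = leaf_partials[row_of_leaf[root]][None, :, :] * np.ones(
                (ncat, npat, 4))
            for ch in tree.adj[root]:
                ci = node_pos[ch]
                Pc = P[pidx_local, :, ci]
                prod *= np.einsum("pcij,cpj->cpi", Pc, partial[ci])
            root_partial = prod
        pi = np.array([models.models[pid].base_freqs for pid in part_ids])
        with np.errstate(divide="ignore"):
            site_cat = np.log(np.einsum("pj,cpj->cp", pi[pidx_local],
                                        root_partial)) + logscale
        site_lnl = logsumexp(site_cat, axis=0) - np.log(ncat)
        if not np.all(np.isfinite(site_lnl)):
            k = int(np.argmax(~np.isfinite(site_lnl)))
            raise LikelihoodError(
                f"non-finite site likelihood at partition {pidx_global[k]}, "
                f"pattern {k}")
        out = np.zeros(tab.n_partitions)
        np.add.at(out, pidx_global, weights * site_lnl)
        return out

    def log_likelihood(self, tree: Tree, models: PartitionedModel) -> float:
        return float(self.per_partition_log_likelihood(tree, models).sum())


def log_likelihood(tree: Tree, models: PartitionedModel,
                   table: PatternTable, n_categories: int | None = None) -> float:
    """Convenience wrapper around :class:`LikelihoodEngine`."""
    if n_categories is None:
        n_categories = max(m.n_categories for m in models.models)
    return LikelihoodEngine(table, n_categories).log_likelihood(tree, models)


# ---------------------------------------------------------------------------
# enumeration oracle
# ---------------------------------------------------------------------------

def brute_force_log_likelihood(tree: Tree, models: PartitionedModel,
                               alignment: Alignment,
                               scheme: PartitionScheme | None = None,
                               max_taxa: int = 6) -> float:
    """Explicit sum over all internal-node state assignments per site.

    Independent of the pruning code path (transition matrices via
    ``scipy.linalg.expm``); refuses above *max_taxa* leaves.
    """
    if tree.n_taxa > max_taxa:
        raise LikelihoodError(
            f"enumeration refused for {tree.n_taxa} > {max_taxa} taxa")
    if scheme is None:
        scheme = single_partition(alignment.length)
    site_to_part = np.empty(alignment.length, int)
    for p, cs in enumerate(scheme.charsets):
        site_to_part[list(cs.sites)] = p

    root = min(tree.internal_nodes()) if tree.n_taxa > 2 else 0
    order = tree.postorder(root)
    internals = [nd for nd, par in order if nd >= tree.n_taxa]
    if root < tree.n_taxa and root not in internals:
        internals = internals  # 2-taxon tree: no internal nodes

    total = 0.0
    for site in range(alignment.length):
        p = int(site_to_part[site])
        model = models.models[p]
        mult = float(models.multipliers[p])
        Q = model.rate_matrix
        pi = np.array(model.base_freqs)
        cat_rates = model.category_rates
        site_like = 0.0
        for r in cat_rates:
            Pm = {}
            for nd, par in order:
                if par is not None:
                    t = tree.branch_length(nd, par) * mult * r
                    Pm[(par, nd)] = expm(Q * t)
            cat_like = 0.0
            leaf_vecs = {
                lf: leaf_vector(alignment.matrix[
                    alignment.taxa.index(tree.taxa[lf]), site])
                for lf in tree.leaves()
            }
            for assign in itertools.product(range(4), repeat=len(internals)):
                states = dict(zip(internals, assign))
                like = 1.0
                if root >= tree.n_taxa:
                    like *= pi[states[root]]
                for nd, par in order:
                    if par is None:
                        continue
                    if nd >= tree.n_taxa:
                        like *= Pm[(par, nd)][states[par], states[nd]]
                    else:
                        if par >= tree.n_taxa:
                            sp = states[par]
                            like *= float(
                                Pm[(par, nd)][sp] @ leaf_vecs[nd])
                        else:  # 2-taxon tree: leaf-to-leaf edge
                            v_par = leaf_vecs[par]
                            like *= float(
                                (pi * v_par) @ Pm[(par, nd)] @ leaf_vecs[nd])
                cat_like += like
            site_like += cat_like / len(cat_rates)
        total += np.log(site_like)
    return float(total)
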