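"""AICc-based per-partition substitution-model selection.

Each candidate family is fitted by maximizing the log-likelihood over its free
parameters (relative rate classes, base frequencies, gamma shape, plus one
shared tree-scale nuisance factor) on a fixed guide tree — a neighbor-joining
tree from JC-corrected pairwise distances, the usual fixed-topology practice
of model-selection tools.  The winner by

    AICc = -2 lnL + 2K + 2K(K+1) / (n - K - 1),   n = site count,

is then passed through the substitution rule: families the Bayesian engine
cannot parameterize directly (TrN/TPM/TIM/TVM variants) map to GTR, the
nearest over-parameterized family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from Bio.Phylo.TreeConstruction import DistanceMatrix, DistanceTreeConstructor
from scipy.optimize import minimize

from .likelihood import LikelihoodEngine
from .models import (FAMILY_RATE_CLASSES, PartitionedModel, SubstitutionModel,
                     map_to_available, n_free_parameters)
from .partitions import single_partition
from .seqdata import Alignment
from .trees import Tree

DEFAULT_CANDIDATES = ("JC", "K80", "HKY", "TrN", "TPM", "TIM", "TVM", "SYM",
                      "GTR")


class SelectionError(ValueError):
    pass


@dataclass
class ModelSelectionResult:
    partition_name: str
    best_family: str
    aicc: float
    lnL_at_selection: float
    mapped_family: str
    gamma: bool = True
    all_aicc: dict[str, float] | None = None


def aicc(lnL: float, k: int, n: int) -> float:
    if n <= k + 1:
        raise SelectionError(f"AICc undefined: n={n} <= K+1={k + 1}")
    return -2.0 * lnL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# guide tree
# ---------------------------------------------------------------------------

def jc_distance_matrix(alignment: Alignment) -> np.ndarray:
    """Pairwise JC-corrected distances (ambiguous/gap sites excluded)."""
    m = alignment.matrix
    known = np.isin(m, list("ACGT"))
    n = alignment.n_taxa
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = known[i] & known[j]
            nb = int(both.sum())
            if nb == 0:
                d = 0.75
            else:
                p = float((m[i, both] != m[j, both]).mean())
                p = min(p, 0.749)
                d = -0.75 * np.log(1 - 4.0 * p / 3.0)
            D[i, j] = D[j, i] = d
    return D


def nj_tree(alignment: Alignment, min_branch: float = 1e-6) -> Tree:
    """Neighbor-joining guide tree (Biopython), negative branches clamped."""
    D = jc_distance_matrix(alignment)
    names = list(alignment.taxa)
    lower = [[float(D[i, j]) for j in range(i + 1)] for i in range(len(names))]
    bt = DistanceTreeConstructor().nj(DistanceMatrix(names, lower))
    for cl in bt.find_clades():
        if cl.branch_length is not None and cl.branch_length < min_branch:
            cl.branch_length = min_branch
    import io
    from Bio import Phylo
    buf = io.StringIO()
    Phylo.write(bt, buf, "newick")
    return Tree.from_newick(buf.getvalue(), taxa=alignment.taxa)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _empirical_freqs(alignment: Alignment) -> np.ndarray:
    m = alignment.matrix
    counts = np.array([(m == b).sum() for b in "ACGT"], float) + 1.0
    return counts / counts.sum()


def _fit_family(engine: LikelihoodEngine, tree: Tree, family: str,
                gamma: bool, freqs0: np.ndarray,
                n_gamma_categories: int) -> tuple[float, SubstitutionModel]:
    classes, free_freqs = FAMILY_RATE_CLASSES[family]
    n_classes = max(classes) + 1

    def unpack(x: np.ndarray):
        i = 0
        rates = np.ones(n_classes)
        if n_classes > 1:
            rates[:-1] = np.exp(x[i:i + n_classes - 1])
            i += n_classes - 1
        if free_freqs:
            logits = np.concatenate([x[i:i + 3], [0.0]])
            i += 3
            pi = np.exp(logits - logits.max())
            pi = pi / pi.sum()
        else:
            pi = np.full(4, 0.25)
        shape = None
        if gamma:
            shape = float(np.exp(x[i]))
            i += 1
        scale = float(np.exp(x[i]))
        model = SubstitutionModel.from_family(
            family, rates, pi, shape, n_gamma_categories)
        return model, scale

    def neg_lnl(x: np.ndarray) -> float:
        try:
            model, scale = unpack(x)
        except Exception:
            return 1e10
        t = tree.copy()
        for key in t.lengths:
            t.lengths[key] *= scale
        pm = PartitionedModel([model], np.ones(1), np.ones(1))
        try:
            return -engine.log_likelihood(t, pm)
        except Exception:
            return 1e10

    x0 = []
    if n_classes > 1:
        x0.extend([0.0] * (n_classes - 1))
        # start transitions high where the family has a transition class
        if family in ("K80", "HKY"):
            x0[-1] = np.log(4.0)
    if free_freqs:
        ref = np.log(np.maximum(freqs0, 1e-6) / max(freqs0[3], 1e-6))
        x0.extend(ref[:3])
    if gamma:
        x0.append(0.0)  # shape = 1
    x0.append(0.0)      # tree scale = 1
    res = minimize(neg_lnl, np.array(x0), method="L-BFGS-B",
                   options={"maxiter": 200, "ftol": 1e-8})
    model, _ = unpack(res.x)
    return float(-res.fun), model


def select_model_aicc(block: Alignment,
                      candidates=DEFAULT_CANDIDATES,
                      guide_tree: Tree | None = None,
                      gamma: bool = True,
                      n_gamma_categories: int = 4,
                      partition_name: str = "block") -> ModelSelectionResult:
    """Pick the AICc-best family for one alignment block on a fixed tree."""
    if block.n_taxa < 4:
        raise SelectionError("model selection needs >= 4 taxa")
    if guide_tree is None:
        guide_tree = nj_tree(block)
    engine = LikelihoodEngine.for_alignment(
        block, single_partition(block.length),
        n_categories=n_gamma_categories if gamma else 1)
    freqs0 = _empirical_freqs(block)
    n = block.length
    scores: dict[str, float] = {}
    lnls: dict[str, float] = {}
    for fam in candidates:
        k = n_free_parameters(fam, gamma)
        if n <= k + 1:
            warnings.warn(f"candidate {fam} skipped: n={n} <= K+1")
            continue
        lnl, _ = _fit_family(engine, guide_tree, fam, gamma, freqs0,
                             n_gamma_categories)
        scores[fam] = aicc(lnl, k, n)
        lnls[fam] = lnl
    if not scores:
        raise SelectionError("every candidate was skipped (block too short)")
    best = min(scores, key=lambda f: (scores[f], candidates.index(f)))
    return ModelSelectionResult(partition_name, best, scores[best],
                                lnls[best], map_to_available(best),
                                gamma, scores)
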