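"""Comparing partitioning strategies: credible sets, Bayes factors, congruence.

The marginal likelihood of each strategy is estimated as the harmonic mean of
the post-burn-in likelihood samples; two strategies are compared on the
Kass–Raftery scale through

    2 ln B10 = 2 [ ln HM1 - ln HM0 ],

with |2lnB10| in [0,2) indecisive, [2,6) favoured, [6,10) strong, and >= 10
very strong (flagged significant).  Because the harmonic means are full-data
marginal likelihoods, these values scale with alignment size: realistic
whole-mitogenome comparisons land in the hundreds or thousands of log units.

Topological uncertainty is summarized by credible sets: topologies ranked by
sampled frequency (ties broken by first occurrence), a level set being the
shortest prefix whose cumulative frequency reaches the level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mcmc import PosteriorTrace, harmonic_mean_lnL
from .trees import Tree, rf_distance, topology_key

__all__ = [
    "CredibleSetSummary", "BayesFactorMatrix", "topology_key",
    "credible_sets", "bayes_factor_2ln", "interpret_bf", "bf_matrix",
    "tree_length_stats", "rf_distance", "congruence_report",
]


@dataclass(frozen=True)
class CredibleSetSummary:
    n_distinct_topologies: int
    n_in_99: int
    n_in_95: int

    def __post_init__(self) -> None:
        if not (self.n_in_95 <= self.n_in_99 <= self.n_distinct_topologies):
            raise ValueError("credible-set sizes must be nested")


def credible_sets(trace: PosteriorTrace | Sequence,
                  levels: tuple[float, float] = (0.95, 0.99),
                  burnin_fraction: float | None = None) -> CredibleSetSummary:
    """Credible-set sizes of sampled topologies at the given levels."""
    if isinstance(trace, PosteriorTrace):
        topo = trace.post_burnin(burnin_fraction).topologies
    else:
        topo = list(trace)
    if not topo:
        raise ValueError("no post-burn-in samples")
    order: list = []
    counts: dict = {}
    for key in topo:
        if key not in counts:
            order.append(key)
            counts[key] = 0
        counts[key] += 1
    n = len(topo)
    freqs = sorted(((counts[k], -order.index(k)) for k in counts),
                   reverse=True)
    cum = 0.0
    sizes = {lv: None for lv in levels}
    for rank, (c, _) in enumerate(freqs, start=1):
        cum += c / n
        for lv in levels:
            if sizes[lv] is None and cum >= lv - 1e-12:
                sizes[lv] = rank
    lo, hi = sorted(levels)
    return CredibleSetSummary(len(counts), int(sizes[hi]), int(sizes[lo]))


def bayes_factor_2ln(lnHM1: float, lnHM0: float) -> float:
    """2 ln B10 = 2 (ln HM1 - ln HM0); positive favours model 1."""
    if not (np.isfinite(lnHM1) and np.isfinite(lnHM0)):
        raise ValueError("harmonic-mean log-likelihoods must be finite")
    return 2.0 * (lnHM1 - lnHM0)


def interpret_bf(v: float) -> str:
    """Kass–Raftery category of a 2lnB10 value; sign names the winner."""
    if not np.isfinite(v):
        raise ValueError("Bayes factor must be finite")
    a = abs(v)
    if a < 2:
        return "none"
    winner = "M1" if v > 0 else "M0"
    if a < 6:
        return f"favoured:{winner}"
    if a < 10:
        return f"strong:{winner}"
    return f"very strong:{winner}:significant"


@dataclass
class BayesFactorMatrix:
    labels: list[str]
    values: np.ndarray                  # 2lnB10, M1 = row, M0 = column
    interpretation: list[list[str]] = field(default_factory=list)
    ln_hm: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if not np.allclose(v, -v.T, atol=1e-9):
            raise ValueError("Bayes-factor matrix must be antisymmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        self.values = v
        if not self.interpretation:
            self.interpretation = [[interpret_bf(x) for x in row]
                                   for row in v]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels,
                            columns=self.labels)

    def value(self, m1: str, m0: str) -> float:
        return float(self.values[self.labels.index(m1),
                                 self.labels.index(m0)])


def bf_matrix(traces: Mapping[str, PosteriorTrace],
              burnin_fraction: float | None = None) -> BayesFactorMatrix:
    """Pairwise 2lnB10 between strategies from their traces' harmonic means."""
    if len(traces) < 2:
        raise ValueError("need at least two strategies to compare")
    labels = list(traces)
    ln_hm = {}
    for name, trace in traces.items():
        if trace is None:
            raise ValueError(f"missing trace for strategy {name!r}")
        ln_hm[name] = harmonic_mean_lnL(
            trace.post_burnin(burnin_fraction).lnl)
    k = len(labels)
    values = np.zeros((k, k))
    for i, m1 in enumerate(labels):
        for j, m0 in enumerate(labels):
            if i != j:
                values[i, j] = bayes_factor_2ln(ln_hm[m1], ln_hm[m0])
    return BayesFactorMatrix(labels, values, ln_hm=ln_hm)


def tree_length_stats(trace: PosteriorTrace,
                      burnin_fraction: float | None = None) -> tuple[float, float]:
    """Post-burn-in mean and (n-1)-denominator SD of sampled tree length."""
    lens = trace.post_burnin(burnin_fraction).tree_length
    if len(lens) < 2:
        raise ValueError("need >= 2 post-burn-in samples")
    return float(np.mean(lens)), float(np.std(lens, ddof=1))


def congruence_report(single_gene_trees: Mapping[str, Tree],
                      reference: Tree) -> pd.DataFrame:
    """Per-gene Robinson–Foulds distance to the concatenated-data reference."""
    rows = []
    ref_key = topology_key(reference)
    for gene, tree in single_gene_trees.items():
        rf = rf_distance(tree, reference)
        rows.append({"gene": gene, "rf": rf,
                     "topologically_identical": topology_key(tree) == ref_key})
    return pd.DataFrame(rows, columns=["gene", "rf", "topologically_identical"])
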