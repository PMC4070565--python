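"""Desk-scale evaluation studies of the whole pipeline.

Each function runs one self-contained study at a size a workstation can
afford, returning plain dictionaries of measured quantities.  They are the
computations behind the numbered analysis scripts and the acceptance checks:
partition bookkeeping on the full-size gene table, likelihood verification
against the enumeration oracle, MCMC calibration against exact references,
the Bayes-factor preference property, the credible-set/complexity property,
the single-gene congruence property, and ESS estimator calibration.

Study sizes (taxon counts, alignment lengths, generation counts, seed counts)
are fixed here as the package's committed desk-scale conditions and are
documented in the methods note.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad

from .likelihood import (LikelihoodEngine, brute_force_log_likelihood)
from .mcmc import McmcConfig, effective_sample_size, harmonic_mean_lnL, run_mcmc
from .models import (PartitionedModel, SubstitutionModel,
                     count_free_parameters, uniform_partitioned_model)
from .partitions import build_partition_scheme, single_partition
from .posterior import credible_sets, rf_distance
from .seqdata import Alignment, build_dataset
from .simulate import (SimSpec, make_fixture_study, reference_gene_map,
                       simulate_alignment, simulate_tree)
from .trees import majority_rule_consensus, random_topology


def _derive_seed(seed: int, k: int) -> int:
    return int((seed * 100_003 + k) % 2**31)


# ---------------------------------------------------------------------------
# bookkeeping studies (deterministic)
# ---------------------------------------------------------------------------

def partition_bookkeeping_study() -> dict[str, int]:
    """Charset counts of the strategies on the full-size 37-gene structure."""
    gmap = reference_gene_map()
    aln = Alignment(["x", "y"], np.full((2, gmap.total_length), "A"))
    out = {}
    for strat, dataset in (("PS3", "D37"), ("PS4", "D37"),
                           ("PS8", "D15"), ("PS12", "D13")):
        _, sub_map = build_dataset(aln, gmap, dataset)
        scheme = build_partition_scheme(sub_map, dataset, strat)
        out[f"charsets_{strat.lower()}"] = len(scheme.charsets)
    return out


def free_parameter_study() -> dict[str, int]:
    """GTR+G free-parameter sums for 37-, 63- and 13-partition schemes."""
    gmap = reference_gene_map()
    aln = Alignment(["x", "y"], np.full((2, gmap.total_length), "A"))
    out = {}
    for strat, dataset, label in (("PS3", "D37", "37"), ("PS4", "D37", "63"),
                                  ("PS11", "D13", "13")):
        _, sub_map = build_dataset(aln, gmap, dataset)
        scheme = build_partition_scheme(sub_map, dataset, strat)
        pm = uniform_partitioned_model(scheme, "GTR", gamma_shape=1.0)
        out[f"free_params_{label}_partitions"] = count_free_parameters(
            scheme, pm)
    return out


def matrix_length_study() -> dict[str, int]:
    """Class lengths of the reference gene table and their total."""
    gmap = reference_gene_map()
    lens = gmap.class_lengths()
    return {
        "matrix_length_total": gmap.total_length,
        "matrix_length_pcg": lens["PCG"],
        "matrix_length_rrna": lens["rRNA"],
        "matrix_length_trna": lens["tRNA"],
    }


# ---------------------------------------------------------------------------
# likelihood verification
# ---------------------------------------------------------------------------

def likelihood_oracle_study(seed: int = 0,
                            n_instances: int = 50) -> dict[str, float]:
    """Pruning vs enumeration on random small instances + JC closed form."""
    rng = np.random.default_rng(_derive_seed(seed, 1))
    max_err = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(4, 7))
        taxa = [f"t{i}" for i in range(n)]
        tree = random_topology(taxa, rng)
        aln = Alignment(taxa, rng.choice(
            list("ACGTRN-?"), p=[0.22] * 4 + [0.04, 0.04, 0.02, 0.02],
            size=(n, 8)))
        model = SubstitutionModel(
            "GTR", tuple(rng.random(6) + 0.2), tuple(rng.dirichlet([6] * 4)),
            gamma_shape=float(rng.uniform(0.3, 2.0)), n_gamma_categories=3)
        pm = PartitionedModel([model], np.ones(1), np.ones(1))
        eng = LikelihoodEngine.for_alignment(aln, None, n_categories=3)
        a = eng.log_likelihood(tree, pm)
        b = brute_force_log_likelihood(tree, pm, aln)
        max_err = max(max_err, abs(a - b))
    # JC closed form: 2 taxa, matching site, t = 0.1
    from .trees import Tree
    t2 = Tree(("a", "b"), {0: [1], 1: [0]}, {(0, 1): 0.1})
    aln2 = Alignment.from_sequences([("a", "A"), ("b", "A")])
    pm2 = PartitionedModel([SubstitutionModel.jc()], np.ones(1), np.ones(1))
    eng2 = LikelihoodEngine.for_alignment(aln2, None, 1)
    closed = np.log(0.25 * (0.25 + 0.75 * np.exp(-4 * 0.1 / 3)))
    jc_err = abs(eng2.log_likelihood(t2, pm2) - closed)
    return {"lnl_max_abs_error_vs_enumeration": float(max_err),
            "lnl_jc_closed_form_abs_error": float(jc_err),
            "n": n_instances}


# ---------------------------------------------------------------------------
# MCMC calibration
# ---------------------------------------------------------------------------

def prior_topology_study(seed: int = 0,
                         n_generations: int = 50_000) -> dict[str, float]:
    """Prior-only 4-taxon run: sampled topology frequencies vs uniform 1/3."""
    from collections import Counter

    taxa = ["a", "b", "c", "d"]
    aln = Alignment(taxa, np.full((4, 5), "?"))
    cfg = McmcConfig(n_generations=n_generations, n_chains=1, sample_every=10,
                     seed=_derive_seed(seed, 2), n_gamma_categories=1,
                     start_tree="random")
    trace = run_mcmc(aln, single_partition(5), "best_fit", families=["JC"],
                     config=cfg)
    post = trace.post_burnin()
    counts = Counter(post.topologies)
    n = post.n_samples
    freqs = [counts.get(k, 0) / n for k in counts] + [0.0] * (3 - len(counts))
    max_dev = max(abs(f - 1 / 3) for f in freqs)
    mc_se = float(np.sqrt((1 / 3) * (2 / 3) / n))
    return {"prior_topology_max_abs_deviation": float(max_dev),
            "prior_topology_3_mc_se": 3 * mc_se, "n": n}


def branch_posterior_study(seed: int = 0,
                           n_generations: int = 20_000) -> dict[str, float]:
    """2-taxon JC branch-length posterior mean vs numerical quadrature."""
    n_same, n_diff = 15, 5
    aln = Alignment.from_sequences([("a", "A" * (n_same + n_diff)),
                                    ("b", "A" * n_same + "C" * n_diff)])
    cfg = McmcConfig(n_generations=n_generations, n_chains=1, sample_every=10,
                     seed=_derive_seed(seed, 3), n_gamma_categories=1)
    trace = run_mcmc(aln, single_partition(n_same + n_diff), "best_fit",
                     families=["JC"], config=cfg)
    mcmc_mean = float(trace.post_burnin().tree_length.mean())

    mu = 0.1  # exponential prior mean

    def density(t: float) -> float:
        same = 0.25 + 0.75 * np.exp(-4 * t / 3)
        diff = 0.25 - 0.25 * np.exp(-4 * t / 3)
        return same ** n_same * diff ** n_diff * np.exp(-t / mu)

    num = quad(lambda t: t * density(t), 0, 5, limit=200)[0]
    den = quad(density, 0, 5, limit=200)[0]
    oracle = num / den
    return {"branch_posterior_mean_mcmc": mcmc_mean,
            "branch_posterior_mean_quadrature": float(oracle),
            "branch_posterior_rel_error": abs(mcmc_mean - oracle) / oracle,
            "n": trace.post_burnin().n_samples}


# ---------------------------------------------------------------------------
# the Bayes-factor preference property
# ---------------------------------------------------------------------------

def bf_preference_study(seed: int = 0, n_seeds: int = 20,
                        n_generations: int = 1000) -> dict[str, float]:
    """On heterogeneous mini-study data, is the gene-by-codon strategy very
    strongly preferred (2lnB10 > 10) over no partitioning?"""
    values = []
    for k in range(n_seeds):
        bundle = make_fixture_study("nymphalid-mini",
                                    seed=_derive_seed(seed, 10 + k))
        aln, gmap = build_dataset(bundle.alignment, bundle.gene_map, "D13")
        ln_hm = {}
        for j, strat in enumerate(("PS9", "PS12")):
            scheme = build_partition_scheme(gmap, "D13", strat)
            cfg = McmcConfig(n_generations=n_generations, n_chains=1,
                             sample_every=10, seed=_derive_seed(seed,
                                                                500 + 2 * k + j),
                             start_tree="nj")
            trace = run_mcmc(aln, scheme, "GTR_G", config=cfg)
            ln_hm[strat] = harmonic_mean_lnL(trace.post_burnin().lnl)
        values.append(2.0 * (ln_hm["PS12"] - ln_hm["PS9"]))
    values = np.array(values)
    return {"bf_gene_codon_vs_unpartitioned_median": float(np.median(values)),
            "bf_property_success_fraction": float((values > 10).mean()),
            "n": n_seeds}


# ---------------------------------------------------------------------------
# the credible-set / complexity property
# ---------------------------------------------------------------------------

def credible_monotonicity_study(seed: int = 0, n_seeds: int = 10,
                                n_generations: int = 3000) -> dict[str, float]:
    """On fixed homogeneous data, are credible sets non-decreasing along the
    free-parameter ladder (1 -> 3 -> 39 partitions)?

    Homogeneous generating conditions isolate the complexity effect: any
    growth in topological uncertainty along the ladder is attributable to the
    added parameters, not to fit differences.
    """
    flat_rates = {k: 1.0 for k in ("pos1", "pos2", "pos3", "rRNA", "tRNA")}
    ok = 0
    ladders = []
    for k in range(n_seeds):
        spec = SimSpec(n_taxa=8, tree_height=0.12,
                       gene_map=reference_gene_map(scale=40),
                       seed=_derive_seed(seed, 40 + k), ambiguity_rate=0.0,
                       class_freqs=None, class_rates=dict(flat_rates))
        tree = simulate_tree(spec)
        aln, gmap = simulate_alignment(tree, spec)
        sub_aln, sub_map = build_dataset(aln, gmap, "D13")
        sizes = []
        for strat in ("PS9", "PS10", "PS12"):
            scheme = build_partition_scheme(sub_map, "D13", strat)
            cfg = McmcConfig(n_generations=n_generations, n_chains=2,
                             heat_increment=0.3, n_gamma_categories=2,
                             sample_every=5, seed=_derive_seed(seed, 70 + k),
                             start_tree="nj")
            trace = run_mcmc(sub_aln, scheme, "GTR_G", config=cfg)
            sizes.append(credible_sets(trace).n_distinct_topologies)
        ladders.append(sizes)
        ok += sizes[0] <= sizes[1] <= sizes[2]
    return {"credible_monotone_fraction": ok / n_seeds,
            "credible_ladders": ladders, "n": n_seeds}


# ---------------------------------------------------------------------------
# single-gene congruence property
# ---------------------------------------------------------------------------

def single_gene_study(seed: int = 0, n_generations: int = 800,
                      concat_generations: int = 1500) -> dict[str, float]:
    """Whole-matrix vs single-gene topology recovery on a strong-signal
    fixture: every gene tree should be at least as far from the truth as the
    concatenated tree."""
    bundle = make_fixture_study("nymphalid-mini", seed=_derive_seed(seed, 90))
    aln, gmap = build_dataset(bundle.alignment, bundle.gene_map, "D15")
    truth = bundle.true_tree

    scheme = build_partition_scheme(gmap, "D15", "PS6")
    cfg = McmcConfig(n_generations=concat_generations, n_chains=1,
                     sample_every=10, seed=_derive_seed(seed, 91),
                     start_tree="nj")
    trace = run_mcmc(aln, scheme, "GTR_G", config=cfg)
    concat_tree = majority_rule_consensus(trace.post_burnin().trees)
    rf_concat = rf_distance(concat_tree, truth)

    gene_rfs = {}
    for g_idx, entry in enumerate(gmap):
        block = aln.subset_columns(range(entry.start, entry.end))
        cfg_g = McmcConfig(n_generations=n_generations, n_chains=1,
                           sample_every=10,
                           seed=_derive_seed(seed, 100 + g_idx),
                           start_tree="nj")
        tr = run_mcmc(block, single_partition(block.length), "GTR_G",
                      config=cfg_g)
        gene_tree = majority_rule_consensus(tr.post_burnin().trees)
        gene_rfs[entry.name] = rf_distance(gene_tree, truth)
    rfs = np.array(list(gene_rfs.values()), float)
    return {"concatenated_rf_to_truth": float(rf_concat),
            "single_gene_rf_mean": float(rfs.mean()),
            "single_gene_rf_min": float(rfs.min()),
            "single_gene_not_better_fraction": float(
                (rfs >= rf_concat).mean()),
            "n": len(gene_rfs)}


# ---------------------------------------------------------------------------
# ESS calibration
# ---------------------------------------------------------------------------

def ess_calibration_study(seed: int = 0, n_iid: int = 10_000,
                          n_ar1: int = 30_000) -> dict[str, float]:
    """ESS on iid noise (expect ~n) and AR(1) rho=0.5 (expect ~n/3)."""
    rng = np.random.default_rng(_derive_seed(seed, 4))
    iid_ess = effective_sample_size(rng.standard_normal(n_iid)).value
    rho = 0.5
    x = np.empty(n_ar1)
    x[0] = 0.0
    eps = rng.standard_normal(n_ar1) * np.sqrt(1 - rho ** 2)
    for i in range(1, n_ar1):
        x[i] = rho * x[i - 1] + eps[i]
    ar1_ess = effective_sample_size(x).value
    return {"ess_iid_ratio_to_n": iid_ess / n_iid,
            "ess_ar1_ratio_to_n_over_3": ar1_ess / (n_ar1 / 3.0),
            "n": n_iid}
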