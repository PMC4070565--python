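"""Study orchestration: datasets x strategies x model settings.

`run_study` drives the full design for a configured set of cells: build the
dataset selection and partition scheme, assign models (all-GTR+G or AICc
best-fit with the substitution rule), run the MCMC with the ESS rule, and
summarize everything into the two standard report tables — the pairwise
Bayes-factor matrix per dataset and the uncertainty table (partitions, free
parameters, harmonic mean, credible-set sizes, tree-length mean/SD).

`run_single_gene_suite` runs an independent Bayesian analysis per major gene
(PCGs and rRNAs) and reports each gene tree's congruence with the
concatenated reference topology.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .mcmc import (McmcConfig, PosteriorTrace, Priors, run_mcmc,
                   write_param_trace, write_tree_trace)
from .modelselect import nj_tree, select_model_aicc
from .partitions import (STRATEGY_DATASET, PartitionScheme,
                         build_partition_scheme, single_partition)
from .posterior import (bf_matrix, congruence_report, credible_sets,
                        tree_length_stats)
from .seqdata import Alignment, DatasetSelection, GeneMap, build_dataset
from .trees import Tree, majority_rule_consensus

log = logging.getLogger("mitopart")


class StudyConfigError(ValueError):
    pass


@dataclass
class StudyConfig:
    alignment_path: str | None = None
    genemap_path: str | None = None
    fixture_preset: str | None = None       # alternative to input paths
    datasets: Sequence[str] = ("D13",)
    strategies: Sequence[str] = ("PS9", "PS12")
    model_settings: Sequence[str] = ("GTR_G",)
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    priors: Priors = field(default_factory=Priors)
    seed: int = 0
    output_dir: str = "study_out"
    min_gene_length: int = 20               # single-gene suite floor
    apply_ess_rule: bool = False

    def validate(self) -> None:
        for d in self.datasets:
            DatasetSelection(d)
        for s in self.strategies:
            if s not in STRATEGY_DATASET:
                raise StudyConfigError(f"unknown strategy {s!r}")
            if STRATEGY_DATASET[s] not in self.datasets:
                raise StudyConfigError(
                    f"strategy {s} needs dataset {STRATEGY_DATASET[s]}, "
                    f"which is not in the configured datasets")
        for m in self.model_settings:
            if m not in ("GTR_G", "best_fit"):
                raise StudyConfigError(f"unknown model setting {m!r}")
        if self.fixture_preset is None and (self.alignment_path is None
                                            or self.genemap_path is None):
            raise StudyConfigError(
                "either a fixture preset or alignment+genemap paths required")

    def config_hash(self) -> str:
        payload = json.dumps({
            k: v for k, v in self.__dict__.items()
            if not isinstance(v, (McmcConfig, Priors))
        }, sort_keys=True, default=str)
        payload += json.dumps(self.mcmc.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class StudyCell:
    dataset: str
    strategy: str
    model_setting: str
    scheme: PartitionScheme | None = None
    families: list[str] | None = None
    trace: PosteriorTrace | None = None
    free_parameters: int | None = None
    error: str | None = None

    @property
    def label(self) -> str:
        prefix = "g" if self.model_setting == "GTR_G" else "o"
        return f"{prefix}{self.strategy}"


@dataclass
class StudyReport:
    cells: list[StudyCell]
    bf_matrices: dict[str, object]
    uncertainty_table: pd.DataFrame
    consensus_trees: dict[str, Tree]
    config_hash: str
    failed: list[str] = field(default_factory=list)


def _load_inputs(config: StudyConfig) -> tuple[Alignment, GeneMap]:
    if config.fixture_preset is not None:
        from .simulate import make_fixture_study
        bundle = make_fixture_study(config.fixture_preset, seed=config.seed)
        return bundle.alignment, bundle.gene_map
    from .seqdata import read_alignment
    fmt = "NEXUS" if str(config.alignment_path).endswith(
        (".nex", ".nexus")) else "FASTA"
    aln, _ = read_alignment(config.alignment_path, fmt)
    gmap = GeneMap.from_tsv(config.genemap_path)
    return aln, gmap


def _cell_families(aln: Alignment, scheme: PartitionScheme,
                   setting: str, guide: Tree) -> list[str]:
    if setting == "GTR_G":
        return ["GTR"] * len(scheme.charsets)
    fams = []
    for cs in scheme.charsets:
        block = aln.subset_columns(list(cs.sites))
        try:
            res = select_model_aicc(block, guide_tree=guide,
                                    partition_name=cs.name)
            fams.append(res.mapped_family)
        except Exception as exc:  # short blocks: fall back to GTR
            log.warning("model selection failed for %s (%s); using GTR",
                        cs.name, exc)
            fams.append("GTR")
    return fams


def run_study(config: StudyConfig,
              write_outputs: bool = True) -> StudyReport:
    """Run every configured (dataset, strategy, setting) cell and summarize."""
    config.validate()
    aln, gmap = _load_inputs(config)
    gmap.validate_against(aln)
    chash = config.config_hash()
    outdir = Path(config.output_dir)
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)

    datasets: dict[str, tuple[Alignment, GeneMap]] = {}
    for d in config.datasets:
        datasets[d] = build_dataset(aln, gmap, d)

    cells: list[StudyCell] = []
    failed: list[str] = []
    for setting in config.model_settings:
        for strat in config.strategies:
            d = STRATEGY_DATASET[strat]
            cell = StudyCell(d, strat, setting)
            t0 = time.time()
            try:
                sub_aln, sub_map = datasets[d]
                scheme = build_partition_scheme(sub_map, d, strat)
                guide = nj_tree(sub_aln)
                families = _cell_families(sub_aln, scheme, setting, guide)
                mcfg = replace(config.mcmc,
                               seed=int((config.seed * 1009 + len(cells))
                                        % 2**31))
                if config.apply_ess_rule:
                    from .mcmc import run_until_stationary
                    trace, _ = run_until_stationary(
                        sub_aln, scheme,
                        "GTR_G" if setting == "GTR_G" else "best_fit",
                        families=families, priors=config.priors, config=mcfg)
                else:
                    trace = run_mcmc(
                        sub_aln, scheme,
                        "GTR_G" if setting == "GTR_G" else "best_fit",
                        families=families, priors=config.priors, config=mcfg)
                cell.scheme = scheme
                cell.families = families
                cell.trace = trace
                cell.free_parameters = _free_parameter_sum(families, scheme)
                log.info("cell %s/%s/%s done in %.1fs seed=%d",
                         d, strat, setting, time.time() - t0, mcfg.seed)
            except Exception as exc:
                cell.error = str(exc)
                failed.append(cell.label)
                log.error("cell %s/%s/%s failed: %s", d, strat, setting, exc)
            cells.append(cell)

    # per-dataset Bayes-factor matrices over the successful cells
    bf_matrices = {}
    for d in config.datasets:
        traces = {c.label: c.trace for c in cells
                  if c.dataset == d and c.trace is not None}
        if len(traces) >= 2:
            bf_matrices[d] = bf_matrix(traces)

    rows = []
    consensus: dict[str, Tree] = {}
    for c in cells:
        if c.trace is None:
            continue
        summary = credible_sets(c.trace)
        mean, sd = tree_length_stats(c.trace)
        from .mcmc import harmonic_mean_lnL
        post = c.trace.post_burnin()
        rows.append({
            "cell": c.label, "dataset": c.dataset,
            "model_setting": c.model_setting,
            "partitions": len(c.scheme.charsets),
            "free_parameters": c.free_parameters,
            "ln_harmonic_mean": harmonic_mean_lnL(post.lnl),
            "credible_total": summary.n_distinct_topologies,
            "credible_99": summary.n_in_99,
            "credible_95": summary.n_in_95,
            "generations": c.trace.config.n_generations,
            "tree_length_mean": mean, "tree_length_sd": sd,
        })
        consensus[c.label] = majority_rule_consensus(post.trees)
    table = pd.DataFrame(rows)

    if write_outputs:
        table.to_csv(outdir / "uncertainty_table.tsv", sep="\t", index=False)
        for d, bf in bf_matrices.items():
            frame = bf.to_frame()
            frame.insert(0, "strategy", frame.index)
            frame.to_csv(outdir / f"bayes_factors_{d}.tsv", sep="\t",
                         index=False)
        for label, tree in consensus.items():
            (outdir / f"consensus_{label}.nwk").write_text(
                tree.to_newick() + "\n")
        for c in cells:
            if c.trace is not None:
                write_param_trace(c.trace, outdir / f"trace_{c.label}.p.tsv")
                write_tree_trace(c.trace, outdir / f"trace_{c.label}.t.tsv")
        (outdir / "manifest.json").write_text(json.dumps({
            "config_hash": chash, "seed": config.seed,
            "cells": [c.label for c in cells], "failed": failed,
        }, indent=2))
    return StudyReport(cells, bf_matrices, table, consensus, chash, failed)


def _free_parameter_sum(families: Sequence[str],
                        scheme: PartitionScheme) -> int:
    from .models import n_free_parameters
    k = len(scheme.charsets)
    total = sum(n_free_parameters(f, gamma=True) for f in families)
    return total + (k - 1 if k > 1 else 0)


def run_single_gene_suite(config: StudyConfig,
                          reference: Tree | None = None,
                          model_setting: str = "GTR_G",
                          write_outputs: bool = False) -> tuple[
                              dict[str, Tree], pd.DataFrame]:
    """Independent Bayesian run per major gene (PCGs + rRNAs), then the
    congruence table against the concatenated reference consensus.

    Genes shorter than the configured floor are skipped with a warning.
    """
    config.validate()
    aln, gmap = _load_inputs(config)
    d15_aln, d15_map = build_dataset(aln, gmap, "D15")
    if reference is None:
        scheme = build_partition_scheme(d15_map, "D15", "PS6")
        mcfg = replace(config.mcmc, seed=int((config.seed * 1009 + 777)
                                             % 2**31))
        trace = run_mcmc(d15_aln, scheme, "GTR_G", priors=config.priors,
                         config=mcfg)
        reference = majority_rule_consensus(trace.post_burnin().trees)

    gene_trees: dict[str, Tree] = {}
    for g_idx, entry in enumerate(d15_map):
        if entry.length < config.min_gene_length:
            log.warning("gene %s (%d bp) below the %d bp floor: skipped",
                        entry.name, entry.length, config.min_gene_length)
            continue
        block = d15_aln.subset_columns(range(entry.start, entry.end))
        scheme = single_partition(block.length, name=entry.name)
        mcfg = replace(config.mcmc,
                       seed=int((config.seed * 1009 + 1000 + g_idx) % 2**31))
        trace = run_mcmc(block, scheme, model_setting, priors=config.priors,
                         config=mcfg)
        gene_trees[entry.name] = majority_rule_consensus(
            trace.post_burnin().trees)
    report = congruence_report(gene_trees, reference)
    if write_outputs:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.to_csv(outdir / "single_gene_congruence.tsv", sep="\t",
                      index=False)
    return gene_trees, report
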