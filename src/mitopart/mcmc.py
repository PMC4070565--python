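"""Metropolis-coupled MCMC over trees, model parameters and partition rates.

The sampler follows the standard Bayesian phylogenetics recipe: one cold chain
plus heated chains with incremental heating beta_r = 1/(1 + lambda*r), a swap
attempt between a random chain pair each generation, and a reversible move set
(NNI on topology, branch-length multipliers, Dirichlet proposals on base
frequencies / exchangeability classes / partition rate multipliers, and a
multiplier move on the gamma shape).

Priors (all proper, all configurable): uniform over unrooted binary labeled
topologies, iid exponential branch lengths (mean 0.1), flat Dirichlet on base
frequencies and exchangeability classes, Uniform(0, 200) gamma shape, and a
flat Dirichlet on the site-weighted partition-rate simplex (so multipliers
keep site-weighted mean 1).

Also here: the trace container, autocorrelation-based effective sample size,
the harmonic-mean marginal-likelihood estimator, and the run-length rule
(extend when any monitored ESS falls under the threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import dirichlet as dirichlet_dist

from .likelihood import LikelihoodEngine
from .models import (FAMILY_RATE_CLASSES, PartitionedModel, SubstitutionModel)
from .partitions import PartitionScheme
from .seqdata import Alignment
from .trees import Tree, random_nni, random_topology, topology_key

MONITORED = ("lnL", "tree_length", "gamma_shape")


class McmcError(RuntimeError):
    pass


@dataclass(frozen=True)
class Priors:
    branch_length_mean: float = 0.1
    shape_upper: float = 200.0
    freq_concentration: float = 1.0       # flat Dirichlet
    rate_concentration: float = 1.0


@dataclass(frozen=True)
class McmcConfig:
    n_generations: int = 10_000
    n_chains: int = 8
    heat_increment: float = 0.1
    sample_every: int = 100
    burnin_fraction: float = 0.25
    seed: int = 0
    ess_threshold: float = 100.0
    extension_cap_generations: int = 4 * 10_000
    n_gamma_categories: int = 4
    start_tree: str = "random"           # or "nj"
    # proposal tuning
    branch_multiplier_lambda: float = 2.0 * np.log(1.6)
    shape_multiplier_lambda: float = 2.0 * np.log(1.5)
    dirichlet_concentration: float = 300.0

    @property
    def n_heated(self) -> int:
        return self.n_chains - 1

    def __post_init__(self) -> None:
        if not 0 <= self.burnin_fraction < 1:
            raise ValueError("burnin_fraction must be in [0, 1)")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")


@dataclass
class ChainState:
    tree: Tree
    models: list[SubstitutionModel]
    rate_point: np.ndarray  # simplex p with multiplier_i = p_i / w_i

    def multipliers(self, weights: np.ndarray) -> np.ndarray:
        w = weights / weights.sum()
        return self.rate_point / w

    def partitioned_model(self, weights: np.ndarray) -> PartitionedModel:
        return PartitionedModel(list(self.models),
                                self.multipliers(weights), weights)

    def copy(self) -> "ChainState":
        return ChainState(self.tree.copy(), list(self.models),
                          self.rate_point.copy())


@dataclass
class PosteriorTrace:
    """Cold-chain samples plus run provenance."""

    config: McmcConfig
    scheme_id: str
    generations: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    lnl: np.ndarray = field(default_factory=lambda: np.empty(0))
    tree_length: np.ndarray = field(default_factory=lambda: np.empty(0))
    topologies: list = field(default_factory=list)
    trees: list = field(default_factory=list)
    shapes: np.ndarray | None = None        # (n_samples, n_partitions)
    freqs0: np.ndarray | None = None        # (n_samples, 4), partition 0
    multipliers: np.ndarray | None = None   # (n_samples, n_partitions)
    swap_acceptance: float = float("nan")

    @property
    def n_samples(self) -> int:
        return len(self.generations)

    def burnin_index(self, burnin_fraction: float | None = None) -> int:
        bf = (self.config.burnin_fraction
              if burnin_fraction is None else burnin_fraction)
        return int(np.floor(self.n_samples * bf))

    def post_burnin(self, burnin_fraction: float | None = None) -> "PosteriorTrace":
        i = self.burnin_index(burnin_fraction)
        return PosteriorTrace(
            self.config, self.scheme_id, self.generations[i:], self.lnl[i:],
            self.tree_length[i:], self.topologies[i:], self.trees[i:],
            None if self.shapes is None else self.shapes[i:],
            None if self.freqs0 is None else self.freqs0[i:],
            None if self.multipliers is None else self.multipliers[i:],
            self.swap_acceptance)

    def monitored_series(self) -> dict[str, np.ndarray]:
        out = {"lnL": self.lnl, "tree_length": self.tree_length}
        if self.shapes is not None and self.shapes.size:
            out["gamma_shape"] = self.shapes[:, 0]
        return out


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EssResult:
    value: float
    degenerate: bool = False

    def __float__(self) -> float:
        return self.value


def effective_sample_size(series: Sequence[float]) -> EssResult:
    """ESS = n / (1 + 2 * sum rho_k), autocorrelations summed until the first
    nonpositive one (initial-positive-sequence truncation)."""
    x = np.asarray(series, float)
    n = len(x)
    if n < 10:
        raise McmcError("need >= 10 samples for an ESS estimate")
    var = x.var()
    if var == 0:
        return EssResult(0.0, degenerate=True)
    xc = x - x.mean()
    acov = np.correlate(xc, xc, mode="full")[n - 1:] / n
    rho = acov / acov[0]
    s = 0.0
    for k in range(1, n):
        if rho[k] <= 0:
            break
        s += rho[k]
    return EssResult(float(n / (1.0 + 2.0 * s)))


def harmonic_mean_lnL(lnl_samples: Sequence[float]) -> float:
    """ln of the harmonic mean of likelihoods: ln n - logsumexp(-lnL_i).

    Numerically stable for mitogenome-scale log-likelihoods (~ -3e5).
    """
    x = np.asarray(lnl_samples, float)
    if x.size == 0:
        raise McmcError("harmonic mean of an empty sample")
    if not np.all(np.isfinite(x)):
        raise McmcError("non-finite log-likelihood samples")
    return float(np.log(len(x)) - logsumexp(-x))


@dataclass(frozen=True)
class StationarityDecision:
    accept: bool
    min_ess: float
    new_n_generations: int | None = None
    capped: bool = False


def assess_stationarity(trace: PosteriorTrace,
                        config: McmcConfig | None = None) -> StationarityDecision:
    """Accept when every monitored scalar's post-burn-in ESS meets the
    threshold; otherwise request a doubled run, bounded by the extension cap
    (past the cap: accept with a warning flag)."""
    cfg = config or trace.config
    post = trace.post_burnin(cfg.burnin_fraction)
    ess_values = []
    for name, series in post.monitored_series().items():
        if len(series) < 10:
            ess_values.append(0.0)
            continue
        res = effective_sample_size(series)
        if res.degenerate:
            continue  # constant scalar (e.g. fixed shape): not a mixing issue
        ess_values.append(res.value)
    min_ess = min(ess_values) if ess_values else 0.0
    if min_ess >= cfg.ess_threshold:
        return StationarityDecision(True, min_ess)
    proposed = 2 * cfg.n_generations
    if proposed > cfg.extension_cap_generations:
        return StationarityDecision(True, min_ess, None, capped=True)
    return StationarityDecision(False, min_ess, proposed)


# ---------------------------------------------------------------------------
# proposals
# ---------------------------------------------------------------------------

def _dirichlet_step(x: np.ndarray, conc: float,
                    rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Propose x' ~ Dirichlet(conc*x); returns (x', log Hastings ratio)."""
    alpha_fwd = conc * x + 1e-4
    y = rng.dirichlet(alpha_fwd)
    y = np.maximum(y, 1e-12)
    y = y / y.sum()
    alpha_rev = conc * y + 1e-4
    logh = (dirichlet_dist.logpdf(x, alpha_rev)
            - dirichlet_dist.logpdf(y, alpha_fwd))
    return y, float(logh)


def propose(state: ChainState, move: str, rng: np.random.Generator,
            config: McmcConfig, weights: np.ndarray,
            priors: Priors) -> tuple[ChainState, float, int | None]:
    """One reversible proposal.

    Returns (new state, log Hastings ratio, touched partition or None when the
    move affects every partition).  Raises ``McmcError`` for moves that do not
    apply to the current state (callers pre-filter the move list).
    """
    if move == "NNI":
        return ChainState(random_nni(state.tree, rng), list(state.models),
                          state.rate_point.copy()), 0.0, None
    if move == "branch-multiplier":
        t = state.tree.copy()
        keys = list(t.lengths)
        key = keys[rng.integers(len(keys))]
        m = float(np.exp(config.branch_multiplier_lambda * (rng.random() - 0.5)))
        t.lengths[key] *= m
        return ChainState(t, list(state.models),
                          state.rate_point.copy()), float(np.log(m)), None
    if move in ("Dirichlet-frequencies", "Dirichlet-exchangeabilities",
                "shape-window"):
        candidates = [p for p, mod in enumerate(state.models)
                      if _move_applies(move, mod)]
        if not candidates:
            raise McmcError(f"move {move} applies to no partition")
        p = candidates[int(rng.integers(len(candidates)))]
        mod = state.models[p]
        if move == "Dirichlet-frequencies":
            pi = np.asarray(mod.base_freqs)
            pi2, logh = _dirichlet_step(pi, config.dirichlet_concentration, rng)
            new = replace(mod, base_freqs=tuple(pi2))
        elif move == "Dirichlet-exchangeabilities":
            classes, _ = FAMILY_RATE_CLASSES[mod.family]
            n_classes = max(classes) + 1
            rates = np.array([mod.exchangeabilities[classes.index(c)]
                              for c in range(n_classes)])
            simplex = rates / rates.sum()
            simplex2, logh = _dirichlet_step(
                simplex, config.dirichlet_concentration, rng)
            new = SubstitutionModel.from_family(
                mod.family, simplex2, mod.base_freqs, mod.gamma_shape,
                mod.n_gamma_categories)
        else:  # shape-window (multiplier on the shape)
            m = float(np.exp(config.shape_multiplier_lambda
                             * (rng.random() - 0.5)))
            shape = mod.gamma_shape * m
            logh = float(np.log(m))
            if shape >= priors.shape_upper:
                logh = -np.inf  # outside the uniform prior: certain rejection
            new = replace(mod, gamma_shape=shape)
        models = list(state.models)
        models[p] = new
        return ChainState(state.tree, models,
                          state.rate_point.copy()), logh, p
    if move == "multiplier-Dirichlet":
        if len(state.rate_point) < 2:
            raise McmcError("rate-multiplier move needs >= 2 partitions")
        p2, logh = _dirichlet_step(state.rate_point,
                                   config.dirichlet_concentration, rng)
        return ChainState(state.tree, list(state.models), p2), logh, None
    raise McmcError(f"unknown move {move!r}")


def _move_applies(move: str, model: SubstitutionModel) -> bool:
    classes, free_freqs = FAMILY_RATE_CLASSES[model.family]
    if move == "Dirichlet-frequencies":
        return free_freqs
    if move == "Dirichlet-exchangeabilities":
        return max(classes) >= 1
    if move == "shape-window":
        return model.gamma_shape is not None
    return True


def _available_moves(state: ChainState) -> list[tuple[str, float]]:
    # per-partition parameter moves are weighted up with the partition count
    # so each partition's parameters are refreshed at a partition-independent
    # rate (they touch a single partition and are cheap to evaluate)
    k = max(1, len(state.models))
    pw = 0.10 * np.sqrt(k)
    moves: list[tuple[str, float]] = [("branch-multiplier", 0.35)]
    if state.tree.internal_edges():
        moves.append(("NNI", 0.25))
    if any(_move_applies("Dirichlet-frequencies", m) for m in state.models):
        moves.append(("Dirichlet-frequencies", pw))
    if any(_move_applies("Dirichlet-exchangeabilities", m)
           for m in state.models):
        moves.append(("Dirichlet-exchangeabilities", pw))
    if any(_move_applies("shape-window", m) for m in state.models):
        moves.append(("shape-window", pw))
    if len(state.rate_point) >= 2:
        moves.append(("multiplier-Dirichlet", 0.10))
    return moves


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

def log_prior(state: ChainState, priors: Priors) -> float:
    lp = 0.0
    mu = priors.branch_length_mean
    for bl in state.tree.lengths.values():
        if bl <= 0:
            return -np.inf
        lp += -np.log(mu) - bl / mu
    for mod in state.models:
        if mod.gamma_shape is not None:
            if not 0 < mod.gamma_shape < priors.shape_upper:
                return -np.inf
            lp += -np.log(priors.shape_upper)
        # flat Dirichlets on frequencies and exchangeability classes are
        # constant on the simplex interior
        if min(mod.base_freqs) <= 0:
            return -np.inf
    if np.any(state.rate_point <= 0):
        return -np.inf
    return lp


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

def _empirical_partition_freqs(alignment: Alignment,
                               scheme: PartitionScheme) -> np.ndarray:
    """(k, 4) smoothed empirical base frequencies per charset."""
    out = np.empty((len(scheme.charsets), 4))
    for p, cs in enumerate(scheme.charsets):
        block = alignment.matrix[:, list(cs.sites)]
        counts = np.array([(block == b).sum() for b in "ACGT"], float) + 1.0
        out[p] = counts / counts.sum()
    return out


def _empirical_multiplier_point(alignment: Alignment,
                                scheme: PartitionScheme) -> np.ndarray:
    """Simplex point whose implied multipliers track per-partition mean
    pairwise p-distance (a cheap data-informed starting value)."""
    m = alignment.matrix
    known = np.isin(m, list("ACGT"))
    rates = np.empty(len(scheme.charsets))
    for p, cs in enumerate(scheme.charsets):
        cols = list(cs.sites)
        sub, ok = m[:, cols], known[:, cols]
        diffs, comps = 0, 0
        for i in range(len(sub)):
            for j in range(i + 1, len(sub)):
                both = ok[i] & ok[j]
                comps += int(both.sum())
                diffs += int((sub[i, both] != sub[j, both]).sum())
        rates[p] = (diffs + 0.5) / (comps + 1.0)
    w = np.array(scheme.sizes, float)
    w = w / w.sum()
    mult = rates / np.dot(w, rates)
    point = mult * w
    return point / point.sum()


def initial_state(alignment: Alignment, scheme: PartitionScheme,
                  families: Sequence[str], config: McmcConfig,
                  rng: np.random.Generator) -> ChainState:
    """Data-informed starting state: NJ or random tree, per-partition
    empirical frequencies, p-distance-based rate multipliers, shape 1."""
    from .modelselect import nj_tree

    if config.start_tree == "nj" and alignment.n_taxa >= 4:
        try:
            tree = nj_tree(alignment)
        except Exception:
            tree = random_topology(alignment.taxa, rng)
    else:
        tree = random_topology(alignment.taxa, rng)
    for key, bl in tree.lengths.items():
        tree.lengths[key] = max(bl, 1e-4)
    freqs = _empirical_partition_freqs(alignment, scheme)
    models = []
    for p, fam in enumerate(families):
        free_freqs = FAMILY_RATE_CLASSES[fam][1]
        models.append(SubstitutionModel.from_family(
            fam, base_freqs=tuple(freqs[p]) if free_freqs else (0.25,) * 4,
            gamma_shape=1.0, n_gamma_categories=config.n_gamma_categories))
    try:
        point = _empirical_multiplier_point(alignment, scheme)
    except Exception:
        w = np.array(scheme.sizes, float)
        point = w / w.sum()
    return ChainState(tree, models, point)


def run_mcmc(alignment: Alignment, scheme: PartitionScheme,
             model_setting: str = "GTR_G",
             families: Sequence[str] | None = None,
             priors: Priors | None = None,
             config: McmcConfig | None = None,
             engine: LikelihoodEngine | None = None,
             start: ChainState | None = None) -> PosteriorTrace:
    """Run MC^3 and return the cold chain's trace.

    ``model_setting`` is either ``GTR_G`` (every partition GTR+G) or
    ``best_fit`` (per-partition families supplied via *families*, e.g. from
    AICc selection followed by the substitution rule).
    """
    priors = priors or Priors()
    config = config or McmcConfig()
    if model_setting == "GTR_G":
        families = ["GTR"] * len(scheme.charsets)
    elif model_setting == "best_fit":
        if families is None:
            raise McmcError("best_fit setting requires per-partition families")
        if len(families) != len(scheme.charsets):
            raise McmcError("one family per partition required")
    else:
        raise McmcError(f"unknown model setting {model_setting!r}")

    if engine is None:
        engine = LikelihoodEngine.for_alignment(
            alignment, scheme, n_categories=config.n_gamma_categories)
    weights = np.array(scheme.sizes, float)

    n_chains = config.n_chains
    lam = config.heat_increment
    betas = np.array([1.0 / (1.0 + lam * r) for r in range(n_chains)])
    chain_rngs = [np.random.default_rng(np.random.SeedSequence([config.seed, r]))
                  for r in range(n_chains)]
    swap_rng = np.random.default_rng(np.random.SeedSequence(
        [config.seed, 999_983]))

    if start is None:
        start = initial_state(alignment, scheme, families, config,
                              chain_rngs[0])
    states = [start.copy() for _ in range(n_chains)]
    part_lnls = []
    for st in states:
        v = engine.per_partition_log_likelihood(
            st.tree, st.partitioned_model(weights))
        part_lnls.append(v)
    if not np.isfinite(part_lnls[0].sum()):
        raise McmcError("non-finite log-likelihood at initialization")
    lps = [log_prior(st, priors) for st in states]

    n_part = len(scheme.charsets)
    samples: dict[str, list] = {k: [] for k in
                                ("gen", "lnl", "tlen", "topo", "tree",
                                 "shape", "freqs0", "mult")}
    swap_tries = 0
    swap_accepts = 0

    def record(gen: int) -> None:
        st = states[0]
        samples["gen"].append(gen)
        samples["lnl"].append(float(part_lnls[0].sum()))
        samples["tlen"].append(st.tree.total_length())
        samples["topo"].append(topology_key(st.tree))
        samples["tree"].append(st.tree.copy())
        samples["shape"].append([m.gamma_shape if m.gamma_shape is not None
                                 else np.nan for m in st.models])
        samples["freqs0"].append(list(st.models[0].base_freqs))
        samples["mult"].append(list(st.multipliers(weights)))

    record(0)
    for gen in range(1, config.n_generations + 1):
        for c in range(n_chains):
            rng = chain_rngs[c]
            st = states[c]
            moves = _available_moves(st)
            names = [m for m, _ in moves]
            probs = np.array([wgt for _, wgt in moves])
            probs = probs / probs.sum()
            move = names[int(rng.choice(len(names), p=probs))]
            try:
                new_st, logh, touched = propose(st, move, rng, config,
                                                weights, priors)
            except McmcError:
                continue
            new_lp = log_prior(new_st, priors)
            if not np.isfinite(new_lp) or not np.isfinite(logh):
                continue
            pm = new_st.partitioned_model(weights)
            if touched is None:
                new_part = engine.per_partition_log_likelihood(new_st.tree, pm)
            else:
                new_part = part_lnls[c].copy()
                v = engine.per_partition_log_likelihood(new_st.tree, pm,
                                                        only=[touched])
                new_part[touched] = v[touched]
            delta = (new_part.sum() - part_lnls[c].sum()) + (new_lp - lps[c])
            ln_alpha = betas[c] * delta + logh
            if ln_alpha >= 0 or rng.random() < np.exp(ln_alpha):
                states[c] = new_st
                part_lnls[c] = new_part
                lps[c] = new_lp
        if n_chains > 1:
            i, j = swap_rng.choice(n_chains, size=2, replace=False)
            post_i = part_lnls[i].sum() + lps[i]
            post_j = part_lnls[j].sum() + lps[j]
            ln_a = (betas[i] - betas[j]) * (post_j - post_i)
            swap_tries += 1
            if ln_a >= 0 or swap_rng.random() < np.exp(ln_a):
                states[i], states[j] = states[j], states[i]
                part_lnls[i], part_lnls[j] = part_lnls[j], part_lnls[i]
                lps[i], lps[j] = lps[j], lps[i]
                swap_accepts += 1
        if gen % config.sample_every == 0:
            record(gen)

    return PosteriorTrace(
        config=config, scheme_id=scheme.strategy_id,
        generations=np.array(samples["gen"]),
        lnl=np.array(samples["lnl"]),
        tree_length=np.array(samples["tlen"]),
        topologies=samples["topo"],
        trees=samples["tree"],
        shapes=np.array(samples["shape"]),
        freqs0=np.array(samples["freqs0"]),
        multipliers=np.array(samples["mult"]),
        swap_acceptance=(swap_accepts / swap_tries) if swap_tries else
        float("nan"))


def run_until_stationary(alignment: Alignment, scheme: PartitionScheme,
                         model_setting: str = "GTR_G",
                         families: Sequence[str] | None = None,
                         priors: Priors | None = None,
                         config: McmcConfig | None = None) -> tuple[
                             PosteriorTrace, StationarityDecision]:
    """run_mcmc plus the ESS rule: extend (doubling) until accepted/capped."""
    config = config or McmcConfig()
    while True:
        trace = run_mcmc(alignment, scheme, model_setting, families, priors,
                         config)
        decision = assess_stationarity(trace, config)
        if decision.accept:
            return trace, decision
        config = replace(config, n_generations=decision.new_n_generations)


# -- trace serialization -----------------------------------------------------

def write_param_trace(trace: PosteriorTrace, path) -> None:
    """MrBayes-like .p file: tab-separated scalar trace with a config header."""
    import pandas as pd

    df = pd.DataFrame({
        "generation": trace.generations,
        "lnL": trace.lnl,
        "tree_length": trace.tree_length,
    })
    if trace.shapes is not None:
        for p in range(trace.shapes.shape[1]):
            df[f"shape_{p}"] = trace.shapes[:, p]
    if trace.multipliers is not None:
        for p in range(trace.multipliers.shape[1]):
            df[f"mult_{p}"] = trace.multipliers[:, p]
    with open(path, "w") as fh:
        fh.write(f"# scheme={trace.scheme_id} seed={trace.config.seed} "
                 f"n_generations={trace.config.n_generations} "
                 f"n_chains={trace.config.n_chains} "
                 f"sample_every={trace.config.sample_every}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_tree_trace(trace: PosteriorTrace, path) -> None:
    """Newick-per-line tree trace (.t analogue)."""
    with open(path, "w") as fh:
        fh.write(f"# scheme={trace.scheme_id} seed={trace.config.seed}\n")
        for gen, tree in zip(trace.generations, trace.trees):
            fh.write(f"{gen}\t{tree.to_newick()}\n")
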