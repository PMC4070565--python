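# Methods

`mitopart` implements the full evaluation design behind partitioned Bayesian
mitogenome phylogenetics: building partitioning strategies over an annotated
concatenated alignment, inferring trees under partitioned GTR+Γ models with a
Metropolis-coupled MCMC, and comparing strategies with harmonic-mean Bayes
factors, credible sets of topologies, and single-gene congruence. This note
records the models, the numerical choices, and what the synthetic data do and
do not emulate.

## Data model and partitioning

A mitogenome matrix concatenates 37 genes — 13 protein-coding genes (PCGs),
2 rRNAs, 22 tRNAs — described by a `GeneMap` of 0-based half-open spans with
gene class, reading-frame offset (PCGs) and strand. Minus-strand genes are
stored already re-oriented; strand is bookkeeping only. Three dataset
selections are supported: all 37 genes (D37), PCGs + rRNAs (D15), PCGs only
(D13).

Twelve partitioning strategies assign every site of a selection to exactly
one character set: no partition (PS1/5/9), pooled codon positions plus one
combined RNA set where the selection has RNA genes (PS2/6/10), one charset
per gene (PS3/7/11), and gene-by-codon — each PCG split into its three codon
positions, RNA genes whole (PS4/8/12). Codon position is
`(site − gene_start − frame) mod 3`, computed per gene; trailing partial
codons keep their computed position. Charsets are emitted in gene order with
codon sub-charsets in order 1, 2, 3, so outputs are byte-stable. NEXUS output
converts to the format's 1-based inclusive coordinates (with `a-b\3` stride
notation); everything in memory stays 0-based half-open.

Site classification follows the polymorphism-software convention: gaps,
`?` and IUPAC ambiguity codes are excluded from state counting; a column is
variable with ≥ 2 distinct unambiguous nucleotides and parsimony-informative
with ≥ 2 states each in ≥ 2 taxa. In the likelihood, by contrast, ambiguity
codes become possibility vectors (1 on each compatible state, not
frequency-renormalized) and gaps/`?` are all-ones — so an all-missing column
contributes exactly zero log-likelihood.

## Substitution models

Families JC, K80, HKY, TrN, TPM, TIM, TVM, SYM, GTR are encoded by tying the
six exchangeabilities (order AC, AG, AT, CG, CT, GT) into shared classes and
fixing or freeing the base frequencies. The generator is the standard
reversible form `q_ij = r_ij π_j`, normalized to one expected substitution
per unit branch length; transition matrices come from the symmetric-form
eigendecomposition, which is stable and lets a branch's matrices for all
gamma categories be computed in one vectorized pass.

Among-site rate variation is the discrete gamma with **4 equal-probability
categories and category-mean rates** (the de-facto standard behind "+G");
the category count is configurable. No +I track is provided: the gamma shape
is strongly confounded with a proportion of invariable sites, and the
evaluation design uses +G throughout.

Per-partition free parameters: rate classes − 1, plus 3 when frequencies are
free, plus 1 for the gamma shape (GTR+G = 5 + 3 + 1 = 9). A k-partition
scheme adds k − 1 free rate multipliers, so an all-GTR+G scheme carries
9k + (k−1) substitution-model parameters — 9, 39, 129, 369, 409, 629 for
k = 1, 4, 13, 37, 41, 63. Branch lengths and topology are shared across
partitions and not counted in that sum.

Model selection fits each candidate family by maximizing lnL (L-BFGS-B on
log-rates, frequency logits, log-shape, and one shared tree-scale nuisance
factor) on a fixed guide tree — neighbor joining on JC-corrected distances,
the fixed-topology practice of model-selection tools — and picks the AICc
winner, `AICc = −2lnL + 2K + 2K(K+1)/(n−K−1)` with n the site count.
Families the Bayesian engine cannot parameterize directly (TrN, TPM, TIM,
TVM variants) are replaced by the nearest over-parameterized family, GTR.

## Likelihood

Felsenstein pruning over site patterns compressed within each partition.
The pass runs vectorized over all patterns of all partitions simultaneously,
with per-(partition, category) transition tensors indexed per pattern;
per-node scaling factors are accumulated in log space, so ~70 taxa × 16 kb
does not underflow. The traversal roots at an arbitrary internal node;
correctness under re-rooting is guaranteed by reversibility and tested.
A brute-force oracle (explicit sum over internal-node state assignments,
transition matrices via `expm`) verifies the engine to < 1e−8 on random
≤ 6-taxon instances; it deliberately shares no code with the pruning path.

Partition rate multipliers scale branch lengths per partition and are
constrained to site-weighted mean 1; doubling a partition's multiplier is
exactly equivalent to doubling every branch length for that partition's
contribution (tested as an identity). Incremental evaluation of a single
partition is available for MCMC parameter moves.

## MCMC

Metropolis coupling with `n_chains` chains (default 8: seven heated, one
cold), incremental heating β_r = 1/(1 + λ r) with λ = 0.1 by default, and one
swap attempt between a random chain pair per generation using the standard
MC³ ratio on the heated posterior. Default run shape: sample every 100
generations, discard the first 25% of samples as burn-in; both configurable.

Priors (all proper, all config-exposed; the design uses common defaults):
uniform over unrooted binary labeled topologies; iid Exp(mean 0.1) branch
lengths; flat Dirichlet on base frequencies and on exchangeability classes;
Uniform(0, 200) gamma shape; flat Dirichlet on the site-weighted
partition-rate simplex (so multipliers keep site-weighted mean 1 by
construction).

Moves: NNI on a uniform internal edge (symmetric kernel, two alternatives
each at probability ½ — tested on the 4-taxon case); branch multiplier with
log-Hastings ln m; Dirichlet proposals centered on the current point for
frequencies, exchangeability classes and the rate simplex (concentration
300); a multiplier move on the gamma shape rejected outside the prior.
Per-partition parameter moves touch one partition and are re-weighted with
√k so that each partition's parameters refresh at a roughly
partition-independent rate; they use the engine's incremental single-
partition evaluation, which keeps richly partitioned runs affordable.

The starting state is data-informed (a practical initialization, not part of
the model): NJ tree (or random), smoothed per-partition empirical base
frequencies, rate multipliers proportional to per-partition mean pairwise
p-distance, shape 1. Randomness uses one seed sequence per run with
per-chain child streams keyed by rank, so the cold chain's stream does not
depend on the number of chains; swap decisions draw from a dedicated stream.

Diagnostics: ESS = n / (1 + 2 Σ ρ_k) with the autocorrelation sum truncated
at the first nonpositive term; a constant series reports ESS 0 with a
degenerate flag (skipped, not failed, by the stationarity rule, since a
constant monitored scalar is not a mixing problem). The run-length rule
accepts when every monitored scalar (lnL, tree length, gamma shape) reaches
the ESS threshold (default 100) after burn-in, otherwise doubles the run up
to a cap, past which it accepts with a warning flag.

The marginal likelihood of a strategy is the harmonic mean of post-burn-in
likelihoods, `ln HM = ln n − logsumexp(−lnL_i)`, stable at mitogenome scale
(lnL ≈ −3·10⁵). Two strategies compare through `2lnB10 = 2(lnHM1 − lnHM0)`,
binned |v| < 2 none, [2,6) favoured, [6,10) strong, ≥ 10 very strong
(flagged significant), with the sign naming the winner. Because these are
full-data marginal likelihoods, realistic whole-matrix comparisons produce
values in the hundreds or thousands of log units; the harmonic-mean
estimator is known to be noisy and upward-biased, which is why only
differences far above the decision threshold are treated as meaningful.
Stepping-stone or path sampling are deliberately out of scope: the design
under evaluation used the harmonic mean.

Credible sets rank sampled topologies by frequency (ties broken by first
occurrence); the level-set size is the shortest prefix with cumulative
frequency ≥ the level. Robinson–Foulds distance counts the symmetric
difference of non-trivial bipartitions, unnormalized by default.

## ML and parsimony cross-checks

Maximum likelihood: NNI hill climbing with per-branch bounded Brent
optimization cycled to a 1e−6 lnL tolerance; candidate neighbors are
screened at current branch lengths and re-optimized when improving, so the
lnL trace is non-decreasing. Parsimony: vectorized Fitch counting with
ambiguities as state sets and gaps as the full set; exhaustive search
enumerates all (2n−5)!! topologies up to 9 taxa and returns every minimal
tree, above that an NNI heuristic returns a best-found set flagged
incomplete. Heavy tree-search machinery (ratchet/drifting/fusing, SPR/TBR)
is out of scope — correctness at desk scale is what is testable, and the
exhaustive mode provides the oracle. Nonparametric bootstrap resamples
columns with replacement to the original length and reports bipartition
support as percentages. Majority-rule consensus keeps splits above the
threshold frequency (threshold 1.0 degenerates to strict consensus) and is
cross-checked against an independent implementation in the tests.

## Synthetic data

The generator emulates the statistical structure of an insect mitogenome
matrix, not its sequence content:

- **Gene structure.** A synthetic 37-gene coordinate table in the conserved
  lepidopteran gene order with plausible per-gene lengths adjusted so class
  totals are exactly 11,340 (PCG), 2,528 (rRNA) and 1,627 bp (tRNA) —
  total 15,495 bp. The `nymphalid-mini` preset divides every length by 10
  (~1.5 kb total), preserving the class-length ratio.
- **Trees.** Birth–death (default pure-birth), rescaled to height 0.35
  substitutions/site — a typical within-family mitochondrial depth — with
  internal branches floored at 0.005 so the true topology is identifiable;
  12 taxa by default.
- **Composition.** Stationary frequencies realize A+T ≈ 0.80, inside the
  0.778–0.827 band observed for butterfly mitogenomes. Codon positions get
  distinct compositions (third positions strongly AT-rich at 0.93, first and
  second more balanced), the signature compositional heterogeneity of these
  genomes; the site-weighted mean stays ~0.80. This per-class heterogeneity
  matters: rate multipliers alone can be absorbed by a single model's gamma
  shape, and without compositional differences the data would not actually
  contain the between-partition structure the partitioning comparison is
  about.
- **Rates.** Codon-position rate multipliers 1 : 0.4 : 4 (pos1:pos2:pos3)
  with rRNA 0.8 and tRNA 0.9, normalized to site-weighted mean 1; shared
  transition-biased GTR exchangeabilities; gamma shape 0.8.
- **Ambiguities.** Exactly `round(rate × cells)` random cells are replaced
  by IUPAC codes compatible with the true state, at rate 2·10⁻⁴ (the "below
  0.02%" scale of real assemblies). No indels are simulated; alignments are
  gapless by construction.

What passing tests on these data do **not** show: robustness to alignment
error, indels, saturation at deep divergences, compositional
non-stationarity across lineages, or model misspecification beyond the
partition structure — all present in real matrices and all outside the
generator.

## Desk-scale study conditions

The full-size design (70 taxa, 15.5 kb, 5–20 million generations) is not
reproducible on a workstation; the evaluation studies run the same code at
committed reduced sizes:

- Likelihood verification: 50 random 4–6-taxon instances against the
  enumeration oracle (tolerance 1e−8) plus JC closed forms.
- Prior sampling: 4 taxa, 50,000 prior-only generations, topology
  frequencies within 3 Monte-Carlo SE of uniform; 2-taxon branch-length
  posterior mean within 2% of a quadrature oracle.
- Bayes-factor preference: 20 replicate mini studies (12 taxa, ~1.1 kb PCG
  selection), gene-by-codon (39 charsets) vs unpartitioned, single cold
  chain, 1,000 generations sampled every 10 from an NJ start; success =
  2lnB10 > 10.
- Credible-set ladder: 10 replicates of homogeneous fixed data (8 taxa,
  ~290 bp, no generating partition structure) analyzed under 1-, 3- and
  39-partition schemes (9, 29, 389 parameters), two coupled chains, 3,000
  generations; homogeneous generating conditions isolate the complexity
  effect, since any growth in topological uncertainty along the ladder is
  then attributable to the added parameters rather than to fit differences.
- Single-gene congruence: one mini study; concatenated D15 run under the
  4-partition strategy vs 15 per-gene runs (800 generations each),
  majority-rule consensus, RF to the known truth.

## Known limitations

- The harmonic-mean marginal likelihood is used because the evaluated design
  uses it; its instability is inherited deliberately.
- NNI-only topology moves can mix slowly on large trees; at the package's
  desk scales this is compensated by heating and data-informed starts, but
  credible-set totals from short runs remain mixing-sensitive for richly
  partitioned models (see the ladder study above).
- The credible-set/complexity pattern — larger credible sets under more
  heavily parameterized schemes — is scale-sensitive. It emerges on large
  matrices with many taxa, where numerous weakly resolved nodes let
  parameter uncertainty diffuse the topology posterior. At the ladder
  study's desk scale (8 taxa, ~290 bp) the opposite force often wins:
  richer partitioned models extract or overfit more signal and *sharpen*
  the topology posterior, and the sampled distinct-topology count is also
  mixing-limited. The ladder study reports the measured monotone fraction
  as it falls; readers should not expect the large-matrix pattern to
  reproduce reliably at this size.
- The exhaustive parsimony and enumeration oracles cap at 9 and 6 taxa;
  above that only heuristic modes exist.
- Model selection optimizes substitution parameters on fixed guide-tree
  branch lengths (with a single shared scale factor); this mirrors standard
  fixed-topology practice but can mis-rank families on data where branch
  lengths interact strongly with the model.
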