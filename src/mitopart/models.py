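"""Time-reversible nucleotide substitution models and their rate matrices.

A model is a family (JC ... GTR), six relative exchangeabilities in the fixed
order (AC, AG, AT, CG, CT, GT), stationary base frequencies, and an optional
gamma shape for among-site rate variation discretized into equal-probability
categories with category-mean rates (4 by default).

Families are encoded by which exchangeabilities are tied into shared classes
and whether base frequencies are free:

=======  =======================  ==========  ==============
family   rate classes             free rates  free freqs
=======  =======================  ==========  ==============
JC       all equal                0           no (1/4 each)
K80      ti vs tv                 1           no
HKY      ti vs tv                 1           yes (3)
TrN      AG, CT, tv               2           yes
TPM      AC=GT, AG=CT, AT=CG      2           yes
TIM      AC=GT, AG, CT, AT=CG     3           yes
TVM      AG=CT, 4 tv free         4           yes
SYM      all free                 5           no
GTR      all free                 5           yes
=======  =======================  ==========  ==============

The generator Q has q_ij = r_ij * pi_j (i != j) and is normalized to one
expected substitution per unit branch length at stationarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import cached_property

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

#: exchangeability order
PAIRS = ("AC", "AG", "AT", "CG", "CT", "GT")

#: rate class index per exchangeability, and whether frequencies are free
FAMILY_RATE_CLASSES: dict[str, tuple[tuple[int, ...], bool]] = {
    # classes are ids over the 6 pairs (AC, AG, AT, CG, CT, GT)
    "JC":  ((0, 0, 0, 0, 0, 0), False),
    "K80": ((0, 1, 0, 0, 1, 0), False),
    "HKY": ((0, 1, 0, 0, 1, 0), True),
    "TrN": ((0, 1, 0, 0, 2, 0), True),
    "TPM": ((0, 1, 2, 2, 1, 0), True),
    "TIM": ((0, 1, 2, 2, 3, 0), True),
    "TVM": ((0, 1, 2, 3, 1, 4), True),
    "SYM": ((0, 1, 2, 3, 4, 5), False),
    "GTR": ((0, 1, 2, 3, 4, 5), True),
}

#: best-fit families the Bayesian engine cannot parameterize directly are
#: replaced by the nearest over-parameterized model (GTR).
_UNAVAILABLE_TO_GTR = {"TrN", "TPM", "TPM1", "TPM2", "TPM3",
                       "TIM", "TIM1", "TIM2", "TIM3", "TVM"}
_ALIASES = {"TPM1": "TPM", "TPM2": "TPM", "TPM3": "TPM",
            "TIM1": "TIM", "TIM2": "TIM", "TIM3": "TIM",
            "K2P": "K80", "JC69": "JC", "F81": "HKY"}


class ModelError(ValueError):
    pass


class DegenerateModelError(ModelError):
    pass


def map_to_available(family: str) -> str:
    """The substitution rule: best-fit families the MCMC engine cannot fit
    directly map to the nearest over-parameterized family (GTR); the rest map
    to themselves."""
    fam = family.strip()
    if fam in _UNAVAILABLE_TO_GTR:
        return "GTR"
    canon = _ALIASES.get(fam, fam)
    if canon not in FAMILY_RATE_CLASSES:
        raise ModelError(f"unknown model family {family!r}")
    return canon


def n_free_parameters(family: str, gamma: bool) -> int:
    """Free substitution-model parameters (GTR+G = 5 + 3 + 1 = 9)."""
    fam = _ALIASES.get(family, family)
    classes, free_freqs = FAMILY_RATE_CLASSES[fam]
    k = (max(classes))  # n_classes - 1 free relative rates
    if free_freqs:
        k += 3
    if gamma:
        k += 1
    return k


def discrete_gamma_rates(shape: float, n_categories: int) -> np.ndarray:
    """Category-mean rates of the equal-probability discrete gamma (mean 1)."""
    if n_categories == 1:
        return np.ones(1)
    if shape <= 0:
        raise ModelError("gamma shape must be positive")
    probs = np.arange(1, n_categories) / n_categories
    cuts = gamma_dist.ppf(probs, a=shape, scale=1.0 / shape)
    bounds = np.concatenate([[0.0], cuts, [np.inf]])
    # mean of X on (a,b] for X~Gamma(shape, 1/shape): uses the CDF at shape+1
    upper = gammainc(shape + 1, shape * bounds[1:])
    lower = gammainc(shape + 1, shape * bounds[:-1])
    rates = n_categories * (upper - lower)
    return rates / rates.mean()


@dataclass(frozen=True)
class SubstitutionModel:
    """Immutable reversible nucleotide model; mutate via `dataclasses.replace`."""

    family: str = "GTR"
    exchangeabilities: tuple[float, ...] = (1.0,) * 6  # AC AG AT CG CT GT
    base_freqs: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    gamma_shape: float | None = None
    n_gamma_categories: int = 4

    def __post_init__(self) -> None:
        if self.family not in FAMILY_RATE_CLASSES:
            raise ModelError(f"unknown model family {self.family!r}")
        ex = np.asarray(self.exchangeabilities, float)
        pi = np.asarray(self.base_freqs, float)
        if ex.shape != (6,) or (ex < 0).any():
            raise ModelError("need 6 nonnegative exchangeabilities")
        if pi.shape != (4,) or (pi < 0).any() or abs(pi.sum() - 1) > 1e-9:
            raise ModelError("base frequencies must be 4 values summing to 1")
        classes, free_freqs = FAMILY_RATE_CLASSES[self.family]
        for c in set(classes):
            vals = ex[[i for i, ci in enumerate(classes) if ci == c]]
            if np.ptp(vals) > 1e-9 * max(1.0, vals.max()):
                raise ModelError(
                    f"{self.family}: tied exchangeabilities differ ({PAIRS})")
        if not free_freqs and np.abs(pi - 0.25).max() > 1e-9:
            raise ModelError(f"{self.family} requires equal base frequencies")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ModelError("gamma shape must be positive")
        object.__setattr__(self, "exchangeabilities", tuple(ex))
        object.__setattr__(self, "base_freqs", tuple(pi))

    # -- constructors ----------------------------------------------------
    @classmethod
    def jc(cls, gamma_shape: float | None = None,
           n_gamma_categories: int = 4) -> "SubstitutionModel":
        return cls("JC", (1.0,) * 6, (0.25,) * 4, gamma_shape,
                   n_gamma_categories)

    @classmethod
    def from_family(cls, family: str, rates_by_class: "np.ndarray | None" = None,
                    base_freqs=None, gamma_shape: float | None = None,
                    n_gamma_categories: int = 4) -> "SubstitutionModel":
        """Build a model from per-class relative rates (last class fixed 1)."""
        classes, free_freqs = FAMILY_RATE_CLASSES[family]
        n_classes = max(classes) + 1
        if rates_by_class is None:
            rates_by_class = np.ones(n_classes)
        rates_by_class = np.asarray(rates_by_class, float)
        ex = tuple(float(rates_by_class[c]) for c in classes)
        if base_freqs is None or not free_freqs:
            base_freqs = (0.25,) * 4
        return cls(family, ex, tuple(np.asarray(base_freqs, float)),
                   gamma_shape, n_gamma_categories)

    # -- derived quantities ----------------------------------------------
    @property
    def n_categories(self) -> int:
        return self.n_gamma_categories if self.gamma_shape is not None else 1

    @cached_property
    def category_rates(self) -> np.ndarray:
        if self.gamma_shape is None:
            return np.ones(1)
        return discrete_gamma_rates(self.gamma_shape, self.n_gamma_categories)

    @cached_property
    def rate_matrix(self) -> np.ndarray:
        return build_rate_matrix(self)

    @cached_property
    def _eigen(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Symmetric-form eigendecomposition of Q: (eigenvalues, U, Uinv)."""
        pi = np.asarray(self.base_freqs)
        sq = np.sqrt(np.maximum(pi, 1e-300))
        B = self.rate_matrix * sq[:, None] / sq[None, :]
        lam, V = np.linalg.eigh((B + B.T) / 2)
        U = V / sq[:, None]
        Uinv = V.T * sq[None, :]
        return lam, U, Uinv

    @property
    def free_parameters(self) -> int:
        return n_free_parameters(self.family, self.gamma_shape is not None)

    def with_gamma(self, shape: float) -> "SubstitutionModel":
        return replace(self, gamma_shape=float(shape))


def build_rate_matrix(model: SubstitutionModel) -> np.ndarray:
    """Normalized GTR-form generator: q_ij = r_ij * pi_j, mean rate 1."""
    ex = np.asarray(model.exchangeabilities)
    pi = np.asarray(model.base_freqs)
    R = np.zeros((4, 4))
    idx = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]  # AC AG AT CG CT GT
    for k, (i, j) in enumerate(idx):
        R[i, j] = R[j, i] = ex[k]
    for i in range(4):
        if pi[i] == 0 and R[:, i].sum() > 0:
            raise DegenerateModelError(
                "zero stationary frequency with nonzero inbound rate")
    Q = R * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -float(np.dot(pi, np.diag(Q)))
    if mu <= 0:
        raise DegenerateModelError("rate matrix has zero total rate")
    return Q / mu


def transition_probabilities(model: SubstitutionModel, t: float) -> np.ndarray:
    """P(t) per gamma category: array (n_categories, 4, 4), rows sum to 1."""
    if t < 0:
        raise ModelError("branch length must be nonnegative")
    lam, U, Uinv = model._eigen
    rates = model.category_rates
    expo = np.exp(lam[None, :] * rates[:, None] * t)  # (cat, 4)
    P = np.einsum("ik,ck,kj->cij", U, expo, Uinv)
    P = np.clip(P, 0.0, None)
    return P / P.sum(axis=2, keepdims=True)


# ---------------------------------------------------------------------------
# partitioned models
# ---------------------------------------------------------------------------

@dataclass
class PartitionedModel:
    """Per-partition substitution models plus partition rate multipliers.

    The multipliers scale branch lengths per partition and are constrained to
    a site-weighted mean of 1 (weights = charset sizes).
    """

    models: list[SubstitutionModel]
    multipliers: np.ndarray = field(default=None)  # type: ignore[assignment]
    weights: np.ndarray = field(default=None)      # type: ignore[assignment]

    def __post_init__(self) -> None:
        k = len(self.models)
        if self.multipliers is None:
            self.multipliers = np.ones(k)
        self.multipliers = np.asarray(self.multipliers, float)
        if self.weights is None:
            self.weights = np.ones(k)
        self.weights = np.asarray(self.weights, float)
        if len(self.multipliers) != k or len(self.weights) != k:
            raise ModelError("multipliers/weights must match model count")
        w = self.weights / self.weights.sum()
        mean = float(np.dot(w, self.multipliers))
        if abs(mean - 1) > 1e-6:
            raise ModelError(
                f"site-weighted mean of rate multipliers is {mean:.6f}, not 1")

    @property
    def n_partitions(self) -> int:
        return len(self.models)

    def free_parameter_count(self) -> int:
        k = self.n_partitions
        total = sum(m.free_parameters for m in self.models)
        if k > 1:
            total += k - 1  # free rate multipliers
        return total


def count_free_parameters(scheme, models: PartitionedModel) -> int:
    """Sum of per-partition free parameters plus (k-1) rate multipliers."""
    if len(scheme.charsets) != models.n_partitions:
        raise ModelError("scheme and models are not aligned")
    return models.free_parameter_count()


def uniform_partitioned_model(scheme, family: str = "GTR",
                              gamma_shape: float | None = 1.0,
                              n_gamma_categories: int = 4) -> PartitionedModel:
    """One identical model per charset, unit multipliers."""
    sizes = np.array(scheme.sizes, float)
    model = SubstitutionModel.from_family(
        family, gamma_shape=gamma_shape,
        base_freqs=(0.25,) * 4 if not FAMILY_RATE_CLASSES[family][1] else None,
        n_gamma_categories=n_gamma_categories)
    return PartitionedModel([model] * len(scheme.charsets),
                            np.ones(len(scheme.charsets)), sizes)
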