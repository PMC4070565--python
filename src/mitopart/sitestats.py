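"""Alignment summary statistics: site classification, composition, windows.

Gaps, missing data and IUPAC ambiguity codes are excluded from state counting,
the convention of standard polymorphism software: a column is *variable* when
at least two distinct unambiguous nucleotides occur in it, and
*parsimony-informative* when at least two states are each carried by at least
two taxa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqdata import Alignment

BASES = np.array(["A", "C", "G", "T"])


class CompositionError(ValueError):
    pass


class WindowError(ValueError):
    pass


@dataclass(frozen=True)
class SiteCounts:
    n_sites: int
    n_variable: int
    n_parsimony_informative: int
    at_fraction: float | None

    def __post_init__(self) -> None:
        if not (0 <= self.n_parsimony_informative <= self.n_variable
                <= self.n_sites):
            raise ValueError("inconsistent site counts")


def _base_counts(alignment: Alignment) -> np.ndarray:
    """(4, n_sites) counts of unambiguous A/C/G/T per column."""
    m = alignment.matrix
    return np.stack([(m == b).sum(axis=0) for b in BASES])


def classify_sites(alignment: Alignment) -> SiteCounts:
    """Count variable and parsimony-informative columns and A+T composition."""
    if alignment.length == 0:
        return SiteCounts(0, 0, 0, None)
    counts = _base_counts(alignment)
    n_states = (counts > 0).sum(axis=0)
    variable = n_states >= 2
    informative = (counts >= 2).sum(axis=0) >= 2
    total = counts.sum()
    at = None
    if total > 0:
        at = float((counts[0].sum() + counts[3].sum()) / total)
    return SiteCounts(alignment.length, int(variable.sum()),
                      int(informative.sum()), at)


def at_fraction(alignment: Alignment) -> float:
    """(#A + #T) / (#A + #C + #G + #T); ambiguities, gaps and '?' excluded."""
    counts = _base_counts(alignment)
    total = counts.sum()
    if total == 0:
        raise CompositionError("no unambiguous nucleotides in alignment")
    return float((counts[0].sum() + counts[3].sum()) / total)


def sliding_window_polymorphism(alignment: Alignment, width: int = 500,
                                step: int = 2) -> pd.DataFrame:
    """Variable-site counts in sliding windows.

    Windows start at 0, step, 2*step, ... while a full window fits.  Returns a
    DataFrame with columns ``window_start`` (0-based) and ``n_variable``.
    """
    if width < 1 or step < 1:
        raise WindowError("width and step must be >= 1")
    if alignment.length < width:
        raise WindowError(
            f"alignment length {alignment.length} is shorter than the window "
            f"width {width}: no window fits")
    counts = _base_counts(alignment)
    variable = ((counts > 0).sum(axis=0) >= 2).astype(int)
    csum = np.concatenate([[0], np.cumsum(variable)])
    starts = np.arange(0, alignment.length - width + 1, step)
    n_var = csum[starts + width] - csum[starts]
    return pd.DataFrame({"window_start": starts, "n_variable": n_var})
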