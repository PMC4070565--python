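"""The twelve partitioning strategies over the three dataset selections.

Each strategy assigns every site of its dataset to exactly one character set:

========  =======  ==========================================================
strategy  dataset  charsets
========  =======  ==========================================================
PS1       D37      1: everything combined
PS2       D37      4: PCG codon positions 1/2/3 + one combined RNA set
PS3       D37      37: one per gene
PS4       D37      63: PCG gene x codon position + each RNA gene whole
PS5       D15      1
PS6       D15      4: codon positions + the two rRNAs combined
PS7       D15      15: one per gene
PS8       D15      41: PCG gene x codon + rRNA genes whole
PS9       D13      1
PS10      D13      3: codon positions
PS11      D13      13: one per gene
PS12      D13      39: gene x codon
========  =======  ==========================================================

Codon position of a PCG site is ``(site - gene_start - frame) mod 3`` computed
per gene; trailing partial codons keep their computed position.  Charsets are
emitted in gene order with codon sub-charsets in order 1, 2, 3, so output is
stable run to run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .seqdata import DatasetSelection, GeneEntry, GeneMap

STRATEGY_DATASET: dict[str, str] = {
    "PS1": "D37", "PS2": "D37", "PS3": "D37", "PS4": "D37",
    "PS5": "D15", "PS6": "D15", "PS7": "D15", "PS8": "D15",
    "PS9": "D13", "PS10": "D13", "PS11": "D13", "PS12": "D13",
}


class PartitionConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CharSet:
    name: str
    sites: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.sites:
            raise PartitionConfigError(f"charset {self.name} is empty")

    def __len__(self) -> int:
        return len(self.sites)


@dataclass
class PartitionScheme:
    strategy_id: str
    charsets: list[CharSet]
    n_sites: int

    def __post_init__(self) -> None:
        seen: set[int] = set()
        total = 0
        for cs in self.charsets:
            s = set(cs.sites)
            if s & seen:
                raise PartitionConfigError(
                    f"charset {cs.name} overlaps an earlier charset")
            seen |= s
            total += len(s)
        if total != self.n_sites or (seen and max(seen) >= self.n_sites):
            raise PartitionConfigError(
                f"charsets cover {total} sites, expected exactly {self.n_sites}")

    def __len__(self) -> int:
        return len(self.charsets)

    @property
    def names(self) -> list[str]:
        return [cs.name for cs in self.charsets]

    @property
    def sizes(self) -> list[int]:
        return [len(cs) for cs in self.charsets]


def codon_position(entry: GeneEntry, site: int) -> int:
    """1-based codon position of an absolute site inside a PCG span."""
    if entry.gene_class != "PCG":
        raise PartitionConfigError(f"{entry.name} is not a PCG")
    return (site - entry.start - entry.frame) % 3 + 1


def build_partition_scheme(gmap: GeneMap, sel: DatasetSelection | str,
                           strategy: str) -> PartitionScheme:
    """Build the charsets of one strategy on a dataset's (remapped) gene map.

    *gmap* must already be the gene map of the selected dataset (the output of
    :func:`mitopart.seqdata.build_dataset`), so that gene spans index the
    dataset's own columns.
    """
    if isinstance(sel, str):
        sel = DatasetSelection(sel)
    if strategy not in STRATEGY_DATASET:
        raise PartitionConfigError(f"unknown strategy {strategy!r}")
    if STRATEGY_DATASET[strategy] != sel.id:
        raise PartitionConfigError(
            f"strategy {strategy} applies to dataset "
            f"{STRATEGY_DATASET[strategy]}, not {sel.id}")
    present = {e.gene_class for e in gmap}
    if not present <= set(sel.included_classes):
        raise PartitionConfigError(
            f"gene map contains classes {present} outside selection {sel.id}")

    n_sites = gmap.total_length
    kind = {"PS1": "none", "PS5": "none", "PS9": "none",
            "PS2": "codon", "PS6": "codon", "PS10": "codon",
            "PS3": "gene", "PS7": "gene", "PS11": "gene",
            "PS4": "gene_codon", "PS8": "gene_codon", "PS12": "gene_codon",
            }[strategy]

    charsets: list[CharSet] = []
    if kind == "none":
        charsets.append(CharSet("all", tuple(range(n_sites))))
    elif kind == "codon":
        pos_sites: dict[int, list[int]] = {1: [], 2: [], 3: []}
        rna_sites: list[int] = []
        for e in gmap:
            if e.gene_class == "PCG":
                for s in range(e.start, e.end):
                    pos_sites[codon_position(e, s)].append(s)
            else:
                rna_sites.extend(range(e.start, e.end))
        for p in (1, 2, 3):
            charsets.append(CharSet(f"pos{p}", tuple(pos_sites[p])))
        if rna_sites:
            name = "rRNA" if sel.id == "D15" else "RNA"
            charsets.append(CharSet(name, tuple(rna_sites)))
    elif kind == "gene":
        for e in gmap:
            charsets.append(CharSet(e.name, tuple(range(e.start, e.end))))
    else:  # gene_codon
        for e in gmap:
            if e.gene_class == "PCG":
                for p in (1, 2, 3):
                    sites = tuple(s for s in range(e.start, e.end)
                                  if codon_position(e, s) == p)
                    charsets.append(CharSet(f"{e.name}_pos{p}", sites))
            else:
                charsets.append(CharSet(e.name, tuple(range(e.start, e.end))))
    return PartitionScheme(strategy, charsets, n_sites)


def single_partition(n_sites: int, name: str = "all") -> PartitionScheme:
    """Trivial one-charset scheme covering *n_sites* columns."""
    return PartitionScheme("single", [CharSet(name, tuple(range(n_sites)))],
                           n_sites)


def expected_charset_count(strategy: str, gmap: GeneMap) -> int:
    """Closed-form charset count for a strategy on a gene map (for checks)."""
    counts = gmap.class_counts()
    n_pcg, n_rrna, n_trna = counts["PCG"], counts["rRNA"], counts["tRNA"]
    kind_map = {"PS1": 1, "PS5": 1, "PS9": 1,
                "PS2": 4, "PS6": 4, "PS10": 3}
    if strategy in kind_map:
        return kind_map[strategy]
    if strategy in ("PS3", "PS7", "PS11"):
        return len(gmap)
    return 3 * n_pcg + n_rrna + n_trna  # gene x codon strategies
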