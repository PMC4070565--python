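"""Alignments, gene annotation maps, and dataset selections.

A mitogenome study concatenates the 13 protein-coding genes (PCGs), 2 rRNAs
and 22 tRNAs into one matrix; a :class:`GeneMap` records where each gene sits
(0-based half-open spans), its class, its reading-frame offset (PCGs) and
strand.  :func:`build_dataset` cuts the matrix down to one of the three
standard selections: all 37 genes, the 15 major genes (PCG+rRNA), or the 13
PCGs alone.

FASTA reading/writing goes through Biopython SeqIO; NEXUS reading through
Bio.Nexus (character sets in a ``sets`` block are returned as an external
partition scheme).  NEXUS output uses 1-based inclusive charset coordinates,
as the format requires; everything in memory is 0-based half-open.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Nexus import Nexus

#: IUPAC nucleotide codes -> set of compatible bases.
IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
    "-": "", "?": "ACGT",
}

AMBIGUITY_CODES = set("RYSWKMBDHVN")

GENE_CLASSES = ("PCG", "rRNA", "tRNA")


class AlignmentShapeError(ValueError):
    pass


class SymbolError(ValueError):
    pass


class EmptyDatasetError(ValueError):
    pass


@dataclass
class Alignment:
    """Aligned nucleotide matrix: rows are taxa, columns are sites."""

    taxa: list[str]
    matrix: np.ndarray  # (n_taxa, n_sites) of single-char unicode

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if self.matrix.ndim != 2:
            raise AlignmentShapeError("matrix must be 2-D")
        if len(self.taxa) != self.matrix.shape[0]:
            raise AlignmentShapeError("taxon count does not match matrix rows")
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentShapeError("duplicate taxon labels")
        self._validate_symbols()

    def _validate_symbols(self) -> None:
        valid = set(IUPAC)
        upper = np.char.upper(self.matrix)
        bad = ~np.isin(upper, sorted(valid))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise SymbolError(
                f"unknown symbol {self.matrix[i, j]!r} at taxon "
                f"{self.taxa[i]!r}, column {j}"
            )
        self.matrix = upper

    @property
    def length(self) -> int:
        return int(self.matrix.shape[1])

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def sequence(self, taxon: str) -> str:
        return "".join(self.matrix[self.taxa.index(taxon)])

    def subset_columns(self, cols: Sequence[int]) -> "Alignment":
        return Alignment(list(self.taxa), self.matrix[:, list(cols)])

    @classmethod
    def from_sequences(cls, pairs: Iterable[tuple[str, str]]) -> "Alignment":
        taxa, seqs = [], []
        for name, seq in pairs:
            taxa.append(name)
            seqs.append(list(seq))
        lens = {len(s) for s in seqs}
        if len(lens) > 1:
            raise AlignmentShapeError(f"ragged rows: lengths {sorted(lens)}")
        return cls(taxa, np.array(seqs, dtype="<U1"))


@dataclass(frozen=True)
class GeneEntry:
    name: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    gene_class: str
    frame: int | None = None  # 0..2 for PCGs
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(f"unknown gene class {self.gene_class!r}")
        if self.gene_class == "PCG":
            if self.frame not in (0, 1, 2):
                raise ValueError(f"PCG {self.name}: frame must be 0..2")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad span for {self.name}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneMap:
    """Ordered gene coordinate table over a concatenated alignment."""

    entries: list[GeneEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = 0
        for e in self.entries:
            if e.start < prev_end:
                raise ValueError(f"overlapping/unordered span at {e.name}")
            prev_end = e.end

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def total_length(self) -> int:
        return sum(e.length for e in self.entries)

    def by_class(self, gene_class: str) -> list[GeneEntry]:
        return [e for e in self.entries if e.gene_class == gene_class]

    def class_counts(self) -> dict[str, int]:
        return {c: len(self.by_class(c)) for c in GENE_CLASSES}

    def class_lengths(self) -> dict[str, int]:
        return {c: sum(e.length for e in self.by_class(c)) for c in GENE_CLASSES}

    def validate_against(self, alignment: Alignment) -> None:
        if self.entries and self.entries[-1].end > alignment.length:
            raise ValueError(
                f"gene map extends to {self.entries[-1].end} beyond alignment "
                f"length {alignment.length}"
            )

    # -- TSV interchange -------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"gene": e.name, "start": e.start, "end": e.end,
             "class": e.gene_class,
             "frame": "" if e.frame is None else e.frame,
             "strand": e.strand}
            for e in self.entries
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneMap":
        df = pd.read_csv(path, sep="\t", dtype={"gene": str, "strand": str})
        entries = []
        for _, r in df.iterrows():
            frame = r.get("frame")
            frame = None if pd.isna(frame) or frame == "" else int(frame)
            entries.append(GeneEntry(str(r["gene"]), int(r["start"]),
                                     int(r["end"]), str(r["class"]),
                                     frame, str(r.get("strand", "+"))))
        return cls(entries)


# ---------------------------------------------------------------------------
# dataset selections
# ---------------------------------------------------------------------------

DATASET_CLASSES: dict[str, tuple[str, ...]] = {
    "D37": ("PCG", "rRNA", "tRNA"),
    "D15": ("PCG", "rRNA"),
    "D13": ("PCG",),
}


@dataclass(frozen=True)
class DatasetSelection:
    id: str

    def __post_init__(self) -> None:
        if self.id not in DATASET_CLASSES:
            raise ValueError(f"unknown dataset selection {self.id!r}")

    @property
    def included_classes(self) -> tuple[str, ...]:
        return DATASET_CLASSES[self.id]


def build_dataset(alignment: Alignment, gmap: GeneMap,
                  sel: DatasetSelection | str) -> tuple[Alignment, GeneMap]:
    """Column-subset the alignment to the genes of one dataset selection.

    Gene order is preserved; the returned GeneMap is remapped to the new
    coordinates.
    """
    if isinstance(sel, str):
        sel = DatasetSelection(sel)
    gmap.validate_against(alignment)
    keep = [e for e in gmap if e.gene_class in sel.included_classes]
    if not keep:
        raise EmptyDatasetError(f"selection {sel.id} removes every gene")
    cols: list[int] = []
    new_entries: list[GeneEntry] = []
    offset = 0
    for e in keep:
        cols.extend(range(e.start, e.end))
        new_entries.append(GeneEntry(e.name, offset, offset + e.length,
                                     e.gene_class, e.frame, e.strand))
        offset += e.length
    return alignment.subset_columns(cols), GeneMap(new_entries)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> Alignment:
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise AlignmentShapeError(f"no sequences in {path}")
    return Alignment.from_sequences(records)


def write_fasta(alignment: Alignment, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for i, taxon in enumerate(alignment.taxa):
            fh.write(f">{taxon}\n")
            seq = "".join(alignment.matrix[i])
            for j in range(0, len(seq), width):
                fh.write(seq[j:j + width] + "\n")


def read_nexus(path: str | Path):
    """Read a NEXUS data file; returns (Alignment, external scheme or None).

    Charsets in a sets block come back as a PartitionScheme with strategy id
    ``external``.
    """
    from .partitions import CharSet, PartitionScheme  # cycle guard

    nex = Nexus.Nexus(str(path))
    pairs = [(str(t), str(nex.matrix[t])) for t in nex.taxlabels]
    aln = Alignment.from_sequences(pairs)
    scheme = None
    if nex.charsets:
        charsets = [CharSet(name, tuple(sorted(int(i) for i in sites)))
                    for name, sites in nex.charsets.items()]
        scheme = PartitionScheme("external", charsets, n_sites=aln.length)
    return aln, scheme


def write_nexus(alignment: Alignment, path: str | Path,
                scheme=None) -> None:
    """Write a NEXUS data block (plus a sets block if a scheme is given).

    Charset site numbers are written 1-based inclusive, per the NEXUS dialect.
    """
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"    DIMENSIONS NTAX={alignment.n_taxa} "
                 f"NCHAR={alignment.length};\n")
        fh.write("    FORMAT DATATYPE=DNA MISSING=? GAP=-;\n    MATRIX\n")
        pad = max(len(t) for t in alignment.taxa) + 2
        for i, taxon in enumerate(alignment.taxa):
            fh.write(f"    {taxon:<{pad}}{''.join(alignment.matrix[i])}\n")
        fh.write("    ;\nEND;\n")
        if scheme is not None:
            fh.write("\nBEGIN SETS;\n")
            for cs in scheme.charsets:
                fh.write(f"    CHARSET {cs.name} = "
                         f"{_ranges_1based(cs.sites)};\n")
            fh.write("END;\n")


def _ranges_1based(sites: Sequence[int]) -> str:
    """Compact 1-based inclusive range list, with NEXUS ``a-b\\3`` stride form."""
    sites = sorted(sites)
    parts: list[str] = []
    i = 0
    while i < len(sites):
        j = i
        if i + 1 < len(sites):
            stride = sites[i + 1] - sites[i]
            while j + 1 < len(sites) and sites[j + 1] - sites[j] == stride:
                j += 1
        else:
            stride = 1
        if j == i:
            parts.append(str(sites[i] + 1))
        elif stride == 1:
            parts.append(f"{sites[i] + 1}-{sites[j] + 1}")
        else:
            parts.append(f"{sites[i] + 1}-{sites[j] + 1}\\{stride}")
        i = j + 1
    return " ".join(parts)


def read_alignment(path: str | Path, format: str = "FASTA"):
    """Read an alignment in FASTA or NEXUS format.

    Returns ``(Alignment, scheme_or_None)``; only NEXUS can carry charsets.
    """
    fmt = format.upper()
    if fmt == "FASTA":
        return read_fasta(path), None
    if fmt == "NEXUS":
        return read_nexus(path)
    raise ValueError(f"unknown alignment format {format!r}")
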