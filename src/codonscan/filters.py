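"""Alignment cleaning: from a protein alignment to a filtered codon alignment.

The cascade mirrors standard pre-processing for selection scans:

1. a conserved-block filter (a simplified Gblocks-style trimmer) that drops
   gappy/unconserved columns and short runs of good columns;
2. two singleton sliding-window filters (15-residue windows where one
   species carries >= 10 singleton residues; 5-residue windows where every
   column holds a singleton) that remove tracts typical of assembly or
   annotation error in a single species;
3. back-translation of the surviving protein columns to in-frame codons;
4. removal of every codon column containing a gap or ambiguity, so the
   likelihood engine only ever sees sense codons.

All filters operate on amino-acid coordinates and only ever delete whole
columns; drops from the separate passes are unioned on the original
coordinates, so composition order cannot matter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .io import SequenceRecord

__all__ = [
    "AminoAlignment",
    "CodonAlignment",
    "DegenerateAlignmentError",
    "BacktranslationError",
    "singleton_window_filter",
    "conserved_block_filter",
    "apply_column_mask",
    "backtranslate",
    "clean_gapped_columns",
    "filter_and_backtranslate",
]


class DegenerateAlignmentError(ValueError):
    """Filtering removed every column."""


class BacktranslationError(ValueError):
    """CDS does not translate to the aligned protein row."""


@dataclass
class AminoAlignment:
    """Aligned amino-acid rows: ``chars`` is (n_taxa, width) of single chars."""

    taxa: list[str]
    chars: np.ndarray

    @classmethod
    def from_records(cls, records: Sequence[SequenceRecord], taxa: Sequence[str] | None = None) -> "AminoAlignment":
        names = list(taxa) if taxa is not None else [r.species or r.record_id for r in records]
        widths = {len(r.residues) for r in records}
        if len(widths) != 1:
            raise ValueError(f"rows have unequal widths: {sorted(widths)}")
        chars = np.array([list(r.residues) for r in records], dtype="<U1")
        if len(set(names)) != len(names):
            raise ValueError("duplicate taxa in alignment")
        return cls(names, chars)

    @property
    def width(self) -> int:
        return self.chars.shape[1]

    @property
    def n_taxa(self) -> int:
        return self.chars.shape[0]

    def row(self, taxon: str) -> str:
        return "".join(self.chars[self.taxa.index(taxon)])


@dataclass
class CodonAlignment:
    """Column-synchronised codon rows: ``codons`` is (n_taxa, width) of 3-mers."""

    taxa: list[str]
    codons: np.ndarray  # dtype <U3; '---' marks a gap cell

    @property
    def width(self) -> int:
        return self.codons.shape[1]

    @property
    def n_taxa(self) -> int:
        return self.codons.shape[0]

    def row(self, taxon: str) -> str:
        return "".join(self.codons[self.taxa.index(taxon)])


def _singleton_matrix(aln: AminoAlignment) -> np.ndarray:
    """Boolean (n_taxa, width): cell is a singleton residue — non-gap and the
    only occurrence of that amino acid in its column."""
    chars = aln.chars
    n_taxa, width = chars.shape
    singleton = np.zeros((n_taxa, width), dtype=bool)
    for j in range(width):
        col = chars[:, j]
        vals, counts = np.unique(col, return_counts=True)
        once = {v for v, c in zip(vals, counts) if c == 1 and v != "-"}
        if once:
            singleton[:, j] = np.isin(col, list(once))
    return singleton


def singleton_window_filter(
    aln: AminoAlignment,
    long_window: int = 15,
    long_threshold: int = 10,
    short_window: int = 5,
) -> np.ndarray:
    """Keep-mask over columns after the two singleton sliding-window passes.

    Pass 1: any ``long_window``-column window in which a single species owns
    at least ``long_threshold`` singleton columns is dropped whole. Pass 2:
    any ``short_window``-column window in which *every* column contains a
    singleton (any species) is dropped whole. Both passes are evaluated on
    the original alignment and slide by one column; their drops are unioned.
    Windows longer than the alignment make that pass a no-op.
    """
    singleton = _singleton_matrix(aln)
    width = aln.width
    drop = np.zeros(width, dtype=bool)

    if width >= long_window:
        # per-species rolling count of singleton columns
        cs = np.cumsum(singleton, axis=1)
        for start in range(width - long_window + 1):
            end = start + long_window
            counts = cs[:, end - 1] - (cs[:, start - 1] if start else 0)
            if (counts >= long_threshold).any():
                drop[start:end] = True

    if width >= short_window:
        any_singleton = singleton.any(axis=0)
        cs = np.cumsum(any_singleton)
        for start in range(width - short_window + 1):
            end = start + short_window
            count = cs[end - 1] - (cs[start - 1] if start else 0)
            if count == short_window:
                drop[start:end] = True

    return ~drop


def conserved_block_filter(
    aln: AminoAlignment,
    min_block: int = 10,
    max_gap_fraction: float = 0.5,
) -> np.ndarray:
    """Keep-mask of a simplified conserved-block trimmer.

    A column is "good" when its gap fraction is at most ``max_gap_fraction``
    and at least half of its non-gap residues agree on one amino acid. Bad
    columns are dropped, as are runs of good columns shorter than
    ``min_block``.
    """
    if min_block < 1:
        raise ValueError("min_block must be >= 1")
    if not 0 <= max_gap_fraction <= 1:
        raise ValueError("max_gap_fraction must be in [0, 1]")
    chars = aln.chars
    n_taxa, width = chars.shape
    good = np.zeros(width, dtype=bool)
    for j in range(width):
        col = chars[:, j]
        gaps = int((col == "-").sum())
        if n_taxa and gaps / n_taxa > max_gap_fraction:
            continue
        residues = col[col != "-"]
        if residues.size == 0:
            continue
        _, counts = np.unique(residues, return_counts=True)
        if 2 * counts.max() >= residues.size:
            good[j] = True
    keep = np.zeros(width, dtype=bool)
    j = 0
    while j < width:
        if not good[j]:
            j += 1
            continue
        k = j
        while k < width and good[k]:
            k += 1
        if k - j >= min_block:
            keep[j:k] = True
        j = k
    return keep


def apply_column_mask(aln: AminoAlignment, keep: np.ndarray) -> AminoAlignment:
    return AminoAlignment(list(aln.taxa), aln.chars[:, np.asarray(keep, dtype=bool)])


def write_column_mask(keep: np.ndarray, path) -> None:
    """Audit file for a filter decision: 1-based column index, keep/drop."""
    with open(path, "w") as fh:
        fh.write("column\tdecision\n")
        for j, k in enumerate(np.asarray(keep, dtype=bool), start=1):
            fh.write(f"{j}\t{'keep' if k else 'drop'}\n")


def read_column_mask(path) -> np.ndarray:
    with open(path) as fh:
        header = next(fh)
        if header.strip() != "column\tdecision":
            raise ValueError(f"unexpected mask header in {path}")
        return np.array([line.split("\t")[1].strip() == "keep" for line in fh])


_STOPS = {"TAA", "TAG", "TGA"}


def backtranslate(aa: AminoAlignment, cds: Mapping[str, SequenceRecord]) -> CodonAlignment:
    """Thread each species' CDS through its aligned protein row.

    Every aligned residue is replaced by its source codon and every gap by
    ``---``, so codon columns correspond 1:1 to protein columns. The CDS
    must translate exactly to the ungapped row under the universal code; a
    single terminal stop codon is tolerated and dropped.
    """
    n_taxa, width = aa.chars.shape
    codons = np.empty((n_taxa, width), dtype="<U3")
    for i, taxon in enumerate(aa.taxa):
        try:
            rec = cds[taxon]
        except KeyError:
            raise BacktranslationError(f"no CDS provided for taxon {taxon!r}") from None
        seq = rec.ungapped()
        if len(seq) % 3:
            raise BacktranslationError(f"{taxon}: CDS length {len(seq)} not divisible by 3")
        cods = [seq[k : k + 3] for k in range(0, len(seq), 3)]
        if cods and cods[-1] in _STOPS:
            cods = cods[:-1]
        row = aa.chars[i]
        n_res = int((row != "-").sum())
        if len(cods) != n_res:
            raise BacktranslationError(
                f"{taxon}: CDS encodes {len(cods)} residues but aligned row has {n_res}"
            )
        k = 0
        for j in range(width):
            if row[j] == "-":
                codons[i, j] = "---"
                continue
            codon = cods[k]
            aa_obs = str(Seq(codon).translate())
            if aa_obs != row[j] and row[j] != "X":
                raise BacktranslationError(
                    f"{taxon}: codon {codon} at aa position {k + 1} translates to "
                    f"{aa_obs}, alignment has {row[j]}"
                )
            codons[i, j] = codon
            k += 1
    return CodonAlignment(list(aa.taxa), codons)


def clean_gapped_columns(codon: CodonAlignment) -> CodonAlignment:
    """Drop every codon column containing a gap or any non-ACGT character.

    This is the in-package analogue of running the likelihood with gap and
    ambiguity sites excluded; the engine afterwards only sees sense codons.
    """
    keep = np.ones(codon.width, dtype=bool)
    for j in range(codon.width):
        col = codon.codons[:, j]
        for cell in col:
            if cell == "---" or any(ch not in "ACGT" for ch in cell) or cell in _STOPS:
                keep[j] = False
                break
    out = codon.codons[:, keep]
    if out.shape[1] == 0:
        raise DegenerateAlignmentError("no codon columns survive gap/ambiguity cleaning")
    return CodonAlignment(list(codon.taxa), out)


def filter_and_backtranslate(
    aa: AminoAlignment,
    cds: Mapping[str, SequenceRecord],
    min_block: int = 10,
    max_gap_fraction: float = 0.5,
    long_window: int = 15,
    long_threshold: int = 10,
    short_window: int = 5,
) -> CodonAlignment:
    """Full cascade: block filter + singleton windows (drops unioned on the
    original coordinates), back-translation, then gap-column cleaning.

    Back-translation happens on the unfiltered alignment (the CDS covers the
    full rows); the amino-acid keep-mask then maps 1:1 onto codon columns.
    """
    keep = conserved_block_filter(aa, min_block, max_gap_fraction)
    keep &= singleton_window_filter(aa, long_window, long_threshold, short_window)
    if not keep.any():
        raise DegenerateAlignmentError("no amino-acid columns survive filtering")
    codon = backtranslate(aa, cds)
    codon = CodonAlignment(list(codon.taxa), codon.codons[:, keep])
    return clean_gapped_columns(codon)
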