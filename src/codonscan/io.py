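"""Readers and writers for every on-disk format the scan touches.

FASTA (protein and CDS), 12-column tabular similarity hits, the results
table of the scan, ortholog-group tables and gene x tissue TPM matrices.
Parsing of FASTA itself is delegated to Biopython; this module adds the
validation the pipeline relies on (unique ids, alphabet checks, frame
checks for CDS).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "HitRecord",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_hits_table",
    "write_hits_table",
    "write_results_table",
    "read_results_table",
    "read_tpm_table",
    "write_tpm_table",
    "write_groups_table",
    "read_groups_table",
]

_AA_CHARS = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*-")
_NT_CHARS = set("ACGTUN-")

RESULT_COLUMNS = [
    "gene",
    "branch",
    "lnL_alt",
    "lnL_null",
    "lrt_stat",
    "p_value",
    "q_value",
    "omega2",
    "positive",
    "selected_sites",
]


class FormatError(ValueError):
    """Malformed input file (bad alphabet, duplicate id, wrong columns...)."""


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record. ``species`` and ``gene_id`` are optional metadata;
    ``gene_id`` is parsed from a ``gene=<id>`` token in the description when
    present (assembler headers carry free text after the first whitespace,
    which is otherwise ignored for identity)."""

    record_id: str
    residues: str
    species: str | None = None
    gene_id: str | None = None

    def ungapped(self) -> str:
        return self.residues.replace("-", "")


@dataclass(frozen=True)
class HitRecord:
    """One similarity hit: the four columns the orthology stage consumes."""

    query_id: str
    subject_id: str
    evalue: float
    bitscore: float


_GENE_RE = re.compile(r"\bgene=(\S+)")


def read_fasta(path: str | Path, alphabet: str = "aa", species: str | None = None) -> list[SequenceRecord]:
    """Read a FASTA file into validated records.

    ``alphabet`` is ``"aa"`` or ``"nt"``; sequences are upper-cased and each
    character checked against the alphabet. Duplicate ids and illegal
    characters raise :class:`FormatError` naming the offending record and
    position.
    """
    if alphabet not in ("aa", "nt"):
        raise ValueError(f"alphabet must be 'aa' or 'nt', got {alphabet!r}")
    allowed = _AA_CHARS if alphabet == "aa" else _NT_CHARS
    out: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if rid in seen:
            raise FormatError(f"duplicate record id {rid!r} in {path}")
        seen.add(rid)
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for record {rid!r} in {path}")
        for pos, ch in enumerate(seq, start=1):
            if ch not in allowed:
                raise FormatError(
                    f"illegal {alphabet} character {ch!r} at position {pos} of record {rid!r} in {path}"
                )
        m = _GENE_RE.search(rec.description)
        out.append(SequenceRecord(rid, seq, species=species, gene_id=m.group(1) if m else None))
    return out


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            desc = f" gene={rec.gene_id}" if rec.gene_id else ""
            fh.write(f">{rec.record_id}{desc}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_hits_table(path: str | Path) -> list[HitRecord]:
    """Read a 12-column tabular hits file (the standard ``outfmt 6`` layout).

    Only query, subject, e-value and bitscore are retained; row order is
    preserved. A row with a different column count raises
    :class:`FormatError` with its line number.
    """
    out: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(f"{path}:{lineno}: expected 12 columns, found {len(fields)}")
            try:
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric evalue/bitscore") from exc
            if evalue < 0 or bitscore < 0:
                raise FormatError(f"{path}:{lineno}: negative evalue or bitscore")
            out.append(HitRecord(fields[0], fields[1], evalue, bitscore))
    return out


def write_hits_table(hits: Iterable[HitRecord], path: str | Path) -> None:
    """Write hits in the 12-column dialect (unused columns zero-filled)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [h.query_id, h.subject_id, "0", "0", "0", "0", "0", "0", "0", "0",
                     f"{h.evalue:g}", f"{h.bitscore:g}"]
                )
                + "\n"
            )


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_results_table(rows: Sequence, path: str | Path) -> None:
    """Write scan rows as TSV, sorted by (gene, branch), 6 significant digits.

    ``selected_sites`` renders as comma-separated ``index:posterior`` pairs
    with 1-based codon indices; an empty list renders as an empty field.
    """
    rows = sorted(rows, key=lambda r: (r.gene, str(r.branch)))
    with open(path, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in rows:
            sites = ",".join(f"{i}:{_fmt(p)}" for i, p in r.selected_sites)
            fh.write(
                "\t".join(
                    [
                        r.gene,
                        str(r.branch),
                        _fmt(r.lnL_alt),
                        _fmt(r.lnL_null),
                        _fmt(r.lrt_stat),
                        _fmt(r.p_value),
                        _fmt(r.q_value),
                        _fmt(r.omega2),
                        "1" if r.positive else "0",
                        sites,
                    ]
                )
                + "\n"
            )


def read_results_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "branch": str, "selected_sites": str})
    df["selected_sites"] = df["selected_sites"].fillna("")
    return df


def read_tpm_table(path: str | Path) -> pd.DataFrame:
    """Gene x tissue TPM matrix: genes as the index, tissues as columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise FormatError(f"negative TPM value in {path}")
    return df


def write_tpm_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def write_groups_table(groups: Sequence, species_list: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(["anchor_gene", *species_list]) + "\n")
        for g in sorted(groups, key=lambda g: g.anchor_gene):
            fh.write("\t".join([g.anchor_gene, *(g.members[s] for s in species_list)]) + "\n")


def read_groups_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)
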