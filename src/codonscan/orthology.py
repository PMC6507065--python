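"""One-to-one ortholog grouping from pairwise similarity hits.

The design anchors orthology through a single outgroup proteome: each
outgroup gene is paired with its reciprocal best hit (RBH) in every ingroup
species, and only genes with a partner in *all* species form a group
("full occupancy"). This trades recall for a low paralogy rate, which is the
right trade for selection scans that are sensitive to misorthology.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io import HitRecord, SequenceRecord

__all__ = [
    "OrthologGroup",
    "select_longest_isoform",
    "reciprocal_best_hits",
    "build_ortholog_groups",
]


@dataclass(frozen=True)
class OrthologGroup:
    """An anchor (outgroup) gene plus exactly one member per species."""

    anchor_gene: str
    members: Mapping[str, str]  # species -> record_id (includes the outgroup)


def select_longest_isoform(records: Iterable[SequenceRecord]) -> list[SequenceRecord]:
    """Per gene, keep the isoform encoding the longest (ungapped) protein.

    Ties break to the lexicographically smallest record id so repeated runs
    pick the same representative. Records without a ``gene_id`` are rejected.
    """
    best: dict[str, SequenceRecord] = {}
    for rec in records:
        if rec.gene_id is None:
            raise ValueError(f"record {rec.record_id!r} has no gene_id")
        cur = best.get(rec.gene_id)
        if cur is None:
            best[rec.gene_id] = rec
            continue
        key_new = (-len(rec.ungapped()), rec.record_id)
        key_cur = (-len(cur.ungapped()), cur.record_id)
        if key_new < key_cur:
            best[rec.gene_id] = rec
    return [best[g] for g in sorted(best)]


def _best_hits(hits: Iterable[HitRecord]) -> dict[str, HitRecord]:
    """Best hit per query: minimal e-value, then maximal bitscore, then
    lexicographically smallest subject id."""
    best: dict[str, HitRecord] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None:
            best[h.query_id] = h
            continue
        key_new = (h.evalue, -h.bitscore, h.subject_id)
        key_cur = (cur.evalue, -cur.bitscore, cur.subject_id)
        if key_new < key_cur:
            best[h.query_id] = h
    return best


def reciprocal_best_hits(
    hits_ab: Iterable[HitRecord],
    hits_ba: Iterable[HitRecord],
    evalue_max: float = 1e-10,
) -> set[tuple[str, str]]:
    """Reciprocal best hit pairs (a, b) between proteomes A and B.

    A pair is kept iff b is a's best hit A->B, a is b's best hit B->A, and
    both best hits satisfy ``evalue < evalue_max`` (strict, mirroring the
    search cutoff). Each id appears in at most one pair by construction.
    """
    best_ab = _best_hits(hits_ab)
    best_ba = _best_hits(hits_ba)
    pairs: set[tuple[str, str]] = set()
    for a, hit in best_ab.items():
        if hit.evalue >= evalue_max:
            continue
        back = best_ba.get(hit.subject_id)
        if back is None or back.subject_id != a or back.evalue >= evalue_max:
            continue
        pairs.add((a, hit.subject_id))
    return pairs


def build_ortholog_groups(
    rbh_maps: Mapping[str, set[tuple[str, str]]],
    species_list: Sequence[str],
) -> list[OrthologGroup]:
    """Full-occupancy groups anchored on the outgroup gene.

    ``rbh_maps`` maps each ingroup species name to the RBH pair set between
    the outgroup (first element of each pair) and that species. A group is
    emitted for every outgroup gene with an RBH partner in *every* species in
    ``species_list``.
    """
    if not species_list:
        raise ValueError("species_list must be non-empty")
    partner: dict[str, dict[str, str]] = {}
    for sp in species_list:
        partner[sp] = {a: b for a, b in rbh_maps.get(sp, set())}
    anchors = set.intersection(*(set(partner[sp]) for sp in species_list))
    groups = []
    for anchor in sorted(anchors):
        members = {sp: partner[sp][anchor] for sp in species_list}
        groups.append(OrthologGroup(anchor, members))
    return groups
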