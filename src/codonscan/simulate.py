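"""Synthetic data with known ground truth for the whole pipeline.

The generator evolves codon alignments on a fixed 6-taxon tree (one
outgroup plus five ingroup species, mirroring the shape of a small
vertebrate selection-scan study) under the four-class branch-site mixture:
each site draws a class, the root codon draws from the equilibrium
frequencies, and states propagate along every edge by the class-appropriate
transition matrix. Alignments are simulated gap-free and never contain stop
codons.

:func:`make_scan_fixture` additionally writes every on-disk input the
pipeline consumes — per-species protein/CDS FASTA (with decoy short
isoforms for the outgroup), directional similarity-hit tables with planted
reciprocal-best-hit structure plus strictly worse decoy paralog hits, a
Newick tree with named clades, a gene x tissue TPM table with planted
tissue-specific genes — and a ground-truth manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .codon import (
    BranchSiteParams,
    SENSE_CODONS,
    _build_q_raw,
    _eigendecompose,
    mixture_scale,
)
from .filters import CodonAlignment
from .io import HitRecord, SequenceRecord, write_fasta, write_hits_table, write_tpm_table
from .trees import LabeledTree, read_newick_labeled
from .comparative import TISSUES

__all__ = [
    "SimTruth",
    "fixture_tree",
    "FIXTURE_NEWICK",
    "simulate_codon_alignment",
    "make_scan_fixture",
]

#: Fixed 6-taxon study tree: outgroup (Xenopus) plus five ingroup species,
#: with named internal clades used to address foreground branches. Branch
#: lengths are expected substitutions per codon, desk-scale (0.05-0.5).
FIXTURE_NEWICK = (
    "(Xenopus:0.5,(Rhinatrema:0.3,((Caecilia:0.2,Typhlonectes:0.2)CaeTyp:0.1,"
    "(M_unicolor:0.15,M_dermatophaga:0.15)Microcaecilia:0.1)Teresomata:0.15)"
    "Gymnophiona:0.2);"
)

OUTGROUP = "Xenopus"
INGROUP = ("Rhinatrema", "Caecilia", "Typhlonectes", "M_unicolor", "M_dermatophaga")

CLASS_NAMES = ("0", "1", "2a", "2b")


def fixture_tree(foreground: str | None = "Gymnophiona") -> LabeledTree:
    """The default study tree, optionally with a foreground branch marked."""
    tree = read_newick_labeled(FIXTURE_NEWICK)
    return tree.with_foreground(foreground) if foreground else tree


@dataclass
class SimTruth:
    """Hidden state of one simulated gene."""

    seed: int
    params: BranchSiteParams
    tree_newick: str
    site_classes: np.ndarray  # per-site labels from CLASS_NAMES
    gene_status: str  # "null" or "selected"


def _sample_states(P: np.ndarray, parents: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one child state per site from rows of P selected by parent."""
    cum = np.cumsum(P[parents], axis=1)
    u = rng.random(parents.shape[0])
    return np.minimum((u[:, None] > cum).sum(axis=1), P.shape[1] - 1)


def simulate_codon_alignment(
    tree: LabeledTree,
    params: BranchSiteParams,
    n_sites: int,
    seed: int,
    pi: np.ndarray | None = None,
) -> tuple[CodonAlignment, SimTruth]:
    """Evolve a gap-free codon alignment under the branch-site mixture.

    Per site: a class is drawn from (p0, p1, p2a, p2b); the root codon is
    drawn from ``pi`` (uniform over the 61 sense codons by default); states
    evolve along each edge under that edge's class-appropriate omega.
    Deterministic given ``seed``.
    """
    if tree.foreground is None:
        raise ValueError("tree must carry one foreground branch")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    original = tree
    tree = tree.unrooted_view()  # same branch structure the likelihood sees
    rng = np.random.default_rng(seed)
    pi = np.full(61, 1.0 / 61) if pi is None else np.asarray(pi, dtype=float)

    weights = params.class_weights()
    site_class = rng.choice(4, size=n_sites, p=weights)

    # transition matrix per (edge, class); all classes share one rate scale
    # (the background-mixture mean rate), so omega2 > 1 sites genuinely
    # accumulate more substitutions on the foreground branch
    rho = mixture_scale(params.kappa, params.omega0, weights, pi)
    omegas = (params.omega0, 1.0, params.omega2)
    eigs = [_eigendecompose(_build_q_raw(params.kappa, om, pi)[0], pi) for om in omegas]
    # class -> (background omega index, foreground omega index)
    class_omega = ((0, 0), (1, 1), (0, 2), (1, 2))

    states: dict[int, np.ndarray] = {}
    root = tree.root
    states[root.index] = rng.choice(61, size=n_sites, p=pi / pi.sum())
    for node in reversed(tree.postorder()):
        if node.parent is None:
            continue
        t = (node.length if node.length is not None else 0.1) / rho
        is_fg = tree.foreground == node.index
        child = np.empty(n_sites, dtype=np.int64)
        for c, (bg, fg) in enumerate(class_omega):
            mask = site_class == c
            if not mask.any():
                continue
            w, A, B = eigs[fg if is_fg else bg]
            P = np.clip((A * np.exp(w * t)[None, :]) @ B, 0.0, 1.0)
            P /= P.sum(axis=1, keepdims=True)
            child[mask] = _sample_states(P, states[node.parent][mask], rng)
        states[node.index] = child

    taxa = tree.leaf_labels()
    rows = np.empty((len(taxa), n_sites), dtype="<U3")
    codon_arr = np.array(SENSE_CODONS)
    for i, node in enumerate(n for n in tree.postorder() if n.is_leaf):
        rows[i] = codon_arr[states[node.index]]
    aln = CodonAlignment(taxa, rows)
    truth = SimTruth(
        seed=seed,
        params=params,
        tree_newick=original.newick(),
        site_classes=np.array(CLASS_NAMES)[site_class],
        gene_status="selected" if params.omega2 > 1 else "null",
    )
    return aln, truth


# ---------------------------------------------------------------------------
# full on-disk fixture
# ---------------------------------------------------------------------------

#: Generator defaults: the study conditions the synthetic fixtures emulate.
NULL_PARAMS = BranchSiteParams(kappa=2.0, p0=0.5, p1=0.3, omega0=0.2, omega2=1.0)
SELECTED_PARAMS = BranchSiteParams(kappa=2.0, p0=0.5, p1=0.2, omega0=0.2, omega2=8.0)


def _translate_row(codons: np.ndarray) -> str:
    return "".join(str(Seq("".join(codons)).translate()))


def _plant_error_tract(
    aln: CodonAlignment, taxon: str, start: int, rng: np.random.Generator, length: int = 15
) -> None:
    """Overwrite a 15-codon window in one taxon with random sense codons —
    the single-species junk tract the singleton filters are built to catch."""
    i = aln.taxa.index(taxon)
    idx = rng.integers(0, 61, size=length)
    aln.codons[i, start : start + length] = np.array(SENSE_CODONS)[idx]


def _gene_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(k,)).generate_state(1)[0] % (2**31))


def make_scan_fixture(
    outdir: str | Path,
    n_genes: int = 20,
    prop_selected: float = 0.25,
    seed: int = 0,
    n_sites: int = 300,
    foreground: str = "Gymnophiona",
    error_tract_every: int = 5,
) -> dict:
    """Write a complete synthetic input layout and return its manifest.

    ``round(n_genes * prop_selected)`` genes are simulated with positive
    selection (omega2 = 8, ~30% foreground-selected sites) on the
    ``foreground`` branch, the rest under the null. Every ``error_tract_every``-th
    null gene receives a species-specific 15-codon error tract. Decoy
    paralog hits always have e-values at least 10x the true ortholog's, so
    reciprocal-best-hit orthology must recover the planted groups exactly.
    """
    if not 0 <= prop_selected <= 1:
        raise ValueError("prop_selected must be in [0, 1]")
    outdir = Path(outdir)
    (outdir / "alignments").mkdir(parents=True, exist_ok=True)
    (outdir / "hits").mkdir(exist_ok=True)
    (outdir / "sequences").mkdir(exist_ok=True)

    n_selected = round(n_genes * prop_selected)
    tree = fixture_tree(foreground)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(10**6,)))

    genes = [f"g{k:04d}" for k in range(n_genes)]
    status = ["selected"] * n_selected + ["null"] * (n_genes - n_selected)
    manifest: dict = {
        "seed": seed,
        "outgroup": OUTGROUP,
        "species": list(INGROUP),
        "tree_newick": fixture_tree(None).newick(),
        "foreground": foreground,
        "n_sites": n_sites,
        "genes": {},
    }

    species_order = fixture_tree(None).leaf_labels()
    cds_records: dict[str, list[SequenceRecord]] = {sp: [] for sp in species_order}
    aa_records: dict[str, list[SequenceRecord]] = {sp: [] for sp in species_order}
    null_counter = 0
    for k, (gene, st) in enumerate(zip(genes, status)):
        params = SELECTED_PARAMS if st == "selected" else NULL_PARAMS
        gseed = _gene_seed(seed, k)
        aln, truth = simulate_codon_alignment(tree, params, n_sites, gseed)
        tract = None
        if st == "null":
            null_counter += 1
            if error_tract_every and null_counter % error_tract_every == 0:
                sp = INGROUP[null_counter % len(INGROUP)]
                start = int(rng.integers(0, n_sites - 15))
                _plant_error_tract(aln, sp, start, rng)
                tract = {"species": sp, "start_codon": start + 1, "length": 15}
        # per-species sequences + per-group amino-acid alignment
        grp_aa = []
        for i, sp in enumerate(aln.taxa):
            rid = f"{sp}_{gene}"
            cds = "".join(aln.codons[i])
            prot = _translate_row(aln.codons[i])
            cds_records[sp].append(SequenceRecord(rid, cds, species=sp, gene_id=gene))
            aa_records[sp].append(SequenceRecord(rid, prot, species=sp, gene_id=gene))
            grp_aa.append(SequenceRecord(sp, prot, species=sp, gene_id=gene))
        write_fasta(grp_aa, outdir / "alignments" / f"{gene}.aa.fasta")
        manifest["genes"][gene] = {
            "status": st,
            "seed": gseed,
            "params": {
                "kappa": params.kappa,
                "p0": params.p0,
                "p1": params.p1,
                "omega0": params.omega0,
                "omega2": params.omega2,
            },
            "site_classes": truth.site_classes.tolist(),
            "error_tract": tract,
        }

    # outgroup decoy short isoforms: same gene, 60% length, distinct id
    decoy_isoforms = []
    for rec in cds_records[OUTGROUP][:: max(1, n_genes // 4)]:
        cut = (len(rec.residues) // 3 * 3) * 3 // 5
        cut -= cut % 3
        decoy_isoforms.append(
            SequenceRecord(rec.record_id + "_iso2", rec.residues[:cut],
                           species=OUTGROUP, gene_id=rec.gene_id)
        )
    for sp in species_order:
        recs = list(cds_records[sp])
        aas = list(aa_records[sp])
        if sp == OUTGROUP:
            recs += decoy_isoforms
            aas += [
                SequenceRecord(r.record_id, _translate_row(np.array([r.residues[i:i + 3] for i in range(0, len(r.residues), 3)])),
                               species=sp, gene_id=r.gene_id)
                for r in decoy_isoforms
            ]
        write_fasta(recs, outdir / "sequences" / f"{sp}.cds.fasta")
        write_fasta(aas, outdir / "sequences" / f"{sp}.prot.fasta")

    # hit tables with planted RBH structure + decoy paralog hits
    for sp in INGROUP:
        fwd, rev = [], []
        for k, gene in enumerate(genes):
            a = f"{OUTGROUP}_{gene}"
            b = f"{sp}_{gene}"
            true_e = 1e-50
            fwd.append(HitRecord(a, b, true_e, 500.0))
            rev.append(HitRecord(b, a, true_e, 500.0))
            decoy_gene = genes[(k + 1) % n_genes]
            fwd.append(HitRecord(a, f"{sp}_{decoy_gene}", true_e * 1e10, 80.0))
            rev.append(HitRecord(b, f"{OUTGROUP}_{decoy_gene}", true_e * 1e10, 80.0))
        write_hits_table(fwd, outdir / "hits" / f"{OUTGROUP}_vs_{sp}.tsv")
        write_hits_table(rev, outdir / "hits" / f"{sp}_vs_{OUTGROUP}.tsv")

    # tree file (no mark; the pipeline marks branches programmatically)
    (outdir / "tree.nwk").write_text(manifest["tree_newick"] + "\n")

    # TPM table: broad expression, with the first gene planted skin-specific
    tpm = pd.DataFrame(
        rng.gamma(2.0, 50.0, size=(n_genes, len(TISSUES))),
        index=genes,
        columns=list(TISSUES),
    )
    specific_gene = genes[0]
    total = tpm.loc[specific_gene].sum()
    tpm.loc[specific_gene] = total * 0.04 / (len(TISSUES) - 1)
    tpm.loc[specific_gene, "skin"] = total * 0.96
    write_tpm_table(tpm.round(3), outdir / "tpm.tsv")
    manifest["tissue_specific"] = {specific_gene: "skin"}

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
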