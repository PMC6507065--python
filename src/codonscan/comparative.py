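"""Downstream comparative arithmetic on scan results.

Sister-branch comparisons (exact two-tailed binomial tests of equal
probability), per-branch summaries of positive-selection calls, and
tissue-expression presence/specificity calls from a gene x tissue TPM
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy.stats import binom

__all__ = [
    "BranchSummary",
    "TISSUES",
    "binom_two_tailed",
    "branch_summary",
    "expression_calls",
]

TISSUES = (
    "foregut",
    "heart",
    "kidney",
    "liver",
    "lung",
    "muscle",
    "skin",
    "spleen",
    "testis",
)


@dataclass(frozen=True)
class BranchSummary:
    branch: str
    n_positive: int
    percent_of_total: float  # of the pooled positive-gene total


def binom_two_tailed(k1: int, k2: int) -> float:
    """Exact two-tailed binomial test of k1 vs k2 successes at p = 0.5.

    The p-value doubles the tail of the larger count, capped at 1:
    p = min(1, 2 * P(X >= max(k1, k2))) with X ~ Binomial(k1 + k2, 0.5).
    """
    if k1 < 0 or k2 < 0:
        raise ValueError("counts must be non-negative")
    n = k1 + k2
    if n == 0:
        raise ValueError("at least one count must be positive")
    k = max(k1, k2)
    p = 2.0 * float(binom.sf(k - 1, n, 0.5))
    return min(1.0, p)


def branch_summary(rows: Sequence) -> tuple[list[BranchSummary], dict]:
    """Per-branch positive counts plus pooled totals.

    Returns (summaries, totals) where totals carries the pooled unique
    positive-gene count, the number of genes tested, and the scan-wide
    percentage 100 * pooled / tested. Branch percentages are computed
    against the pooled positive total (a gene positive on two branches
    counts once in the pool), rounded to two decimals for display.
    """
    by_branch: dict[str, set[str]] = {}
    pooled: set[str] = set()
    genes: set[str] = set()
    for r in rows:
        genes.add(r.gene)
        by_branch.setdefault(str(r.branch), set())
        if r.positive:
            by_branch[str(r.branch)].add(r.gene)
            pooled.add(r.gene)
    n_pool = len(pooled)
    summaries = [
        BranchSummary(
            b,
            len(g),
            round(100.0 * len(g) / n_pool, 2) if n_pool else 0.0,
        )
        for b, g in sorted(by_branch.items())
    ]
    totals = {
        "n_positive_pooled": n_pool,
        "n_genes_tested": len(genes),
        "scan_wide_percent": round(100.0 * n_pool / len(genes), 2) if genes else 0.0,
    }
    return summaries, totals


def expression_calls(
    tpm: pd.DataFrame,
    presence: float = 0.05,
    specificity: float = 0.95,
) -> pd.DataFrame:
    """Tissue presence and specificity from a gene x tissue TPM matrix.

    A tissue is "present" for a gene when it holds more than ``presence``
    (default 5%) of the gene's total TPM; the gene is "specific" to a
    tissue holding more than ``specificity`` (default 95%). Genes whose row
    sums to zero are excluded (reported in the ``excluded`` attribute of
    the returned frame's ``attrs``).
    """
    if (tpm.values < 0).any():
        raise ValueError("TPM values must be non-negative")
    totals = tpm.sum(axis=1)
    excluded = list(tpm.index[totals == 0])
    ok = tpm.loc[totals > 0]
    shares = ok.div(ok.sum(axis=1), axis=0)
    records = []
    for gene, row in shares.iterrows():
        present = [t for t in ok.columns if row[t] > presence]
        spec = [t for t in ok.columns if row[t] > specificity]
        records.append(
            {
                "gene": gene,
                "tissues_present": ",".join(present),
                "specific_tissue": spec[0] if spec else "",
            }
        )
    out = pd.DataFrame.from_records(records, columns=["gene", "tissues_present", "specific_tissue"])
    out.attrs["excluded"] = excluded
    return out
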