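"""Codon substitution model and branch-site mixture likelihood.

The substitution process is the classic codon model in which the
instantaneous rate from codon i to codon j is non-zero only for single
nucleotide changes and is proportional to the target codon's equilibrium
frequency, multiplied by kappa for transitions and by omega (dN/dS) for
amino-acid-changing substitutions. Equilibrium codon frequencies come from
position-specific nucleotide frequencies (the F3x4 construction).

The branch-site mixture assigns each codon site to one of four classes:

====== ===================== =====================
class  foreground branch      background branches
====== ===================== =====================
0      omega0 (< 1)           omega0
1      1                      1
2a     omega2                 omega0
2b     omega2                 1
====== ===================== =====================

with weights (p0, p1, p2a, p2b) where p2a = (1-p0-p1) p0/(p0+p1) and
p2b = (1-p0-p1) p1/(p0+p1). Site likelihoods are computed by Felsenstein
pruning over the 61 sense codons with per-node log-scaling; site patterns
are compressed internally, which cannot change the value.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from Bio.Data import CodonTable

from .filters import CodonAlignment
from .trees import LabeledTree

__all__ = [
    "NUCS",
    "SENSE_CODONS",
    "STOP_CODONS",
    "CODON_INDEX",
    "BranchSiteParams",
    "RateMatrix",
    "f3x4_frequencies",
    "gy94_rate_matrix",
    "transition_matrix",
    "BranchSiteLikelihood",
    "mixture_loglik",
]

NUCS = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")

_TABLE = CodonTable.unambiguous_dna_by_id[1]
SENSE_CODONS = tuple(
    c for c in ("".join(t) for t in itertools.product(NUCS, repeat=3)) if c not in STOP_CODONS
)
assert len(SENSE_CODONS) == 61
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
AMINO_ACIDS = tuple(_TABLE.forward_table[c] for c in SENSE_CODONS)

# codon -> nucleotide index at each of the 3 positions, shape (61, 3)
CODON_NUC = np.array([[NUCS.index(ch) for ch in c] for c in SENSE_CODONS])


def _pair_masks() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = len(SENSE_CODONS)
    single = np.zeros((n, n), dtype=bool)
    transition = np.zeros((n, n), dtype=bool)
    nonsyn = np.zeros((n, n), dtype=bool)
    ts_pairs = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            transition[i, j] = diffs[0] in ts_pairs
            nonsyn[i, j] = AMINO_ACIDS[i] != AMINO_ACIDS[j]
    return single, transition, nonsyn

_SINGLE, _TS, _NONSYN = _pair_masks()


@dataclass(frozen=True)
class BranchSiteParams:
    """Parameters of the four-class branch-site mixture.

    ``omega2`` is the foreground dN/dS of the selected classes: >= 1 under
    the alternative model, exactly 1 under the null. Class 1's omega is
    fixed at 1 by the model.
    """

    kappa: float
    p0: float
    p1: float
    omega0: float
    omega2: float

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if not (self.p0 > 0 and self.p1 > 0 and self.p0 + self.p1 <= 1 + 1e-12):
            raise ValueError("need p0, p1 > 0 and p0 + p1 <= 1")
        if not 0 < self.omega0 < 1:
            raise ValueError("omega0 must be in (0, 1)")
        if self.omega2 < 1:
            raise ValueError("omega2 must be >= 1")

    @property
    def p2a(self) -> float:
        rest = max(0.0, 1.0 - self.p0 - self.p1)
        return rest * self.p0 / (self.p0 + self.p1)

    @property
    def p2b(self) -> float:
        rest = max(0.0, 1.0 - self.p0 - self.p1)
        return rest * self.p1 / (self.p0 + self.p1)

    def class_weights(self) -> np.ndarray:
        w = np.array([self.p0, self.p1, self.p2a, self.p2b])
        assert abs(w.sum() - 1.0) < 1e-12
        return w


@dataclass(frozen=True)
class RateMatrix:
    """A scaled codon rate matrix Q with its stationary distribution pi.

    Rows sum to zero, only single-nucleotide changes between sense codons
    have non-zero rates, detailed balance holds, and the matrix is scaled so
    the expected rate at stationarity, sum_i pi_i * (-q_ii), equals 1 — i.e.
    branch lengths are expected substitutions per codon.
    """

    Q: np.ndarray
    pi: np.ndarray


def f3x4_frequencies(aln: CodonAlignment, pseudocount: float = 0.5) -> np.ndarray:
    """Equilibrium codon frequencies from positional nucleotide frequencies.

    Counts nucleotides separately at the three codon positions (adding
    ``pseudocount`` to each of the 4 nucleotides at each position, which
    keeps degenerate alignments well-behaved), forms the product frequency
    for each sense codon, excises stops and renormalises.
    """
    counts = np.full((3, 4), pseudocount)
    for row in aln.codons:
        for cell in row:
            if cell == "---":
                continue
            for p, ch in enumerate(cell):
                if ch in NUCS:
                    counts[p, NUCS.index(ch)] += 1
    posfreq = counts / counts.sum(axis=1, keepdims=True)
    pi = posfreq[0, CODON_NUC[:, 0]] * posfreq[1, CODON_NUC[:, 1]] * posfreq[2, CODON_NUC[:, 2]]
    return pi / pi.sum()


def _build_q_raw(kappa: float, omega: float, pi: np.ndarray) -> tuple[np.ndarray, float]:
    """Unscaled rate matrix and its mean rate sum_i pi_i * (-q_ii)."""
    rates = np.where(_SINGLE, np.where(_TS, kappa, 1.0), 0.0)
    rates = rates * np.where(_NONSYN, omega, 1.0)
    Q = rates * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    return Q, mu


def _build_q(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    Q, mu = _build_q_raw(kappa, omega, pi)
    if mu <= 0:
        raise ValueError("degenerate rate matrix (zero mean rate)")
    return Q / mu


def mixture_scale(kappa: float, omega0: float, weights: np.ndarray, pi: np.ndarray) -> float:
    """Common rate scale of the branch-site mixture.

    All four class matrices are divided by one factor — the mean rate under
    the background mixture, rho = (p0 + p2a) mu(omega0) + (p1 + p2b) mu(1) —
    so a branch length is the expected number of substitutions per codon on
    a background branch, and sites in the selected classes genuinely evolve
    faster on the foreground branch when omega2 > 1. Scaling each class to
    unit rate separately would silently discard that rate excess, which is
    most of the test's signal.
    """
    _, mu0 = _build_q_raw(kappa, omega0, pi)
    _, mu1 = _build_q_raw(kappa, 1.0, pi)
    rho = (weights[0] + weights[2]) * mu0 + (weights[1] + weights[3]) * mu1
    if rho <= 0:
        raise ValueError("degenerate mixture scale")
    return float(rho)


def gy94_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> RateMatrix:
    """Scaled codon rate matrix for given kappa, omega and frequencies."""
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (61,) or (pi < 0).any() or abs(pi.sum() - 1) > 1e-8:
        raise ValueError("pi must be a length-61 distribution")
    if kappa <= 0 or omega < 0:
        raise ValueError("need kappa > 0 and omega >= 0")
    return RateMatrix(_build_q(kappa, omega, pi), pi)


def _eigendecompose(Q: np.ndarray, pi: np.ndarray):
    """Eigendecomposition via the pi-symmetrised matrix.

    Returns (w, A, B) with P(t) = A @ diag(exp(w t)) @ B; exact for the
    reversible Q used here and numerically stable.
    """
    sq = np.sqrt(pi)
    S = Q * (sq[:, None] / sq[None, :])
    S = 0.5 * (S + S.T)
    w, V = np.linalg.eigh(S)
    A = V / sq[:, None]
    B = V.T * sq[None, :]
    return w, A, B


def transition_matrix(rm: RateMatrix, t: float) -> np.ndarray:
    """P(t) = exp(Qt); rows sum to 1, entries clipped into [0, 1]."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    w, A, B = _eigendecompose(rm.Q, rm.pi)
    P = (A * np.exp(w * t)[None, :]) @ B
    return np.clip(P, 0.0, 1.0)


def _batch_transition(w: np.ndarray, A: np.ndarray, B: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """All P(t) for a vector of branch lengths at once: shape (E, 61, 61)."""
    ew = np.exp(np.outer(ts, w))  # (E, 61)
    P = (A[None, :, :] * ew[:, None, :]) @ B
    np.clip(P, 0.0, 1.0, out=P)
    return P


# class -> which omega (0: omega0, 1: one, 2: omega2) applies on
# (background, foreground) edges
_CLASS_OMEGA = ((0, 0), (1, 1), (0, 2), (1, 2))


class BranchSiteLikelihood:
    """Pruning likelihood of a gap-cleaned codon alignment on a marked tree.

    The engine precomputes site-pattern compression and the tree layout so
    repeated evaluations during optimisation only pay for rate-matrix
    eigendecompositions and the pruning matmuls. Branch lengths are passed
    per call (edge order = post-order over non-root nodes), which is what
    the model fits need; convenience wrappers take them from the tree.
    """

    def __init__(self, aln: CodonAlignment, tree: LabeledTree, pi: np.ndarray | None = None):
        tree = tree.unrooted_view()  # binary-root edges merge into one branch
        leaf_set = set(tree.leaf_labels())
        if not set(aln.taxa) <= leaf_set:
            raise ValueError(f"alignment taxa {set(aln.taxa) - leaf_set} not in tree")
        if set(aln.taxa) != leaf_set:
            raise ValueError("tree has leaves absent from the alignment; prune it first")
        self.tree = tree
        self.aln = aln
        self.pi = f3x4_frequencies(aln) if pi is None else np.asarray(pi, dtype=float)

        idx = np.empty((aln.n_taxa, aln.width), dtype=np.int64)
        for i in range(aln.n_taxa):
            for j in range(aln.width):
                cell = aln.codons[i, j]
                if cell not in CODON_INDEX:
                    raise ValueError(
                        f"non-sense codon {cell!r} at row {aln.taxa[i]}, column {j + 1}; "
                        "clean the alignment first"
                    )
                idx[i, j] = CODON_INDEX[cell]
        patterns, inverse, counts = np.unique(
            idx, axis=1, return_inverse=True, return_counts=True
        )
        self._patterns = patterns          # (n_taxa, n_pat)
        self._pattern_of_site = inverse    # (n_sites,)
        self._counts = counts.astype(float)
        self.n_sites = aln.width

        # tree layout: edges indexed by child node, in post-order
        nodes = tree.postorder()
        self._edge_index: dict[int, int] = {}
        self.edge_lengths: list[float | None] = []
        self.edge_nodes: list[int] = []
        for n in nodes:
            if n.parent is not None:
                self._edge_index[n.index] = len(self.edge_nodes)
                self.edge_nodes.append(n.index)
                self.edge_lengths.append(n.length)
        self.n_edges = len(self.edge_nodes)
        self.foreground_edge = (
            self._edge_index[tree.foreground] if tree.foreground is not None else None
        )
        row_of = {t: i for i, t in enumerate(aln.taxa)}
        self._leaf_pat = {
            n.index: self._patterns[row_of[n.label]] for n in nodes if n.is_leaf
        }
        self._internal = [n for n in nodes if not n.is_leaf]
        self._root = nodes[-1].index

    # ------------------------------------------------------------------
    def _prune_batch(self, P_stack: np.ndarray) -> np.ndarray:
        """Per-pattern log conditional likelihoods for a batch of classes.

        ``P_stack``: (C, n_edges, 61, 61) transition matrices; the batch
        axis lets all site classes share one set of BLAS calls per edge.
        """
        npat = self._patterns.shape[1]
        C = P_stack.shape[0]
        partial: dict[int, np.ndarray] = {}
        logscale: dict[int, np.ndarray] = {}
        for node in self._internal:
            M = np.ones((C, 61, npat))
            ls = np.zeros((C, npat))
            for child in node.children:
                P = P_stack[:, self._edge_index[child]]
                if child in self._leaf_pat:
                    M *= P[:, :, self._leaf_pat[child]]
                else:
                    M *= P @ partial.pop(child)
                    ls += logscale.pop(child)
            mx = np.maximum(M.max(axis=1), 1e-300)
            M /= mx[:, None, :]
            partial[node.index] = M
            logscale[node.index] = ls + np.log(mx)
        lik = np.einsum("i,cip->cp", self.pi, partial[self._root])
        if (lik <= 0).any():
            raise FloatingPointError("site likelihood underflow despite scaling")
        return np.log(lik) + logscale[self._root]

    def _prune_class(self, P_edge: np.ndarray) -> np.ndarray:
        """Per-pattern log conditional likelihood for a single class."""
        return self._prune_batch(P_edge[None])[0]

    def class_pattern_logliks(
        self,
        kappa: float,
        omega0: float,
        omega2: float,
        lengths: np.ndarray,
        weights: np.ndarray | None = None,
        scale: float | None = None,
    ) -> np.ndarray:
        """(4, n_patterns) log L_c per site class at the given parameters.

        The four class matrices share one rate scale (see
        :func:`mixture_scale`); it is derived from ``weights`` unless a
        precomputed ``scale`` is supplied (as when site posteriors sweep a
        parameter grid at fixed branch lengths).
        """
        lengths = np.asarray(lengths, dtype=float)
        if lengths.shape != (self.n_edges,):
            raise ValueError(f"expected {self.n_edges} branch lengths")
        if (lengths < 0).any():
            raise ValueError("branch lengths must be >= 0")
        if self.foreground_edge is None:
            raise ValueError("tree has no foreground branch marked")
        if scale is None:
            if weights is None:
                raise ValueError("need class weights or an explicit scale")
            scale = mixture_scale(kappa, omega0, weights, self.pi)
        t_eff = lengths / scale
        omegas = (omega0, 1.0, omega2)
        eigs = {}
        for k, om in enumerate(omegas):
            dup = next((j for j in eigs if omegas[j] == om), None)
            if dup is not None:
                eigs[k] = eigs[dup]
                continue
            Q, _ = _build_q_raw(kappa, om, self.pi)
            eigs[k] = _eigendecompose(Q, self.pi)
        Psets = {k: _batch_transition(*eigs[k], t_eff) for k in eigs}
        fg = self.foreground_edge
        # deduplicate classes with identical per-edge omega assignments
        # (e.g. classes 1 and 2b coincide under the null where omega2 = 1)
        keys = [(bg, fg_om) if omegas[bg] != omegas[fg_om] else (bg, bg)
                for bg, fg_om in _CLASS_OMEGA]
        uniq = list(dict.fromkeys(keys))
        stack = np.empty((len(uniq), self.n_edges, 61, 61))
        for u, (bg, fg_om) in enumerate(uniq):
            stack[u] = Psets[bg]
            if fg_om != bg:
                stack[u, fg] = Psets[fg_om][fg]
        res = self._prune_batch(stack)
        return res[[uniq.index(k) for k in keys]]

    def loglik_and_grad(
        self,
        kappa: float,
        omega0: float,
        omega2: float,
        lengths: np.ndarray,
        weights: np.ndarray,
    ) -> tuple[float, np.ndarray, np.ndarray, float]:
        """Mixture log-likelihood with analytic derivatives.

        Returns ``(ll, d_dteff, d_dw, rho)`` where ``d_dteff[e]`` is the
        derivative with respect to the *scaled* length of edge e (raw
        length / rho), ``d_dw[c]`` the derivative with respect to class
        weight c at fixed rho, and ``rho`` the common mixture rate scale.
        Derivatives follow the classic down/up-message construction: for
        edge e, dL/dt = U_e . (Q P_e D_e) while L = U_e . (P_e D_e); both
        sides share the same per-node normalisations, so the ratio needs no
        scale bookkeeping. Only kappa and the omegas are left to the
        caller's finite differences.
        """
        lengths = np.asarray(lengths, dtype=float)
        rho = mixture_scale(kappa, omega0, weights, self.pi)
        t_eff = lengths / rho
        omegas = (omega0, 1.0, omega2)
        eigs, Qs = {}, {}
        for k, om in enumerate(omegas):
            dup = next((j for j in eigs if omegas[j] == om), None)
            if dup is not None:
                eigs[k], Qs[k] = eigs[dup], Qs[dup]
                continue
            Q, _ = _build_q_raw(kappa, om, self.pi)
            Qs[k] = Q
            eigs[k] = _eigendecompose(Q, self.pi)
        Psets = {k: _batch_transition(*eigs[k], t_eff) for k in eigs}
        fg = self.foreground_edge
        E = self.n_edges
        npat = self._patterns.shape[1]

        # per-class per-edge transition and rate matrices (C=4, no dedup)
        P_stack = np.empty((4, E, 61, 61))
        Q_stack = np.empty((4, E, 61, 61))
        for c, (bg, fg_om) in enumerate(_CLASS_OMEGA):
            P_stack[c] = Psets[bg]
            Q_stack[c] = Qs[bg]
            if fg_om != bg:
                P_stack[c, fg] = Psets[fg_om][fg]
                Q_stack[c, fg] = Qs[fg_om]

        # down pass, storing normalised partials and per-edge messages T
        D: dict[int, np.ndarray] = {}
        T: dict[int, np.ndarray] = {}  # keyed by child node index
        logscale: dict[int, np.ndarray] = {}
        for node in self._internal:
            M = np.ones((4, 61, npat))
            ls = np.zeros((4, npat))
            for child in node.children:
                P = P_stack[:, self._edge_index[child]]
                if child in self._leaf_pat:
                    Tc = P[:, :, self._leaf_pat[child]]
                else:
                    Tc = P @ D[child]
                    ls += logscale[child]
                T[child] = Tc
                M = M * Tc
            mx = np.maximum(M.max(axis=1), 1e-300)
            M /= mx[:, None, :]
            D[node.index] = M
            logscale[node.index] = ls + np.log(mx)
        lik = np.einsum("i,cip->cp", self.pi, D[self._root])
        if (lik <= 0).any():
            raise FloatingPointError("site likelihood underflow despite scaling")
        cls_ll = np.log(lik) + logscale[self._root]  # (4, npat)

        # mixture value and per-class pattern posteriors
        logw = np.log(np.maximum(weights, 1e-300))[:, None]
        a = cls_ll + logw
        mx = a.max(axis=0)
        site_ll = mx + np.log(np.exp(a - mx).sum(axis=0))
        ll = float(site_ll @ self._counts)
        r = np.exp(a - site_ll[None, :])  # (4, npat), sums to 1 over classes

        # up pass: gradient of each class log-likelihood per edge
        g = np.zeros((4, E, npat))
        U: dict[int, np.ndarray] = {self._root: np.broadcast_to(
            self.pi[None, :, None], (4, 61, npat)).copy()}
        for node in reversed(self._internal):
            Up = U.pop(node.index)
            kids = node.children
            Ts = [T[c] for c in kids]
            for i, child in enumerate(kids):
                Ue = Up
                for j, Tj in enumerate(Ts):
                    if j != i:
                        Ue = Ue * Tj
                e = self._edge_index[child]
                QT = Q_stack[:, e] @ Ts[i]
                den = np.einsum("cip,cip->cp", Ue, Ts[i])
                num = np.einsum("cip,cip->cp", Ue, QT)
                g[:, e] = num / np.maximum(den, 1e-300)
                if child not in self._leaf_pat:
                    Un = np.swapaxes(P_stack[:, e], 1, 2) @ Ue
                    un_mx = np.maximum(Un.max(axis=1), 1e-300)
                    U[child] = Un / un_mx[:, None, :]

        # assemble: d lnL / d t_eff_e = sum_pat counts * sum_c r_c g_{c,e}
        d_dteff = np.einsum("cp,cep,p->e", r, g, self._counts)
        d_dw = (np.exp(cls_ll - site_ll[None, :]) @ self._counts)
        return ll, d_dteff, d_dw, rho

    def class_site_logliks(self, params: BranchSiteParams, lengths: np.ndarray) -> np.ndarray:
        """(4, n_sites) log L_c expanded back to original site order."""
        pat = self.class_pattern_logliks(
            params.kappa, params.omega0, params.omega2, lengths, params.class_weights()
        )
        return pat[:, self._pattern_of_site]

    def loglik(self, params: BranchSiteParams, lengths: np.ndarray) -> float:
        """Mixture log-likelihood: sum_sites log sum_c w_c L_c(site)."""
        w = params.class_weights()
        cls = self.class_pattern_logliks(
            params.kappa, params.omega0, params.omega2, lengths, w
        )
        return self.mixture_from_class(cls, w)

    def mixture_from_class(self, cls_pattern_ll: np.ndarray, weights: np.ndarray) -> float:
        a = cls_pattern_ll + np.log(np.maximum(weights, 1e-300))[:, None]
        mx = a.max(axis=0)
        site_ll = mx + np.log(np.exp(a - mx).sum(axis=0))
        return float(site_ll @ self._counts)

    def tree_lengths(self) -> np.ndarray:
        """Branch lengths read off the tree (error when any is missing)."""
        if any(v is None for v in self.edge_lengths):
            raise ValueError("tree is missing branch lengths")
        return np.array(self.edge_lengths, dtype=float)


def mixture_loglik(aln: CodonAlignment, tree: LabeledTree, params: BranchSiteParams) -> float:
    """Branch-site mixture log-likelihood with branch lengths from the tree."""
    engine = BranchSiteLikelihood(aln, tree)
    return engine.loglik(params, engine.tree_lengths())


def dump_rate_matrix(rm: RateMatrix, path) -> None:
    """Debug dump: codon frequencies and the full Q matrix as TSV."""
    with open(path, "w") as fh:
        fh.write("codon\tpi\t" + "\t".join(SENSE_CODONS) + "\n")
        for i, codon in enumerate(SENSE_CODONS):
            row = "\t".join(f"{x:.8g}" for x in rm.Q[i])
            fh.write(f"{codon}\t{rm.pi[i]:.8g}\t{row}\n")
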