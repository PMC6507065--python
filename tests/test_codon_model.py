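"""Likelihood engine tests, anchored by an independent enumeration oracle.

The oracle computes the mixture likelihood of small unrooted 4-taxon trees
by summing the joint probability over all 61 x 61 internal-state
assignments, with transition matrices from scipy's generic ``expm`` and a
rate matrix rebuilt from first principles (explicit loops over codon
pairs) — sharing no code path with the pruning engine.
"""

import numpy as np
import pytest
from Bio.Data import CodonTable
from scipy.linalg import expm

import codonscan as cs
from codonscan.codon import (
    CODON_INDEX,
    SENSE_CODONS,
    BranchSiteParams,
    f3x4_frequencies,
    gy94_rate_matrix,
    transition_matrix,
)
from codonscan.filters import CodonAlignment
from codonscan.trees import read_newick_labeled

from conftest import make_codon

# ---------------------------------------------------------------------------
# independent model construction (test-local, loop-based)
# ---------------------------------------------------------------------------

_CODE = CodonTable.unambiguous_dna_by_id[1].forward_table
_TS = {frozenset("AG"), frozenset("CT")}


def oracle_q(kappa, omega, pi):
    """Unscaled rate matrix via explicit loops over codon pairs."""
    n = 61
    Q = np.zeros((n, n))
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            rate = pi[j]
            if frozenset(diffs[0]) in _TS:
                rate *= kappa
            if _CODE[ci] != _CODE[cj]:
                rate *= omega
            Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def oracle_mixture_loglik(aln, lengths, fg_edge, params, pi):
    """Exhaustive-summation likelihood for the unrooted quartet
    (A, B, (C, D)): edges ordered [A, B, C, D, internal]. For each site and
    class the full 61 x 61 joint table over the two internal states (x at
    the root junction, y at the inner node) is formed and summed — no
    message passing, no shared code with the engine (generic ``expm``)."""
    w = params.class_weights()
    mus = {}
    for om in (params.omega0, 1.0, params.omega2):
        Q = oracle_q(params.kappa, om, pi)
        mus[om] = -(pi * np.diag(Q)).sum()
    rho = (w[0] + w[2]) * mus[params.omega0] + (w[1] + w[3]) * mus[1.0]
    class_bg_fg = [(params.omega0, params.omega0), (1.0, 1.0),
                   (params.omega0, params.omega2), (1.0, params.omega2)]
    P_by_class = []
    for bg, fg in class_bg_fg:
        oms = [bg] * 5
        oms[fg_edge] = fg
        P_by_class.append([expm(oracle_q(params.kappa, om, pi) / rho * t)
                           for om, t in zip(oms, lengths)])
    idx = np.array([[CODON_INDEX[c] for c in row] for row in aln.codons])
    total = 0.0
    for site in range(aln.width):
        a, b, c, d = idx[:, site]
        site_lik = 0.0
        for cls in range(4):
            PA, PB, PC, PD, PN = P_by_class[cls]
            joint = (pi * PA[:, a] * PB[:, b])[:, None] * PN * (PC[:, c] * PD[:, d])[None, :]
            site_lik += w[cls] * joint.sum()
        total += np.log(site_lik)
    return total


def _quartet_tree(lengths, fg_edge):
    labels = ["A", "B", "C", "D"]
    ta, tb, tc, td, tn = lengths
    marks = [""] * 5
    marks[fg_edge] = "#1"
    return read_newick_labeled(
        f"(A{marks[0]}:{ta},B{marks[1]}:{tb},"
        f"(C{marks[2]}:{tc},D{marks[3]}:{td}){marks[4]}:{tn});"
    )


# ---------------------------------------------------------------------------
# F3x4 frequencies
# ---------------------------------------------------------------------------

class TestF3x4:
    def test_uniform_usage_gives_uniform_codons(self):
        # every nucleotide equally often at every position
        rows = {"a": "".join(SENSE_CODONS), "b": "".join(SENSE_CODONS[::-1])}
        aln = make_codon(rows)
        pi = f3x4_frequencies(aln)
        # not exactly uniform (61 sense codons have unequal positional
        # composition) but a valid distribution; uniformity needs balanced
        # input, which ATG/TAC pairs provide:
        aln2 = make_codon({"a": "ACGT" * 3, "b": "CATG" * 3, "c": "GTAC" * 3, "d": "TGCA" * 3})
        pi2 = f3x4_frequencies(aln2)
        assert pi2 == pytest.approx(np.full(61, 1 / 61), abs=1e-12)
        assert pi.sum() == pytest.approx(1.0)

    def test_distribution_properties_random_alignment(self):
        rng = np.random.default_rng(3)
        codons = np.array(SENSE_CODONS)[rng.integers(0, 61, size=(5, 50))]
        pi = f3x4_frequencies(CodonAlignment([f"s{i}" for i in range(5)], codons))
        assert pi.sum() == pytest.approx(1.0)
        assert (pi > 0).all()

    def test_all_atg_alignment_peaks_at_atg(self):
        aln = make_codon({"a": "ATG" * 10, "b": "ATG" * 10})
        pi = f3x4_frequencies(aln)
        assert np.argmax(pi) == CODON_INDEX["ATG"]
        # direct arithmetic with 0.5 pseudocounts: position freqs are
        # (20.5, 0.5, 0.5, 0.5)/22 for the observed base, so
        # pi(ATG) ~ (20.5/22)^3 before stop-excision renormalisation
        raw = (20.5 / 22) ** 3
        renorm = pi[CODON_INDEX["ATG"]] / raw
        assert 1.0 <= renorm < 1.1  # renormalisation can only inflate


# ---------------------------------------------------------------------------
# rate matrix and transition probabilities
# ---------------------------------------------------------------------------

class TestRateMatrix:
    pi = np.full(61, 1 / 61)

    def test_multi_position_changes_are_structural_zeros(self):
        rm = gy94_rate_matrix(2.0, 0.5, self.pi)
        assert rm.Q[CODON_INDEX["AAA"], CODON_INDEX["AGG"]] == 0.0

    def test_omega_zero_kills_nonsynonymous_rates(self):
        rm = gy94_rate_matrix(2.0, 0.0, self.pi)
        # AAA (Lys) -> GAA (Glu) is non-synonymous
        assert rm.Q[CODON_INDEX["AAA"], CODON_INDEX["GAA"]] == 0.0
        # AAA -> AAG is synonymous (both Lys)
        assert rm.Q[CODON_INDEX["AAA"], CODON_INDEX["AAG"]] > 0.0

    def test_neutral_kappa_one_uniform_pi_equal_offdiagonals(self):
        rm = gy94_rate_matrix(1.0, 1.0, self.pi)
        off = rm.Q[~np.eye(61, dtype=bool)]
        nonzero = off[off > 0]
        assert np.allclose(nonzero, nonzero[0])

    def test_rows_sum_to_zero_and_detailed_balance_and_scaling(self):
        rng = np.random.default_rng(0)
        pi = rng.dirichlet(np.ones(61))
        rm = gy94_rate_matrix(3.1, 0.4, pi)
        assert np.abs(rm.Q.sum(axis=1)).max() < 1e-10
        flux = pi[:, None] * rm.Q
        assert np.abs(flux - flux.T).max() < 1e-10
        assert -(pi * np.diag(rm.Q)).sum() == pytest.approx(1.0, abs=1e-10)

    def test_matches_loop_built_oracle(self):
        rng = np.random.default_rng(5)
        pi = rng.dirichlet(np.ones(61))
        rm = gy94_rate_matrix(2.7, 0.3, pi)
        Q = oracle_q(2.7, 0.3, pi)
        Q /= -(pi * np.diag(Q)).sum()
        assert np.abs(rm.Q - Q).max() < 1e-12


class TestTransitionMatrix:
    pi = np.full(61, 1 / 61)

    def test_zero_time_is_identity(self):
        rm = gy94_rate_matrix(2.0, 0.5, self.pi)
        assert np.abs(transition_matrix(rm, 0.0) - np.eye(61)).max() < 1e-12

    def test_long_time_reaches_stationarity(self):
        rng = np.random.default_rng(1)
        pi = rng.dirichlet(np.ones(61) * 5)
        rm = gy94_rate_matrix(2.0, 0.5, pi)
        P = transition_matrix(rm, 1e6)
        assert np.abs(P - pi[None, :]).max() < 1e-6

    def test_semigroup_property(self):
        rng = np.random.default_rng(2)
        pi = rng.dirichlet(np.ones(61) * 5)
        rm = gy94_rate_matrix(1.7, 0.8, pi)
        for _ in range(3):
            t1, t2 = rng.uniform(0.01, 1.0, size=2)
            lhs = transition_matrix(rm, t1 + t2)
            rhs = transition_matrix(rm, t1) @ transition_matrix(rm, t2)
            assert np.abs(lhs - rhs).max() < 1e-8

    def test_rows_are_distributions(self):
        rm = gy94_rate_matrix(2.0, 1.5, self.pi)
        P = transition_matrix(rm, 0.3)
        assert np.abs(P.sum(axis=1) - 1).max() < 1e-10
        assert P.min() >= 0

    def test_negative_time_rejected(self):
        rm = gy94_rate_matrix(2.0, 0.5, self.pi)
        with pytest.raises(ValueError):
            transition_matrix(rm, -0.1)


# ---------------------------------------------------------------------------
# mixture likelihood
# ---------------------------------------------------------------------------

class TestMixtureLoglik:
    def test_identical_sequences_zero_lengths_give_log_pi(self):
        aln = make_codon({"A": "ATG", "B": "ATG"})
        tree = read_newick_labeled("(A#1:0.0,B:0.0);")
        pi = np.full(61, 1 / 61)
        eng = cs.BranchSiteLikelihood(aln, tree, pi=pi)
        params = BranchSiteParams(2.0, 0.5, 0.3, 0.2, 3.0)
        ll = eng.loglik(params, np.zeros(eng.n_edges))
        assert ll == pytest.approx(np.log(1 / 61), abs=1e-10)

    def test_matches_enumeration_on_quartet(self):
        rng = np.random.default_rng(42)
        pi = np.full(61, 1 / 61)
        lengths = rng.uniform(0.05, 0.6, size=5)
        tree = _quartet_tree(lengths, fg_edge=4)
        params = BranchSiteParams(1.9, 0.45, 0.3, 0.25, 3.5)
        aln, _ = cs.simulate_codon_alignment(tree, params, 3, seed=8)
        eng = cs.BranchSiteLikelihood(aln, tree, pi=pi)
        ll = eng.loglik(params, eng.tree_lengths())
        # oracle edge order: A, B, C, D, inner — match engine's post-order
        oracle = oracle_mixture_loglik(aln, list(lengths), 4, params, pi)
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_degenerate_mixture_approaches_single_class(self):
        tree = cs.fixture_tree()
        params0 = BranchSiteParams(2.0, 0.6, 0.2, 0.3, 2.0)
        aln, _ = cs.simulate_codon_alignment(tree, params0, 40, seed=4)
        eng = cs.BranchSiteLikelihood(aln, tree)
        L = eng.tree_lengths()
        eps = 1e-9
        near_pure = BranchSiteParams(2.0, 1 - 2 * eps, eps, 0.3, 1.0)
        ll_mix = eng.loglik(near_pure, L)
        # pure class 0: all edges omega0, weight 1 (scale: class-0 only)
        cls = eng.class_pattern_logliks(2.0, 0.3, 1.0, L, np.array([1.0, 0, 0, 0]))
        ll_pure = float(cls[0] @ eng._counts)
        assert ll_mix == pytest.approx(ll_pure, abs=1e-5)

    def test_invariant_to_taxon_and_site_order(self, study_tree):
        params = BranchSiteParams(2.0, 0.5, 0.3, 0.2, 2.0)
        aln, _ = cs.simulate_codon_alignment(study_tree, params, 60, seed=21)
        pi = f3x4_frequencies(aln)
        eng = cs.BranchSiteLikelihood(aln, study_tree, pi=pi)
        ll = eng.loglik(params, eng.tree_lengths())
        rng = np.random.default_rng(0)
        taxon_perm = rng.permutation(aln.n_taxa)
        site_perm = rng.permutation(aln.width)
        shuffled = CodonAlignment(
            [aln.taxa[i] for i in taxon_perm],
            aln.codons[np.ix_(taxon_perm, site_perm)],
        )
        eng2 = cs.BranchSiteLikelihood(shuffled, study_tree, pi=pi)
        assert eng2.loglik(params, eng2.tree_lengths()) == pytest.approx(ll, abs=1e-9)

    def test_null_invariant_to_class1_class2b_weight_shuffle(self, study_tree):
        aln, _ = cs.simulate_codon_alignment(
            study_tree, BranchSiteParams(2.0, 0.5, 0.3, 0.2, 1.0), 50, seed=9
        )
        eng = cs.BranchSiteLikelihood(aln, study_tree)
        L = eng.tree_lengths()
        cls = eng.class_pattern_logliks(2.0, 0.2, 1.0, L, np.array([0.5, 0.2, 0.2, 0.1]))
        w1 = np.array([0.5, 0.2, 0.2, 0.1])
        w2 = np.array([0.5, 0.05, 0.2, 0.25])  # weight moved class1 <-> class2b
        ll1 = eng.mixture_from_class(cls, w1)
        ll2 = eng.mixture_from_class(cls, w2)
        assert ll1 == pytest.approx(ll2, abs=1e-9)

    def test_taxon_mismatch_rejected(self, study_tree):
        aln = make_codon({"A": "ATG", "B": "ATG"})
        with pytest.raises(ValueError):
            cs.BranchSiteLikelihood(aln, study_tree)

    def test_unmarked_tree_rejected_at_evaluation(self):
        aln = make_codon({"A": "ATG", "B": "ATGCCC"[:3], "C": "ATG"})
        tree = read_newick_labeled("(A:0.1,B:0.1,C:0.1);")
        eng = cs.BranchSiteLikelihood(aln, tree)
        with pytest.raises(ValueError, match="foreground"):
            eng.loglik(BranchSiteParams(2.0, 0.5, 0.3, 0.2, 2.0), eng.tree_lengths())


def test_rate_matrix_debug_dump(tmp_path):
    from codonscan.codon import dump_rate_matrix

    rm = gy94_rate_matrix(2.0, 0.5, np.full(61, 1 / 61))
    p = tmp_path / "q.tsv"
    dump_rate_matrix(rm, p)
    lines = p.read_text().splitlines()
    assert len(lines) == 62
    assert lines[0].split("\t")[:2] == ["codon", "pi"]
    assert len(lines[1].split("\t")) == 63


class TestParamsType:
    def test_derived_weights_sum_to_one(self):
        p = BranchSiteParams(2.0, 0.55, 0.25, 0.1, 4.0)
        w = p.class_weights()
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert p.p2a == pytest.approx(0.2 * 0.55 / 0.8)
        assert p.p2b == pytest.approx(0.2 * 0.25 / 0.8)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(kappa=-1.0, p0=0.5, p1=0.3, omega0=0.2, omega2=2.0),
            dict(kappa=2.0, p0=0.0, p1=0.3, omega0=0.2, omega2=2.0),
            dict(kappa=2.0, p0=0.8, p1=0.3, omega0=0.2, omega2=2.0),
            dict(kappa=2.0, p0=0.5, p1=0.3, omega0=1.2, omega2=2.0),
            dict(kappa=2.0, p0=0.5, p1=0.3, omega0=0.2, omega2=0.5),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BranchSiteParams(**kwargs)
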