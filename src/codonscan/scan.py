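"""Branch-site model fits, the likelihood-ratio test and site posteriors.

For each gene and foreground branch the scan fits the alternative model
(omega2 >= 1 free) and the null model (omega2 fixed at 1) by maximum
likelihood over (kappa, p0, p1, omega0[, omega2]) and all branch lengths.
The LRT statistic 2(lnL_alt - lnL_null) is referred to a 50:50 mixture of
chi-square(1) and a point mass at zero (the boundary null), i.e. the
chi-square(1) upper tail divided by two. Genes are called positively
selected when the BH-adjusted q-value is below 0.1 and the fitted omega2
exceeds 1; selected sites are localised by empirical-Bayes posteriors over
the four site classes, either at the MLEs (NEB) or averaged over a grid of
(p0, p1, omega2) weighted by the data likelihood (BEB).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .codon import BranchSiteLikelihood, BranchSiteParams, mixture_scale
from .filters import CodonAlignment
from .trees import LabeledTree

__all__ = [
    "FitResult",
    "ScanRow",
    "fit_model_a",
    "fit_null_a",
    "fit_gene",
    "lrt_pvalue",
    "bh_fdr",
    "call_positive",
    "site_posteriors",
    "contiguity_fraction",
]


@dataclass
class FitResult:
    params: BranchSiteParams
    branch_lengths: np.ndarray
    loglik: float
    converged: bool
    n_restarts_used: int


@dataclass
class ScanRow:
    """One gene x foreground-branch test result."""

    gene: str
    branch: str
    lnL_alt: float
    lnL_null: float
    lrt_stat: float
    p_value: float
    q_value: float
    omega2: float
    positive: bool
    selected_sites: list[tuple[int, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# parameter transforms: optimisation runs on unconstrained coordinates
# ---------------------------------------------------------------------------

_BL_LO, _BL_HI = np.log(1e-4), np.log(20.0)


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def _theta_to_params(theta: np.ndarray, n_edges: int, null: bool):
    k = float(np.exp(theta[0]))
    z0, z1 = theta[1], theta[2]
    e = np.exp(np.array([z0, z1, 0.0]) - max(z0, z1, 0.0))
    s = e / e.sum()
    p0, p1 = float(s[0]), float(s[1])
    omega0 = float(_sigmoid(theta[3]))
    if null:
        omega2 = 1.0
        bl = np.exp(theta[4:])
    else:
        omega2 = 1.0 + float(np.exp(theta[4]))
        bl = np.exp(theta[5:])
    p0 = min(max(p0, 1e-9), 1 - 2e-9)
    p1 = min(max(p1, 1e-9), 1 - p0 - 1e-9)
    omega0 = min(max(omega0, 1e-9), 1 - 1e-9)
    return BranchSiteParams(k, p0, p1, omega0, omega2), bl


def _params_to_theta(params: BranchSiteParams, bl: np.ndarray, null: bool) -> np.ndarray:
    rest = max(1.0 - params.p0 - params.p1, 1e-9)
    z0 = np.log(params.p0 / rest)
    z1 = np.log(params.p1 / rest)
    w0 = min(max(params.omega0, 1e-6), 1 - 1e-6)
    head = [np.log(params.kappa), z0, z1, np.log(w0 / (1 - w0))]
    if not null:
        head.append(np.log(max(params.omega2 - 1.0, 1e-5)))
    return np.concatenate([head, np.log(np.clip(bl, 1.5e-4, 19.0))])


def _bounds(n_edges: int, null: bool):
    head = [(np.log(0.05), np.log(50.0)), (-15, 15), (-15, 15), (-15, 15)]
    if not null:
        head.append((np.log(1e-5), np.log(150.0)))
    return head + [(_BL_LO, _BL_HI)] * n_edges


_START = BranchSiteParams(kappa=2.0, p0=0.5, p1=0.25, omega0=0.4, omega2=1.5)


def _optimize(engine: BranchSiteLikelihood, theta0: np.ndarray, null: bool,
              maxiter: int, ftol: float):
    """L-BFGS-B on the transformed parameters.

    Branch-length and mixture-weight derivatives come from the engine's
    analytic gradient; kappa and the omegas use forward differences (they
    change the rate matrices, whose derivative is not worth hand-coding).
    """
    n_edges = engine.n_edges
    nb = 4 if null else 5
    h = 1e-6

    def nll_grad(theta: np.ndarray):
        try:
            params, bl = _theta_to_params(theta, n_edges, null)
            w = params.class_weights()
            ll, d_dteff, d_dw, rho = engine.loglik_and_grad(
                params.kappa, params.omega0, params.omega2, bl, w
            )
            grad = np.zeros_like(theta)
            grad[nb:] = d_dteff / rho * bl  # theta holds log-lengths
            d_drho = -(d_dteff * bl).sum() / rho**2
            for idx in (1, 2):  # weight logits: chain rule through (w, rho)
                tp, tm = theta.copy(), theta.copy()
                tp[idx] += h
                tm[idx] -= h
                pp, _ = _theta_to_params(tp, n_edges, null)
                pm, _ = _theta_to_params(tm, n_edges, null)
                wp, wm = pp.class_weights(), pm.class_weights()
                rp = mixture_scale(pp.kappa, pp.omega0, wp, engine.pi)
                rm = mixture_scale(pm.kappa, pm.omega0, wm, engine.pi)
                grad[idx] = (d_dw @ (wp - wm) + d_drho * (rp - rm)) / (2 * h)
            for idx in (0, 3) if null else (0, 3, 4):  # kappa, omega0[, omega2]
                tp = theta.copy()
                tp[idx] += h
                pp, blp = _theta_to_params(tp, n_edges, null)
                grad[idx] = (engine.loglik(pp, blp) - ll) / h
            return -ll, -grad
        except (FloatingPointError, ValueError):
            return 1e12, np.zeros_like(theta)

    res = minimize(
        nll_grad,
        theta0,
        method="L-BFGS-B",
        jac=True,
        bounds=_bounds(n_edges, null),
        options={"maxiter": maxiter, "ftol": ftol, "maxcor": 12},
    )
    return res


def _start_lengths(engine: BranchSiteLikelihood) -> np.ndarray:
    return np.array([0.1 if v is None else max(v, 2e-4) for v in engine.edge_lengths])


def _run_fit(
    engine: BranchSiteLikelihood,
    null: bool,
    seed: int = 0,
    n_restarts: int = 2,
    start: tuple[BranchSiteParams, np.ndarray] | None = None,
    maxiter: int = 200,
    ftol: float = 1e-9,
) -> FitResult:
    """Multistart fit: a first run from the canonical (or supplied) start,
    then jittered restarts launched from the best point found so far."""
    rng = np.random.default_rng(seed)
    if start is None:
        p = _START if not null else BranchSiteParams(2.0, 0.5, 0.25, 0.4, 1.0)
        theta0 = _params_to_theta(p, _start_lengths(engine), null)
    else:
        theta0 = _params_to_theta(start[0], start[1], null)
    best = None
    converged = False
    used = 0
    lo_hi = np.array(_bounds(engine.n_edges, null))
    for r in range(max(1, n_restarts)):
        res = _optimize(engine, theta0, null, maxiter, ftol)
        used += 1
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)
        jitter = rng.normal(0.0, 0.25, size=best.x.shape)
        theta0 = np.clip(best.x + jitter, lo_hi[:, 0], lo_hi[:, 1])
    params, bl = _theta_to_params(best.x, engine.n_edges, null)
    if null:
        params = BranchSiteParams(params.kappa, params.p0, params.p1, params.omega0, 1.0)
    return FitResult(params, bl, -float(best.fun), converged, used)


def fit_model_a(
    aln: CodonAlignment | BranchSiteLikelihood,
    tree: LabeledTree | None = None,
    seed: int = 0,
    n_restarts: int = 2,
    maxiter: int = 200,
) -> FitResult:
    """ML fit of the alternative branch-site model (omega2 >= 1 free).

    Starts from kappa 2, omega0 0.4, omega2 1.5 and the tree's branch
    lengths (0.1 where absent); ``n_restarts`` >= 2 jittered restarts guard
    against local optima. Returns the best fit found (``converged`` False
    when no run satisfied the optimiser's own criterion).
    """
    engine = aln if isinstance(aln, BranchSiteLikelihood) else BranchSiteLikelihood(aln, tree)
    return _run_fit(engine, null=False, seed=seed, n_restarts=n_restarts, maxiter=maxiter)


def fit_null_a(
    aln: CodonAlignment | BranchSiteLikelihood,
    tree: LabeledTree | None = None,
    seed: int = 0,
    n_restarts: int = 2,
    maxiter: int = 200,
) -> FitResult:
    """ML fit of the null branch-site model (omega2 fixed at 1)."""
    engine = aln if isinstance(aln, BranchSiteLikelihood) else BranchSiteLikelihood(aln, tree)
    return _run_fit(engine, null=True, seed=seed, n_restarts=n_restarts, maxiter=maxiter)


def fit_gene(
    engine: BranchSiteLikelihood,
    seed: int = 0,
    n_restarts: int = 2,
    maxiter: int = 200,
) -> tuple[FitResult, FitResult]:
    """Fit null and alternative models with shared warm starts.

    The null is fitted first; the alternative starts from the null MLE
    (omega2 at 1.5); the null is then refined once from the alternative MLE
    with omega2 collapsed to 1. The shared starts keep the models honestly
    nested: lnL_null <= lnL_alt up to optimiser tolerance.
    """
    # the null's second start arrives via the alt-collapse refinement below,
    # so its multistart here is a single run
    null = _run_fit(engine, null=True, seed=seed, n_restarts=1, maxiter=maxiter)
    p = null.params
    alt_start = (BranchSiteParams(p.kappa, p.p0, p.p1, p.omega0, 1.5), null.branch_lengths)
    alt = _run_fit(engine, null=False, seed=seed + 1, n_restarts=n_restarts,
                   start=alt_start, maxiter=maxiter)
    a = alt.params
    null_start = (BranchSiteParams(a.kappa, a.p0, a.p1, a.omega0, 1.0), alt.branch_lengths)
    null2 = _run_fit(engine, null=True, seed=seed + 2, n_restarts=1,
                     start=null_start, maxiter=maxiter)
    if null2.loglik > null.loglik:
        null = FitResult(null2.params, null2.branch_lengths, null2.loglik,
                         null.converged or null2.converged,
                         null.n_restarts_used + null2.n_restarts_used)
    if null.loglik > alt.loglik:
        # The refined null overtook the alt by optimiser tolerance. omega2=1
        # lies inside the alternative's parameter space (its boundary), so
        # the null solution is itself a valid alternative fit: adopt it.
        n = null.params
        alt = FitResult(BranchSiteParams(n.kappa, n.p0, n.p1, n.omega0, 1.0),
                        null.branch_lengths, null.loglik,
                        alt.converged or null.converged, alt.n_restarts_used)
    return null, alt


# ---------------------------------------------------------------------------
# test statistics
# ---------------------------------------------------------------------------

def lrt_pvalue(lnl_alt: float, lnl_null: float) -> float:
    """p-value of the boundary LRT: chi-square(1) upper tail of
    max(0, 2 * (lnL_alt - lnL_null)), divided by two. A zero statistic
    (including optimiser noise clamped to zero) gives p = 0.5."""
    stat = max(0.0, 2.0 * (lnl_alt - lnl_null))
    return float(chi2.sf(stat, df=1) / 2.0)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_positive(q: float, omega2: float, q_max: float = 0.1) -> bool:
    """Positive-selection call: q below the FDR ceiling and omega2 > 1."""
    return bool(q < q_max and omega2 > 1.0)


# ---------------------------------------------------------------------------
# site posteriors
# ---------------------------------------------------------------------------

def _beb_grids() -> tuple[np.ndarray, np.ndarray]:
    # 10-point triangle over (p0, p1): category midpoints v=(2i+1)/8 with
    # v0 + v1 < 1; 10 omega2 values at the midpoints of [1, 11]
    v = (2 * np.arange(4) + 1) / 8.0
    tri = np.array([(a, b) for a in v for b in v if a + b < 1.0])
    omegas = 1.0 + np.arange(10) + 0.5
    return tri, omegas


def _weights(p0: float, p1: float) -> np.ndarray:
    rest = 1.0 - p0 - p1
    return np.array([p0, p1, rest * p0 / (p0 + p1), rest * p1 / (p0 + p1)])


def site_posteriors(
    engine: BranchSiteLikelihood,
    fit_alt: FitResult,
    mode: str = "beb",
    threshold: float = 0.5,
) -> tuple[np.ndarray, list[tuple[int, float]]]:
    """Per-site posterior over the four classes and the selected-site list.

    ``mode="neb"`` evaluates P(class | site) proportional to
    w_c * L_c(site) at the MLEs; ``mode="beb"`` averages the same quantity
    over a uniform grid of (p0, p1) (10-point triangle) and omega2 (10
    points spanning [1, 11]), each grid point weighted by its data
    likelihood (kappa, omega0 and branch lengths held at their MLEs). Sites
    whose P(2a) + P(2b) exceeds ``threshold`` are listed (1-based) with that
    posterior.
    """
    if not fit_alt.converged:
        raise RuntimeError("site posteriors require a converged alternative fit")
    p = fit_alt.params
    bl = fit_alt.branch_lengths
    if mode == "neb":
        cls = engine.class_pattern_logliks(p.kappa, p.omega0, p.omega2, bl, p.class_weights())
        logw = np.log(np.maximum(p.class_weights(), 1e-300))[:, None]
        a = cls + logw
        post_pat = np.exp(a - a.max(axis=0)[None, :])
        post_pat /= post_pat.sum(axis=0)[None, :]
    elif mode == "beb":
        tri, omegas = _beb_grids()
        # branch lengths and the mixture rate scale stay at their MLEs while
        # the grid sweeps the mixture weights and omega2
        rho = mixture_scale(p.kappa, p.omega0, p.class_weights(), engine.pi)
        cls_by_omega = [
            engine.class_pattern_logliks(p.kappa, p.omega0, om, bl, scale=rho)
            for om in omegas
        ]
        counts = engine._counts
        n_pat = cls_by_omega[0].shape[1]
        grid_ll = np.empty((len(tri), len(omegas)))
        grid_post_site = []  # per grid point: (4, n_pat) P(c|site)
        for gi, (p0, p1) in enumerate(tri):
            logw = np.log(_weights(p0, p1))[:, None]
            for oi in range(len(omegas)):
                a = cls_by_omega[oi] + logw
                mx = a.max(axis=0)
                site_ll = mx + np.log(np.exp(a - mx).sum(axis=0))
                grid_ll[gi, oi] = site_ll @ counts
                grid_post_site.append(np.exp(a - site_ll[None, :]))
        flat_ll = grid_ll.ravel()
        gw = np.exp(flat_ll - flat_ll.max())
        gw /= gw.sum()
        post_pat = np.zeros((4, n_pat))
        for w, ps in zip(gw, grid_post_site):
            post_pat += w * ps
    else:
        raise ValueError(f"mode must be 'neb' or 'beb', got {mode!r}")
    post = post_pat[:, engine._pattern_of_site]
    sel_prob = post[2] + post[3]
    selected = [(i + 1, float(sel_prob[i])) for i in np.flatnonzero(sel_prob > threshold)]
    return post, selected


def contiguity_fraction(selected: Mapping[str, Sequence[int]]) -> float:
    """Percent of selected codons with a selected immediate neighbour.

    ``selected`` maps gene -> sorted unique 1-based codon indices. A codon
    counts as contiguous when index-1 or index+1 of the same gene is also
    selected. Returns 0 for an empty input.
    """
    total = 0
    contiguous = 0
    for sites in selected.values():
        s = set(sites)
        total += len(s)
        contiguous += sum(1 for i in s if i - 1 in s or i + 1 in s)
    if total == 0:
        return 0.0
    return 100.0 * contiguous / total
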