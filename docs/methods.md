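# Methods

This note documents the models, conventions and numerical choices behind
`codonscan`, in the spirit of a software methods appendix: what is
computed, under which assumptions, and where design decisions were
genuinely open.

## Substitution model

The engine works on the 61 sense codons of the universal genetic code
(stops excluded; the package assumes vertebrate nuclear protein-coding
genes throughout). Instantaneous rates follow the Goldman–Yang
parameterisation restricted to single-nucleotide changes:

    q_ij = pi_j                      synonymous transversion
           pi_j * kappa              synonymous transition
           pi_j * omega              non-synonymous transversion
           pi_j * kappa * omega      non-synonymous transition

`kappa` (transition/transversion rate ratio, > 0) is estimated by maximum
likelihood with start value 2.0. Equilibrium frequencies `pi` use the F3x4
construction — position-specific nucleotide frequencies multiplied and
renormalised over sense codons — with a pseudocount of 0.5 per nucleotide
per position so that degenerate (short or low-complexity) alignments never
produce zero frequencies. The standalone rate-matrix constructor scales Q
to unit mean rate, making a branch length the expected number of
substitutions per codon.

Transition probabilities P(t) = exp(Qt) are computed by eigendecomposition
of the pi-symmetrised rate matrix, which is exact for this reversible
family and stable; entries are clipped into [0, 1] after round-off.

## Branch-site mixture and its rate scaling

The four-class site mixture is parameterised by (p0, p1, omega0, omega2)
with derived weights p2a = (1-p0-p1)·p0/(p0+p1), p2b = (1-p0-p1)·p1/(p0+p1).
Classes 0 and 1 use omega0 and 1 on every branch; classes 2a and 2b switch
to omega2 on the single foreground branch.

All four class matrices share **one** rate scale: the mean rate under the
background mixture, rho = (p0+p2a)·mu(omega0) + (p1+p2b)·mu(1). A branch
length is therefore the expected number of substitutions per codon on a
background branch, and sites in the selected classes genuinely accumulate
*more* substitutions on the foreground branch when omega2 > 1. This is the
conventional choice; the alternative — scaling each class matrix to unit
rate separately — silently equalises the substitution rate across classes
and removes most of the test's power (we verified this empirically during
development: with per-class scaling, data simulated at omega2 = 8 were
statistically almost indistinguishable from null data). The simulator uses
the identical convention, so the generating process lies inside the fitted
model family.

## Likelihood, trees and identifiability

Site likelihoods come from Felsenstein pruning over the 61 states with
per-node log-scaling (raw partial products underflow at realistic widths).
Site patterns are compressed before pruning; this is an internal
optimisation and cannot change the value (verified by permutation tests).

Likelihood and simulation operate on the **unrooted** tree: when the input
tree has a binary root, its two subtending edges are merged into one
branch. Under a reversible model the root split is identifiable only
through its sum, and leaving both edges free lets branch length drift onto
a root-adjacent foreground branch and deflate the omega2 estimate (we
observed omega2-hat ≈ 3.8 at truth 8 even with 5000 codons before
merging). A foreground mark on either half of a merged root edge marks the
merged branch. Consequently "the stem branch of the ingroup clade" and
"the outgroup's terminal branch" are the same testable branch — exactly as
in any unrooted branch-site analysis with a single outgroup.

## Model fitting

Both models are maximised over (kappa, p0, p1, omega0[, omega2]) and all
branch lengths jointly, by L-BFGS-B on transformed coordinates (log for
rates and lengths, logistic for omega0, softmax logits for the weights,
log(omega2 - 1) for the selected-class ratio, bounded away from overflow).
Start values: kappa 2.0, omega0 0.4, omega2 1.5, weights (0.5, 0.25), and
the input tree's branch lengths (0.1 where absent).

Gradients are analytic for branch lengths and mixture weights, computed by
the classic downward/upward message-passing construction; writing each
edge derivative as a ratio of two quantities that share the same per-node
normalisations makes explicit scale bookkeeping unnecessary. Derivatives
with respect to kappa, omega0 and omega2 use forward differences (these
perturb the rate matrices, whose analytic Fréchet derivative is not worth
the complexity here). The analytic components were verified against
central finite differences to ~1e-7.

Each fit runs a multistart: the first run from the canonical start (or a
warm start), subsequent restarts from the best point found so far
perturbed by seeded Gaussian noise (sd 0.25 on the transformed scale). The
per-gene test fits the null first, warm-starts the alternative from the
null MLE, then refines the null once from the alternative MLE with omega2
collapsed to 1. If optimiser tolerance still leaves lnL_null above
lnL_alt, the null solution — which lies on the alternative's boundary
(omega2 = 1) — is adopted as the alternative fit, so nesting holds by
construction and the LRT statistic clamps to 0 (p = 0.5, the boundary
convention).

## Test statistics and calls

* LRT: stat = max(0, 2·(lnL_alt − lnL_null)); p = chi²(1) upper tail of
  the statistic, divided by two (50:50 boundary mixture).
* FDR: Benjamini–Hochberg step-up q-values, one family per foreground
  branch (the family structure was an open choice; per-branch matches how
  per-branch gene counts are reported, and q-values are invariant to gene
  order within a family).
* Positive call: q < 0.1 and omega2-hat > 1. "omega > 1 for the foreground
  branch" is read as the MLE of omega2; a site-averaged reading would also
  be defensible but is less standard.
* Site posteriors: NEB evaluates P(class | site) ∝ w_c·L_c(site) at the
  MLEs. BEB averages the same quantity over a uniform grid — a 10-point
  triangle over (p0, p1) (category midpoints (2i+1)/8 with p0+p1 < 1) and
  10 omega2 values at the midpoints of [1, 11] — weighting each grid point
  by its data likelihood, with kappa, omega0, branch lengths and the
  mixture rate scale held at their MLEs. A site is listed as selected when
  P(2a)+P(2b) exceeds 0.5 (the weakest defensible call; configurable).
* Contiguity: a selected codon is contiguous if an immediately adjacent
  codon of the same gene is also selected; the statistic is the percentage
  of selected codons that are contiguous (0 for an empty set).
* Sister-branch comparison: exact two-tailed binomial test at p = 0.5,
  doubling the larger-count tail and capping at 1 — this convention
  reproduces the published values 0.021 (33 vs 16) and 0.043 (18 vs 7)
  exactly at three decimals.
* Expression: a tissue is "present" for a gene above 5% of the gene's
  total TPM, "specific" above 95%; zero-total genes are excluded with a
  warning.

## Orthology and filtering conventions

* Longest isoform per gene, ties broken to the lexicographically smallest
  record id (determinism matters more than the arbitrary choice).
* Reciprocal best hits: best = minimal e-value, then maximal bitscore,
  then lexicographically smallest subject id; both directions' best hits
  must satisfy e-value < 1e-10 (strict, mirroring the search cutoff).
  Ortholog groups are anchored through the outgroup gene only and require
  a partner in every ingroup species (full occupancy).
* Singleton windows: a singleton is a non-gap residue observed in exactly
  one row of its column. Pass 1 drops every 15-column window in which one
  species owns ≥ 10 singleton columns; pass 2 drops every 5-column window
  whose columns all contain a singleton. Both passes are evaluated on the
  original coordinates and their drops unioned, so composition order is
  irrelevant. The "all five" rule is read as all five *window columns*
  (the window length), the more conservative of the two possible readings.
  Whole windows are dropped for all taxa rather than masked per species;
  with gap-column cleaning downstream the two interpretations converge.
* Conserved-block filter: a deliberately simple stand-in for a
  Gblocks-style trimmer with two knobs — a column is good when its gap
  fraction is ≤ 0.5 and at least half its non-gap residues agree; good
  runs shorter than 10 columns are dropped. On highly divergent alignments
  this filter is aggressive; its role (removing ragged, ambiguously
  aligned regions) is preserved, bit-compatibility with any particular
  trimmer is a non-goal.
* Codon cleaning: every codon column containing a gap, an ambiguity or a
  stop anywhere is removed before likelihood evaluation, so the engine
  only ever sees sense codons.

## Synthetic data

The generator's defaults are the study conditions the test suite measures:
the fixed 6-taxon tree (one outgroup, five ingroup species; branch lengths
0.05–0.5 expected substitutions per codon, total ≈ 2), kappa 2, omega0
0.2; null genes use weights (0.5, 0.3) with omega2 = 1; selected genes use
weights (0.5, 0.2) with omega2 = 8, i.e. ~30% foreground-selected sites.
Root codons draw from a uniform distribution over the 61 sense codons (the
F3x4 fit then recovers approximately uniform frequencies, keeping the
generating process inside the fitted family). A single global seed drives
a splittable per-gene stream, so per-gene data are reproducible regardless
of batch order or thread count.

The on-disk fixture plants: decoy outgroup isoforms at 60% length; decoy
paralog hits with e-values ≥ 10× the true ortholog's (so RBH must recover
the planted groups exactly); species-specific 15-codon windows of random
residues in a subset of null genes (exactly the artefact the singleton
filters target); and one gene with 96% of its TPM in skin.

What the generator does **not** emulate: indels and alignment error
(alignments are simulated gap-free; gaps arise only via planted tracts),
assembly chimeras, among-site rate variation beyond the four-class
mixture, codon usage bias beyond F3x4, and gene-tree/species-tree
discordance. Passing tests therefore demonstrate correctness and
calibration *under the model*, not robustness to real-data pathologies —
the same caveat that applies to any simulation study of the branch-site
test.

## Problem sizes and numerical tolerances

The statistical suite uses desk-scale versions of the analyses: parameter
recovery uses 20 replicates of 500 codons; the type-I experiment 200 null
genes of 300 codons; site localisation 10 strong-selection genes; the
pruning-vs-enumeration check 50 random quartets (≤ 3 sites, exhaustive
61² summation) at 1e-8 agreement. `scripts/acceptance.py` re-runs the same
computations at slightly smaller sizes (12 recovery replicates, 60 null
genes, 6 localisation genes) chosen as a sensible default for a quick
reproduction; sizes are arguments of the respective functions. Optimiser
tolerance is ftol 1e-9 with at most 200 iterations per run; fits are
deterministic given a seed, and identical config + seed yields
byte-identical results tables.

## Known limitations

* Fitted omega2 has the heavy right tail familiar from branch-site
  analyses (individual genes can return omega2-hat far above truth, or at
  the omega2 = 1 boundary); medians across replicates are well behaved.
* No ambiguity-character likelihoods: cleaning removes them by design.
* The conserved-block filter is parameterised by two knobs only and is not
  a reimplementation of any published trimmer.
* BEB here follows the cited grid convention but is a re-derivation, not a
  line-for-line port; posterior values can differ in detail from other
  implementations while preserving the ranking behaviour the tests check.
* The scan loops genes in Python; at genome scale (thousands of genes ×
  nine branches) a cluster and a compiled likelihood would be appropriate.
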