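# Methods

This note records the models implemented, the defaults and why they were
chosen, the numerical decisions, and what the synthetic-data experiments do
and do not demonstrate.

## Motif model and exact p-values

A position frequency matrix (PFM) of base counts per column is transformed
into a position weight matrix by

    w(b, j) = round( log2( ((n_bj + p·q_b) / (N_j + p)) / q_b ), d )

with pseudocount p = 1 spread in proportion to the background probabilities
q, and d = 1 decimal of rounding.  Weights are base-2 log-odds ("bits"); the
base is a convention choice — ratios of scores and all p-values are
unaffected, and the per-species affinity statistic remains comparable across
species because each genome is scored against its own background.

The background is an order-0 (Bernoulli) model estimated from the scanned
sequence set, smoothed by mixing with the uniform distribution at total mass
4·bg_pseudo (bg_pseudo = 0.01) and renormalising, so every base has positive
probability.  Ambiguous bases are excluded from the counts.

Rounding is applied *before* both scanning and the null-distribution
computation.  Scores therefore live on an integer lattice (units of
10^−d), and the distribution of the score of a random background window is
computed exactly by dynamic-programming convolution over motif columns on
that lattice.  Hit p-values are the upper tail P(S ≥ s) of this
distribution, so a hit's p-value and the distribution can never disagree;
for widths ≤ 6 the DP is verified against exhaustive enumeration of all 4^w
words.  Scanning is threshold-inclusive (p ≤ uth), reports all overlapping
hits without masking, skips windows containing N, and scores both strands at
the same forward coordinates; the per-window-strand p-value is reported
without cross-strand correction, matching per-site reporting.

## Regions, target calls, affinity

Coordinates are 0-based half-open internally; GFF3 IO converts at the
boundary.  One transcript per gene is used; when isoforms are present the
longest transcript is canonical.  The upstream region is the 10 kb 5' of the
TSS on the gene's strand, clipped at chromosome bounds (silently — a
truncated window is still a window).  Introns are the gaps between
consecutive exons.

A gene is a target when ≥ 1 hit overlaps (≥ 1 bp) its upstream region,
exons, or introns; the interval-overlap rule is used for motif hits because
hits are narrow, while ChIP peaks — which are wide — are classified by
midpoint.  The per-gene affinity score is the maximum hit score among
contributing hits; the per-species mean affinity averages over target genes
only.  The target ratio divides targets by all annotated genes supplied.

Peak classification uses a fixed precedence — 5'UTR > Coding Exon > 3'UTR >
Intron > UpStream > DownStream > Distal (> 20 kb from every gene) — because
a midpoint can satisfy several labels at once (overlapping genes, UTR inside
exon); the precedence makes classification deterministic and the class
ratios sum to 1 by construction.  Exonic positions in genes without CDS/UTR
sub-annotation count as Coding Exon.

TSS-anchored windows are strand-oriented: TSS_Up ends at the TSS, TSS_Body
starts at it and extends into the gene, TSS_Around is split symmetrically
(the TSS base goes to the downstream half).  Sizes 2.5/5/7.5/10 kb.

## Codon branch models

The substitution model is Goldman–Yang over the 61 sense codons of the
standard genetic code: single-nucleotide changes only, rate ∝ π_j times κ
for transitions and ω for nonsynonymous changes, generator scaled so one
unit of branch length is one expected substitution per codon.  Codon
frequencies default to F3x4 estimated from the alignment (F61 and uniform
available); frequencies are empirical and not counted as free parameters,
so np = (#branches) + 1 (κ) + (#free ω), which reproduces the conventional
branch-model parameter accounting (fixed-ω model has np one less than
one-ratio; a free-ratio model on B branches has np = 2B + 1).

Likelihoods use Felsenstein pruning with site-pattern compression and
per-node rescaling in log space.  Gapped or ambiguous codons are missing
data (all-ones partial likelihoods).  The rate matrix is reversible, so it
is symmetrised with √π and eigendecomposed once per (κ, ω); transition
matrices exp(Qt) are assembled from the cached decomposition, clipped at 0
and row-renormalised against round-off.  Pruning is verified against
brute-force summation over ancestral states on 3–4 taxon trees (1e-8 in log
units) and against re-rooting invariance.

Fitting maximises over log-transformed κ, ω, and branch lengths with
L-BFGS-B (ftol 1e-9; bounds: branch lengths in [1e-6, 50], κ in [0.01,
200], ω in [1e-4, 99]).  The first start uses the input tree's branch
lengths, κ = 2, ω = 0.4; seeded jittered restarts serve as a fallback when
the first optimisation fails to converge.  Free- and two-ratio fits
warm-start from a one-ratio fit, which in practice guarantees the nested
log-likelihood ordering.  Per branch the fitted model is decomposed into
expected nonsynonymous and synonymous substitution counts, N·dN = t·ρ_N·L
and S·dS = t·ρ_S·L where ρ_N + ρ_S = 1 is the equilibrium rate split and L
is the alignment length in codons — the familiar per-branch N·dN/S·dS/ω
report.

The LRT statistic 2Δℓ is clamped at zero within a 1e-3 tolerance; a more
negative value indicates an optimiser failure and raises rather than
producing a silently invalid test.  For the free-ratio comparison df equals
the branch count minus one, i.e. the np difference.

Conservation summaries call a column identical when at most one distinct
non-gap residue occurs; group contrasts call a column "conserved in A but
different/divergent in B" when A is fixed and B is either variable or fixed
for a different residue.

## Comparative methods

*t-test.* Pooled-variance two-sample t (df = n₁ + n₂ − 2), two-tailed, with
a Welch option.  Zero variance with equal means degenerates to t = 0, p = 1;
zero variance with unequal means is an error.

*Phylogenetic ANOVA.* The observed one-way F is compared against F values
from traits simulated under Brownian motion on the tree.  The Brownian rate
is the GLS residual variance about the phylogenetic mean (equivalently the
mean squared independent contrast); the tail probability uses the +1
correction, p = (1 + #{F_sim ≥ F_obs})/(n_sim + 1), so p is never 0.  Under
the null the p-value is uniform on its n_sim + 1 support points, which is
what the type-I calibration checks.

*Threshold model.* Liability ℓ and value x follow a joint Brownian process
with trait covariance [[1, rσ], [rσ, σ²]]; the liability diffusion scale is
fixed at 1 because only the sign of ℓ is observed (binary state = ℓ > 0), so
only r, σ, and the two root means are estimable.  The sampler alternates a
Metropolis sweep over tip liabilities (proposals violating the observed sign
have prior mass zero), a reflected random-walk update of r under a uniform
[−1, 1] prior, a log-scale random walk for σ (flat prior on log σ), and a
joint random walk for the root means.  Because the tree covariance C is
fixed, the Gaussian quadratic form is maintained incrementally (rank-one
updates of Y'C⁻¹Y), making one generation O(n²) at worst and fast in
practice.  Step sizes adapt toward target acceptance rates during the 20%
burn-in only, preserving detailed balance afterwards; r is recorded every
10 generations.  The "95% interval" reported is the central credible
interval of the post-burn-in samples, and the tail statistic is the
posterior P(r ≤ 0), labelled as such.  If the r-update acceptance rate ends
outside [0.1, 0.9] the result carries a warning rather than failing.

*Fold change.* ΔΔCt = (Ct_target − Ct_ref)_state − (Ct_target − Ct_ref)_baseline,
fold = 2^−ΔΔCt; invariant to uniform Ct shifts and reciprocal under swapping
state and baseline.

## Synthetic-data generators

All generators are pure functions of recipe + seed (byte-identical reruns)
and emit truth tables consistent with the emitted files.

The fixture motif is a 20-column nuclear-receptor-style DR1 matrix: a strong
direct-repeat core (consensus base 85/100 per column), a near-uniform
spacer, and moderately informative 5' flanking columns (55/100), about 16
bits in total.  The width and graded information content mirror ChIP-derived
nuclear-receptor matrices; a short, sharply peaked motif would leave only
near-consensus words below the 5×10⁻⁷ threshold and collapse the affinity
statistic onto the consensus score.

A synthetic genome is one chromosome of i.i.d. background (uniform
composition by default) carrying 20 regularly structured genes (4 exons of
200 bp, introns of 1.5 kb, 50 bp terminal UTRs, random strand), each in its
own slot wide enough that the 10 kb upstream window of one gene can never
reach a neighbour — so truth labels cannot leak between genes.  Sites are
planted as Poisson counts per gene region (defaults: 0.5 upstream, 0.2
intron, 0 exon) at planting strength 0.75, where strength interpolates
between sampling each base from the PFM column (0) and always planting the
consensus (1).

A cohort is 64 such genomes on a seeded Yule tree scaled to unit height,
with 16 hibernators occupying a random contiguous block of tips — clumped,
because a real hibernation trait carries phylogenetic signal, and clumping
is the conservative case for the comparative tests.  Hibernators receive a
planting-rate uplift of +0.5 per active region and a strength uplift of
+0.15.  These effect sizes were chosen once to produce a clear but not
trivial contrast (roughly 2 bits of mean affinity and 0.3 of target ratio
between groups at the default genome size).

Codon alignments are simulated forward along the tree from π at the root
using the same eigendecomposed transition matrices as the likelihood; stop
codons cannot arise.  Threshold traits draw bivariate Brownian tips via the
Cholesky factors of the tree and trait covariances and redraw with an
incremented sub-seed (up to 100 times) if the binary trait comes out
constant.  ChIP-peak fixtures place midpoints inside candidate intervals of
the requested class and verify each placement against the annotator's own
precedence rules, so the emitted class labels are exact by construction.

What the generators do **not** emulate: real base composition heterogeneity
(isochores, repeats, CpG islands), realistic gene-structure statistics,
motif clustering in enhancers, alignment error, or rate variation across
codon sites.  Passing the cohort experiments therefore demonstrates that the
pipeline's statistics detect a planted regulatory contrast at realistic
sample sizes — not that any particular real clade shows such a contrast.

## Problem sizes used in the checks

The end-to-end statistical checks run at deliberately scaled-down sizes
chosen to give stable rates at interactive runtimes: false-positive
calibration on 10 Mb of background; ω recovery on 16 taxa × 500 codons; LRT
null calibration on 200 replicates of 8 taxa × 150 codons; phylogenetic
ANOVA type-I error on 500 replicates of a 64-tip tree with 200 null
simulations each; threshold-model coverage on 50 replicates at 4,000
generations (the MCMC default for real use is 100,000); cohort power on 20
replicates of 64 species × 20 genes.  The binomial/Poisson tolerance bands
asserted in the tests are the 99%-ish ranges implied by those replicate
counts.

## Known limitations

- The branch-model optimiser uses finite-difference gradients; on large
  trees an analytic-gradient implementation would be substantially faster.
- F3x4 is the only frequency estimator wired into the fitting path's
  defaults; branch-site and site-class models are out of scope.
- The threshold-model sampler is single-chain; the seed-agreement test
  guards against gross non-convergence but formal diagnostics (R-hat,
  effective sample size) are not computed.
- Peak annotation assumes a flat gene universe; nested or overlapping genes
  are resolved solely by the class precedence order.
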