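# Methods

This note documents the models implemented in `nichevol`, the assumptions
behind them, the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical choices that matter
for reproducing results.

## Characters and coding

Two discrete characters drive all analyses. The preferred-substrate
character (PS) lives on the fixed five-state alphabet *rock, soil, bark,
wood, lichen* ("lichen" = other lichen thalli used as substrate); the
alphabet is never shrunk to the observed states, so rate matrices and
diversification parameter vectors stay comparable across datasets. The
ecological-strategy character (GS) is binary, *generalist/specialist*.
When occurrence counts are available, a species is coded specialist iff the
share of its most frequent substrate is **strictly greater than 0.95**; the
preferred substrate is the argmax substrate, and modal ties for generalists
are flagged rather than broken. The rule is scale-invariant in the counts
and monotone in the threshold. Secondary substrates, if present in a table,
are carried as annotations only — every model here is single-state-per-tip.

Per-state sampling fractions ρᵢ (0 < ρᵢ ≤ 1) are ratios of sampled to
described species; an all-ones scheme expresses the 100%-completeness
scenario. Sampling fractions enter only the SSE tip conditions; clade-level
sampling schemes are out of scope.

## Trees and node identity

Trees are rooted, with branch lengths in arbitrary time units. Ultrametricity
is checked with relative tolerance 1e-6 × tree height; operations that
require it (the λ transform, SSE likelihoods) reject violations, everything
else accepts with the discrepancy visible to the caller. Zero-length
branches are legal and propagate an exact identity map. Polytomies are
accepted natively by the pruning likelihood and rejected by the SSE
likelihood (where the node product is defined for bifurcations only).

Across a posterior sample, topologies vary, so "the same node" is defined by
an **anchor**: a fixed reference tip set whose MRCA is taken in every tree.
Votes and reconstructions are always attached to the MRCA; whether the MRCA
is exactly monophyletic for the reference set is recorded and reported
alongside, never used to discard trees.

Pagel's λ transform multiplies internal branches by λ ∈ [0, 1] and
re-stretches pendant branches so all root-to-tip depths are preserved; λ = 0
is a star phylogeny. Note the total tree length is maximal at λ = 0 — the
pendant stretching dominates the internal shrinking.

## Mk machinery

Rate matrices are built from integer constraint masks: each off-diagonal
cell holds a free-parameter index (ties allowed) or a structural zero.
ER/SYM/ARD are the standard 1, k(k−1)/2, k(k−1)-parameter templates. The
*no-switch* family contains one mask per non-empty proper subset S of
states: every rate out of every state in S is fixed to zero and the
remainder is all-rates-different — 2ᵏ−2 masks, 30 for k = 5, enumerated by
subset size then lexicographically.

Transition probabilities use an eigendecomposition fast path (one
decomposition per likelihood evaluation, vectorised over all branches) with
a scaling-and-squaring (`scipy.linalg.expm`) fallback whenever the
eigenbasis reconstructs Q to worse than 1e-10 — masked matrices can be
defective. The pruning (Felsenstein) likelihood rescales partials per node
and is compiled with numba. Root treatment is configurable: uniform
(default), stationary (long-run distribution from a uniform start, which is
well defined even for reducible/absorbing Q), FitzJohn-conditional, or an
explicit vector.

ML fitting runs in log-rate space with box constraints [1e-9, 1e3]. One-
parameter models use bounded Brent search. Multi-parameter models start
from the shared-rate (ER) optimum — a cheap, well-scaled initial point for
any mask — and refine with L-BFGS-B (ftol 1e-9); additional restarts jitter
the start in log space (σ = 1.5). Spot checks against high-effort fits
(maxfun 8000, multiple restarts) show agreement to < 0.01 log-likelihood
units at the default budgets, well below any AIC decision margin used here.
Failures surface as `converged=False` (AIC = ∞) and are excluded from rank
summaries, never raised.

Marginal ancestral states use the standard inside–outside pass; stochastic
maps sample node states exactly from their joint conditional distribution
(up-pass partials, root-to-tip sampling) and branch histories by
uniformization with dominating rate max|Qᵢᵢ|, which is exact; below
Ωt < 1e-8 a branch is treated as event-free (or, for discordant endpoints,
as carrying the single dominant event). Per-map transition counts are exact
event counts, and the per-node sampled-state frequencies converge to the
marginal reconstruction (verified at 10 000 maps in the test suite).

## Phylogenetic-signal tests

Both tests compare the observed character to tip-label permutations and use
the add-one estimator p = (1 + #{null at least as extreme})/(1 + n_perm),
which is never zero; exact ties count as extreme, so the λ = 0 star-tree
scenario — where the likelihood is permutation-invariant — yields p = 1 by
construction. Default 999 permutations (199 in calibration batches), one
RNG stream per tree.

The λ test fits an equal-rates Mk model on the λ-transformed tree; the
scenario grid defaults to λ ∈ {0, 0.25, 0.5, 0.75, 1}. The ER restriction
keeps the statistic one-dimensional, which allows an exact closed-form
propagator and a vectorised ternary search over log-rate for the observed
data and all permutations simultaneously. The distance test's statistic is
the mean patristic distance over unordered same-state tip pairs, per state
and pooled; states with fewer than two tips are reported untestable with
their tip counts so power caveats stay visible. Under i.i.d. tip labels
both tests reject at the nominal 5% level (calibration checked over 400
replicates in the acceptance suite).

## Ensemble ancestral reconstruction

The default grids are the full documented products: for multi-state
characters, marginal-ML under {ER, SYM, ARD} × {uniform, stationary,
conditional} root priors plus stochastic mapping under each model (12
cells); for binary characters SYM collapses into ER, leaving 8 cells. Grids
are plain data and fully configurable. Per tree × cell the point state at
each anchored node is the marginal argmax (ML cells) or the modal sampled
node state (mapping cells); failed fits accumulate in a failure ledger so
votes + failures always equal trees × cells. Node summaries report the
majority state, the vote margin, per-method tallies and the anchor's
monophyly fraction; ties are reported as ties.

## Dead-end model ranking

Every no-switch model is fitted to every tree; per tree, models are ranked
by AIC with dense ranks (ties within 1e-6 share a rank; exact ties order by
fewer parameters, then model order). The headline summary counts, per
model, the trees on which it ranks within the top five, and returns the
models exceeding a strict majority of non-dropped trees.

A structural caveat, confirmed both analytically and in simulation: with a
single truly absorbing state W and informative data, the ranking interleaves
{W}, {X₁+W}, {X₁}, {X₂+W}, … because adding the true W constraint to any
mask is free in likelihood and worth a fixed 8-point AIC discount, while the
penalty for constraining a free state X varies by tens of units across
states. The top-five window therefore almost always admits the singleton
mask of the weakest-identified free state alongside the W-containing
models. Consequently "every windowed winner contains W" is a
realization-lucky event, not a reproducible property — the corresponding
acceptance check is left failing with this analysis on record. The same
phenomenon appears in the empirical system this package models, where
combination masks outranked the single-substrate mask.

## MuSSE

The likelihood integrates, per branch, the coupled equations

    dEᵢ/dt = μᵢ − (λᵢ + μᵢ + Σⱼqᵢⱼ)Eᵢ + Σⱼ qᵢⱼEⱼ + λᵢEᵢ²
    dDᵢ/dt =     − (λᵢ + μᵢ + Σⱼqᵢⱼ)Dᵢ + Σⱼ qᵢⱼDⱼ + 2λᵢEᵢDᵢ

with tip conditions Dᵢ(0) = ρᵢ·1[state = i], Eᵢ(0) = 1 − ρᵢ, node joins
Dᵢ ← λᵢ Dᵢᴸ Dᵢᴿ, per-node rescaling of D, FitzJohn root weighting by
default (uniform and explicit weights available), and optional survival
conditioning Dᵢ/(λᵢ(1 − Eᵢ)²). Integration is adaptive Cash–Karp RK4(5),
rtol 1e-9 / atol 1e-12 (relaxed to 1e-7 inside ML searches, with the
returned optimum re-evaluated at full precision). These tolerances hold the
accumulated log-likelihood error below ~1e-8 across a few hundred branches,
tight enough for the closed-form reductions the suite checks: k = 1 with
μ = 0 reproduces the Yule likelihood; k = 1 with μ > 0 reproduces the
constant-rate birth–death closed form (whose per-branch factors depend on
node *ages*, since extinction probability accumulates from the tips); equal
rates across states factorise into birth–death × Mk.

ML fitting mirrors the Mk fitter (log space, Nelder–Mead with box bounds,
restarts); λ and μ can be tied across states (the character-independent
reductions) or μ fixed (pure birth). MCMC is random-walk
Metropolis–Hastings on log parameters with independent Exponential priors
(mean 1 by default) and scale adaptation toward 23% acceptance during
burn-in only; a prior-only target (no tree) is supported and recovers the
prior in expectation. Defaults: 10 000 steps, 10% burn-in; when pooling
across many trees the pipeline runs 1 000-step per-tree chains, matching
the pooled-density use of the output. Diversification summaries pool
r = λ − μ draws per state with quantiles and a Gaussian KDE; pairwise state
comparisons use the two-sided Mann–Whitney test (exact enumeration for
tie-free samples of ≤ 8, tie-corrected normal approximation otherwise).

The trait-independence test simulates neutral characters under symmetric
Mk(q) on a fixed tree and counts how often the character-dependent model
beats the character-independent one (likelihood-ratio test at α = 0.05).
On a pure-birth tree the fitted class should also be pure birth
(`fix_mu=0`, df = 1): leaving μ free puts its true value on the boundary of
the parameter space, the LRT null drops below the χ² reference, and the
test becomes conservative — measured rejection rates near zero rather than
5%. With the matched class the false-positive rate is calibrated (checked
at 200 simulations).

## Synthetic data

The generator emulates the empirical study design: birth–death chronograms
conditioned on a tip count (forward simulation stopped at a uniform time
inside the n-lineage interval, so pendant branches are strictly positive;
extinct lineages pruned; full-extinction attempts resampled), posterior-set
emulation by i.i.d. lognormal branch-length jitter (σ = `jitter`) with
pendant re-stretching to restore ultrametricity and optional NNI moves for
topological variation, forward Mk simulation with retainable full histories,
and joint MuSSE tree+character simulation with optional ρ-subsampling. The
bundled demo dataset mirrors the empirical scale — 100 tips, 100 trees, a
five-state substrate character with a handful of expected changes across the
tree (strong clustering), a correlated binary strategy character and a
consistent occurrence table.

What the generator does **not** emulate: real posterior samples correlate
branch lengths and topology through the data (jitter is i.i.d.), empirical
substrate assignments carry observation error and secondary substrates, and
real clades violate the constant-rates birth–death assumption. Passing
tests therefore demonstrate correctness and calibration of the machinery
under its own assumptions, not robustness to their violation.

## Problem sizes in the test suite

The acceptance-level checks run at the following scales, chosen as the
package's desk-scale study conditions: the full 30 × 100 dead-end grid on
100-tip trees (optimizer budget 400 evaluations per fit — rank bookkeeping,
not rank quality, is under test there); permutation calibration at 400
replicates × 199 permutations on a 50-tip tree; stochastic-map consistency
at 10 000 maps (12 tips) and 100 000 conditional branch draws;
dead-end recovery on 200-tip trees × 20 jittered replicates with converged
fits (budget 1 500); MuSSE rank recovery at 500 tips × 10 replicates;
trait-independence calibration at 200 simulations on a 60-tip pure-birth
tree. Exact-oracle checks (enumeration, closed forms) use ≤ 6-tip trees
where brute force is feasible.

## Known limitations

- Hidden-rate (covarion/precursor) models, model averaging over masks,
  Bayes-factor comparisons, HiSSE-style hidden states and time-varying
  rates are out of scope.
- The SSE likelihood requires binary trees; resolve polytomies upstream.
- The MCMC is a plain adaptive random-walk sampler; for large parameter
  counts (full 5-state MuSSE has 30 parameters) mixing is slow and chains
  should be long or reparameterised externally.
- `stationary_distribution` of a reducible Q returns the long-run
  distribution from a uniform start — one defensible choice among several
  for absorbing chains.
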