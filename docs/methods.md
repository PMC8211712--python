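# Methods

`karstrad` implements the quantitative battery used to diagnose adaptive
radiation on a time-calibrated phylogeny: did lineage accumulation,
ecological (habitat) diversification and morphological disparification
accelerate together at some point in a clade's history, and did
independent subclades converge on shared adaptive peaks?  This note
records the models, their assumptions, the numerical choices, and what
the synthetic data generator does and does not emulate.

## The tree substrate

Every analysis consumes a rooted, binary, ultrametric chronogram with
branch lengths in millions of years (My).  Ages are measured backward
from the present (tips at age 0); every "shift age" parameter is an age
in this sense.  Polytomies are resolved deterministically (lexicographic
by smallest descendant label) into zero-length binary splits, because
consensus trees routinely contain them.  Ultrametricity is enforced with
a relative tolerance of 1e-6 times tree height, which absorbs the
rounding that Newick serialisation introduces.

## Lineage accumulation

The gamma statistic standardises the position of internal-node times
against a constant-rates expectation; negative values mean nodes are
concentrated early ("early burst" followed by slowdown).  With `g_k` the
duration during which the reconstructed tree has exactly `k` lineages and
`T = sum k*g_k`:

    gamma = [ mean_{i=2..n-1} sum_{k=2..i} k*g_k  -  T/2 ] / ( T * sqrt(1/(12(n-2))) )

The Monte-Carlo test simulates pure-birth nulls conditioned on the same
tip count.  Under pure birth the `g_k` are independent Exponential(k*λ)
and gamma is invariant to λ, so nulls are drawn directly on the interval
representation — exact, and far cheaper than building trees.  The p-value
is one-sided (lower tail; the hypothesis is directional) with the
(r+1)/(N+1) correction, so it is never exactly zero.

## Birth-death and diversity-dependent model selection

The model family allows speciation rate λ, extinction rate μ and a
carrying capacity K to shift at an age `t_shift`; diversity dependence is
linear, `λ(N) = max(0, λ0 - (λ0-μ) N/K)`.  The likelihood of the
branching times is computed from a master equation over the number of
*hidden* lineages (alive at some time but leaving no sampled
descendants), integrated between successive branching events:

* a hidden lineage is born from a hidden parent (rate `n λ_N`) or as
  either daughter of an observed parent (rate `2k λ_N`);
* hidden lineages die at rate `μ`; observed lineages carry the exposure
  discount `(λ_N + μ)` with death forbidden (the per-lineage D/E
  accounting of state-dependent birth-death likelihoods);
* each observed branching contributes a factor `λ_N`, and the likelihood
  is the weight of zero hidden lineages at the present.

For constant rates this reproduces the classical closed-form birth-death
likelihood (verified to 1e-14); with μ = 0 only the zero-hidden state is
reachable and the computation collapses to a fast closed form.  The state
space is truncated at `N_max = max(2K, n+100)` capped at `n+600` (with a
warning if boundary mass exceeds 1e-8), and the likelihood is conditioned
on survival of both crown lineages — computed exactly for constant rates,
by a two-dimensional descendant-count master equation under diversity
dependence, and equal to 1 for pure birth.

Fitting uses bounded quasi-Newton optimisation from deterministic
multi-starts; a free shift age is first profiled on a 0.5-My grid across
the central 90% of the tree depth and then refined jointly.  Models are
compared with AIC and Akaike weights `w_i = exp(-Δ_i/2)/Σ exp(-Δ_j/2)`.
A pure-birth variant of the family (μ fixed at 0) is provided for systems
where estimated extinction is negligible; it is the default in the
pipeline because every likelihood evaluation is then closed-form.

## Habitat evolution: Mk, stochastic maps, CTT

Habitat categories evolve under a continuous-time Markov chain.  The
default structure is symmetric (SYM) — matching time-reversibility with a
flat root prior — because six states under all-rates-different means 30
rates, overparameterised at a few hundred tips; ER and ARD are available.
Tips with unknown habitat enter the pruning likelihood as a vector of
ones (equal probability on every state).  Rates are bounded above at ~20
expected changes per average branch: beyond that the chain is saturated,
the likelihood flat, and endpoint-conditioned path sampling pathological.

Stochastic maps draw node states from their joint conditional
distribution (pruning pass up, sampling pass down) and within-branch
histories by uniformization conditioned on the branch endpoints, with
per-branch caching of transition matrices and jump-chain powers.  The
changes-through-time (CTT) curve is the mean number of changes across
maps divided by the total branch length present in each of 50 equal-width
age bins (binning is a free choice; 50 is the default).  The conservation
identity `sum_bins value * edge_length = mean changes per map` holds
exactly by construction and is asserted in tests.

The CTT null test simulates tip data forward under the fitted Q (root
from the flat prior).  By default each null replicate then samples
stochastic maps *conditioned on its own simulated tips* and averages
them, exactly as the observed curve was built — this makes null and
observed curves exchangeable, so the rank envelope test is calibrated.
The literal alternative (each free forward history used directly as one
null curve) is available via `conditioned=False`.

## Morphological disparity

Disparity is the mean squared pairwise Euclidean distance among species
in trait space.  The DTT curve visits divergence events from the root
toward the present; at each event every lineage crossing that moment
defines a subclade, and the curve records the mean of subclade
disparity / whole-clade disparity (singleton subclades contribute 0).
The curve opens at 1.0 (before the root event the single ancestral
lineage's "subclade" is the whole clade) and the root event itself is the
two-crown-subclade average.  Species missing any trait are removed
listwise and the tree pruned accordingly.

Nulls are drawn from multivariate Brownian motion with the full REML rate
matrix estimated from the data (an independent-traits null would
miscalibrate for correlated traits); tip values are sampled directly from
the exact BM tip distribution `N(0, C ⊗ Σ)`.  The MDI is the trapezoidal
integral over relative time of (observed − null mean), integrated over
the whole curve; both a two-sided and a one-sided (disparity above null)
Monte-Carlo p are reported, since the directionality convention is a
user choice.

The rank envelope test scores every curve by its most extreme pointwise
rank (from below or above) across the grid and reports a p-interval.
Ties share the *less* extreme rank: a value tied with many others (e.g.
bins tied at zero) is not evidence of extremity.  Two practical points
follow from the discrete ranks: the liberal interval bound is only
near-exact when the number of simulations is much larger than the number
of grid points (a few hundred simulations per ten grid points), while the
conservative bound never exceeds its level; calibration tests therefore
decide at the conservative bound unless simulations dominate the grid.

## Trait geometry

Size correction regresses each trait on body length by GLS with Brownian
covariance (intercept included) and keeps the residuals; body length
itself stays raw (optionally log-transformed; default untransformed).
Phylogenetic PCA eigen-decomposes the GLS-estimated evolutionary
covariance and projects the GLS-centred data; on a star tree this reduces
exactly to ordinary PCA.  The node height test regresses the absolute
standardized independent contrast on node height (root-to-node distance)
with OLS and a two-sided t-test; a positive slope means rates increase
toward the present.  Morphotypes are delimited by Ward's hierarchical
clustering on Euclidean distances with deterministic label-order
tie-breaking; the reference dataset uses k = 9 groups.

## Multivariate trait models with a fixed-time shift

The comparison set holds BM, EB/ACDC (rate `σ² e^{r u}`; r < 0
decelerates, r > 0 is the accelerating ACDC variant) and OU as
single-process models, plus every ordered mode pair switching at a fixed
shift age (taken from the diversification analysis, not optimised), with
and without "independent drift" (a separate rate matrix for the second
phase).  The tip covariance is additive across phases: each phase
accumulates variance over the part of the shared root-to-MRCA path inside
its age window under its own time transform, with the EB/OU clock
starting at the phase boundary; trait dimensions enter as Kronecker
products with the phase rate matrix.  The mean vector is profiled by GLS;
rate matrices are parameterised by log-diagonal Cholesky factors; r and α
get deterministic multi-starts because their profiles can be multimodal.
Parameter counts are derived from the parameterisation (e.g. 2 traits:
BM = 5, BM→EB = 6, BM→EB with independent drift = 9).

## Convergence (stepwise Hansen model)

The Hansen model paints branches with regimes; a tip's expectation is the
α-weighted mixture of the optima along its path (the root sits at the
root regime's optimum), covariance is the fixed-root OU form, and traits
are independent given the painting, each with its own α and σ² shared
across regimes.  The forward phase proposes a new regime on every branch
and accepts the best AICc improvement (AICc with sample size = tips ×
traits); the backward phase greedily merges regime pairs while AICc
drops.  Regimes reached by more than one origin (root or shift) after
merging are convergent peaks.

Because the forward phase takes the best of ~#branches candidates at
every step, a raw AICc rule admits spurious regimes on perfectly
homogeneous data (measured: best-of-candidates likelihood-ratio inflation
of 8-17 against a penalty of ~4).  Acceptance therefore additionally
requires the improvement `2ΔlogL` to exceed the chi-square(p) quantile at
`1 - 0.01/#branches` — a Bonferroni-corrected gate at the strict 1% level,
chosen because the selection repeats across steps.  This keeps the
false-positive rate on single-regime data near zero while leaving
detection of genuinely displaced optima (which improve the likelihood by
tens of units) untouched.  During the search α is profiled on a cached
16-point log grid (1e-4 to 20 per My) and refined continuously only for
the final model.

## Ancestral geography

Coordinates are embedded on the unit sphere, `(cos lat cos lon,
cos lat sin lon, sin lat)`, and each Cartesian axis treated as an
independent Brownian trait with a common REML rate (isotropy of the
embedding).  Because the Brownian posterior of any ancestral value —
node or along-branch time slice — is Gaussian given the tips, ancestral
locations are sampled from the exact conditional distribution rather
than by MCMC; samples are renormalised to the sphere.  The 95% credible
region discards the 5% of samples with the largest great-circle distance
from the normalised mean-vector centroid.  Renormalisation makes the
method sensible for continental extents; for near-antipodal spreads the
centroid degenerates and an error is raised.

## The synthetic reference dataset

`make_reference_dataset` emulates the study conditions end to end:
377 tips, crown age 47 My, six monophyletic focal clades of sizes
28/41/29/41/38/25, habitat known for 331 tips, morphometrics for 256.
The tree is built by an exact point-process sampler: under time-varying
pure birth conditioned on n tips and crown age T, non-crown node ages are
iid with density ∝ λ(t)·exp(-Λ(t)), invertible analytically for
piecewise-constant rates; topology follows by forward random joining.
The backbone runs slow (λ = 0.06/My) before the 15.7-My shift, fast
after it, and decelerates again from 5 My (λ = 0.05/My) — the
niche-filling slowdown that makes the genus-level gamma strongly negative
while model selection still places the speciation-rate shift near
15.7 My.  Focal clades radiate at λ = 0.26/My from crown ages drawn in
11-15.5 My with the same terminal slowdown.  Habitats evolve under a
symmetric 6-state chain at 0.012/My; the 11 traits under correlated BM
(pairwise correlation 0.3) whose rate jumps 6-fold at the shift,
emulating the late disparification; body length is exponentiated around
10 mm; coordinates follow spherical BM from a Western-European origin.
General simulators (`sim_tree` forward birth-death with retries,
`sim_discrete` exact Gillespie, `sim_traits`, `sim_regime_traits`) cover
arbitrary parameter choices, with every stochastic operation taking an
explicit seed.

What the generator does *not* emulate: phylogenetic uncertainty (one
tree, not a posterior sample), non-random missingness (museum specimens
are missing in clumps; here missing tips are uniform draws so clade
definitions stay valid), measurement error in traits, habitat-dependent
diversification, and any correlation between habitat and morphology.
Passing tests therefore demonstrate that the estimators recover the
processes they model, not that those processes describe any real clade.

## Problem sizes

Routine tests and the acceptance script run at desk scale: recovery and
calibration loops use tens to a few hundred replicates on trees of
25-150 tips, stochastic-map checks use up to 10,000 maps on toy trees,
the reference-dataset analyses run at the full 377 tips with 500-1000
null simulations, and the convergence search runs on a 69-tip two-clade
subset (mirroring the pruned two-clade rerun design).  These sizes are
stated in each test and in `scripts/acceptance.py` alongside the
quantity they produce.

## Known limitations

* The diversity-dependent likelihood assumes complete extant sampling and
  linear diversity dependence; no fossilised or sampled-ancestor variants.
* The shifted trait models add phase variances rather than propagating
  OU decay across the boundary; for strongly attracting first phases this
  additive convention differs from a fully path-integrated two-phase OU.
* SURFACE-style search is greedy; near-ties between shift placements are
  visible in the recorded forward path but not enumerated exhaustively.
* The rank envelope p-interval is meaningful only relative to its
  simulation count; with few simulations the interval is wide and only
  the conservative bound should be used for decisions.
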