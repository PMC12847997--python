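# Methods

This note documents the models, estimators, and design choices behind
`cohortseq`: what each stage assumes, which parameters matter, what the
synthetic generator does and does not emulate, and the numerical decisions a
user reproducing or extending the analyses should know about.

## Corpus model and conventions

The unit of analysis is the utterance: an ordered sequence of
(surface, category) tokens with a 1-based position index, a speaker role and
an optional speaker age in months. All modules share the 1-based position
convention. Corpora are exchanged as a one-token-per-line TSV
(`utterance_id, position, surface, pos, speaker_role, age_months`);
surfaces are lowercased on read, and part-of-speech tags are kept as literal
strings (no tagset normalization beyond case), because tagset granularity is
itself an analytic choice and the pipeline treats the tagset as data.

Age stratification uses half-open `[low, high)` bands in months and
explicitly permits overlapping bands — developmental cohort definitions
often overlap (e.g., a 3–6-year band and a 5–12-year band), and an utterance
whose age falls in two bands belongs to both. Cohort balancing samples whole
utterances uniformly without replacement until a token target is reached,
preserving original order; utterances are never split, because every
downstream statistic is sequence-positional. The realized token count lies
within one maximum-utterance-length of the target. Positional truncation
(default: position 25) drops tokens beyond a cutoff and reports the removed
fraction; beyond such a cutoff positions are too sparse to estimate
position-specific quantities reliably.

## Synthetic generator

The generator realizes exactly the structures the estimators measure:

* **Lengths**: i.i.d. Geometric(p) — `p` is the per-step termination
  probability — truncated at `max_length` (default 50) by rejection
  sampling. For `p ≥ 0.3` the truncated tail mass is below 1e-7, so
  truncation bias is negligible at the supports used here.
* **Categories**: a first-order Markov chain over the category set with a
  configurable initial distribution and row-stochastic transition matrix.
* **Surfaces**: given category `c` at position `i`, a synthetic lexeme is
  drawn from `c`'s vocabulary with Zipf weights `rank^(-s)` over an
  *effective* vocabulary `clip(round(V · exp(g·(i−1))), 1, V)`. The
  gradient `g` is a phenomenological control of where in the utterance
  lexical variety concentrates; it does not assert any mechanism for that
  concentration in real speech.

`ground_truth_summary` returns the analytic targets implied by a
configuration: the expected position rank-fit slope `log10(1−p)`, the
entropy of the (truncated, renormalized) length distribution by direct
summation — indistinguishable from the closed form
`[−p·log2 p − (1−p)·log2(1−p)]/p` at these supports — the stationary
distribution of the transition matrix, and the stationary adjacent-pair
mutual information by direct summation over joint outcomes.

Each corpus is produced by one seeded numpy generator and is fully
vectorized; identical configurations (including seed) yield identical
corpora. Per-utterance substreams were considered and rejected: generation
is never parallelized within a corpus, so substreams would add complexity
without changing any guarantee.

What the generator does **not** emulate: realistic vocabulary, morphology,
prosody, semantics, speaker turn structure, or the heavy-tailed
length/frequency deviations of real speech. Passing tests therefore show
that the *estimators* recover known structure, not that real corpora have
that structure.

## Sequence information measures

All information measures use base-2 logarithms (bits) and plug-in
(maximum-likelihood) estimators without bias correction: the intended
corpus scale is 1e5–1e6 tokens per cohort, where plug-in bias
(≈ (cells−1)/(2n·ln2)) is small except at very sparse positions, which a
minimum cell count excludes anyway. Rank–frequency fits use base-10 logs,
so the position-histogram slope is directly `log10(1−p)`.

* **Rank–frequency fit**: OLS of log10(count) on rank, ranks by descending
  count with ties broken stably by label. Cells below `min_count`
  (default 1; the positional pipeline uses 50) are dropped before fitting:
  log-counts of near-empty cells are Poisson-noise dominated and would
  spuriously depress R² for a genuinely geometric distribution. The full
  record (slope, SE, t, 95% CI, R², n, df = n−2) is returned.
* **Adjacent MI**: computed over within-utterance adjacent category pairs
  only — windows and pairs never cross utterance boundaries, since boundary
  effects are the object of study. Marginals come from the same pair table
  (first and second pair elements), so aggregate MI is exactly the
  direct-summation value on the pooled table. Positional MI restricts the
  table to pairs starting at a position.
* **JSD**: order 1 compares each position's category distribution to the
  corpus-wide (token-weighted) category distribution; order 2 does the same
  for the adjacent-pair joint. JSD(P‖Q) = ½KL(P‖M) + ½KL(Q‖M), M = ½(P+Q),
  bounded by 1 bit. Note the baseline is token-weighted, so early positions
  dominate it; with geometric lengths roughly `p` of all tokens sit at
  position 1. Interior positions therefore carry a small constant
  divergence from the baseline, and "boundary concentration" manifests as
  the position-1 value exceeding interior values, not as interior values
  near zero.
* **Positional sparsity floor**: positions (or position×category cells)
  with fewer than 50 observations are omitted from positional profiles by
  default; sparser cells are dominated by estimation noise.
* **Lexical diversity**: type–token ratio (TTR) per (position, category)
  cell. TTR is confounded with cell size: under geometric lengths, late
  positions have geometrically fewer tokens and hence inflated raw TTR. The
  `rarefy=m` option reports instead the expected number of distinct types
  among `m` draws without replacement (exact hypergeometric expectation,
  deterministic), divided by `m`. Cross-position and cross-cohort diversity
  comparisons in this package's own analyses use the rarefied form; the
  plain TTR remains the default output. Which diversity index best reflects
  "lexical diversity" in developmental data is an open question; TTR is
  this package's explicit choice and is labeled as such in outputs.

## Embeddings

CBOW and skipgram with negative sampling are implemented in-package (a
single-threaded numba kernel) rather than delegated, so that training is
bit-reproducible for a fixed seed and context windows can be truncated at
utterance boundaries. Defaults: 15 dimensions, symmetric window 5, 20
epochs, 5 negatives from the unigram distribution raised to 3/4, initial
learning rate 0.01 decaying linearly to 1e-4 of its initial value. The
window is fixed (not sampled per token). `min_count` defaults to 1:
cohort-stratified corpora are small, and discarding rare words would bias
exactly the open-class categories of interest. No frequent-word subsampling
is applied. Input vectors initialize uniformly in ±0.5/dim; output vectors
at zero; with `epochs=0` the returned vectors equal the seeded
initialization.

Correctness is established without a reference implementation by (a) the
theoretical anchor that the negative-sampling objective's optimum is a
shifted-PMI factorization, tested as a rank correlation between learned
input·output scores and windowed PMI; (b) exchangeability — words with
identical context distributions converge to nearby vectors; (c) monotone
decrease of the epoch-averaged objective; and (d) category separability on
corpora with divergent transition rows.

The position-coded sequence variant interleaves a marker token `<p{i}>`
*before* the content token originally at position i (markers carry a
dedicated category tag and enter the vocabulary); the marker-before-token
dialect is fixed here as a convention.

## Representational geometry

Distances: cosine (1 − cosine similarity, range [0, 2]), Euclidean, and
Mahalanobis with the pooled covariance of the analyzed word set,
ridge-regularized with λ = 1e-3·trace(S)/dim so the metric stays defined
when the word set is smaller than the embedding dimension.

The Mantel statistic is the Pearson (default) or Spearman correlation of
the upper-triangle off-diagonal entries; the null permutes rows and columns
of the first matrix jointly; the one-sided p-value is
(1+#{perm ≥ obs})/(1+N) for sampled permutations, or the exact proportion
over all n! permutations when enumeration is requested (n ≤ 8).

Procrustes is the symmetric variant: both configurations centered and
scaled to unit Frobenius norm, optimal rotation from the SVD of XᵀY,
optimal scaling = the sum of singular values d, so ss = 1 − d² and the
Procrustes correlation R = √(1−ss). Per-point residuals localize misfit;
the protest-style test permutes rows of the second configuration. Different
column counts are reconciled by zero-padding; distance matrices enter
Procrustes via classical (Torgerson) multidimensional scaling. When cohort
vocabularies differ, comparisons use the vocabulary intersection.

t-SNE uses the exact (non-approximate) algorithm at perplexity 20 with
early exaggeration 12 — point counts in these analyses are at most a few
hundred — behind scikit-learn's implementation; the final KL divergence and
seed are recorded with the map.

## Positional smooth model

The positional model is a penalized-likelihood GAM fitted by
penalized IRLS:

    g(E[y]) = β₀ + parametric(cohort×category) + f(position) + f_cohort(position)

with a cubic B-spline basis (default dimension 10, uniform knots). The
global smooth carries a second-order difference penalty (null space: the
linear-in-link trend); each cohort factor smooth carries a first-order
difference penalty plus a null-space ridge, so increasing its smoothing
parameter shrinks the whole deviation to zero — deviations are penalized
toward the shared curve. Each basis is centered by absorbing the
sum-to-zero constraint, leaving constants to the unpenalized parametric
part. The default family is Gamma with log link: positional responses such
as diversity are positive and right-skewed. For this family the IRLS weight
equals the prior weight, so the working normal equations are cheap to
iterate.

Smoothing parameters are chosen by generalized cross-validation on the
deviance, GCV = n·D/(n−EDF)², by coordinate descent over a log-spaced grid
traversed from large to small λ so exact ties resolve to the smoother fit
(REML was deliberately not implemented; the curve/EDF contract this package
exposes does not depend on the selection criterion's fine structure, and
GCV keeps the fit self-contained). Per-term EDF is the trace of the
corresponding block of (XᵀWX+S)⁻¹XᵀWX; credible bands are Wald bands from
the penalized-coefficient covariance scaled by the deviance-based scale
estimate (Bayesian-style bands, not bootstrap). The penalty orders are
recorded in the fit metadata. Basis-dimension adequacy can be checked by
refitting at twice the dimension and comparing curves/EDF.

## The four-cohort reference study

`cohortseq.study` fixes the package's canonical simulated study: four cohorts
(TO, 3PLUS, 5PLUS, ADULT) with termination probabilities 0.45/0.42/0.40/0.38,
transition determinism α = 0.30/0.45/0.60/0.75 (α-mixture of a cyclic kernel
with the uniform kernel, keeping the stationary distribution uniform), a
shared concentrated utterance-initial category distribution, base
vocabularies 250/200/160/120 per category, and diversity gradients
−0.18/−0.10/−0.045/0.0. These values are fixed study conditions, not tuning
knobs: together they produce, by construction, the qualitative pattern the
pipeline is designed to detect — aggregate MI rising with age, boundary-
concentrated JSD rising with age, position rank-fit slopes flattening from
log10(0.55) ≈ −0.260 to log10(0.62) ≈ −0.208, segmentation entropy rising,
and the cohort ordering of rarefied initial-position diversity reversing by
late positions. The default scale (60,000 utterances per cohort, roughly
130k–160k tokens) keeps a full pipeline run to seconds while leaving every
positional cell above the sparsity floor through position 10.

## Numerical and degenerate-input conventions

* Seeds: every stochastic operation takes an explicit integer seed; cohort
  series and balancing derive per-cohort streams from a master seed via
  `SeedSequence`.
* Ties in ranking are broken stably by label after descending count.
* Distance matrices are symmetrized, clipped at zero, and forced to a zero
  diagonal before validation; symmetry is enforced to 1e-10.
* Degenerate inputs raise typed errors: empty corpora, all-singleton
  utterances for MI, constant upper triangles for Mantel, fewer than three
  points or all-identical configurations for Procrustes, non-positive
  responses under the Gamma family, infeasible perplexity for t-SNE.
* `p = 1` lengths are all 1, and the expected rank slope is −∞; the
  generator handles it, downstream pair statistics correctly refuse.

## Known limitations

* Plug-in information estimators are biased upward at sparse cells; the
  sparsity floor controls but does not remove this (visible as a mild rise
  of second-order JSD at late positions in small corpora).
* The GAM's GCV grid search optimizes two smoothing parameters (global,
  shared factor) rather than one per cohort; strongly heterogeneous cohort
  wiggliness would be better served by per-cohort λ.
* The embedding trainer is deliberately single-threaded for exact
  reproducibility; it is fast at the corpus scales used here but not tuned
  for corpora orders of magnitude larger.
* The synthetic generator's diversity gradient can only shrink the
  effective vocabulary relative to its base size; growing diversity across
  cohorts is expressed through the base vocabulary and a flatter gradient.
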