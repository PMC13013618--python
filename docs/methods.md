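# Methods

`knowmap` estimates what a learner knows — concept by concept — from short
multiple-choice quizzes, by embedding lecture content and quiz questions in a
shared topic space and treating quiz correctness as noisy observations of a
smooth latent knowledge field over that space. This note documents the model,
the numerical choices, the synthetic study the test-suite runs against, and
the limitations of both.

## Text embedding

Each lecture transcript (one caption line every few seconds) is decomposed
into overlapping sliding windows of up to `w = 30` lines. Windows *ramp* at
both ends — the first window covers line 0 alone, the second lines 0–1, and
so on, with a mirrored ramp-down — so that every line contributes to exactly
`w` windows and no part of a lecture is over-represented in the training
corpus. A transcript with `n` lines yields `n + w − 1` windows; when `w > n`
the construction repeats the full-coverage span so both guarantees still
hold (windows are positional, not unique spans). Each window's timestamp is
the midpoint of its first and last line start times.

Window text is lower-cased, stripped of punctuation, lemmatized, and
filtered against the standard English stop-word list augmented with 20
corpus-specific stop-words ("actual", "actually", "also", "bit", …). The
lemmatizer is a compact rule-based English lemmatizer (plural and verbal
suffixes plus a table of frequent irregulars); it is a configuration option
recorded in run metadata, and any standard lemmatizer can be substituted.

The pooled windows of all lectures train a single Latent Dirichlet
Allocation model (scikit-learn's batch variational implementation) with
symmetric priors `1/k` and enough batch passes (default 50) for held-out
perplexity to plateau on desk-scale corpora; the fit is bit-reproducible
under a fixed seed. The number of topics is chosen as the smallest `k`
whose fitted model leaves at least one *unused* topic — word weights uniform
to within 1% relative deviation — indicating `k` exceeds the corpus's latent
support. With variational LDA an extra topic or two beyond the true support
may still be used to split real themes, so the selected `k` typically
overshoots the generative topic count slightly; the selection rule, not a
particular offset, is the contract.

Every window is embedded as a `k`-simplex topic vector, and each lecture's
window sequence is linearly interpolated (per topic dimension, then
re-normalized against floating-point drift) to one vector per second of
video. Question texts are embedded with the same model; documents with no
in-vocabulary tokens embed to the uniform vector `1/k` (the LDA prior mean).

## Knowledge estimation

A participant's knowledge about the concept at coordinate `x` is the
correlation-weighted proportion of quiz questions they answered correctly:

    k̂(x) = Σ_{i ∈ correct} ncorr(x, q_i) / Σ_{j=1..N} ncorr(x, q_j)

where `ncorr` is the Pearson correlation min–max normalized to [0, 1] over
the relevant (timepoint × question) correlation set, so every question
contributes a non-negative weight. Degenerate cases are defined explicitly:
if all relevant correlations are equal, every pair gets weight 1 and the
estimator reduces to the plain proportion correct; if a query point receives
zero total weight, the proportion correct is returned with a warning.
Zero-variance (uniform) vectors correlate 0 with everything.

Evaluating k̂ along a lecture trajectory gives a per-second *knowledge
trace*; quiz-to-quiz changes in its time average are compared with two-sided
paired t-tests across participants.

### Held-out estimation and rebalancing

To test predictive validity, each answered question is held out in turn and
k̂ is evaluated at its coordinate from the remaining questions — either all
other questions on the quiz, the other questions about the same lecture, or
the questions about the other lecture. For the first two modes the target's
own correctness shifts the candidates' proportion correct, so a rebalancing
correction pairs the target with each opposite-correctness candidate in
turn, estimates from the rest, and averages; every subset then contains
`n − 1` correct answers out of `q − 2` items, making the null expectation
`(n−1)/(q−2)` identical for correct and incorrect targets. Participants
with single-label quizzes cannot be rebalanced and are excluded for that
quiz. Normalization bounds for each held-out estimate are computed over the
candidate set actually used (target excluded), mirroring the per-lecture,
per-quiz bound rule of the trace estimator.

## Mixed-model validation

Per quiz and estimation mode, a logistic mixed model predicts per-question
accuracy from estimated knowledge, with correlated random intercepts and
slopes for participant and question (plus lecture when content areas mix;
question ids are globally unique, so the question grouping is implicitly
nested in lecture). Fitting is by maximum likelihood under the Laplace
approximation, implemented here directly: an inner penalized Newton solves
the conditional modes of the spherical random effects, an outer Nelder-Mead
runs over the relative-covariance Cholesky parameters and the fixed effects
(the same objective as `glmer` at `nAGQ = 1`; a profiled-β variant matching
`nAGQ = 0` serves as the fast path). On shared fixtures the log-likelihood
agrees with lme4's `glmer` to ~1e-4. When a fit fails or its random-effect
covariance is singular (diagonal Cholesky entry below 1e-4), structure is
removed stepwise — correlation, then slope, then the whole term — attempting
groups in the order lecture → question → participant (smallest expected
variance first); the order is a documented choice, as is Laplace over
adaptive quadrature (crossed random effects make quadrature impractical).

Effect sizes are odds ratios `exp(β_knowledge)` with percentile 95% CIs from
a nonparametric bootstrap over rows (full size, with replacement).
Significance uses a parametric-bootstrap likelihood-ratio test: simulate
responses from the fitted null (new random effects each draw), refit both
models, and report `p = (r + 1)/(n + 1)` over the exceedances.

**Full-pipeline null simulation.** The knowledge predictor is itself a
function of the responses: in the rebalanced modes each estimate is built
from the same quiz whose accuracy it predicts, and even in the
across-lecture mode the response of one row enters the predictor of other
rows. A null simulation that redraws responses while freezing the predictor
destroys this coupling and is strongly anti-conservative (measured type-I
error near 1.0 for the rebalanced modes on flat-knowledge data). The
pipeline therefore re-estimates the knowledge column inside every
simulation. Because the ncorr weights never depend on correctness labels,
they are precomputed once per participant-quiz (`HeldoutEstimator`), making
re-estimation a handful of dot products. The deviance comparisons of the
LRT chain use the fast profiled-β fits, identically for the observed and
every simulated statistic, which leaves the bootstrap p-value exchangeable
by construction; reported point estimates come from the full Laplace fit.

## Smoothness of knowledge

For each reference question a participant answered, concentric spheres of
correlation-distance radius 0.00–2.00 (step 0.01, 201 spheres) are grown
around its embedding, and the proportion of enclosed questions answered
correctly is averaged across correctly- and incorrectly-answered references
separately. The reference counts as enclosed in its own sphere, so the
radius-0 values are 1 and 0 respectively; at radius 2 both curves equal the
participant's overall proportion correct exactly (the final grid value is
set to the pooled proportion to avoid the last-bit rounding of a float
mean). Participants lacking a reference label contribute NaN and are
dropped from across-participant means at each radius.

The *divergence distance* — how far performance remains distinguishable from
the overall score — is estimated with a nested bootstrap: outer resamples of
participants (paper scale 10,000; desk scale 200), an inner bootstrap
(1,000 / 200) giving the 95% band of the mean overall proportion per quiz,
and per outer sample the smallest radius at which the averaged curve lies
inside the band, scanning upward from 0. Curves that never enter the band
record radius 2 with a flag.

## Knowledge and learning maps

For visualization, a high-resolution model (`k = 100`) re-embeds lectures
and questions; all statistics elsewhere use the selected-`k` model. Topic
vectors are log-transformed (after adding 1e-12, since variational LDA can
produce numerical zeros) and projected to a plane. Two projectors are
provided: UMAP with correlation distance in the high-dimensional space and
Euclidean distance in the plane (the study configuration; stochastic, with
a recorded seed and an approximate inverse), and a deterministic linear
projector — the top-2 principal directions of the centered log-vectors —
that is exactly invertible on its subspace and is used wherever
reproducibility matters (tests, deterministic runs). Inverting any plane
coordinate exponentiates the inverse-projected log-vector and renormalizes,
so every map location corresponds to a valid topic mixture that can be
rendered as a weighted word list with per-word lecture association scores.

Knowledge at plane coordinate `x` is the RBF-weighted proportion correct
with `RBF(x, μ) = exp(−‖x − μ‖²/λ)` and `λ = 50` in squared plane units (no
rescaling of the plane), evaluated on a 100 × 100 grid tiling the bounding
rectangle of the projected lectures and questions, padded 2% per side.
Learning maps are pointwise differences of two quizzes' knowledge maps.

## The synthetic study

The generator emulates the study design end to end: `k_true = 12` topics
over a 150-word vocabulary of pronounceable nonsense words (shaped to pass
the preprocessing untouched); two lectures, each a piecewise-linear path on
the topic simplex biased toward an overlapping topic subset, emitting a
caption line of 8 sampled words every 2.4 s for 6 minutes (the real caption
cadence at a desk-friendly length); 15 + 15 + 9 questions — lecture
questions sample 30 words from the mixture at a planted timepoint, general
questions from two reserved off-path topics; and 50 learners taking three
13-question quizzes (5/5/3 per content area, every question exactly once
per learner, allocation randomized per learner).

Each learner's latent knowledge field is `base + Σ a_b·exp(−d²/ℓ²)` over
correlation distance `d` to random bump centers, clipped to [0, 1], with
lengthscale `ℓ = 0.5` and bump amplitude ±0.25 around a base of 0.2.
Viewing a lecture (lecture 1 between quizzes 1–2, lecture 2 between 2–3)
adds `0.5·exp(−d_min²/ℓ²)` of the distance to that lecture's trajectory.
`P(correct) = 0.25 + 0.75·K(v)` — a four-option guessing floor the study
design implies but the estimator does not model; it is toggleable to 0.
With `ℓ → 0` the field is flat and responses are independent of embedding
geometry: the null scenario for type-I calibration. The field lives on the
*true* simplex, so fitting with `k ≠ k_true` exercises representational
mismatch.

What the generator does **not** emulate: natural language (documents are
bags of sampled words — which is all LDA observes), item difficulty or
discrimination parameters, participant-level ability beyond the field,
response times, or fatigue. Passing tests therefore demonstrate correctness
of the estimation machinery under the model's own assumptions, not
performance on real classroom data.

## Problem sizes and defaults

Desk-scale defaults (CLI and tests) are 199 likelihood-ratio simulations,
500 odds-ratio bootstrap resamples and a 200 × 200 nested smoothness
bootstrap; `--paper-scale` restores 10,000 everywhere. Calibration checks
use 100 replicate response sets at 199 simulations; the scenario-ordering
smoothness check pairs 20 seeds. These sizes were chosen so the full test
suite and the acceptance script each complete in minutes on a single CPU
while leaving the Monte-Carlo error comfortably inside the asserted bands.

## Known limitations

- The unused-topic rule is tied to the variational LDA implementation;
  collapsed Gibbs samplers leave surplus topics closer to the prior and may
  select smaller `k`.
- The rule-based lemmatizer is intentionally small; rare inflections pass
  through unlemmatized (harmless for bag-of-words modeling, but vocabulary
  sizes are slightly inflated).
- The UMAP inverse is approximate away from the fitted data; only the
  linear projector guarantees simplex-faithful round-trips, which is why it
  is the default in tests.
- With strongly imbalanced cells (near-ceiling quiz performance) the
  within-lecture held-out estimates rest on one or two opposite-label
  questions and are noisy; the mixed-model results for such cells should be
  read with that in mind.
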