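# Methods

## Choice model

A trial presents a reference image r and two options a, b; the participant
chooses the option more similar to the reference.  Images are represented as
nonnegative vectors x_i ∈ R^K_{≥0} and the choice rule is a softmax over
reference-option dot products,

    P(choose a | r; a, b) = σ(x_r·x_a − x_r·x_b),

with σ the logistic function.  The model embodies three assumptions about
perceptual dimensions: **sparsity** (not every feature is expressed in every
image — enforced by an L1 penalty), **continuity** (weights are graded, not
binary) and **positivity** (a dimension can only add evidence; enforced by
projection onto the nonnegative orthant).  Nothing in the fit enforces
symmetry or metricity of the induced similarity; both emerge from the dot
product form.

## Fitting

The objective is mean cross-entropy of observed choices plus λ·mean|W|,
minimized by mini-batch Adam with projection W ← max(W, 0) after every step,
so nonnegativity holds throughout training, not just at convergence.
Defaults (all configurable through `FitConfig` and logged in the embedding
sidecar):

| parameter | default | notes |
|---|---|---|
| initial dimensions | 90 | generously over-complete; L1 empties the excess |
| λ | 0.0038 | kept as the historical default for real 600-image data; because the penalty here is *mean* absolute weight (scale-stable across image counts), informative synthetic runs need λ of order 0.1–1, and λ should in general be chosen by `select_lambda` |
| train fraction | 0.9 | split by trial, seeded; the held-out 10% gives test accuracy |
| learning rate / batch | 0.02 / 2048 | Adam |
| max epochs / patience | 200 / 10 | early stopping on the penalized training objective — validation accuracy saturates long before the L1 term finishes emptying spurious dimensions, so stopping on accuracy would freeze a non-sparse solution |
| pruning tolerance | 0.1 × global max weight | a dimension is dropped when its largest weight falls below it |

After pruning, dimensions are ordered by descending mean weight (stable
tie-break on original index).  Fits are bit-reproducible given the seed.
λ selection is k-fold CV on mean validation accuracy with ties resolved to
the larger (sparser) λ.

## Similarity by context marginalization

Pair similarity is p(i, j) = mean over contexts k ∉ {i, j} of the average of
the two feasible reference assignments,
½[P(j chosen | r = i, {j, k}) + P(i chosen | r = j, {i, k})].
Contexts where k is the reference contribute to p(i, k)/p(j, k), not
p(i, j).  Under this convention the three pair probabilities within any
context sum to 3/2, so the mean off-diagonal similarity of an exact-mode
matrix is 0.50 for any embedding — a structural identity of the 2-AFC task,
used as a self-check throughout.  Exact enumeration is vectorized as a
row-sum of logistic terms with the k = i, j terms corrected analytically
(O(n³) time, O(chunk·n²) memory) and is the default up to the ~600-image
scale; a sampled mode with Monte-Carlo standard errors exists for larger
stress tests.  The empirical (behavioral) matrix applies the same definition
to observed choices, averaging within (pair, context, reference) cells, then
over references, then over contexts; pairs never co-presented are explicit
NaNs, never imputed.  The diagonal is set to 1 for display and excluded from
every statistic.

## Evaluation

- **Noise ceiling**: mean over repeated unique triplets of the
  modal-response fraction max(c_A, c_B)/m.  This estimator has a small
  upward small-sample bias relative to mean max(p, 1−p) (of order one
  percentage point at m = 60 for p near ½); the acceptance test checks it
  against the exact binomial expectation instead.
- **Chance-corrected accuracy**: 100·(accuracy − chance)/(ceiling − chance).
- **Matrix agreement**: Pearson r over lower triangles, p by Mantel
  permutation of item labels (default 10,000 permutations), 95% CI by
  bootstrap over items.
- **Split-half reliability**: responses split within each unique-triplet
  cell, behavioral matrices correlated, averaged over splits, Spearman-Brown
  corrected (2r/(1+r)).  Explainable variance is reported as
  100·r²/reliability — one documented interpretation among several the
  literature uses; it is reported, not asserted against any external value.
- **Probability-level fit**: for repeated triplets, 100 minus the mean
  absolute deviation between predicted and observed choice probabilities (in
  percentage points), reported alongside the Pearson r; the subtraction form
  is an interpretation and is flagged as such in the API docs.
- **Class structure**: per class, mean within-exemplar similarity vs mean
  similarity of its exemplars to all other images; paired t across classes.
- **Decoding**: three-fold leave-one-exemplar-out linear SVMs (C = 1,
  logged); pairwise accuracy averages independent 2-class SVMs over all
  class pairs; top-k and median rank come from the multiclass decision
  function.
- **Semantic comparison**: class-level behavioral similarity is the mean of
  the exemplar block per class pair (aggregation choice documented here);
  the semantic matrix is the Pearson correlation of class semantic vectors;
  R² is the squared Pearson r between lower triangles.
- **Dimension-pruning curve**: each image's smallest nonzero weight is
  zeroed simultaneously across images, step by step; after each step the
  squared correlation between pruned-model and full-model choice
  probabilities on evaluation triplets is recorded, and the minimal
  per-image dimension count reaching 95%/99% is reported.

## Stability

Reproducibility of a reference dimension is its best-match Pearson
correlation against each refit's dimensions — greedy per reference dimension
(two reference dimensions may legitimately match the same run dimension;
Hungarian one-to-one matching is available as an option) — averaged across
runs after Fisher z-transformation, with r = 1 clamped to 1 − 1e-7 before
the transform.  Restart seeds derive from a master seed by fixed offsets and
are logged.  Category-subset stability removes all exemplars of selected
classes and every trial touching them (for a fully sampled design the
removed fraction is 1 − C(n−m, 3)/C(n, 3) for m removed images), refits, and
matches dimensions on the retained images.

## Image-computable stage

Each embedding dimension is predicted from image feature vectors by ridge
regression with standardized features and an intercept.  Generalization uses
a leave-one-material-out outer loop — all exemplars of a class held out
together, preventing exemplar leakage (a per-image variant exists behind a
flag) — with inner k-fold CV over a logarithmic λ grid spanning 8 decades.
For novel images the per-dimension λ chosen on the full training set is
reused and predictions are clipped at zero.  A caution for null
interpretation: with uninformative features the regularized prediction
collapses toward the training mean, which under leave-one-class-out is
*anti-correlated* with the held-out class value, so null held-out r is
biased negative rather than centered at zero.  The tests therefore check
that uninformative features show no positive predictivity, not r ≈ 0.

## Synthetic generator

Class prototypes are Bernoulli(sparsity) masks times Gamma(2, 0.5)
magnitudes (positive and right-skewed, like fitted SPoSE weights);
exemplars add nonnegative half-normal noise (sd 0.15) on active dimensions
and are rescaled to the prototype's L1 norm, so within-class profiles stay
more correlated than between-class ones.  Simulated choices follow the
softmax rule with a lapse rate (default 5%) that flips the response;
the generator reports its own Bayes accuracy, mean max(p, 1−p) over sampled
triplets, as the reference upper bound.  Worker profiles: clean (RT ≥
900 ms by construction; the chosen option's screen side counterbalanced per
worker), fast responders (log-normal RTs with median ≈ 380 ms), and
position-biased workers (click a preferred side with probability 0.75).
Semantic vectors mix a random projection of class prototypes with Gaussian
noise under a coupling in [0, 1]; feature vectors are a nonnegative random
mixing of the true dimensions plus noise, with the mixing matrix kept for
oracle checks.

What the generator does *not* emulate: real image content (features are
synthetic mixtures, not network activations), worker-specific perceptual
idiosyncrasies (a single ground truth serves all workers, so the noise
ceiling reflects lapses only), response-time dependence on difficulty, and
sequential effects.  Passing tests therefore demonstrate correctness of the
estimators and recoverability under the model's own assumptions, not that
real behavior satisfies those assumptions.

## Problem sizes and numerical choices

Tests run reduced designs chosen to keep the full suite in a few minutes:
parameter recovery uses 6 true dimensions, 40 classes × 3 exemplars, 300k
simulated trials and 3 seeds (λ = 0.3, chosen once by cross-validation for
these conditions); stability tests use 2–5 restarts; the Mantel test runs
at 99–1,000 permutations in tests (10,000 default in analyses).  Exact
marginalization is checked against a scalar triple-loop oracle at n = 10 to
1e-12.  Degenerate inputs are handled explicitly: all-zero fitted embeddings
prune to zero dimensions; zero-variance dimensions are excluded from
matching with a warning; workers with missing RTs are flagged rather than
silently passed; a ceiling at or below chance raises.

## 2-D map export

t-SNE on distances 1 − similarity, initialized from classical (Torgerson)
MDS, with affinity matrices computed at two perplexities (defaults 5 and 30)
and averaged — implemented directly because installed t-SNE implementations
do not accept precomputed affinities.  Defaults: 1,000 iterations, early
exaggeration 12 for the first quarter, momentum 0.5 → 0.8, learning rate
n/12 (min 1).  Coordinates are deterministic given the seed (a 1e-8 jitter
breaks exact ties between duplicate items).

## Known limitations

- The optimizer is plain Adam with projection; no convergence guarantee to a
  global optimum exists (the objective is non-convex), which is precisely
  why the stability analyses are part of the pipeline.
- The retained dimensionality depends on λ and the pruning tolerance;
  "close to zero" has no canonical quantification, so the 0.1 relative
  threshold is a documented choice, not an estimate.
- Exact marginalization above ~700 images becomes memory/time heavy in this
  vectorization; use the sampled mode there.
- The behavioral similarity estimator weights the two reference assignments
  equally; under unbalanced designs this differs from pooling raw trials.
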