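# Methods

This note documents the models and procedures implemented in
`subtypebench`, the defaults they use, and the design choices made where
several reasonable options existed.

## Problem setting

Molecular subtyping of a cancer cohort clusters patients from two or
more omics layers (mRNA expression, miRNA expression, DNA methylation,
copy-number variation) measured on the same patients.  Integration
methods disagree with each other and across candidate cluster numbers
k, and no gold standard exists for most cancers, so the package's job is
not to propose yet another integrator but to *evaluate and compare*
integrators: run each method for every k in 2..k_max, score every run
with clustering and survival metrics, pool all runs into a consensus
co-clustering, and — when expert-defined subtypes exist — flag the best
method with a weighted score.

## Preprocessing

Layers are features x samples matrices with NaN as the missing sentinel
(empty cell on disk, so matrices round-trip through plain TSV/CSV).
The pipeline is: intersect samples across layers (canonical order =
lexicographic on sample id) → missingness filter → imputation →
normalization → feature selection.

* **Missingness filter** drops features with more than
  `feature_missing_max` (default 20%) missing values, *then* samples
  with more than `sample_missing_max` (default 20%) missing over the
  surviving features.  The single features-then-samples pass is not
  idempotent in pathological cases (dropping samples can push a kept
  feature back over the threshold); it is applied once, as stated.
* **Imputation**: per-feature mean or median, or k-nearest-neighbour
  (default, `knn_k = 10`): a missing entry (f, s) is filled with the
  mean over the `knn_k` features closest to f — Euclidean distance over
  samples where both features are observed, unscaled by the co-observed
  count — among features observed at sample s.  A feature with no
  qualifying neighbour falls back to its own mean; a feature with no
  observed value at all is an error.  Neighbours live in feature space
  (co-expression carries the signal), not sample space.
* **Normalization**: `zscore` (population SD; constant features map to
  zeros), `log` (ln(1+x), requires values > -1), `minmax` (constant
  features map to 0.5) and `quantile` ((rank - 0.5)/n with average
  ranks on ties).  The platform uses the *population* SD everywhere —
  preprocessing and method scoring alike — so one convention holds
  throughout.
* **Feature selection**: top `ceil(fraction * n_features)` features
  (default fraction 0.10) by variance or median absolute deviation
  (MAD = median |x - median(x)|; default), ties broken by original
  feature order; or replacement of the features by the leading
  principal-component scores.

## Subtyping methods

A method is any callable `(layers, k, seed) -> SubtypingResult`; results
carry labels in 1..k, an optional integrated matrix (patient-patient
similarity, patient-patient distance, or patient-feature) and the
wall-clock time of the run.  The grid runner executes p methods x
(k_max - 1) values of k with per-cell seeds derived by hashing
(seed, method, k); a failing cell is recorded and excluded downstream
rather than aborting the comparison.

Two baselines make the platform exercisable end to end (published
integrators plug in through the same interface or as user-supplied
results):

* **concat** — early integration: per-layer feature z-scoring, feature
  stacking, then k-means with 300 random restarts keeping the lowest
  within-cluster sum of squares.  Restarts (not Lloyd iterations) are
  what make the labelling reproducible across runs.
* **simfuse** — late integration: per layer a Gaussian-kernel patient
  similarity `exp(-d^2 / (2 sigma^2))` with sigma the median nonzero
  pairwise distance, averaged across layers, then spectral clustering
  of the fused similarity.

**Reduced-dimension selection.**  Low-rank embeddings expose an
explained-variance (EV) curve: `ev(d)` = cumulative squared singular
values of the stacked z-scored matrix through dimension d over the
total (default d = 1..10).  The elbow is found automatically by the
adjusted turning score:

    h(i, j)          = (ev(j) - ev(i)) / |x(j) - x(i)|^delta    (0 if x(i) = x(j))
    turning_score(i) = sum_k h(k, i)
    penalty(i)       = exp(-(x(i) - mu)^2 / (5 v))
    adjusted(i)      = turning_score(i) * penalty(i)

with delta = 2.2, mu and v the mean and population variance of the
x-coordinates, and ties broken toward the smallest dimension.  The
split-sum form `sum_{k<i} h(k,i) - sum_{k>i} h(i,k)` equals the single
sum by antisymmetry of h; the test suite asserts the identity on random
curves.  On two-segment piecewise-linear curves (n = 10, slope ratio 5)
the procedure recovers every interior breakpoint b in 3..8.

## Evaluation metrics

* **Silhouette coefficient**: `s(i) = (b(i) - a(i)) / max(a(i), b(i))`,
  `SC = mean s(i)`, with `a(i)` the mean distance to i's own cluster.
  The platform's primary definition takes `b(i)` as the minimum distance
  to any *individual* out-of-cluster sample; the classical Rousseeuw
  variant (smallest per-cluster mean) is available via
  `variant="cluster_mean"`.  Singleton clusters and `a = b = 0`
  contribute `s(i) = 0`.  Distances come from the result's integrated
  matrix (features → Euclidean; similarity S → `max(S) - S` with the
  diagonal re-zeroed, chosen because it assumes nothing about the scale
  of S; distance → as-is) or, as a fallback, from the stacked z-scored
  layers.
* **NMI** `2 I(X;Y) / (H(X) + H(Y))` with natural-log entropies (the
  ratio is base-invariant).  Degenerate rules: both partitions trivial →
  1; exactly one trivial → 0.
* **ARI** from the contingency-table formula
  `(sum_ij C(n_ij,2) - E) / (max - E)`; two trivial partitions → 1 by
  convention.  Both NMI and ARI are implemented from their definitions
  and cross-checked in tests against pair-counting/loop oracles and
  scikit-learn.
* **Survival**: the Cox proportional-hazards model with k-1 subtype
  indicators, reported as the model-level likelihood-ratio p-value (the
  model-level choice among Wald/score/LR); non-convergent fits return
  NaN with a warning instead of raising.  Kaplan-Meier curves are
  emitted per subtype as tidy (cluster, time, survival) tables.
* **Cross-method agreement**: for each k with at least two methods, each
  method's mean NMI and mean ARI against all other methods at that k.

## Consensus and best-method selection

Each run t yields a binary co-membership matrix M(t) (diagonal 1: a
sample trivially shares its own cluster); the overall consensus matrix
is the elementwise sum over all successful runs, so each entry counts
co-clustering votes in [0, n_runs] and failed cells shrink n_runs
rather than diluting the frequencies.

Consensus clustering applies average-linkage hierarchical clustering to
the dissimilarity `1 - votes / n_runs` (average linkage is the common
choice for consensus matrices; the linkage is configurable in code).
When the final k is not fixed by the user it is chosen in 2..k_max by
the **largest dendrogram merge-height gap**.  Silhouette maximization
over cuts (`k_select="silhouette"`) was evaluated first and retained as
an option, but on near-binary consensus distances it systematically
over-splits: the grid's own large-k runs plant consistent sub-blocks
into the vote matrix, those sub-blocks have internal dissimilarity ~0,
and every sub-block member then gets s(i) ~ 1.  On the default synthetic
cohort the gap rule recovers the planted k in ~96% of seeds versus ~60%
for silhouette maximization, which is why it is the default.

With true labels available, each method at k = number of true subtypes
is scored by

    score(i) = alpha * z_cox(i) + (beta / 3) * (z_nmi(i) + z_ari(i) + z_sc(i))

with alpha = beta = 0.5, where each z is the across-method
standardization (population SD) of the metric, Cox p-values transformed
to -log10 p first (clipped at 1e-300 so a perfectly separated fit stays
finite).  A zero-spread metric carries no information and maps to all-
zero z-scores.  Ties break toward the smaller Cox p-value, then the
lexicographically smaller name.  The score is invariant under affine
rescaling of any single metric across methods, because z-scores are.

## Synthetic cohorts

The generator produces the study conditions every stage is tested on:
samples split into subtypes as equally as possible, and for each layer
subtype g's samples drawn feature-wise from
`Normal(separation * noise_sd * r, noise_sd)` with `r in {-1, 0, +1}`
drawn once per (subtype, feature).  Missing entries are injected
uniformly at an exact count `round(rate * n_entries)`; survival is
exponential at a per-subtype hazard with independent exponential
censoring (time = min, event = event-first indicator).  Everything is
reproducible bit-for-bit from the seed.

Defaults: 60 samples, 3 subtypes, a 100-feature and an 80-feature
layer, separation 5, unit noise, no missing values, hazards
(0.02, 0.08, 0.2), censor rate 0.01 — a clearly structured cohort in
which a sound pipeline should recover the planted subtypes, with an
order-of-magnitude hazard spread so survival tests have power at this
size.  Statistical checks use 200 samples and hazards (0.02, 0.2) for
Cox calibration/power, and 50 replicate cohorts for consensus recovery;
these sizes give stable Monte-Carlo rates while keeping the default
suite quick.

What the generator does **not** emulate: realistic marginal
distributions (read counts, methylation beta values), feature-feature
correlation beyond the shared subtype offsets, batch effects, or
copy-number segment structure.  Passing tests therefore demonstrate the
correctness and calibration of the machinery, not performance on real
cohorts.

## Numerical conventions and edge cases

* Population SD throughout (z-scoring, metric standardization,
  penalty variance).
* Exact-zero-spread detection for z-scores uses the range, not the
  floating-point SD, so constant inputs map to exactly zero.
* `fcluster(..., maxclust=k)` can return fewer than k clusters when
  merge heights tie (e.g. perfectly unanimous runs); the automatic
  k-selection skips such degenerate cuts.
* Consensus labels are re-encoded to consecutive 1..k; all metrics are
  invariant to relabeling.
* Silhouette of all-identical points is 0 by the degenerate rule; a
  single-cluster partition is an error (SC undefined).

## Known limitations

* The two built-in integrators are deliberately simple baselines; the
  platform's value on real data depends on plugging in published
  integration methods through `MethodSpec` or user-result files.
* The per-cell wall-clock times in the report are hardware-dependent
  and are never used in scoring.
* kNN imputation is O(F^2 S) per layer; for very wide layers run the
  missingness filter first (the default pipeline does).
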