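# Methods

## Problem and model

Given expression profiles for `n` samples over `p` candidate regulators
(transcription factors, TFs) and `q` pathway genes, the package infers a
multilayered hierarchical gene regulatory network (ML-hGRN) that operates
above the pathway: a bottom layer holding the pathway genes, a layer of
their direct regulators above it, a layer of those regulators' regulators
above that, and so on, with directed edges only between adjacent layers.

Inference is decomposed into `q` nonparametric regression problems. For
pathway gene `j` with profile `y_j`, all pooled TFs act as predictors in a
regression random forest, and a TF's relevance is its variance-reduction
importance: at a node splitting on the TF,

    IV = n·δ_p − n1·δ_c1 − n2·δ_c2,

where `δ` is the population variance of the node's responses and `n, n1,
n2` the parent/child sample counts. Within a tree a TF's importance is the
sum of IV over its split nodes; forest importance is the mean over trees.
With the population-variance convention, `n·δ` is the node's sum of squared
deviations, so IV is exactly additive: per tree, the summed importance over
features equals the summed IV over internal nodes (a conservation identity
the tests check exactly).

### Backward elimination

A single forest fit dilutes importance when thousands of irrelevant TFs
compete for splits. The elimination loop counters this: fit a forest, rank
TFs by importance, drop the least-important fraction (`elimination_rate`,
default 0.1; at least one TF per round), refit on the survivors, and repeat
until one TF remains. A TF's *final* importance is taken from the last
round in which it was modeled — the round of its elimination, or the last
fitted round for the final survivor. This snapshot comes from the least
noise-contaminated model that still contained the TF; as elimination
advances, importance values and their spread grow, which is what separates
genuine regulators from noise.

### Aggregation and layer retention

Final importances are aggregated across pathway genes into one unified
value per TF, `U(t) = Σ_j w_j · imp(t, j)`, with nonnegative per-gene
weights (default 1; promoted layers always use 1). The layer's TFs are then
retained either by a fixed count or by fitting a K-component 1-D Gaussian
mixture to the unified values via EM and keeping the TFs whose posterior
membership is maximal for the component with the largest mean. Retained
TFs are removed from the pool, become the new bottom layer, and the
procedure recurses until the designated layer count is reached, the pool
empties, or selection returns nothing.

### Baseline mode

The single-pass baseline fits one forest per bottom gene (no elimination)
and retains per-layer TF counts matched to a completed elimination run, so
the two networks are size-comparable. This mirrors how GENIE3-style
rankings are turned into a layered network for comparison.

## EM details

The mixture is fitted with the closed-form E/M updates for 1-D Gaussians
(responsibilities by log-space density ratios; means, variances and mixing
proportions by weighted moments). Numerical choices:

- K defaults to 2 (background vs regulator component); the builder treats
  it as a parameter.
- Initialization is deterministic quantile seeding — component k starts at
  the (k−0.5)/K quantile with the global variance and uniform mixing — plus
  `restarts` (default 5) mean-jittered restarts; the best log-likelihood
  run wins.
- Variances are floored at 1e-8 × the global variance so tied importance
  values cannot collapse a component; an emptied component is re-seeded at
  the point with the lowest total responsibility.
- Convergence: |Δ log-likelihood| < 1e-8, at most 500 iterations. The
  log-likelihood trace is non-decreasing (verified in tests).
- When the pool is smaller than 2K or the fit degenerates (everything in
  one component), selection falls back to the top ⌈√pool⌉ TFs and logs a
  warning.

## Forest engine

Tree growing uses scikit-learn's `DecisionTreeRegressor` with the
squared-error criterion and no depth limit, which grows trees until leaves
are pure or rows are indistinguishable and stores, per node, the weighted
sample count and the population-variance impurity — precisely the
quantities in the IV formula. Bootstrap draws (size n, with replacement,
passed as sample weights), per-tree seeds, and all importance accounting
are done in-package from the stored tree arrays, so results are
bit-reproducible from the master seed and independent of execution order:
one `SeedSequence` stream is derived per (pathway gene, round). `mtry`
defaults to max(1, ⌊p/3⌋), the usual regression-forest convention.
Thresholds are midpoints of consecutive sorted feature values (stored in
float32 by the engine — relevant only when comparing thresholds at machine
precision). Split-score ties are resolved by the engine's seeded feature
subsampling, which the fixed per-tree seeds make reproducible.

Elimination ties at the cutoff remove the lexicographically larger gene ID,
so retained sets are deterministic.

## Edge assignment

Which bottom genes an extracted TF is "linked" to is policy-driven:

- `quantile` (default q = 0.9): edge (t, g) iff t is retained and its final
  importance for g reaches the q-quantile (linear interpolation) of all
  TFs' final importance for g — yields sparse networks in which each gene
  keeps only its strongest regulators.
- `all_positive`: edge iff the final importance is strictly positive — the
  permissive alternative.

## Synthetic generators

`generate_toys` emulates the single-target benchmark: three "weak" TFs
~ N(1,1), three "strong" TFs ~ N(3,1), 1000 noise TFs ~ N(0,1), and
y = X1 + … + X6 + z with z ~ N(0, 0.1), n = 100. The second parameter of
every normal law is read as a variance (consistent with the N(1,1)/N(3,1)
notation); `scale_is_sd=True` switches the residual to sd 0.1. Note that
because variance-reduction importance is invariant to per-feature constant
shifts, the weak and strong blocks differ only in location and are
statistically exchangeable in importance — the distinction matters for
descriptions of the data, not for what any importance-based ranking can
recover. Tests and the acceptance summary therefore focus on true-vs-noise
separation, which is the property the design actually probes.

`add_noise_genes` appends decoys to any expression matrix: fresh N(0,1)
profiles, or sample-permuted copies of randomly chosen existing columns
(default) — the download-free analogue of drawing real noise genes from
the same compendium, preserving marginals while destroying association.

`generate_hierarchical` builds a layered cascade for recovery testing:
top-layer profiles are i.i.d. N(0,1); each gene below draws 1–3 parents
from the layer above and is their positive-coefficient (U(0.5, 1.5))
combination plus N(0, noise_scale²) noise; independent decoys are
appended. The default `noise_scale = 1.5` calibrates the regression to
R² ≈ 0.5 (with ~2 parents per target the signal variance is ≈ 2.2), i.e.
noise on the order of the signal, which is the regime in which recovery
benchmarks discriminate between methods. What the generator does *not*
emulate: correlated TF modules, indirect (grandparent) correlations
induced by shared paths are present but weak, heteroskedastic measurement
noise, and non-linear regulation. Passing recovery tests therefore shows
correct mechanics and ranking behavior under clean additive signals, not
performance on real compendia.

## Problem sizes in tests and the acceptance summary

The distributed checks run the full-width toys design (1006 TFs, n = 100)
with ntree = 200 over 5 replicates, and the hierarchical benchmark
(10 regulators → 20 targets, 100 decoys, n = 200) with ntree = 100 and
elimination rate 0.2 over 10 replicates; forest rankings at these settings
are stable enough that conclusions match larger ntree, while a full run at
ntree = 1000 is available through the CLI. EM recovery uses N = 2000
draws from (α = 0.9/0.1, μ = 0/4, σ² = 1/0.25).

## Known limitations

- With p ≪ n and independent decoys, a single forest pass is already near
  ceiling (edge-level AUROC ≈ 1) and elimination cannot improve on it; the
  elimination advantage appears when candidate TFs vastly outnumber
  samples, as in the 1006-TF single-target benchmark.
- Final importances of different TFs for the same gene come from different
  elimination rounds and hence different pool sizes; they are comparable as
  ranks, but their absolute scales mix regimes. No cross-round
  renormalization is applied (an optional per-gene normalization flag
  exists on aggregation for sensitivity analysis).
- Edges carry no sign or mechanism; "regulates" means "predicts in a
  forest", and directionality is imposed by the layer structure, not
  learned.
- The mixture step assumes unified importances form separated components;
  heavy-tailed backgrounds can push the top component to absorb most TFs,
  which triggers the logged fallback rather than a silent bad layer.
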