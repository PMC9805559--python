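# Methods

This note documents the modeling choices behind the package: what each
stage assumes, which parameters matter, what the synthetic benchmark does
and does not emulate, and where the design was genuinely open.

## Doublet simulation and gene selection

Artificial doublets are sums of two uniformly drawn input cells (i ≠ j),
rescaled to a library size drawn uniformly, with replacement, from the real
library sizes that are at least the larger parent's.  This reflects how a
droplet doublet superimposes two transcriptomes with an approximately
additive UMI yield, while keeping the simulated library-size distribution
inside the observed one.  Rescaled rows are kept as reals rather than
re-rounded: every downstream consumer applies log/standardize transforms
that do not require integrality.  Parent index pairs are retained for the
later homotypic-exclusion step; pairs may repeat across doublets.

Gene filtering operates on the stacked real+simulated matrix: genes zero in
more than 99% of rows are dropped (a gene at exactly 99% is kept), then the
2,000 genes with the largest raw-count variance are retained, ties broken
by original gene order.  Variance is computed on raw counts before any
transform — simple and deterministic.

**Standardization convention.** `log_standardize` applies log1p and then
z-scores with the sample (ddof = 1) standard deviation, the scaling
convention of the standard single-cell toolkits; constant slices map to
zero rather than NaN so matrix dimensions never change.  Columns are
standardized for the PCA/knn and VAE inputs; rows are standardized before
clustering.

## Preliminary score, doublet-count estimate, subsampling

The preliminary score of a row is the fraction of simulated doublets among
its k nearest neighbors (Euclidean, self excluded) in the space of the
first 30 principal components.  The default neighborhood size is
k = ⌈√(rows)⌉ — the standard heuristic scale for neighborhood statistics;
it is exposed in the pipeline config.  PCA uses exact SVD up to 5,000 rows
and a seeded randomized solver above, trading bit-stability on small inputs
against tractability on large ones.

The cutoff for the doublet-count estimate is the 25% quantile of the
simulated doublets' scores under the linear-interpolation quantile
convention (numpy's default), fixed and documented so the estimate is
reproducible.  The estimate `n̂_d` counts input cells scoring at or above
the cutoff.  Subsampling draws `n̂_d` simulated doublets without replacement
with probability proportional to score; if fewer rows have positive score,
the shortfall is drawn uniformly from the zero-score rows.  If `n̂_d < 5`
the pipeline retains 5 simulated doublets anyway (with a warning): the PU
step cannot operate on an almost-empty positive set.

## Clustering and homotypic exclusion

Rows are row-standardized, projected on 30 PCs, and clustered with Leiden
(RB modularity, resolution 1.0) on a k = 15 nearest-neighbor graph.  Edges
carry Gaussian distance weights with bandwidth equal to the mean edge
distance; an unweighted graph at k = 15 is nearly complete when the node
count is small (notably for meta-cells) and cannot be partitioned, whereas
the weighted graph matches standard single-cell practice.  Above 1,000 rows
the data is first condensed to meta-cells with mini-batch k-means
(k = 10% of rows); the meta-cells are clustered the same way and every cell
inherits its meta-cell's label.  A single-cluster outcome is valid but
logged, since it forces the next step to drop everything.

A simulated doublet is *homotypic* when its two real parents fall in the
same cluster.  Such doublets resemble singlets of that type and would
poison the positive set, so they are removed; the decision uses the parent
cells' clusters, never the simulated row's own cluster.  The retained
count, preliminary scores and labels are re-synchronized; `n̂_d` is not
re-estimated.  If no simulated doublet survives, the pipeline raises a
descriptive error (this happens only when the data is effectively one
cluster).

## Cluster-aware VAE

Encoder, decoder and cluster classifier are small dense networks
(hidden layer 256 + ReLU, batch normalization, dropout 0.3; probabilistic
heads parameterize diagonal Normals with softplus standard deviations
floored at 1e-5).  The per-example loss is the Gaussian reconstruction
negative log-likelihood plus the closed-form KL to the standard Normal
prior plus β × categorical cross-entropy of the cluster classifier,
β = 20,000.  The reconstruction likelihood is evaluated on the
log-standardized matrix — a Gaussian decoder matches standardized data, not
raw counts.  With a single cluster the classifier term is omitted.

Training: Adamax (default hyperparameters, learning rate 0.001), batch
size 128, multiplicative learning-rate decay 0.75 per epoch starting after
epoch 3, a seeded 10% validation split, early stopping with patience 20 and
best-weight restoration, max 500 epochs.  In practice the aggressive decay
schedule freezes learning within a few tens of epochs and early stopping
triggers around epoch 20–50.  Validation uses the deterministic posterior
mean (no sampling, no dropout, running batch-norm statistics) so the
stopping signal is not noise-driven, and monitors the full loss including
the β-weighted classifier term.  Non-finite losses abort with the epoch
number.  The whole model is implemented directly on numpy with hand-derived
gradients (verified against finite differences in the test suite) and runs
single-threaded, which makes seeded runs bit-reproducible.

The embedding `Z` is the encoder posterior mean — deterministic, repeatable
and row-order equivariant — not a posterior sample.

## PU bagging

Features are `Z̄ = [Z, s]` (latent dimensions plus the preliminary score).
The classifier is logistic regression realized as batch-norm → dense(1,
zero-initialized) → sigmoid, trained full-batch with Adamax (learning
rate 0.01; one epoch = one gradient step, so the probe loss curve is
smooth).  Batch-norm momentum is 0.9 here so inference statistics converge
within short training runs.  The training length is picked once by fitting
250 epochs on positives vs. the first fold and locating the knee of the
loss curve with the Kneedle maximum-difference criterion (light smoothing,
min-max normalization, flip, maximize distance to the chord); for a curve
proportional to exp(−t/5) the knee lands at t = 5·ln(249/5) ≈ 20.  Curves
without genuine curvature fall back to the full 250 epochs.  The probe
classifier is discarded.

N = 5 repetitions × K = 5 folds by default: each repetition splits the
unlabeled set into K seeded folds (repetition r uses seed `rng_seed + r`),
trains a fresh classifier on P vs. each fold, and accumulates predictions
on the held-out cells; the final score is the per-cell average over its
N·(K−1) held-out predictions.  Simulated doublets also need scores for the
caller's FNR; they receive the mean prediction of all N·K classifiers — a
documented design choice, since bagging itself only scores the unlabeled
set.

## Doublet calling

Candidate thresholds are the sorted unique pooled scores plus one value
above the maximum.  FNR(t) is the fraction of simulated doublets below t,
FPR(t) the fraction of input cells at or above t ("scoring above" is
implemented as ≥ t consistently), n(t) the called count, and the penalty is
α·LL(n(t) | μ, σ)² with LL the Normal log-density evaluated at the integer
n(t) without continuity correction.  μ defaults to n²·10⁻⁵ (clipped to
[0, n]) and σ² = μ(1 − μ/n).  α is the reciprocal of LL at the largest
candidate threshold; log-densities are typically negative, so the
implementation uses 1/|LL| — preserving the intended scale normalization —
and logs when the sign flip occurs.  Ties in the composite cost go to the
smallest threshold.  The μ heuristic is quadratic in n and therefore very
conservative below ~1,000 cells; a user-supplied expected count overrides
it.

## Synthetic benchmark

The generator emulates a multi-type 10x-style experiment: per-type relative
expression profiles share a lognormal baseline with type-specific marker
blocks up-regulated 10-fold; singlet counts are negative binomial
(gamma-Poisson, dispersion θ = 2) with lognormal library sizes (median
≈ 2,500 UMIs, sdlog 0.35); doublets are sums of two freshly drawn parent
cells, from different types for 80% and the same type for 20% (so
homotypic behavior can be exercised).  The default benchmark is 2,000
singlets, 1,500 genes, 5 types, 10% doublet rate — sized so the complete
pipeline runs in about a minute on one CPU.

What it does **not** emulate: ambient RNA, empty droplets, batch effects,
UMI saturation, barcode swapping, higher-order multiplets, or realistic
gene-gene correlation structure.  Passing tests on this benchmark therefore
demonstrate that the pipeline's machinery works and recovers planted signal
under negative-binomial noise — not that real-data accuracy will match the
measured average precision, which is flattered by the benchmark's clean
type structure.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run the full pipeline on the
default 2,222-row benchmark (≈ 40 s) and a 333-row variant for the
bit-reproducibility check; unit tests use matrices of tens to hundreds of
rows.  All randomness flows from one global seed fanned out per stage via
`numpy.random.SeedSequence`, and every component (including VAE training)
is deterministic on a single thread.

## Known limitations

* The Gaussian decoder models standardized log counts; count-likelihood
  (NB/ZINB) decoders are out of scope.
* The expected-count heuristic μ = n²·10⁻⁵ under-calls small datasets and
  saturates for very large n; supply μ when the doublet load is known.
* Homotypic doublets are intrinsically hard: they survive neither the
  simulation exclusion (by design) nor detection particularly well, and the
  neighborhood singlet-fraction statistic confirms they sit among singlets.
* Meta-cell clustering trades granularity for speed above 1,000 rows; very
  rare cell types can merge into neighboring meta-cells.
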