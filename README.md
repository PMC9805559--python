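# vaeda

Doublet annotation for droplet-based single-cell RNA sequencing.

In droplet scRNA-seq a fraction of barcodes capture two cells instead of
one.  These *doublets* appear as spurious hybrid expression profiles and
distort clustering, trajectory and differential-expression analyses, so they
should be flagged or removed before downstream work.  `vaeda` scores every
barcode of a raw count matrix for being a doublet and, optionally, converts
the scores into binary singlet/doublet calls.  It is aimed at anyone
processing 10x-style UMI count matrices who wants doublet annotation with a
fully inspectable, pure-Python implementation.

## Method

Given a raw count matrix `X` (n cells × p genes):

1. **Doublet simulation.** For each artificial doublet an index pair
   (i, j), i ≠ j, is drawn; the precursor `x_i + x_j` is rescaled to a
   library size drawn from the real library sizes that are ≥ the larger
   parent.  Real and simulated rows are stacked into `X̄` with labels `y`
   (1 = simulated).  Genes zero in > 99% of rows are removed and the 2,000
   most variable genes kept.
2. **Preliminary score and doublet-count estimate.** Each row's fraction of
   simulated doublets among its k nearest neighbors in 30-PC space gives a
   preliminary score `s`.  The number of real doublets `n̂_d` is the count of
   input cells scoring at or above the 25% quantile of the simulated
   doublets' scores; the simulated set is subsampled to `n̂_d` with
   probability ∝ s.
3. **Clustering and homotypic exclusion.** Leiden clustering of `X̄`
   (directly, or via mini-batch k-means meta-cells for > 1,000 rows) yields
   labels `c`; simulated doublets whose two parents share a cluster are
   removed, since such homotypic doublets resemble singlets and corrupt the
   positive set.
4. **Cluster-aware VAE.** A variational autoencoder with an auxiliary
   cluster classifier is trained on the log-standardized `X̄` with loss
   `−log N(x | μ_d, σ_d) + KL(N(μ_e, σ_e) ‖ N(0, I)) + β·CCE(c, ζ)`
   (β = 20,000), giving a 5-dimensional latent representation `Z`.
5. **PU bagging.** With simulated doublets as positives P and input cells
   as unlabeled U, a logistic classifier is trained on P vs. each of K
   folds of U across N repetitions on `Z̄ = [Z, s]`; a cell's doublet score
   ξ is its prediction averaged over the N·(K−1) classifiers that never saw
   it.
6. **Calling.** The threshold `t* = argmin_t FNR(t) + FPR(t) + α·LL(n(t) | μ, σ)²`
   balances misclassified simulated doublets, called input cells, and the
   Gaussian log-likelihood of the called count under the expected doublet
   count μ (default `n²·10⁻⁵`, σ² = μ(1 − μ/n)).

## Worked example

```python
import vaeda

# synthetic benchmark: 4 cell types, 10% injected doublets, known truth
spec = vaeda.SyntheticSpec(n_singlets=500, n_genes=800, n_types=4, rng_seed=0)
data = vaeda.generate_dataset(spec)
result = vaeda.run_pipeline(data.counts, vaeda.PipelineConfig(seed=1))

ap = vaeda.average_precision(result.scores, data.is_doublet)
print(f"cells: {data.counts.n_cells}   injected doublets: {data.is_doublet.sum()}")
print(f"estimated doublets (n_hat): {result.n_doublets_estimated}")
print(f"expected doublets (mu): {result.mu:.2f}")
print(f"call threshold t*: {result.threshold:.4f}   doublets called: {result.calls.sum()}")
print(f"average precision vs truth: {ap:.3f}")
```

prints

```
cells: 556   injected doublets: 56
estimated doublets (n_hat): 50
expected doublets (mu): 3.09
call threshold t*: 0.8492   doublets called: 3
average precision vs truth: 0.915
```

The scores rank injected doublets far above singlets (average precision
0.915 against a 0.10 prevalence baseline), and the knn-based estimate
`n̂_d = 50` is close to the 56 truly injected doublets.  The *called* count
is governed by the expected-count prior μ = n²·10⁻⁵ ≈ 3.1, which is
deliberately conservative at this small n; pass
`PipelineConfig(expected_doublets=...)` (or `--expected-doublets` on the
CLI) when a better estimate of the doublet load is known.

The same workflow is available from the shell:

```sh
vaeda simulate --output data/ --seed 0
vaeda run --input data/ --output out/ --seed 1
vaeda eval --scores out/doublet_scores.tsv --truth data/truth.csv
```

`vaeda run` accepts a 10x-style MTX directory, an `.h5ad` file, or a CSV
(cells × genes), and writes `doublet_scores.tsv` (barcode, score, call) plus
a JSON run report.

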