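# vnscluster

Medoid (p-median) clustering of spatially resolved transcriptomics cells by
variable neighborhood search (VNS).

## The problem

Spatial transcriptomics platforms (Stereo-seq, 10x Visium, ...) measure gene
expression while retaining each cell's (x, y) position in the tissue.
Upstream tools (PCA, STAGATE, GraphST, CCST, ...) compress the expression
profile of cell *i* into an embedding vector emb_i; this package takes those
embeddings plus coordinates and partitions the cells into K spatially and
transcriptionally coherent domains.

Clustering is cast as a p-median (k-medoids) problem: choose K *cells* as
cluster representatives ("centroids") minimising

    F(Y) = Σ_i D(c_i, x_i),    x_i = the representative in Y nearest to cell i,

under the blended distance

    D = α·D_gene + (1 − α)·D_coord,

where D_gene is the cosine distance between embeddings, D_coord the Euclidean
distance between positions, and α ∈ [0, 1] the embedding weight (α = 1 ignores
space; α = 0.95 adds 5% spatial influence).  Minimising F exactly is NP-hard,
so the solver is a VNS metaheuristic: from an incumbent Y it *shakes* (replaces
k of the K medoids with random outside cells, k sweeping k_min..k_max), then
descends with a randomized first-improvement local search (breadth m,
persistence p), accepting strictly better solutions and resetting k on every
improvement.  Small instances can be solved exactly (enumeration or an ILP via
HiGHS) and serve as oracles for the heuristic.  Because the search is seeded
and stochastic, a configuration is summarised over R runs by f_VNS = min_i F_i,
err = mean_i |F_i − f_VNS|/|F_i| and σ = SD of those relative gaps; agreement
with ground truth uses the adjusted Rand index (ARI).

## Worked example

```python
import vnscluster as vc

# synthetic tissue: 3 planted domains x 30 cells, well separated
ds = vc.generate(vc.SyntheticSpec(seed=2))

model = vc.SpatialPMedian(ds, n_clusters=3, alpha=0.5, normalize_coords=True)
res = model.fit(n_runs=20, seed=1, max_iter=300)
print(res.summary())
print("ARI vs planted truth:", round(res.ari(), 4))
```

prints

```
        Spatial p-median clustering (VNS)
====================================================
No. cells:                  90
Embedding dim:              16
Clusters (K):               3
alpha (gene weight):        0.5
coord scale:                14.8688
Runs (seeds):               20 (base seed 1)
max_iter / k_max / m / p:   300 / 3 / 10 / 10
----------------------------------------------------
f_VNS (best objective):     5.234955
err (mean rel. gap):        0.009501
sigma (SD of gaps):         0.009903
ARI vs truth (best-F run):  1.0000
====================================================
ARI vs planted truth: 1.0
```

f_VNS is the smallest total blended distance over the 20 seeded runs; err ≈ 1%
and σ ≈ 1% mean all 20 seeds landed within about one percent of that best
objective; ARI 1.0 means the best run's medoid partition recovers the planted
domains exactly.  `res.labels_` holds the
per-cell assignment (cluster names are the medoid cell ids) and
`res.save_labels(path)` writes it as CSV.

The same flow is scriptable:

```sh
vnscluster synth --seed 2 --out-prefix demo
vnscluster cluster --coords demo.cells.csv --k 3 --alpha 0.5 \
    --normalize-coords --max-iter 300 --runs 20 --out-prefix demo
vnscluster evaluate --predicted demo.labels.csv --truth demo.truth.csv
```

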