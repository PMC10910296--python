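# Methods

## Model

Given n cells with positions (x_i, y_i) and embedding vectors emb_i (produced
upstream; this package never touches raw expression beyond a MatrixMarket
ingestion convenience), clustering is the p-median problem: pick K cells
("centroids", i.e. medoids) minimising the total distance of every cell to
its nearest chosen cell,

    min_Y  F(Y) = Σ_i  min_{y ∈ Y} D(i, y),   |Y| = K,

equivalently the integer program with assignment indicators x_ij and opening
indicators y_j: minimise Σ_ij x_ij D(i, j) subject to Σ_j x_ij = 1 per cell,
x_ij ≤ y_j, Σ_j y_j = K, all binary.  The assignment vector X (nearest open
centroid per cell, ties to the lowest cell index) makes those constraints
hold by construction, which is what `CentroidSolution.check` verifies on
every solution the tests emit.

The distance blends transcriptional and spatial dissimilarity:

    D(i, j) = α · D_gene(i, j) + (1 − α) · D_coord(i, j) / s.

* **D_gene** is the cosine *distance* 1 − cos(emb_i, emb_j) ∈ [0, 2].  The
  field often says "cosine similarity" loosely; a similarity inside a
  minimisation objective would reward dissimilar cells, so the distance form
  is the default.  The raw-similarity variant remains available behind
  `gene_metric="similarity"` purely for auditing.
* **D_coord** is the Euclidean distance in the input's spatial units.
* **s** (`coord_scale`) is 1 by default — the literal blend of the two raw
  terms — or, with `normalize_coords=True`, the maximum pairwise coordinate
  distance, which puts the spatial term on the same O(1) scale as the cosine
  term.  Pixel- or µm-scale coordinates otherwise dominate the blend for any
  α < 1.  Neither convention is asserted to be "the" published one; the
  constant actually used is recorded in the distance model, every report
  manifest, and the matrix sidecar.
* Tiny negative cosine distances from floating-point rounding are clamped to
  zero; the diagonal is exactly zero.

The dense n×n matrix is precomputed once (the solver touches it millions of
times); a row-on-demand `LazyDistanceModel` with the same interface serves
datasets past ~20,000 cells where n² floats are impractical.

## The VNS solver

* **InitialSolution** — a uniform random K-subset of cells.
* **Shake(Y, k)** — replace k randomly chosen entries of Y with k cells drawn
  without replacement from outside Y; the result always has K distinct
  entries and shares exactly K − k with Y.
* **LocalSearch(Y′, m, p, F\*)** — randomized first-improvement descent.  For
  each position of Y′ in order, draw ind uniformly from {0..m}, redrawing
  while ind == 1 (a size-1 candidate list holds only the centroid itself at
  distance 0, so it is useless); ind == 0 keeps the centroid; ind ≥ 2 forms
  the list of the ind cells nearest to the current centroid (precomputed
  per-cell neighbor order, ties by index), removes cells already in the
  working vector, and picks one survivor uniformly — or a uniform random
  outside cell when none survive.  A full pass yields Y″; if F(Y″) < F\*
  (the *global* incumbent objective) the pass's result is returned
  immediately, otherwise the pass restarts from Y′, at most p times, after
  which Y′ is returned unchanged.  Candidate filtering is against the
  progressively modified working vector, preserving distinctness at every
  step.
* **Main loop** — one iteration = one shake at the current k plus one local
  search.  On strict improvement the incumbent is replaced and k resets to
  k_min; otherwise k grows by k_step, wrapping to k_min past k_max (standard
  practice keeping the search alive within the iteration budget).  The run
  stops after max_iter iterations; the incumbent trace is non-increasing by
  construction.  An improving local-search result goes straight into the
  next shake; it does not re-enter local search first.

### Parameters

| name | meaning | default | why |
|------|---------|---------|-----|
| K | number of clusters | — (required) | domain count is a biological input |
| α | embedding weight in D | 1.0 | pure-embedding clustering unless spatial mixing is requested; published sweeps use {1, 0.95} |
| k_min, k_step | shake schedule start/step | 1 | the conventional defaults |
| k_max | largest shake size | min(10, K) | sweeps use 10–30; it may never exceed K, and is further capped at n − K so the replacement pool is never empty |
| max_iter | shake+descend cycles | 500 | ample for the instance sizes the tests exercise |
| m | local-search breadth | 10 | low end of the published sweep {10..30} |
| p | local-search persistence | 10 | low end of the published sweep {10..20} |
| n_runs | seeds per batch | 20 | the 20-seed reporting protocol |

All randomness flows from one `numpy` generator per run, seeded with the run
seed; a batch uses seeds seed, seed+1, …, seed+R−1.  Identical seed, config
and data give bit-identical output.

### Batch statistics

Over R runs with objectives F_i: f_VNS = min F_i; err_i = |F_i − f_VNS|/|F_i|
(defined as 0 when F_i = 0, which forces f_VNS = 0); err = mean err_i; σ =
population SD of the err_i.  Wall time t_VNS of the best run is recorded but
never asserted (hardware-dependent).  Ties for the best run resolve to the
earliest seed.  Reports carry both the best-F run's ARI and, where a grid is
swept, per-combination rows, so either "best objective" or "best ARI"
summaries can be read off without re-running.

## Exact oracles

`solve_exact` enumerates all C(n, K) subsets (refusing above 2,000,000 —
shrink the instance rather than approximate the oracle) and is correct by
construction; ties go to the lexicographically smallest subset.  `solve_ilp`
solves the integer program with HiGHS through scipy and must agree with the
enumeration to 1e-6 everywhere both run.  The heuristic is validated against
these on random instances with n ≤ 12, K ≤ 4: it must never go below the
exact optimum and is expected to attain it on ≥ 95% of (instance, seed)
pairs at max_iter = 500.

## Synthetic data

The generator plants the joint structure real inputs have: cluster g owns a
spatial center (evenly spaced on a circle, neighbor distance
`coord_separation`) and an embedding center (orthonormal directions scaled by
`emb_center_separation` when n_clusters ≤ emb_dim); cells scatter around both
with Gaussian noise and embeddings are unit-normalised afterwards (cosine
geometry well-conditioned, zero-norm rows impossible, degenerate draws
resampled).  Defaults — 3 clusters × 30 cells, coord noise SD 1 against
separation 10, embedding noise SD 0.05 against separation 1 — describe a
well-separated regime (separation ≥ 10× noise) in which a correct solver
should recover the planted partition with ARI ≥ 0.95 for at least 18 of 20
seeds at K = 3, α = 0.5, normalized blend, max_iter = 300.

What passing on these fixtures shows: the optimisation machinery minimises F
correctly and F's minimisers align with planted joint structure.  What it
does not show: robustness to raw-count noise, dropout, irregular tissue
geometry, embedding pathologies, or platform effects — none of which the
generator simulates.

## Numerical choices and degenerate inputs

* Nearest-centroid ties break to the lowest centroid (cell) index; candidate
  -list distance ties break to the lowest cell index (stable argsort).
* Candidate choice among filtered survivors is uniform random.
* Cosine rounding below zero clamps to 0; assignment minimality is checked
  to 1e-9.
* K = n is answered directly with the all-cells solution (F = 0, provably
  optimal) since no shake is possible; K > n, α ∉ [0, 1], k_max > K, empty
  shake pools and oversized enumerations raise typed errors rather than
  degrade.
* Problem sizes in the test and acceptance experiments (n ≤ 12 for oracle
  comparisons, 90-cell planted instances, 20-seed batches) were chosen as
  the smallest sizes at which each property is informative, keeping the full
  suite under a minute.

## Known limitations

* The dense matrix path is O(n²) memory; the lazy path trades that for
  O(nK) work per objective evaluation and is the only practical route for
  40k-cell tissue sections.
* No VND, skewed VNS, warm starts, or parallel multi-start beyond the seed
  batch; no alternative metrics or k-NN sparsified distances.
* ARI evaluation requires ground-truth labels; without them only the
  objective statistics are reported.
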