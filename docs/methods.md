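# Methods

This note records the models the package implements, the numerical choices
made where the method left freedom, and what the synthetic benchmarks do and
do not establish.

## Rent's rule and the two exponents

Rent's rule `e = k·n^p` relates the nodes `n` inside a block to the edges
`e` crossing its boundary.  Both estimators reduce to a straight-line fit in
log-log space; they differ in how blocks are formed.

### Topological estimator

The network is recursively bisected into halves, quarters, and so on with a
balanced min-cut heuristic, and `log(mean e)` is regressed on `log(mean n)`
across levels, weighted by the number of partitions per level.

* **Partitioner.**  Fiduccia–Mattheyses refinement (single-node moves with
  gain updates, best-prefix rollback, up to 8 passes) over multiple
  initialisations: one spectral start (balanced split along the Fiedler
  vector), a zero-cut component packing when the input is disconnected, and
  random balanced starts up to `restarts` (default 10).  Balance tolerance:
  `||A|−|B|| ≤ max(1, 0.1·n)`.  Random starts alone are unreliable on
  lattices, where the optimal cut is a straight slice; the spectral start
  finds it directly.  On graphs of ≤ 11 nodes the heuristic matches
  exhaustive minimum bisection in the test suite.
* **Boundary counting.**  By default a partition's `e` counts every edge of
  the whole network with exactly one endpoint inside (the external-connection
  count of VLSI practice).  This choice, not the bisection-cut alternative
  (available as `boundary="parent"`), reproduces the characteristic ordering
  observed < randomly-rewired for modular networks; the parent-cut variant
  yields slopes above 1 on dense modular graphs and inverts that ordering,
  so it is only appropriate for sparse lattice-like inputs.
* **Region I/II.**  Boundary effects flatten the scaling at large
  partitions (Region II).  The fit drops the `exclude_top = 2` largest
  usable levels and requires ≥ 3 remaining.  There is no residual-based
  rule: the breakdown is gradual, and a data-driven cut risks tuning.
* **Finite-size bias.**  On small lattices the global hull suppresses `e`
  at *every* level, biasing `p_T` downward: measured 0.45 on a 32×32 grid
  and 0.55 on 8×8×8, versus the asymptotic `1 − 1/D` (0.5, 0.667).  The
  estimator is consistent — 10³ gives 0.61, 12³ gives 0.63 — but desk-scale
  lattice values sit low in any calibration band.  Exact ideal-cut
  computations (no heuristic error) give 0.434 and 0.546 at those sizes, so
  the bias is inherent to the method at this scale, not to the partitioner.

The fractal dimension of the topology is `D_T = 1/(1 − p_T)`; confidence
intervals map through this monotone relation endpoint-wise.

### Box-counting cross-check

The renormalisation-style estimator covers the graph with boxes of
shortest-path diameter < `l_B` for `l_B = 1 … diameter` and fits
`log N_B` on `log l_B` (weights `N_B`, so the saturated tail of one-box
covers does not dominate).  Three covering heuristics are run and the
minimum box count kept per size: greedy colouring of the conflict graph
over 10 random orders, DSATUR colouring, and a centre-grown covering by
balls of radius `⌊(l_B−1)/2⌋`.  All three produce valid coverings, so the
minimum is simply the best available bound on the covering number.
**Known bias:** greedy coverings overshoot the optimum increasingly with box
size; on a 16×16 grid the estimate is ≈ 1.5 rather than 2 (an optimal
covering would give ≈ 1.9).  The estimator is therefore used as an
order-of-magnitude cross-check of the partition estimator (the suite asserts
agreement within 1.0 on lattices and ≈ 1 on chains), not as a precision
instrument.

### Physical estimator

5000 axis-aligned boxes (squares/cubes) are dropped on the embedded
network: corners uniform in the coordinate bounding volume, side lengths
uniform between the 5th-percentile nearest-neighbour distance (below which
boxes are mostly empty) and the full extent, clipped so boxes never overhang
the volume.  Containment is half-open (`lo ≤ x < hi`), so nodes on shared
faces count once; empty boxes are resampled.  All draws are made in
normalised coordinates, making the sample — and the fit — exactly invariant
to uniform rescaling of the input coordinates at fixed seed.  The fit is a
robust bisquare IRLS regression (statsmodels RLM, run to convergence) of
`log e` on `log n` over boxes with `n < N/2` (strict), `n ≥ 2`, `e ≥ 1`;
at least 50 such boxes are required.  The bisquare slope agrees with R's
`MASS::rlm(psi = psi.bisquare)` to < 0.02 in the cross-check test.

The theoretical minimum `p_min = max(p_T, 1 − 1/D_E)` expresses that an
embedding can beat neither the topology's intrinsic dimensionality nor the
surface-to-volume exponent of the Euclidean space (2/3 in 3-D, 1/2 in 2-D).

## Hierarchical modularity

Community structure is detected with Louvain (igraph's C implementation,
resolution 1; `louvain_partition` keeps the best of 20 seeded runs).
Significance of a module's internal structure is tested against two
ensembles of 100 surrogates matched to the subnetwork under test: pure
random `G(n, m)`, and degree-preserving Maslov–Sneppen rewirings with 15
*accepted* double-edge swaps per edge (compiled kernel; proposals creating
self-loops or multi-edges are rejected and retried; swap-free graphs such as
stars and triangles return unchanged with a warning).

Two statistical choices matter and are deliberate:

* The 1-tailed comparison treats the observed network as a **single draw**
  from the null: `t = (Q_obs − Q̄_null)/(s_null·√(1 + 1/n_null))` with
  `n_null − 1` degrees of freedom.  Dividing by the standard error of the
  null mean instead would reject ~40% of genuinely random networks.
* The observed network and every surrogate get the **same number of Louvain
  runs** (default 1) when computing the Q values entering the test;
  maximising over restarts only on the observed side would bias the test
  anticonservative.  The module membership used for recursion comes from a
  separate best-of-10 search on the observed subnetwork.

Decomposition recurses into modules whose tests pass both ensembles at
α = 0.05 (conventional level, configurable); modules below
`min_module_size = 8` become leaves (null Q distributions are too coarse
below that).  Tree depth counts significant hierarchical levels; a
non-modular network has depth 1.  Calibration on 20-seed experiments: the
3-level nested generator at N = 256 recovers depth ≥ 3 in ≥ 18/20 seeds,
and pure-random graphs stay at depth 1 in ≥ 18/20.

The co-classification matrix is a Louvain-consensus approximation (fraction
of seeded hierarchical runs co-assigning a pair, averaged equally over
depths, display order by average-linkage clustering).  It is a
visualisation aid; no quantitative claim in the package depends on it.

## Wiring cost and the efficiency coefficient

* Node spacing `δ` = mean nearest-neighbour Euclidean distance (degree-1
  homogeneous; errors on coincident nodes).
* `L̄` = mean edge length / δ (dimensionless, scale-invariant).
* `κ = L̄ / N^(1/D_E − 1/D_T)`, defined for `D_T > D_E`; near 1 indicates a
  cost-efficient embedding.  Outside that regime (lattice-like networks) κ
  is reported as not applicable rather than extrapolated.
* Minimal rewiring keeps positions and replaces edges by the Euclidean MST
  plus the shortest remaining pairs (ascending distance, lexicographic
  ties) until `m` matches.  Candidates are all pairs up to N = 5000, then a
  50-nearest-neighbour set.  On exhaustive ≤ 6-node checks the greedy
  construction attains the optimum connected subgraph length.

## Allometry

With constant synaptic density per white-matter cross-section (σ) and
constant processing-element density per gray-matter volume (ρ), the
spherical-geometry argument gives `a = (3/2)·p`, i.e. `p = (2/3)·a`.  The
fit of `a` is OLS of `log Vw` on `log Vg` (exact line through two points; CI
from the t distribution otherwise).  White-matter dilation is ignored, and σ
and ρ never appear numerically — they cancel in the exponent relation.

## Synthetic generators (what the benchmarks show)

* **Lattices** pin the known scaling `p = 1 − 1/D` and `D_T = D`.
* **Hierarchical-modular networks** are nested stochastic block models: the
  connection probability of a pair is set by the deepest level at which they
  share a block, strictly denser with depth.  By default each base module
  occupies a recursively halved subcell of the unit cube, so topological
  modules are also spatially compact — the feature of real nervous systems
  that makes observed wiring cheaper than random.  With
  `placement="uniform"` geometry and topology decouple, and the wiring
  comparisons degenerate to coin flips (useful as a negative control).
  Default benchmark conditions: 3 levels × base 64 (N = 256), probabilities
  (0.01, 0.3, 0.6) for modularity calibration; 4 levels × base 16 (N = 128),
  probabilities (0.004, 0.04, 0.15, 0.45) — connectome-like 8% density —
  for the wiring/dimension trade-off.
* **Power-law scatter** draws `n` log-uniform over (2, 2048) and
  `e = k·n^p·exp(ε)`, `ε ~ N(0, sd²)`, for parameter-recovery experiments
  (the fitter covers the true `p` in its 95% CI in ≥ 90/100 seeds at
  sd = 0.1).

What passing these benchmarks does **not** show: real connectomes have
degree heterogeneity, geometric constraints (sheets, tracts) and measurement
biases (e.g. against long-distance connections) that no generator here
emulates; the calibrations validate the estimators, not any empirical claim
about a particular nervous system.

## Reproducibility

Every stochastic routine takes a seed; the pipeline derives per-stage seeds
from a master seed by CRC-hashing stage names (all below 2³¹), so reports
are bitwise-reproducible and stages independently rerunnable.  Null-model
ensembles run through igraph's C core seeded via Python's `random`, and the
swap kernel through numba with its own seeded generator.

## Problem sizes

The shipped experiments use desk-scale sizes: lattices up to 32×32 and
10³, hierarchical networks of N = 128–256, 5000 boxes, 100-surrogate null
ensembles, 20-seed calibrations.  These were chosen so each calibration
isolates one estimator property at sizes where brute-force or closed-form
oracles exist; all routines accept larger inputs.
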