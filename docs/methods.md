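# Methods

## Model and classification procedure

Each CpG's beta values are treated as independent cross-sectional
observations of a smooth age trajectory plus noise. Two models are fitted per
CpG on a design shared across all CpGs (which is what makes the run fast —
all per-CpG work reduces to small matrix algebra against precomputed
cross-products):

**Linear model.** OLS of beta on age and covariates. The slope carries the
direction of linear change; its t-test p-value enters the LM family. BIC
counts the residual variance as a parameter (`-2 loglik + (p + 1) log n`),
matching the convention of common statistical environments so that ΔBIC is
on the familiar scale.

**Penalized smooth.** A cubic B-spline smooth of age with basis dimension
k = 5 (one interior knot at the median age), penalized by the integrated
squared second derivative and constrained to sum to zero over the observed
ages. The penalty null space is the linear-in-age direction, so as the
penalty grows the smooth collapses to a straight line and its effective
degrees of freedom (edf) tend to 1; the edf ceiling is k − 1 = 4. The
smoothing level is selected by restricted maximum likelihood: the smooth's
range space is recast as i.i.d. random effects with variance ratio r, and
the profiled REML criterion is evaluated on a log-spaced grid of 91 ratios
spanning e⁻¹⁸..e¹⁸ (grid REML is deterministic and, at this resolution,
indistinguishable from continuous optimization for classification purposes).
BIC uses total effective parameters (parametric df + random-effect edf + 1
for the scale). The smooth's p-value is an approximate F-test of the whole
age term — penalized fit versus covariates-only fit with df₁ = smooth edf —
which a permutation-null check in the test suite shows to be well calibrated
for detection purposes. An exact replication of any particular GAM software's
p-value is not attempted and not needed: the classification rule consumes the
p-value only through a BH-adjusted 1% threshold paired with ΔBIC > 2.

**Heteroscedasticity.** White's test regresses squared LM residuals on the
regressors, their squares and pairwise cross-products (n·R² against χ²).
When the auxiliary design would exceed n/5 columns it falls back to
regressors + squares, logged. Degenerate inputs (zero response variance,
perfect fits) get p = 1, a flag, and the NC label rather than an abort.

**Labels.** The three p-value families are BH-adjusted separately, each
across all CpGs of the run. Precedence is NL → LI/LD → VI → NC: ΔBIC > 2
already certifies the smooth explains more than the line, so a CpG
satisfying both the nonlinear and the linear rule is called NL.

## Trajectory decomposition and clustering

NL trajectories are predicted on a regular age grid (min to max observed
age, 1-year step) with numeric covariates at their medians and categorical
covariates at the reference level, clipped to [0, 1]. Curves are z-scored
per CpG by default so clustering sees shape, not level — mirroring the
centering/scaling applied before decomposition in the analyses this package
supports. Because the curves are already smooth, dense and regularly
sampled, functional PCA is computed by direct eigendecomposition of the
sample covariance over the grid with uniform quadrature weights;
eigenfunctions are orthonormal under that quadrature and sign-fixed
(largest-magnitude coefficient positive) for reproducibility. Components are
retained to a cumulative 99.99% of variance — deliberately conservative so
sub-cluster structure survives. An optional least-squares spline smoothing of
the eigenfunctions (knots = min(35, floor(0.8 · grid length))) is available
but off by default; on smooth input curves it is a no-op to numerical
precision.

Three clusterers operate on the scores:

* **HDBSCAN** (min cluster size 5 by default); noise keeps label 0 and is
  retained in all outputs. A refinement step can re-cluster one cluster in
  its score subspace, giving decimal sub-labels (cluster 1 → 10, 11, 12);
  a homogeneous target is left unchanged.
* **Fuzzy c-means** with the dimension-based fuzzifier estimate
  m(N, D) = 1 + (1418/N + 22.05)·D⁻² + (12.33/N + 0.243)·D^(−0.0406 ln N − 0.1134).
  Memberships are computed in log space because wide inputs drive m toward 1
  and the membership exponent 1/(m − 1) would otherwise overflow. The number
  of clusters is chosen by the minimum-centroid-distance heuristic: for each
  c (min over 3 seeded runs) record the smallest pairwise centroid distance;
  once c exceeds the true cluster count two centroids share a cluster and
  that distance collapses by an order of magnitude. We place c just before
  the *largest* relative drop (requiring at least a 50% drop): a
  first-drop rule overshoots on tight clusters, where within-cluster
  distances keep halving past the true c.
* **k-means** with 25 restarts; k from the elbow of the within-cluster
  sum-of-squares curve over k = 1..20, located at the maximum second
  difference of **log** WCSS. The raw-scale second difference always peaks
  at small k when clusters have hierarchical structure (the first split
  removes the most absolute variance); the log scale is scale-invariant and
  finds where splitting stops paying off multiplicatively, which is what the
  elbow is meant to capture.

Cluster summaries: the per-sample "eigenvalue" of a cluster is PC1 of its
centered-and-scaled beta values across samples, sign-oriented to correlate
positively with the cluster's mean methylation (preventing mirror-image
clusters from merging spuriously). Clusters whose eigenvalue vectors have
Spearman ρ > 0.90 are merged by single linkage (connected components of the
ρ-graph — the transitive closure is taken deliberately, making merging
idempotent), and merged profiles are recomputed from the union of CpGs.
Cross-cohort comparison interpolates two mean trajectories onto their
common age support and reports Pearson r.

## Wave analysis

For each window center c (default 31–77 years in 2-year steps, 24 centers),
samples aged in [c − 15, c) are compared with (c, c + 15] per CpG. The
default test is a Wilcoxon rank-sum on covariate-residualized values: a
rank-sum test takes no covariates, so each CpG is first residualized on the
covariates (linear, over all samples) — an approximation, with a per-window
linear-model backend (`test="linear"`) provided as the alternative. P-values
are BH-adjusted across CpGs within each window; counts are reported at FDR
0.05/0.01/0.001 and are nested by construction. Windows with a flank of
fewer than 5 samples are skipped, not padded. A peak is *robust* only if it
is an interior local maximum of the count profile at every FDR level —
strict persistence, so a bump that flattens at FDR 0.001 is rejected. When
effects are strong the count profile saturates into a plateau; the plateau
midpoint is then the natural wave location.

## Simulated data

The generator emulates cross-sectional array methylation with known
trajectory classes. Ages are i.i.d. uniform integers on 1..100. Fifteen
archetypes: flat baselines at U(0.2, 0.8) (NC); linear, quadratic
(zero-slope vertex at the young end for increasing, the old end for
decreasing), logarithmic (log(age)/log(100) scaling) and sigmoidal
(logistic, time scale τ = 5 y, inflections at 25/40/80, both directions)
transitions between per-CpG levels lo ~ U(0.10, 0.35) and hi ~ U(0.65,
0.90); a non-monotonic Gaussian bump (center 60 y, SD 20 y, amplitude 0.25
over base 0.35); and a variance-increasing class with flat mean 0.5 and
truncated-Gaussian noise whose SD is 0.01 below age 25 and rises linearly to
0.3 at age 100. All other classes draw values from Beta(μφ, (1 − μ)φ);
φ = 100 gives SD ≈ 0.05 at μ = 0.5, a realistic array noise level. Means are
clamped to (0.01, 0.99).

What the simulation does *not* emulate: probe-type effects, batch structure,
missingness, covariate confounding, or sex-specific trajectories. Passing
benchmarks therefore demonstrate that the statistical machinery separates
the trajectory families at realistic noise — not that any particular cohort
result will replicate.

At the default φ = 100 the archetypes are almost perfectly separable: the
combined partition recovers the 15-class truth at ARI/AMI ≈ 0.99 and the
logarithmic and linear families are not confused. The log/linear adjacency
becomes visible as noise grows — at φ = 25 (SD ≈ 0.1) overall recovery drops
to ARI ≈ 0.95–0.98 and logarithmic-decreasing CpGs begin to leak into the
linear-decreasing label, the expected failure mode of this design since a
log curve is the closest nonlinear neighbor of a line.

## Numerical choices and problem sizes

* Grid REML (91 points, log-spaced) instead of iterative optimization:
  deterministic, vectorizable across thousands of CpGs sharing one design.
* Benchmark and acceptance runs use the full 3,000 x 300 design; unit tests
  use 15 x 15 CpGs x 150 individuals, which the suite shows is already
  sufficient to recover every archetype's coarse label.
* Fuzzy c-means tie-breaks: zero distances are floored at 1e-300 before the
  log-space membership update; the final clustering keeps the best of three
  seeded initialisations by the fuzzy objective.
* All randomness flows from explicit seeds (simulator, clustering inits);
  eigendecompositions are deterministic given the sign convention.

## Known limitations

* The smooth-term p-value is approximate (F-type, conditional on the
  selected smoothing level); it is calibrated for thresholding, not for
  reporting exact tail probabilities.
* Stratified analyses (e.g. by sex) are the caller's job: run the pipeline
  per stratum. Interaction terms are out of scope.
* The wave module's covariate handling residualizes before rank testing,
  which assumes approximately linear covariate effects.
* Cluster counts from the fuzzy/k-means selection heuristics are heuristic;
  the density-based method with explicit min-cluster-size is the default for
  final cluster calls.
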