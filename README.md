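# snitch — nonlinear methylation aging trajectories

`snitch` classifies per-CpG DNA-methylation aging trajectories in bounded
beta-value data and clusters the nonlinear ones by shape. It is aimed at
epigenomics researchers working with cross-sectional array data (a CpG x
sample matrix of beta values in [0, 1] plus ages and optional covariates such
as immune-cell fractions) who want to move beyond linear age models without
pre-specifying a trajectory shape.

## Method

For every CpG, the beta values `y` are modeled against age twice:

* an ordinary least-squares linear model, `y ~ age (+ covariates)`;
* a generalized additive model with a penalized spline smooth
  `y ~ s(age, k = 5) (+ covariates)`, smoothness chosen by REML.

Three test families — the LM slope t-test, an approximate test of the whole
age smooth, and White's heteroscedasticity test (n·R² of squared residuals on
regressors, squares and cross-products) — are each Benjamini–Hochberg
adjusted across all CpGs. With ΔBIC = BIC(LM) − BIC(GAM), labels are assigned
with precedence NL → LI/LD → VI → NC:

| label | rule |
|-------|------|
| NL | ΔBIC > 2 and adj. p(GAM) ≤ 0.01 |
| LI / LD | adj. p(LM) ≤ 0.01, slope > 0 / < 0 |
| VI | adj. p(LM) > 0.01 and adj. p(White) ≤ 0.01 |
| NC | none of the above |

NL trajectories are then predicted on a one-year age grid at reference
covariates, z-scored, decomposed by functional PCA (components retained to
99.99% of variance), and the scores clustered with HDBSCAN, fuzzy c-means
(fuzzifier from the Schwämmle–Jensen estimate) or k-means. Redundant clusters
are merged when the Spearman correlation of their per-sample PC1 "eigenvalue"
scores exceeds 0.90. A sliding-window module (15-year flanks, centers 31–77
in 2-year steps, rank-sum tests with per-window BH correction at FDR
0.05/0.01/0.001) locates age "waves" of dysregulation.

A simulator generates the validation benchmark: 15 trajectory archetypes
(flat, linear ±, quadratic ±, logarithmic ±, sigmoidal ± with inflections at
25/40/80 years, variance-increasing, non-monotonic) x 200 CpGs across 300
individuals aged 1–100, with Beta-distributed noise (precision φ = 100).

## Worked example

```bash
snitch simulate --n-per-class 200 --n-individuals 300 --phi 100 --seed 1 --out sim/
snitch run --beta sim/beta.csv --samples sim/samples.csv --seed 1 --out run/
```

The `run` step prints nothing on success and leaves `run/classification.csv`,
`run/clusters_merged.csv`, `run/cluster_profiles.json` and `run/manifest.json`.
Scoring the pipeline against the simulator's ground truth:

```bash
snitch benchmark --seed 1 --no-standalone --out report.json
```

prints (one line per variant):

```
snitch_fuzzy: ARI=0.991 AMI=0.991
snitch_kmeans: ARI=0.294 AMI=0.526
snitch_hdbscan: ARI=0.992 AMI=0.992
```

ARI (Adjusted Rand Index) and AMI (Adjusted Mutual Information) compare the
combined partition — the four coarse labels plus the NL sub-clusters —
against the 15 archetype labels; both are 1.0 for a perfect recovery and 0
at chance. Values near 0.99 mean nearly every CpG is routed to its own
archetype's cluster. The k-means line shows why the density method is the
default: its WCSS-elbow k selection is a fragile heuristic and here collapsed
to k = 2 (see the methods note), while the fuzzy and density variants recover
the archetypes almost perfectly. Dropping `--no-standalone` adds the three
stand-alone clusterers run directly on the standardized beta matrix, which
score far lower (ARI ≈ 0.1–0.7) — the gap is the value added by
classification + FPCA.

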