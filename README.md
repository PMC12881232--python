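# hsm — health state manifold scoring of cohort omics data

`hsm` quantifies individual health status from cohort expression data
(transcriptomics, metabolomics, proteomics) as two complementary numbers:

* **V score — phenotypic state.** Where an individual sits on the process
  from an optimal phenotype to a disease phenotype.  A "health process
  manifold" is learned from two anchor cohorts — a *background* group with
  the best phenotype and a *target* group with the worst — by a linear
  discriminant projection combined with Laplacian eigenmaps, and every
  sample (including held-out ones) is placed on it by regression.
* **U score — homeostatic resilience.** How stable an individual (or a
  cohort stage with repeated samples) is in its current state.  Following
  dynamic-network-biomarker (DNB) theory, a group of genes whose variance
  and mutual correlation inflate sharply marks an approaching tipping
  point; `hsm` measures this as the minimum principal curvature of a local
  potential landscape fitted per gene, averaged over the k shallowest genes.
  Low U = low resilience = high transition risk.

The package targets computational biologists studying disease progression
cohorts (staged or longitudinal designs with several samples per stage) who
want early-warning signals in addition to a phenotype axis.

## The model

Given anchor matrices `X^H` (m background samples) and `X^D` (n target
samples) over p features, the projection `Y = XC` maximises the trace ratio

```
max_C  tr(C' B C) / tr(C' Σ C)
B = (x̄^D − x̄^H)' (x̄^D − x̄^H)        (between-group scatter, rank 1)
Σ = X' L X,   L = D − W               (graph-Laplacian scatter)
```

where `W` is the sample adjacency built from positive Pearson correlations.
The leading direction of `(Σ + εI)⁻¹B` is the V axis; scores are presented
as `−V` min–max scaled to [0, 1] so the background sits near 0 and the
target near 1.  A tenfold cross-validation filter can first discard features
whose discriminant loadings are unstable (coefficient of variation
`cv = sd/mean` across folds; the most stable ~70% are kept).

For the U score, each unit with ≥ 3 samples gets a coexpression network
(|PCC| > 0.7, p < 0.01).  For every gene the local module (gene +
first-order neighbours) is projected on its first two principal components,
a bivariate Gaussian `P(x)` is fitted, and the landscape `U(x) = −log P(x)`
has constant Hessian `Σ_loc⁻¹`, so the minimum principal curvature is
analytically `1/var(PC1)`.  The global U is the mean of the k (default 20)
smallest curvatures.  The DNB composite `I_DNB = SD_in · PCC_in / PCC_out`
of the k shallowest genes corroborates tipping points, and overlaps with
differentially expressed genes nominate candidate disease genes.

## Worked example

Score a simulated four-stage cohort (10 samples/stage, 50 genes, a 10-gene
signal module drifting one standard deviation per stage):

```python
from hsm import HealthManifold, HomeostaticPotential, zscore_normalize
from hsm.simulate import SimConfig, simulate_health_trajectory, trajectory_design

X = zscore_normalize(simulate_health_trajectory(SimConfig(seed=42)))
design = trajectory_design(X)          # stage_0 = background, stage_3 = target

res = HealthManifold(X, design).fit()
print(res.summary())
print(res.predict(X).to_frame().groupby("stage")["v_neg_scaled"].mean().round(3))

pot = HomeostaticPotential(X, units=list(X.stage_labels), k=20, jitter=True).fit()
print(pot.u_table().round(3))
```

prints

```
Health process manifold (discriminant Laplacian eigenmap)
==========================================================
background / target n: 10 / 10
features (p):          50
embedding dim (d):     1
ridge epsilon:         2.180e-05
trace ratio (dim 1):   1.537
orientation sign:      -1
-V anchors [min,max]:  [-3.394, 3.266]
scaled bg/target mean: 0.098 / 0.929

stage
stage_0    0.098
stage_1    0.332
stage_2    0.679
stage_3    0.929

         u_score   k  n_samples
unit_id
stage_0    0.468  20         10
stage_1    0.484  20         10
stage_2    0.459  20         10
stage_3    0.474  20         10
```

The scaled −V group means rise monotonically from the background (0.098) to
the target (0.929): the manifold recovers the stage ordering.  The U scores
are flat because every stage here was simulated in the stable regime; a
stage simulated with the critical (high-correlation, inflated-variance)
covariance scores visibly lower U — that contrast is what the tipping-point
tests exercise.

A command-line interface wraps the same functionality:

```
hsm simulate --seed 1 --out data/
hsm fit-v  --expr data/expression.tsv --design data/design.yaml --out out/v
hsm score-u --expr data/expression.tsv --units data/units.yaml --out out/u.tsv
hsm run --config run.yaml        # full pipeline incl. DNB report and plot
```

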