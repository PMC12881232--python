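# Methods

This note documents the models implemented in `hsm`, the numerical choices
behind them, what the synthetic generator does and does not emulate, and the
known limitations.  It states no empirical result beyond what the test suite
and `scripts/acceptance.py` compute.

## Phenotypic-state score V

**Model.** Two anchor cohorts define the axis: a background group `X^H`
(m samples, optimal phenotype) and a target group `X^D` (n samples, worst
phenotype), both over the same p features.  The projection `Y = XC` is
chosen to maximise the trace ratio `tr(C'BC)/tr(C'ΣC)` with
`B = (x̄^D − x̄^H)'(x̄^D − x̄^H)` and `Σ = X'LX`, where `L = D − W` is the
graph Laplacian of the sample-correlation adjacency.  The numerator pushes
the anchor groups apart (discriminant goal); the denominator penalises
directions along which correlated samples spread (neighbourhood-preserving,
Laplacian-eigenmap goal).

**Eigenproblem form.** The two side constraints attached to the trace-ratio
objective (`C'C = I` and `C'X'DXC = I`) cannot in general hold
simultaneously, so the solver realises the objective as the eigenproblem of
`(Σ + εI)⁻¹B` followed by renormalising each column of `C` to unit
Euclidean norm.  Because `B` has rank one there is exactly one informative
direction; for d = 1 the leading eigenvector is `(Σ + εI)⁻¹(x̄^D − x̄^H)`
in closed form.  Requested dimensions 2..d are not determined by the
objective and are filled with the smallest-eigenvalue directions of `Σ`
restricted to the orthogonal complement of dimension 1 — pure
Laplacian-eigenmap axes, kept for visualisation.

**Adjacency.** `W_ij = max(PCC(x_i, x_j), 0)` with zero diagonal.  Negative
correlations are clamped to zero because Laplacian weights must be
nonnegative for `L` to be positive semidefinite; an `|PCC|` mode is
available behind `weight_mode="abs"`.  No heat kernel or hard threshold is
applied.  Correlations involving a constant vector are defined as 0
throughout the package.

**Ridge.** `Σ` is singular whenever p exceeds the anchor-sample count — the
normal omics regime — so a ridge `ε = 1e-6 · trace(Σ)/p` (relative to the
mean eigenvalue scale) keeps the solve well posed.  A numerically singular
ridged matrix raises an error advising a larger ε.

**Sign and scaling conventions.** Eigenvector sign is fixed
deterministically (largest-magnitude component positive).  Orientation with
respect to the cohorts is handled only at scoring time: the sign of −V is
chosen so that the target group's mean −V exceeds the background group's,
then −V is min–max scaled to [0, 1] over all samples present at fit time.
The anchors are stored, so samples scored later may legitimately fall
outside [0, 1].  Scaled scores are invariant to any global sign flip of `C`
and to feature permutation.

**Preprocessing matters.** Expression should be z-scored (per feature,
sample sd with denominator n−1, applied over the whole dataset jointly —
a per-stage flag exists via subsetting) before fitting, mirroring the
method's standard preprocessing.  The trajectory-recovery guarantees
exercised by the tests are stated for z-scored input; on raw data with
strongly heterogeneous feature scales the Laplacian scatter is dominated by
high-variance features and stage recovery degrades.  Zero-variance features
z-score to all-zeros rather than NaN; "zero variance" is judged relative to
the feature's magnitude so round-off on a flat feature is not amplified.

**Stability filter.** Tenfold stratified cross-validation refits the
manifold on each 9/10 split and records every feature's first-axis loading.
Per-fold sign is arbitrary, so fold vectors are first flipped into positive
correlation with the fold-average vector; then `cv = sd/|mean|` per feature
(|mean| floored at 1e-12; floored features get `cv = +∞` and are dropped).
The features in the lowest 70% quantile of cv are retained by default; ties
at the boundary are kept.  When the smallest group has fewer samples than
folds, the fold count degrades to the group size with a warning.

**Combining axes.** When several feature classes each get their own V axis,
the combined score is the first principal component of the stacked oriented
−V values, sign-matched to the mean of the input axes (falling back to the
first axis when the axes cancel exactly) so the target-high convention
survives.

## Homeostatic-potential score U

**Model.** For a unit with ≥ 3 samples, a coexpression network is built
(default edge rule |PCC| > 0.7 and two-sided correlation-test p < 0.01 —
the same convention used for the package's other correlation networks,
since the local-module construction itself does not pin down thresholds).
Each feature's local module is the feature plus its first-order neighbours;
isolated features are paired with their single highest-|PCC| partner so a
bivariate fit is always possible (ties toward the smallest feature ID).
The module's samples are projected onto their first two principal
components and a bivariate Gaussian `(μ, Σ_loc)` is fitted there with the
sample (n−1) covariance.

**Curvature.** The landscape is `U(x) = −log P(x)`.  For a Gaussian this
has constant Hessian `Σ_loc⁻¹`, so "minimum Hessian eigenvalue at μ" is
computed analytically as `1/λ_max(Σ_loc) = 1/var(PC1)`; a central
finite-difference Hessian oracle exists in the tests only.  Useful exact
consequences, all asserted in the suite: scaling the sample cloud by c
divides the curvature by c²; orthogonal rotations leave it unchanged; for a
q-variable equicorrelated module with correlation ρ and unit marginals,
`var(PC1) = 1 + (q−1)ρ`, so tightening within-module correlation strictly
lowers the curvature.  This is precisely why the DNB signature (rising
correlation and variance) drives U down near a tipping point.

**Global score.** Per-feature curvatures are sorted ascending (ties broken
by feature ID) and the global U is the mean of the first k.  Default
k = 20, the conventional "top 20 genes" DNB set size; k is capped at the
feature count when units are scored in bulk.  A singular local covariance
(identical samples) is an error unless `jitter=True` adds 1e-10 to the PC
variances.  Networks are rebuilt per unit, because U is a property of the
unit's own sampling distribution.  Units with fewer than 3 samples are
skipped with a warning; n = 3 is accepted but inherently noisy (see the
accuracy harness below).

## DNB metrics

`PCC_in` is the mean absolute correlation over the C(n,2) distinct unordered
in-set pairs.  (A printed variant of this statistic divides the pair sum by
the set size n instead; that normalisation is exposed as
`denominator="n"`, but the pair mean matches the verbal definition
"average correlation among the genes" and is the default.)  `PCC_out`
averages |PCC| over all in×out pairs, `SD_in` averages per-gene sample
standard deviations, and `I_DNB = SD_in · PCC_in / PCC_out` (zero `PCC_out`
errors unless an epsilon floor is supplied).  Differential expression uses
the per-gene two-sided Student t-test at α = 0.05 with no multiplicity
correction, replicating the conventional DNB workflow; Benjamini–Hochberg
is available behind a flag.  Edge counts use the same |PCC|/p rule as the
networks above.

## Synthetic data generator

The generator emulates the two regimes DNB theory distinguishes.  A unit is
n samples over p features (defaults 10 and 50); the first `module_size`
(default 10) features follow an equicorrelated multivariate normal —
correlation `rho_stable = 0.2` and unit variance in the stable regime,
correlation `rho_critical` and variance × `var_inflation` in the critical
regime — and the remaining features are independent noise.  Staged
trajectories stack one unit per stage and shift the module features by
`drift` (default 1) marginal standard deviations per stage; stage 0 is the
background and the last stage the target.  With `drift = 0` the fit is
degenerate by construction (B ≈ 0 in expectation); the generator does not
guard against that, callers asking for separation must supply drift.

The frozen default effect size `rho_critical = 0.6`, `var_inflation = 3.2`
is the package's reference "moderate tipping point": it was calibrated once
so that the pairwise U-score accuracy at three samples per unit sits at
about 0.85 — the regime where the score is informative but far from
saturated — and rises steeply with sample size (≈ 0.94 at n = 5, ≈ 0.99 at
n = 10 under the same configuration).  The accuracy harness draws a stable
and a critical unit per replicate and counts U(critical) < U(stable); a
threshold-based classification variant exists behind `rule="threshold"`.

What the generator does **not** emulate: heavy-tailed and count-valued
expression noise, batch effects, missingness, realistic gene-gene network
topology (one equicorrelated block instead of scale-free modules), and
mechanistic transition dynamics (no stochastic differential or birth–death
model — the Gaussian surrogate only reproduces the second-moment DNB
signature).  Passing tests therefore certify the scores' behaviour under
the assumed covariance structure, not performance on any particular real
dataset.

## Problem sizes and determinism

The validation suite runs at desk scale by design: curvature identities on
100 random modules; trace-ratio optimality against 10⁴ random directions on
50 problems with p ≤ 4; trajectory recovery over 100 seeds at 4 stages × 10
samples × 50 features; tipping-point detection over 200 replicate pairs;
accuracy curves over 500 replicate pairs per sample size.  Every stochastic
component takes an explicit seed or `numpy` Generator and is bit-reproducible
given it; pipeline runs echo their full configuration next to their outputs
and rerun byte-identically.

## Limitations

* Single-sample U scores are out of scope: the curvature needs a within-unit
  covariance, so individuals without repeated measurements can only be
  scored through their stage or group.
* The independence factorisation of the joint density that motivates
  per-gene local scoring is used only as motivation; the implementation
  always goes through the local-module construction.
* Dimensions beyond the first V axis are a documented extension (pure
  Laplacian-eigenmap fill-in), not identified by the discriminant objective.
* The optional real-data script depends on external downloads and a curated
  gene list and is not part of the tested surface.
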