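# Methods

This note documents the models, defaults and numerical choices behind
`metapeak`, and what the synthetic-data experiments do and do not show.

## Data model

A peak table is a features × samples matrix of nonnegative intensities
with an explicit boolean missing mask; per-feature m/z (Th), retention
time (minutes) and optional adduct annotations ride along.  Missing
cells are tracked in the mask (NaN underneath) rather than by sentinel
values.  Empty cells, "NA" and — by default — exact zeros in input files
are treated as *not detected*: most peak pickers export dropouts as
zeros, and the detection-rate filter and MNAR-aware imputation both rely
on dropouts being flagged as missing rather than contributing spurious
zeros to means and variances.  The flag `zero_as_missing=False` restores
literal zeros.

A sample whose `class` field is empty or NA is a pooled QC injection.
QC samples anchor drift correction and CV filtering and are excluded
from all group statistics.

## Pre-processing

**Detection-rate filter.** A feature is dropped iff detected in < 50% of
QC injections or < 20% of biological samples (strict inequalities, both
configurable).  With no QCs only the biological rule applies.  The
operation is idempotent.

**Imputation.** `knn` (default k = 10) finds the k nearest *features* by
Euclidean distance over co-observed samples and imputes the mean of
their values in the affected sample — imputing across features matches
the omics convention that features, not samples, carry redundant
information.  `svd` reconstructs with a rank-3 truncated SVD iterated to
relative change < 1e-6 (max 100 sweeps).  `rf` is a missForest-style
loop of per-feature random-forest regressions (100 trees, seeded),
stopped when the imputed values stop improving; it is deterministic
given the seed.  `min_half` substitutes half the feature's observed
minimum — the conventional choice under intensity-dependent dropout.
`bpca` is a reserved name and raises: Bayesian-PCA imputation is a
project of its own.

**Transforms.** `glog(x) = log₂((x + √(x² + λ))/2)` with λ defaulting to
the squared smallest positive intensity — behaving like log₂ for large x
while staying defined at zero; plain `log` (requires positivity or an
offset) and sign-preserving `cube_root` are available.

**Scaling.** Per feature with mean m, sample sd s (n−1) and range r:
auto (x−m)/s, pareto (x−m)/√s, range (x−m)/r, vast ((x−m)/s)(m/s), level
(x−m)/m, center x−m.  Features with a zero divisor are dropped with a
warning (configurable to error).  The multivariate preset is
glog → Pareto → (implicit) centering.

**Outlier removal.** Rounds of two-component PCA; sample i is outlying
iff T²ᵢ = t²ᵢ₁/s₁² + t²ᵢ₂/s₂² exceeds expand² · 2(n−1)/(n−2) ·
F(conf; 2, n−2) with conf = 0.95 and expand = 1.0 by default — the
ellipse-expansion factor is exposed because reasonable analysts widen it.
At most three rounds by default; stops early on a clean round or when
fewer than four samples would remain.

## Normalization

**Sum** divides each sample by its observed total and rescales by the
median total (keeping intensity units).  **PQN** uses the feature-wise
median over QC samples as the reference spectrum when QCs exist (the
package is QC-centric throughout) and all samples otherwise; each sample
is divided by the median of its per-feature quotients against the
reference.  **Quantile** substitutes rank means; ties receive the mean
of the tied rank values; samples with missing cells are mapped through
interpolation of the reference distribution at their observed quantiles,
so complete samples get the exact classic substitution.

**QC-RSC.**  Per feature and per batch, a cubic smoothing spline is
fitted to QC log intensity vs injection order; the penalty is chosen by
leave-one-out CV over 20 log-spaced candidates scanned smoothest-first,
so ties keep the smoother fit.  Fewer than five QC points cannot support
a spline and get a straight-line drift fit; batches under `min_qc` (4)
usable QCs fall back to QC-median scaling.  The fitted drift is clamped
to the QC order range, subtracted on the log scale, and the feature is
re-anchored to its overall QC median — log-space subtraction and
division-by-curve on the raw scale are equivalent formulations; log
space was chosen for numerical symmetry.

**SVR.**  Same correction with an RBF support-vector regression
(ε = 0.1, C = 1, kernel width defaulting to half the QC order span,
γ = 1/(2·width²)).  Features with constant QC signal are passed through
unchanged.

**ComBat.**  Parametric empirical-Bayes location/scale adjustment on the
log scale: per-feature standardization against the grand mean and pooled
variance, per-batch location γ and scale δ² estimates shrunk toward a
normal / inverse-gamma prior by the standard iterative posterior update
(convergence 1e-4), adjusted and back-transformed.  Means and variances
are computed over observed cells only; a single batch is returned
unchanged with a warning.

**CV filter.**  After normalization, features whose QC CV (sd/mean, n−1)
exceeds 30% are dropped; the boundary value is kept (≤).  CVs are held
as fractions internally and rendered ×100% in reports.

**Method comparison.**  For each method plus a "none" baseline: total
peaks, peaks with QC CV ≤ 30%, mean CV per group, and the DEF count
(q ≤ 0.05 from Mann-Whitney + BH, fold change ≥ 1.5 or ≤ 1/1.5, VIP ≥ 1
from a two-component PLS-DA on glog + Pareto data).  Mann-Whitney was
chosen for the default DEF q-value as the distribution-free option; the
Welch t alternative is reported alongside.

## Statistics

BH q-values follow the step-up definition q₍ᵢ₎ = min_{j≥i} p₍ⱼ₎·m/j.
The Mann-Whitney test uses exact enumeration for small tie-free samples
(n₁+n₂ ≤ 12) and the tie-corrected normal approximation otherwise.
Fold change is mean(case)/mean(control) on normalized, untransformed
intensities.  The univariate AUC is the U-statistic divided by n₁n₂ with
ties counting one half, hence invariant under monotone transforms.

PLS-DA fits a −1/+1 dummy response by NIPALS deflation; R²Y is computed
on the fitted response and Q²Y as 1 − PRESS/SS from stratified 7-fold
cross-validation (folds seeded; centering re-estimated inside each
fold).  OPLS-DA removes y-orthogonal components by the standard O-PLS
deflation, then fits one predictive component; the default is one
orthogonal plus one predictive component.  VIP uses the SSY-weighted
formula, so mean squared VIP is identically 1.  The permutation test
refits Q²Y under label permutation with the +1 smoothing convention
p = (1 + #{Q²_perm ≥ Q²_obs})/(1 + n_perm), so p = 0 is unattainable.

**Power.**  From pilot two-group t statistics: π₀ is estimated by the
Storey method at λ = 0.5; the (1−π₀) fraction of statistics largest in
magnitude is converted to standardized effects d = t·√(1/n₁+1/n₂); the
curve reports the noncentral-t two-sided power averaged over that effect
set for each candidate per-group size (α when the set is empty).  This
is a deliberate simplification of density-deconvolution approaches to
pilot-based power estimation: it needs nothing beyond the pilot
statistics and is exact for a single known effect.

A note on Q²Y ceilings: with a single informative feature at
between-group separation d (in within-group sds), the population R² of
the response regression is (d/2)²/((d/2)²+1) — about 0.86 at d = 5 — so
high Q²Y values require either multiple informative features or larger
separations; the test suite plants d = 8 where it asserts Q²Y > 0.9.

## Networks

Feature pairs require ≥ 5 co-observed samples; constant features are
skipped.  Correlation p-values use the t transform with n−2 df; group
differences use Fisher z with BH control at q ≤ 0.01 (correlations are
clipped at |r| = 1 − 1e-12 before atanh).  Centralities follow the
classical definitions: closeness (reachable−1)/Σdistances within the
component (isolated nodes: 0), betweenness as unnormalized pair counts.
Communities come from fast-greedy (Clauset-Newman-Moore) modularity
maximization; the partition's modularity is recomputed from the direct
formula Q = Σ_c (e_c/m − (d_c/2m)²) as a check.  Graphs export to GML
(with node attributes) and Pajek NET.

## Identification

Neutral mass M = mz·z − shift, with electron-corrected shifts to five
decimals: [M+H]+ 1.00728, [M+Na]+ 22.98922, [M+K]+ 38.96316, [M+NH4]+
18.03383, [M−H]− −1.00728.  The ppm error is (M_obs − M_db)/M_db · 10⁶
(heavier observed ⇒ positive); candidates within the tolerance (default
10 ppm) are retrieved by binary search over the mass-sorted database and
ranked by |Δppm|.  When a feature carries an adduct annotation only that
ion form is tried; annotations naming no known adduct (isotope peaks)
are skipped.  Published worked examples reproduce to within ±0.05 ppm —
the residual reflects the 4-decimal m/z printing precision of the
source table.

## Biomarker selection

Features are ranked by random-forest impurity importance (500 trees,
√p features per split, seeded) or |weights| of a linear SVM; the ranking
is refit at each step of a halving elimination schedule down the
candidate-size grid.  Each panel size is scored by stratified 5-fold
cross-validated ROC AUC *around* the elimination loop (the conventional
placement); the best mean score wins, ties to the smaller panel.
Held-out evaluation supports both stratified random splits and explicit
train/test sample lists so published designs can be mirrored; AUROC uses
the pair-counting formula.

## Synthetic data

The generator emulates a multi-batch untargeted plasma run: per-feature
baselines ~N(17, 2²) on log2 (log-normal intensities around 10⁵),
balanced case/control assignment interleaved across batches, pooled-QC
injections at every `qc_every`-th position carrying the pooled-mean
profile plus the same measurement noise as samples, multiplicative drift
along injection order (linear or one sinusoidal period per batch, with
per-feature amplitude `drift_magnitude`·U(0.5, 1.5) and random sign),
additive per-feature batch offsets ~N(0, batch_sd²) on log2, and
differential effects `effect_log2`·U(0.5, 1.5) with random sign on
`n_diff` features in cases.  Missingness is intensity-dependent (MNAR):
dropout probability is logistic in log2 intensity with slope
`mnar_strength`, centered at the 5th percentile — chosen over MCAR
because the detection-rate filter and half-minimum imputation exist
precisely for detection dropouts.  Defaults (drift 0.3, batch sd 0.3,
noise sd 0.1 log2, effect 1.0 log2, MNAR slope 1.0) represent a
realistic mid-quality large-scale run.

What the simulations do **not** emulate: correlated feature blocks from
shared metabolites/adducts, retention-time-dependent drift, heteroscedastic
noise across the dynamic range, and peak-picking artefacts.  Passing the
recovery tests therefore shows the statistics are implemented and
calibrated correctly, not that any given real dataset will reach the
same power.

## Problem sizes and tolerances

The acceptance computations run at desk scale, chosen so the full suite
completes in minutes on one CPU: 10,000 null features for type-I
calibration; 200 null replicates at 50 permutations for permutation-p
uniformity; 200 features × 60 samples × 2 batches for drift-correction
CV metrics; 300 features for batch-variance removal; five seeds of the
500-feature/40-per-group recovery scenario; 20 seeds of the 50-feature
RFE recovery run.  The recovery scenario runs the filter → impute →
PQN → test pipeline on data without drift or batch structure: that
pipeline contains no drift-correction step, and uncorrected
injection-order drift inflates the false-discovery proportion of any
two-group test in a seed-dependent way — drift and batch correction are
validated by their own dedicated experiments instead.  The residual
observed FDR (a few percent above zero) comes from KNN imputation
borrowing group signal from differential neighbours under MNAR dropout,
a realistic and documented effect.  Numerical tolerances: spline LOOCV ties broken toward
smoother fits; SVD imputation convergence 1e-6; ComBat EB convergence
1e-4; identity checks at 1e-8 relative where drift curves should cancel
exactly.

## Known limitations

- One predictive component only in OPLS-DA (two-class designs); no
  multi-class PLS-DA.
- ComBat implements the parametric priors only.
- VSN normalization and BPCA imputation are reserved names.
- The power curve is a pilot-effect-set average, not a full
  effect-size-distribution deconvolution.
- Quantile normalization of incomplete samples relies on interpolation
  of the reference distribution; exactness holds for complete samples.
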