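# Methods

## The arm-position-matching task and its scoring chain

In the APM task a robot places one (passive) arm on one of nine targets —
a 3×3 grid with 10 cm between adjacent outer targets, centred on the
workspace origin — and the participant mirror-matches with the other
(active) arm. Six blocks of nine pseudorandomized targets give 54 trials.
Workspace coordinates are x lateral (positive rightward) and y anterior;
the mirror operation is a sign flip of x about the body midline x = 0, so
matched positions are mirrored back into target space before scoring.

Eight raw parameters summarise an exam (a ∈ {x, y}; m = mirrored matches,
t = targets):

- absolute error: mean over trials of |m_a − t_a| (cm)
- variability: mean over the 9 targets of the per-target SD of m_a across
  its 6 trials (cm)
- contraction/expansion: range of the 9 per-target mean m_a divided by the
  range of the 9 target coordinates (unitless; 1 = veridical)
- shift: mean over trials of m_a − t_a (signed, cm)

These definitional formulas are frozen as this package's contract; the
vendor analysis document they abstract is not reproduced.

**Normative z-scores.** Each parameter is regressed (OLS) on age, sex and
handedness indicators over a healthy cohort; contraction ratios are
log-transformed first (shrinkage and enlargement are symmetric on the log
scale). z = (pre-transformed raw − prediction) / residual SD. Age enters
linearly and no interactions are fitted.

**Zeta scores.** Parameters where only large values are abnormal
(absolute error, variability) use the one-sided fold
ζ = Φ⁻¹((1 + Φ(z))/2); signed parameters (shift, log-contraction) use
ζ = |z|. Both map best performance to 0 and the healthy 95th percentile of
badness to 1.96. The one-sided fold is computed through the upper tail,
−Φ⁻¹(Φ(−z)/2), and switches to the asymptotic √(z² + 2 ln 2) once the
tail underflows (z ≳ 37), keeping the transform finite for the extreme
deficits stroke simulations produce.

**Task Score.** RSS = √(Σ ζ²) over the eight zetas (zetas only: they
already encode the signed parameters as one-sided badness). The fitting
cohort's RSS values, shifted positive by 10⁻⁶, set a Box-Cox λ by maximum
likelihood and a post-transform mean/SD; a new exam's transformed RSS
z-score is folded one-sided once more to give the Task Score. Impairment
is flagged at Task Score ≥ 1.96, inclusive. Scoring an independent healthy
cohort against a model fit on a disjoint cohort leaves ≈95% below the
cutoff (93–97% at n = 2000 across seeds; the residual spread reflects
Box-Cox tail approximation and model-estimation noise at n_fit = 500).

## Synthetic data: what it emulates and what it does not

The generator provides every pipeline input with planted, recorded
effects.

- **Normative behaviour**: matching noise SD grows linearly with age
  (default 0.012 cm/yr about age 65, base 0.9 cm, between-subject SD
  0.15 cm), males +0.08 cm; contraction jitters lognormally (σ = 0.04) and
  shift normally (σ = 0.45 cm) about veridical; 1% of trials are lapses
  (broad uniform misses). Ages are uniform on 45–85, sexes balanced,
  handedness 95% right. These defaults are plausible magnitudes for
  robotic matching in older adults, not estimates of any proprietary
  normative dataset.
- **Anatomy**: a 40×48×40 grid of 4 mm voxels with an identity-orientation
  affine stands in for template space; registration is assumed done. Each
  tract/hemisphere is a radius-2-voxel tube along a gently bowed
  anterior–posterior centerline; cross-section placements keep tubes ≥ 6
  voxels apart. Control masks jitter the centerline smoothly (σ = 0.6
  voxels) and templates keep voxels in ≥ 6 of 7 controls.
- **Lesions** are multifocal unions of axis-aligned ellipsoids, one per
  targeted tract, centred on a voxel of that tract's realized template,
  with cross-section semi-axes (2.8 voxels) small enough never to reach a
  neighbouring tube; voxels on non-targeted templates are carved out.
  This guarantees the configured per-tract lesion-group memberships —
  the default 26-participant plan reproduces counts SLF I = 3, SLF II = 6,
  SLF III = 8, AF = 20, MdLF = 9 with six participants lesioning no tract.
  A single ellipsoid cannot give that guarantee, which is why the lesions
  are multifocal; components are still individually ellipsoidal.
- **Couplings** (per unit mean damage fraction across the five tracts of
  the lesioned hemisphere): +5 cm matching-noise SD, −0.8 contraction,
  ±5 cm lateral shift, −0.10 FA, +1.5·10⁻⁴ mm²/s MD, −35% tract volume,
  and −60% streamlines on the ROI pairs each tract serves (SLF branches:
  parietal–frontal; AF: temporal–frontal; MdLF: temporal–parietal).
  Directed counts are Poisson around a rate of 0.35 streamlines per mm³
  of seed volume with lognormal participant/edge noise; counts are
  treated as already distance-corrected.

Not emulated: realistic brain geometry, diffusion signal formation,
tractography failure modes, registration error, spatially correlated
metric noise, and lesion aetiology. Passing tests therefore demonstrate
that the *pipeline* recovers planted effects under its stated assumptions,
not that those effects have the magnitudes seen in patients.

## Statistics

Group comparisons screen variance homogeneity with median-centred Levene
(Brown–Forsythe) at α = 0.05 — the robust default where the original
toolchain's choice is unstated. Heterogeneous variances select Welch's
ANOVA with Games–Howell post hocs (studentized range with pairwise
Welch–Satterthwaite df; for two groups this reduces exactly to Welch's
t-test); otherwise classical ANOVA with Sidak-adjusted pairwise t-tests
(1 − (1−p)^m). Note Welch's F equals the classical F under equal variances
only up to a small-sample denominator correction that vanishes as n grows.
Regressions of Task Score on lesioned-hemisphere FA/MD/volume use OLS with
two-sided slope p-values; Benjamini–Hochberg runs per metric family across
the five tracts at q = 0.05. Two-point regressions interpolate exactly and
are flagged degenerate rather than given a p-value.

## Classification

Features are standardized to mean 0, SD 1 on the full table before
cross-validation, replicating the published order of operations despite
the mild leakage it implies; `SelectionConfig(within_fold_scaling=True)`
provides the leakage-free variant. The logistic model is L2-penalised with
C = 1 (the library default of the stated toolbox), folds are stratified
with a single global seed (reshuffled with an incremented, logged seed in
the rare case a training fold is single-class), and metrics come from
pooled out-of-fold predictions with "impaired" as the positive class.

Univariate pruning drops the three premotor/SMA pairs a priori, then
processes feature pairs with |Spearman r| > 0.7 and p < 0.05 in descending
|r|, removing from each offending pair the member with the greater mean
absolute correlation against all surviving features ("greatest mean
coefficient" read as mean absolute Spearman correlation; ties remove the
lexicographically later name). RFE builds one elimination path by
repeatedly dropping the smallest-|coefficient| feature and returns the
prefix size with the best mean CV accuracy (ties favour fewer features).
Importance is the signed mean per-fold coefficient, ranked by absolute
value.

**Cascade-ordering demo.** The qualitative claim that accuracy does not
decrease across all-features → univariate-pruned → RFE is demonstrated on
a purpose-built planted cohort (`planted_feature_scenario`, n = 70): three
informative columns load a latent impairment factor; the other columns
form five clusters of near-duplicate noise (k near-copies of a column
evade 1/k of the L2 penalty, so the all-features model overfits them
until pruning collapses each cluster), and the manually excluded pairs
are heavy-tailed noise whose standardized outliers act as per-participant
dummies. Because the expected accuracy differences between adjacent
models are small relative to single-split noise, the ordering is asserted
on mean accuracy over 8 replicate cohorts × 6 CV repeats — the ordering
is a property of the method under the demo distribution, not of one fold
assignment. At the 26-participant study scale the ordering can and does
invert on single draws.

## Numerical and design notes

- All generators and the pipeline are deterministic given an integer seed;
  `run_all` reports are byte-identical across reruns of the same config.
- Box-Cox positivity shift is 10⁻⁶ + max(0, −min RSS) (RSS ≥ 0, so
  effectively 10⁻⁶); a non-positive shifted RSS is an error.
- Normative design matrices use minimum-norm least squares, so a
  handedness category absent from a small cohort degrades gracefully
  instead of failing.
- Percent damage is expressed relative to template tract volume; the
  lesion-grouping rule (> 0%) is invariant to that denominator choice.
- Probability-map thresholding is inclusive (≥), as is the template
  agreement rule ("at least k") and the impairment cutoff.
- Tube rasterization prefilters with a KD-tree over a densely resampled
  centerline and re-tests the borderline shell against exact
  point-to-segment distance, so mask membership is exact.
- Connectivity features use the lesioned hemisphere's ROI set, matching
  the lesioned-hemisphere convention for FA/MD.
- Problem sizes used by the test suite and acceptance script (normative
  cohorts of 200–500, 2000 scored exams, 200 null ANOVA replicates, 20
  RFE seeds, 8×6 cascade replicates) were chosen to make each check's
  sampling error small relative to its assertion band on desk hardware.

## Known limitations

- The raw-parameter formulas are reasonable readings of one-line
  descriptions, not the vendor's exact algorithms; absolute Task Score
  values are therefore not comparable to clinical reports.
- Whether the composite RSS should include raw z-scores alongside zetas is
  ambiguous in the source material; zeta-only is implemented.
- Univariate collinearity pruning does not systematically improve the
  accuracy of an L2-regularized model; the demo above documents the
  conditions under which the published ordering emerges.
- Lesion groups, not lesion volumes, drive the planted behavioural
  couplings; per-voxel lesion-symptom mapping is out of scope.
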