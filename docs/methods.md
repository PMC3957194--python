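# Methods

## Model and estimation

`pathmap` fits, per voxel, a three-variable structural path model
relating a binary group code A (young = 0, old = 1), a per-subject brain
measure B (a first-level contrast value at that voxel) and a per-subject
performance measure C (seconds of switch cost):

- mediator equation: `B = β0 + a·A + ε`
- moderated outcome equation: `C = β0 + b·B + c′·A + v·A·B + ε`
- simple outcome equation: `C = β0 + b·B + c′·A + ε`

All equations are estimated by ordinary least squares with classical
t-based inference (two-sided p-values; the between-group coding makes
`a` exactly the old-minus-young difference of group means).  Two-sided
tests are the standard regression convention and are used throughout.

Arbitration between the moderated and simple models happens once, on
the original data, per voxel: the interaction is kept iff its p-value
is strictly below the height threshold (default 0.05; p = 0.05 exactly
fails).  The conditional indirect effect is `Ind = a·(b + v·A)`
(`a·b` for the young group, `a·b + a·v` for the old); under the simple
model both groups share `a·b`.

A reversed formulation `B = β0 + g·A + h·C + j·A·C + ε` is available
for methodological comparison.  It is fit with an intercept (standard
design-matrix practice, even where the formulation is sometimes written
without one) and is never used for inference here: it encodes a
different causal ordering, and its interaction t-statistic generally
differs from the causal model's — a property the test suite asserts.

## Bootstrap inference

Indirect-effect significance uses a stratified nonparametric bootstrap:
each of R resamples (default 5000) draws subjects with replacement
*within* age group, preserving both group sizes exactly.  Design
choices:

- **One resample plan per analysis**, shared by all voxels.  This keeps
  whole-brain maps internally consistent (voxel differences reflect
  data, not resampling noise), makes runs reproducible from a single
  seed, and lets the per-resample refits be vectorised: with the young
  columns of the index matrix fixed, the group column of every
  resampled design matrix is constant, so the normal equations can be
  assembled from row sums and solved as a batch.
- **Arbitration is not repeated inside the bootstrap**: resamples refit
  only the model selected on the original data, keeping the draws a
  sample from one model's sampling distribution.
- **Bias-corrected (BC) percentile intervals** by default:
  `z0 = Φ⁻¹(#{draws < point}/R)` (strict inequality; ties count to the
  upper side; the proportion is clamped to [1/(2R), 1−1/(2R)]), with
  endpoints at the nearest-rank empirical quantiles of
  `Φ(2·z0 + z_{α/2})` and `Φ(2·z0 + z_{1−α/2})`.  The nearest-rank
  (ceil(p·R)-th order statistic) quantile makes small-R results match a
  direct enumeration oracle exactly.
- **BCa** is also implemented (jackknife acceleration
  `â = Σ(m−tᵢ)³ / (6·[Σ(m−tᵢ)²]^{3/2})`); with `â = 0` it reduces
  exactly to BC.  The method literature this design follows is itself
  ambiguous about BC vs BCa in places; both are exposed, BC is the
  default, and the whole-brain engine uses BC (per-voxel jackknifes
  would add n refits per voxel for typically negligible effect at these
  skew levels — the single-voxel API offers BCa where it matters).
- Resamples with singular refits (e.g. a resample that draws no
  within-group variance) are dropped when they are ≤ 1% of R, recorded
  per voxel; beyond 1% the voxel is marked degenerate.
- A Sobel normal-theory z-test (`z = a·b/√(a²·se_b² + b²·se_a²)`) is
  provided purely as a cross-check on the bootstrap.

Measured behavior at the defaults (asserted in the acceptance tests):
under a null a-path with n = 40/group and R = 1000, the per-group
rejection rate over 500 replicates sits near 6–8% — the familiar mild
anti-conservatism of BC product-term tests — inside the accepted
[0.03, 0.08] band.

## Voxel-wise engine and reporting

Every in-mask voxel is an independent work unit; original-data fits are
vectorised across voxels (the group and performance vectors are shared,
only B differs, so per-voxel normal equations assemble from column
sums).  Any voxel ordering or subject permutation yields identical
maps; subjects align across files strictly by id, never by row order.

Voxels whose designs are singular (constant B, or B constant within
both groups) are labeled degenerate and excluded from inference and
clustering rather than aborting the sweep.  Alongside the path
coefficients, within-group one-sample t-statistics of the contrast
against zero ("dual > single" simple effects) are computed per group —
the standard within-group simple-effect test.  The interaction maps
(v, its t and p) always report the moderated fit, i.e. what arbitration
saw; the indirect-effect maps use v = 0 where the simple model was
selected.

Two significant sets are formed and are disjoint by construction:
moderated-mediation voxels (moderated model selected, interaction
p < α, indirect effect significant in ≥ 1 group) and mediation voxels
(simple model selected, indirect effect significant, minus any overlap
with the former).  Each set is labeled into connected components
(6/18/26-neighborhood; default 18, the SPM-family convention for
"contiguous"), components below the extent threshold (default 50
voxels) are discarded, and survivors are reported with:

- peak voxel: maximum |interaction t| (moderated family) or maximum
  |indirect effect| (mediation family);
- peak millimeter coordinates via the image affine (voxel indices are
  0-based internally; mm appear only at report boundaries);
- sub-peaks: strict local maxima of the peak statistic (plateau ties
  are not peaks — t-maps are continuous, so ties are degenerate), kept
  greedily in descending order with ≥ 8 mm separation, the common
  reporting convention;
- the full coefficient set and CI bounds at the peak, rounded to
  3 decimals in the TSV output.

All local maxima of surviving clusters are listed without per-peak
significance filtering; anatomical labeling is out of scope (a
user-supplied region-lookup hook can populate the region column).
No multiple-comparison correction is applied beyond the joint
height+extent rule: the low per-voxel threshold is deliberately
compensated by the large extent requirement, and the null-world tests
measure exactly how much suppression that buys.

## Behavioral summaries

The performance metric is the per-subject switch cost: the difference
of median response times on correctly answered trials between
task-switch and single-task conditions (accuracy cost analogously, as a
difference of proportions).  No-response trials contribute no RT and
count as incorrect, except on no-go trials where withholding the
response is correct — the trial generator marks no-go trials explicitly
so either accounting convention can be tested.  Group comparison of
costs uses Welch's unequal-variance t (young minus old), with
Welch–Satterthwaite degrees of freedom.

## Synthetic cohorts

The generator instantiates the structural model directly, so every
stage of the pipeline is testable with known ground truth and no data
download:

- `B_voxel = β0 + a_voxel·A + noise`, with spherical hard-edged effect
  regions (the truth maps are exact and zero outside regions) and a
  stationary smoothed Gaussian noise field (wrap-mode filtering,
  rescaled so the requested sd is the effective per-voxel sd after
  smoothing).
- `C = β0 + c′·A + (b + v·A)·B_driver + noise`, where `B_driver` is the
  B value at the driver region's **center voxel**.  A region-mean
  readout was considered and rejected: it would make every single
  voxel's regressor a noisy proxy for the generative variable
  (errors-in-variables), attenuating fitted coefficients so that no
  voxel carries the nominal truth; the center-voxel readout makes
  ground truth exactly recoverable at the region peak, which is what
  the recovery tests measure.

Default conditions mirror the reference study design: 39 young and 45
old subjects; one ~75-voxel region with a = 0.625, b = −0.021,
v = 0.109, c′ = 0.041 (the magnitudes of a published superior-frontal
peak); brain intercept −0.45 contrast units; performance intercept
0.21 s with noise sd 0.09 s (giving group switch costs near 0.22 s and
0.29 s); unit-variance contrast noise smoothed at FWHM 2 voxels on a
10×10×10 grid of 4 mm voxels — a scaled-down stand-in for whole-brain
2 mm data smoothed at 8 mm, chosen so the full pipeline (including
R = 5000 bootstraps at every voxel) runs in seconds.

What the generator does *not* emulate: hemodynamic time series and
first-level GLM estimation (the tool consumes contrast images),
anatomy, registration error, spatially varying noise, multiple
interacting driver regions, and subject-level confounds (education,
sex).  Passing tests therefore demonstrate the statistical machinery is
correct under the stated model, not that real data satisfy the model's
assumptions.

The trial-level generator draws each subject's latent single-task
median and switch cost around the group targets (costs 0.22 s / 0.29 s
with sds 0.093 / 0.16; note a group's mean per-subject cost is a
distinct quantity from the difference of its condition medians, so the
cost is targeted directly), then lognormal trial RTs
(σ_log = 0.25) truncated by the 1.9 s deadline — draws beyond the
deadline become no-response trials.  One-sixth of trials are no-go.

## Numerical choices and degenerate inputs

- OLS solves via least squares with explicit rank checking; a
  rank-deficient design raises an error naming the first linearly
  dependent column.  Residual sums of squares below 1e-12 of the
  response's total sum of squares are treated as exact fits (SE 0,
  p = 0 for nonzero coefficients).
- A constant response yields slopes 0 with p = 1 and a degenerate flag
  (convention: a slope that cannot be anything else carries no
  evidence) instead of an exception, so voxel sweeps skip flat voxels.
- Batched solves flag near-singular systems by comparing determinants
  against 1e-12 of the diagonal's Hadamard bound.
- Bootstrap quantiles use the nearest-rank order statistic; all
  stochastic components derive from a single integer seed through
  numpy's `default_rng`, and identical seeds give bit-identical output.

## Known limitations

- Inference is conditional on the selected model per voxel; arbitration
  uncertainty is not propagated (re-arbitrating inside the bootstrap
  would mix sampling distributions — documented design choice).
- No covariate adjustment (the equations match the three-variable
  model; the design-block API in `variance_explained` leaves room for
  covariates but the voxel engine does not use them).
- No cluster-level p-values, FDR, or permutation inference; the
  height+extent rule is reported as-is.
- Robust/heteroscedastic standard errors and latent-variable SEM are
  out of scope.
- The nested-R² helper supports group-only vs group+brain comparisons
  at chosen voxels; no whole-brain variance-maximizing predictor
  selection is attempted (any such number depends strongly on the
  unstated selection/regularization procedure).
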