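# Methods

## Scope and design

The package implements a radiomics classification pipeline for 3D ROI data
(volume + aligned binary mask per subject) of the kind used to distinguish
patients from controls and treatment responders from non-responders in
structural-MRI psychiatry studies. Because clinical MRI cohorts of this
kind are generally not redistributable, the package ships a synthetic
cohort generator whose phantoms carry the statistical structure the
analysis assumes; all tests and the acceptance script run on phantoms.

## Feature extraction

**Resampling.** Volumes may be block mean-pooled to a coarser lattice
(e.g. 2 mm isotropic) before extraction; the target spacing must be an
integer multiple of the input spacing per axis, and the mask follows by a
≥50% majority vote per block. No interpolation kernel is ever applied —
pooling reconciles "average to a coarser voxel" with "no interpolation",
and non-integer ratios are rejected rather than silently resampled.
Partial edge blocks average over the source voxels that exist.

**Discretization.** Fixed bin count (default G = 32), equal-width bins over
the in-ROI [min, max]; the maximum maps to level G, and a constant ROI maps
entirely to level 1. Fixed-bin-count discretization keeps the texture
matrices bounded and makes every discretization-based feature invariant to
intensity shifts (the bins re-span the range), which is the property the
inter-scanner checks rely on.

**First-order family (14 features).** energy = Σx², RMS = √(Σx²/n),
population variance, MAD = mean |x − mean|, Pearson kurtosis (normal → 3);
entropy (bits) and uniformity are computed on the discretized histogram.
Zero-variance ROIs report skewness and kurtosis 0, entropy 0, uniformity 1.

**Shape family (8 features).** Volume V = voxel count × voxel volume;
surface area A by exposed-face counting on the voxel mesh; sphericity
= π^{1/3}(6V)^{2/3}/A; spherical disproportion = A/(4πR²) with
R = (3V/4π)^{1/3} (the two are exact reciprocals, which the tests assert);
compactness1 = V/(√π·A^{3/2}); compactness2 = 36πV²/A³; maximum 3D diameter
as the largest center-to-center distance between in-mask voxels (computed
on surface voxels, via the convex hull when the surface is large);
surface-to-volume ratio A/V. The compactness1 exponent 3/2 is the
dimensionless convention of the radiomics literature.

**Texture matrices.** GLCM and GLRLM are built per direction over the 13
unique axes of the 26-neighborhood (opposite offsets identified; the
canonical representative has its first nonzero component positive, in a
fixed documented order). GLCM accumulates every in-mask pair in both
orders (symmetric by construction) and is normalized to probabilities.
GLRLM counts maximal same-level runs of in-mask voxels along each lattice
line; runs break at mask boundaries, so Σ l·R(g,l) equals the ROI voxel
count — an invariant asserted everywhere. Both matrices are checked against
independent brute-force oracles (pair enumeration; line walking) on random
5×5×5 instances. Scalar features follow the IBSI formula sheet; a second,
straight-from-the-formula implementation serves as the test oracle.

**Degenerate conventions.** A direction with no valid voxel pair yields a
flagged-empty GLCM whose features take finite documented values
(correlation 1, entropies 0, energy and maximum probability 1,
homogeneities 1, IMC1/IMC2 0, moment-type features 0). A constant ROI
(single-cell GLCM) gives correlation 1 and IMC1/IMC2 0 by the same
zero-variance convention.

**Wavelet channels.** Single-level separable 3D decomposition (default
`coif1`, configurable), periodized. Each of the 8 subbands is reconstructed
alone to the original lattice, so all 9 channels (W1 = original,
W2..W9 = LLL..HHH in a fixed order recorded in the run manifest) share one
shape and spacing, the subbands sum to the original image, and for an
orthogonal filter the subband energies sum to the input energy (exact on
even-sized grids; the default phantom grids are even). First-order and
texture features are recomputed per channel; shape features are computed
once on the mask.

**Naming.** Canonical names are `W<k>.<family>.<feature>[_<d>|_mean]`,
`shape.<feature>`. The catalog size is a pure function of the
configuration — 3,914 under the defaults (8 shape + 9 channels × (14
first-order + 14 directions-plus-mean × (19 GLCM + 11 GLRLM))) — and is
recorded, with the channel map and rosters, in a JSON manifest. An alias
map to the abbreviated literature style (`W6.Co_Corr_7`, `W1.Mid`, …) is
provided for cross-referencing only; `Mid` is read as median, `Homo2` as
IBSI homogeneity 2 (inverse difference moment), and `Sum_var` as sum
variance.

## Feature selection

Inside a training set only:

1. optional univariate Welch screen at threshold P0 (default 0.05). The
   role of P0 as a pre-LASSO screening p-value is the package's
   interpretation (it makes a grid over 0.01..0.1 meaningful); the screen
   can be disabled. An optional `screen_top_k` cap keeps only the k
   smallest p-values when a strong global effect floods the screen
   (sure-independence-screening style; off by default).
2. the training subjects are split into 10 groups; leaving out each group
   in turn, a squared-error LASSO of the 0/1 label (MSE cost, per the
   pipeline family this implements) is fitted on the remaining nine, with
   the penalty chosen as the *largest* value whose cross-validated MSE is
   within one standard error of the minimum (the sparsest statistically
   tied model). Features are z-scored with statistics of the data passed
   in — never of a held-out fold.
3. a feature's occurrence is the number of repetitions (of 10) with a
   nonzero coefficient; features with occurrence ≥ N survive. Selected
   sets are nested in N by construction.

Numerical choices: the penalty path uses 30 log-spaced values down to
alpha_max/100 with coordinate-descent tolerance 1e-3 — the 1SE rule always
lands in the upper part of the path, so the slow small-penalty tail is not
computed. Zero-variance columns are excluded with a warning. An empty
selected set falls back to the screened set with a warning.

## Classification and evaluation

Repeated k-fold CV (default 10 × 100; reduced sizes are used in tests and
the acceptance script) with the entire selection stage refit inside every
outer training set. Folds are stratified by default (the plain random split
of the original design is available; single-class folds trigger bounded
reshuffles with a warning). Classifiers: random forest with t trees
(other hyperparameters at library defaults) or SVM (linear default);
features are standardized inside the model pipeline with training-fold
statistics. Undefined metric ratios (a test fold without positives) are
reported missing, never coerced to 0. AUC is the tie-corrected rank
statistic, asserted equal to brute-force cross-class pair counting.

Grid search over P0 ∈ {0.01..0.1}, N ∈ {1..10}, t ∈ {5..100 step 5}
maximizes mean CV accuracy with ties broken toward the sparser model
(smaller N, then t, then P0). Selection stays inside the outer training
folds and the grid is scored on the outer test folds; the winner's
accuracy is therefore an optimistic estimate for the winning triple itself
(no second nesting level), which is flagged here deliberately.

The permutation test reruns the supplied pipeline — screening, selection,
fitting, everything — under each permuted labeling and reports the add-one
p-value (1 + #{null ≥ observed})/(1 + m), which cannot reach 0. Calibration
is verified on null phantoms with a reduced pipeline (screen + small
random forest, 2-fold CV) so that 50 replicate experiments at m = 199 fit
in a test run; p-value uniformity under the null is additionally checked by
a Kolmogorov–Smirnov test at smaller m.

DeLong's test compares two AUCs two-sidedly from the structural components
of the Mann–Whitney statistic; both the paired variant (two score sets on
one cohort, covariance subtracted) and the independent-cohorts variant
(variances added — the case that arises when diagnosis and prediction
models are evaluated on different subject sets) are provided. Degenerate
variance with a nonzero AUC difference is reported as non-computable
(NaN), never as p = 0.

Cross-dataset validation: `intra` pools both datasets and holds out a
stratified 20%; `inter_1to2`/`inter_2to1` train on one dataset and test
wholly on the other, selection refit on the training side. The scanner
confound check runs a Welch test per selected feature between datasets
within each class and reports unadjusted p-values with a multiplicity note.

## Outcome labeling and cohort statistics

PANSS percent change is computed relative to the 30-point scale floor,
`(total1 − total0)·100/(total0 − 30)`; baselines at or below 30 are
rejected. A reduction of exactly 30% counts as response (the boundary is
inclusive — the rule is stated as "30% reduction" without strictness, so
the inclusive reading is fixed and tested). Group comparisons use Pearson
chi-square *without* continuity correction for 2×2 tables — the variant
that reproduces the printed gender-row p-values (0.804, 0.226) on the
printed counts to 3 decimals, which the corrected statistic does not — and
Welch's unequal-variance t-test (from summaries or raw values) for
continuous rows.

## Synthetic cohorts

Each subject's volume is mean + SD·field + noise, where the field is white
noise smoothed with a subject-specific Gaussian kernel (a stationary
Gaussian random field) and normalized to unit variance. Between-subject
parameters: kernel width ~ N(1.0, 0.25) voxels, log field SD ~
N(log 10, 0.1), mean intensity ~ N(100, 5), iid voxel noise SD 1.
`texture_effect` shifts the class-1 means of *both* the kernel width
(spatial correlation length) and the log field SD, in units of their
between-subject SDs — so one knob moves both the co-occurrence
correlation-type features and the first-order dispersion features, the two
families a texture difference should express. `intensity_effect` shifts
the mean the same way. Both zero makes the classes exchangeable by
construction, which the null-calibration tests exploit.

ROIs are axis-aligned ellipsoids with ±8% per-subject jitter on the
semi-axes (so shape features vary), or two mirrored ellipsoids forming one
bilateral union ROI; masks must fit inside the grid with a one-voxel
margin and contain at least 200 voxels (grids of about 12³ and up qualify;
smaller grids are rejected as configuration errors). PANSS baselines are
normal draws (default 90 ± 17) truncated at the 60-point inclusion floor;
the percentage reduction is drawn from N(51, 16) truncated to [30, 95] for
responders and N(16, 11) truncated to [0, 30) for non-responders — a
two-component distribution straddling the 30% threshold, so any configured
responder fraction is realizable and the realized fraction converges to
it. Integer rounding at the boundary is nudged one point to preserve the
drawn label. All randomness flows from the spec's single seed through
fixed named substreams (cohort level / per-subject volumes / PANSS), so
identical specs are bit-identical.

Default study conditions: 100 subjects per class on a 24³ grid at 2 mm
isotropic spacing, texture effect 1 SD, responder fraction 61/109 ≈ 0.56,
baseline 90 ± 17. Tests and the acceptance script use scaled-down cohorts
(60 subjects for parameter recovery, 16 for permutation calibration) and
reduced CV (5 repeats; permutation m = 199 over 50 replicate experiments) —
sizes chosen so the full suite runs on a desktop CPU in minutes.

**What the phantoms do and do not show.** They carry between-class texture,
dispersion and intensity differences, subject-level shape variation, a
two-dataset structure, and outcome labels with a controllable responder
fraction — enough to verify recovery of a known effect, chance-level
behavior under the null, permutation calibration, leakage-freedom and
scanner-shift invariance. They do not model scanner bias fields, motion,
registration error, site effects beyond a constant shift, or any
biophysics of real thalamic tissue; passing tests demonstrate the
pipeline's statistical correctness, not clinical performance, and the
original study's clinical accuracies are not reproduction targets here
(its cohort is not public).

## Known limitations

- Wavelet energy conservation is exact only on even-sized grids under the
  periodized transform; odd sizes reconstruct correctly but conserve
  energy only approximately.
- Squared-error LASSO on 0/1 labels (by design, matching the procedure
  this implements) is not a calibrated probability model; it is used only
  to rank/select features.
- The grid search reports outer-fold accuracy for the winning triple
  without a second nesting level (see above).
- `two_ellipsoids` ROIs need a wide enough third axis (about 16 voxels) to
  honor the margin; the single-ellipsoid default works from ~12³.
- The DeLong unpaired variant assumes independent cohorts; partially
  overlapping cohorts are not supported.
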