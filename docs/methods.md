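# Methods

This note documents the models and procedures `petfuse` implements, the
choices made where the design was genuinely open, and what the synthetic
phantoms do and do not establish about real data.

## Phantom generator

The generator emulates template-space FDG-PET volumes on the 79×95×69 grid
at 2×2×2 mm. The control pattern is a large ellipsoidal "brain" (75 % of
the baseline uptake) with a brighter cortical-ribbon shell (125 %), a mild
deterministic low-frequency modulation so that no two axes are equivalent,
blurred by a configurable smoothness (default 6 mm FWHM). Demented
phantoms multiply the pattern inside named ellipsoidal/box regions by a
hypometabolism factor strictly in (0, 1) **before** noise; subtypes (AD,
FT, DLB, MCI, CB) are modelled purely as different region sets. Noise is
additive Gaussian clipped at zero — the simplest model with positive
PET-like values. Ages are drawn uniformly from 23–84 (controls) and 56–88
(demented).

Defaults: baseline uptake 100, noise SD 5 (5 % of baseline), smoothness
6 mm, hypometabolism factor 0.75. The factor is a free parameter of the
simulation, not an estimate of clinical effect size — no quantitative
lesion contrast is published for the patient population the tool
emulates. What passing tests show is therefore *procedural* correctness
(the statistics, features and models do what they claim on signals of
known structure); they do not show that real dementia patterns are
separable at these rates. The phantoms omit anatomy, PET physics
(scatter, attenuation), partial-volume effects and scanner batch effects.

## Preprocessing

Nonlinear spatial normalization is external-tool behavior and is replaced
by affine/trilinear resampling onto the fixed grid (phantoms are generated
natively on-grid). Global-mean scaling divides by the mean within the
brain mask; the mask, when not supplied, is a threshold mask (voxels above
10 % of the volume maximum), configurable. Smoothing is a separable
Gaussian with per-axis σ = FWHM/(2√(2 ln 2))/spacing, zero-padded
boundaries (brain in air) and kernel truncation at 4σ (mass error < 1e-4).

## Voxel-wise statistics

Design: intercept, group indicator (subject = 1), mean-centered age. The
age column is dropped automatically when it has zero variance, raising the
degrees of freedom by one. Voxels with numerically zero residual variance
(relative tolerance 1e-20 on the mean squared signal) get t = 0, as do
out-of-mask voxels. The p-threshold converts to a one-tailed Student t
critical value with df = N + 1 − p; the hypometabolic tail (t < −t_crit)
is the default. Connected components are labelled at 18-connectivity
(configurable 6/18/26) and components with size ≤ min_size are discarded —
the extent rule is strictly "more than". No random-field or FDR correction
is applied; the emulated clinical pipeline uses none.

## Radiomics

Discretization is fixed-bin-number, equal width over the in-mask
[min, max], half-open bins with the top bin closed; a constant region maps
to level 1. The inventory is pinned to the reference (IBSI-style)
nomenclature:

- first order (79): morphology 29, local intensity 2, intensity statistics
  18, intensity histogram 23, intensity-volume histogram 7;
- texture (136): GLCM 25 × {direction-averaged, direction-merged},
  GLRLM 16 × {averaged, merged}, GLSZM 16, GLDZM 16, NGTDM 5, NGLDM 17.

Conventions that had to be pinned:

- δ = 1 (Chebyshev), α = 0 for NGLDM dependence, 26-connectivity for zones
  and dependences, 13 unique 3D directions for GLCM/GLRLM.
- Percentiles use linear interpolation between order statistics (so the
  interquartile range of {1,2,3,4} is 1.5).
- Skewness/kurtosis (excess) are 0 for zero-variance regions; GLCM
  correlation and entropies are 0 for single-level regions; no feature is
  ever non-finite, including on single-voxel regions.
- The NGLDM matrix column index is the raw count of dependent neighbors
  (0 for an isolated voxel); feature weights use the dependence count
  k = j + 1 so inverse-square weights stay defined.
- GLDZM zone distance is the minimum city-block distance to the ROI edge,
  border voxels at distance 1, with the array boundary counting as edge.
- Morphology is computed on a marching-cubes mesh of the mask; for masks
  too degenerate to mesh, voxel-counting fallbacks are used and flagged in
  the feature provenance. The oriented bounding box is approximated by the
  PCA-aligned box and the minimum-volume enclosing ellipsoid by
  Khachiyan's algorithm on convex-hull vertices (tolerance 1e-3).
- Moran's I and Geary's C are exact below 2000 in-mask voxels and use a
  deterministic strided subsample above (the sums are quadratic in voxel
  count); constant regions take I = 1, C = 0.
- Intensity peaks use a 1 cm³ sphere; the sphere mean is taken over its
  in-grid part.

Every texture matrix builder is verified element-wise against an
exhaustive nested-loop enumerator on random arrays up to 4×4×4.

## Feature selection

MRMR uses the MI-difference criterion (relevance minus mean redundancy),
with an MI-quotient variant available. MI is a plug-in estimate after
per-feature equal-frequency discretization into B = clamp(⌊n/5⌋, 2, 8)
bins — pinned for exact reproducibility. Ties break by score then original
column order. Top-fraction retention keeps ⌊fraction·n⌋ features, at least
one; 10 % of 215 is 21. The correlation filter walks the MRMR order and
keeps a feature iff its |Pearson r| with every kept feature is below the
threshold (default 0.30); zero-variance features are dropped but cannot
block others. The size of the final set is data-dependent and is not
asserted on synthetic cohorts.

## Classifiers

All three networks are numpy implementations with hand-written
backpropagation and Adam.

- `feature_only`: z-score normalization (statistics from training rows
  only) → dense(16) → ReLU → dense(2) → softmax.
- `cnn`: image → conv (16 filters, 5×5×5, stride 1, no padding — the
  printed layer list has no pooling; an optional 2× max-pool block exists
  for the pure-CNN variant) → batch norm → ReLU → fully connected 50 →
  flatten → fully connected 2 → softmax. "16 5-by-5 filters" is read as
  isotropic 3D kernels: a 2D kernel cannot consume a 3D input.
- `combined`: the cnn image branch with the selected features concatenated
  onto the width-50 vector, penultimate width 50 + n_features.

Training: stratified split (default 90/10 — validation accuracy is the
model-selection metric), cross-entropy, Adam with defaults epochs 30,
batch 8, learning rate 1e-3, all exposed in `TrainingConfig`; everything
is reproducible from the seed. The default image shape is the full
template grid; tests and the acceptance script use down-scaled grids
(16³–24³), a supported configuration since phantoms regenerate at any
grid — the tiny feature network simply needs more epochs (100–300) than
the convolutional models to converge at this scale.

## Evaluation

Demented is the positive class. Scores are reported on the 0–100 percent
scale to match the clinical table layout. Model comparison uses the
two-sided paired Student t per class; all-zero differences are flagged
degenerate rather than reported as a number. An omit-subjects report
option recomputes summaries over the remainder. No multiple-testing
correction is applied across the six pairwise comparisons.

## Pipeline

`run_pipeline` chains simulate → preprocess → tmap → extract → select →
train → evaluate under a run directory, with a `.done` marker per stage
(timing, seed, outputs) enabling resume. Per-stage seeds derive from the
global seed by crc32 hashing, kept below 2³¹.

## Known limitations

- Phantom realism is deliberately minimal; absolute classification rates
  on phantoms say nothing about clinical accuracy.
- Morphology on a whole-brain threshold mask is dominated by the mask
  shape, which varies little across phantoms — on such cohorts those
  features are near-constant and MRMR correctly ranks them low.
- The Moran/Geary subsample and the OMBB/MVEE approximations trade small,
  documented biases for tractability.
- The numpy networks are CPU-oriented; the full 79×95×69 grid with the
  width-50 dense layer implies ~350 M parameters and is impractical to
  train here — the architecture supports it, but realistic use at full
  grid would motivate the pooling block.
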