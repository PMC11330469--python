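# Methods

This document describes what each stage of the pipeline computes and why the
defaults are what they are.

## Problem setting

The package studies non-invasive molecular-status classification of pediatric
low-grade glioma (pLGG) from masked 3D MRI: every subject is a volume (one or
more channels, FLAIR-like primary) together with a binary tumor mask, and a
label in {BRAF Fusion, BRAF Mutation, non-BRAF altered} (class names
`Fusion`, `Mutation`, `Other`). All feature computation and learning is
restricted to the masked region. Because no patient data ships with the
package, a synthetic cohort generator produces volumes whose class signal is
*designed*, so every downstream claim is testable.

## Synthetic cohorts (`radiofusion.synthetic`)

Each subject is built in four steps, all driven by per-subject child seeds
spawned from the cohort seed (`numpy.random.SeedSequence`), so cohorts are
bitwise reproducible and any subject can be regenerated independently.

1. **Mask.** An ellipsoid with class-dependent axis ratios, a lognormal
   radius jitter (the normal draw is truncated at ±2σ so the largest class
   geometry provably fits the default 32³ volume), random rotation, center
   jitter, and a low-frequency radial perturbation of the boundary. The mask
   is the largest 26-connected component and must contain at least 27 voxels.
2. **Texture.** A Gaussian random field (white noise smoothed with a
   class-dependent σ, then variance-normalized) fills the mask.
3. **Spatial signal.** A class-oriented linear intensity gradient across the
   mask, scaled by a magnitude parameter. This signal is available to a CNN
   that sees voxel positions, but deliberately invisible to the rotation- and
   position-invariant radiomic features.
4. **Noise and normalization.** I.i.d. Gaussian noise is added and the masked
   intensities are z-scored.

Class counts follow largest-remainder rounding of the class proportions
(defaults 142/336, 70/336, 124/336), so a 336-subject cohort has exactly
142/70/124 subjects per class. Optional secondary channels can be marked
missing at random (never the primary), mimicking incomplete MRI protocols.

`complementarity_config()` is a frozen study condition: subtle axis ratios
((1.15, 1, 0.87) and (1.08, 1.05, 0.9)), close texture smoothness values
(σ = 0.85/1.45/1.1), a gradient of magnitude 1.2 and noise 0.4. It was
designed (by pilot runs during development, before the corresponding tests
were frozen) so that the handcrafted features see part of the signal, the
CNN sees a different part, and neither alone saturates — the regime where
feature-level fusion should win.

## Radiomics (`radiofusion.radiomics`)

All texture features are computed from scratch on a discretized ROI:
`level = floor((I − min(I_mask)) / bin_width) + 1` inside the mask, level 0
outside. The default `bin_width` is 25.0, the conventional fixed bin width
for raw MRI intensities; on the synthetic cohorts (which are z-scored to
unit variance) that would collapse the ROI to one gray level, so all
experiments and tests on synthetic data pass `bin_width=0.25`, giving
roughly 15–25 gray levels. This is the package's own calibration choice.

- **GLDM** (gray-level dependence matrix): for each masked voxel, the number
  of 26-neighborhood voxels whose level differs by at most α (default 0)
  from the center. Feature: dependence non-uniformity normalized (DNN).
- **GLRLM** (gray-level run-length matrix): runs of equal level along the 13
  unique 3D directions; a run starts where the previous voxel along the
  direction cannot extend it. Features (run-length variance, gray-level
  non-uniformity normalized) are computed per direction and averaged.
- **GLSZM** (gray-level size-zone matrix): 26-connected zones of equal level
  (via `scipy.ndimage.label` per level). Feature: zone percentage
  (zones / masked voxels).

All three are verified against exhaustive brute-force enumeration of small
arrays by naive reference implementations kept in the test suite.

**Shape** descriptors pad the mask, smooth it with a Gaussian (σ = 0.8) to
antialias the voxel staircase, and extract an isosurface at 0.5 with
marching cubes. Surface area comes from the mesh triangles, volume from the
divergence theorem over the mesh, and the PCA axes of the masked voxel
coordinates give elongation and flatness (`sqrt(λ_least/λ_major)`).
Sphericity is `π^(1/3) (6V)^(2/3) / A`. On voxelized spheres of radius 4,
8 and 16 the sphericity and surface-to-volume errors shrink monotonically
(to < 0.01 absolute error in surface-to-volume at r = 16), and a 4:2:1
ellipsoid's flatness converges to 1/4 within 1.5% at the finest tested
resolution.

## Shallow 3D CNN (`radiofusion.nn`, `radiofusion.cnn`)

PyTorch is not assumed; the network is implemented in NumPy with manual
backpropagation, which makes training bitwise deterministic on CPU:

- three Conv3d(3³) blocks (16/32/64 channels) with BatchNorm, LeakyReLU
  (slope 0.01) and two 2× max-pools; Conv3d uses an im2col layout built from
  27 strided slices so the inner loop is a single matrix multiplication;
- spatial dropout after conv blocks, global average pooling, a 64→16→outputs
  fully-connected head with dropout (classification: softmax cross-entropy;
  regression: a single linear output with MSE);
- SGD with momentum 0.9 under a cosine learning-rate schedule with warm
  restarts; the best epoch is chosen by validation loss and restored;
- optional input-channel dropout during training, so multi-channel models
  tolerate missing sequences at test time.

Every layer's backward pass is verified by float64 central-difference
gradient checks (internal buffers follow the input dtype, so the checks are
not limited by float32 truncation).

## Fusion and Random Forest (`radiofusion.fusion`)

The radiomics arm trains a Random Forest on the feature table with a k-fold
(default 5) grid search over trees, leaf/split minima, depth, per-tree
sample proportion and feature proportion; ties prefer smaller models.
Per-tree subsampling uses scikit-learn's `max_samples` (bootstrap with
replacement); a nominal proportion of 1.0 is classical bootstrap. The
combined arm concatenates the trained CNN's hidden activations (global
average pool + penultimate layer) with the radiomic features — feature-level
fusion — and reuses the Random Forest pipeline. Permutation importance
(held-out, cross-validated) ranks features for the learnability experiment.

## Evaluation protocol (`radiofusion.evaluation`)

Models are compared on `n` paired stratified resamples: per class, the test
count is the largest-remainder share of the test fraction (default 20%,
at least one subject), so class counts are exact in every resample; all
arms see identical splits. The development set is further split (first fold
of a stratified 5-fold) into train/validation for CNN model selection. The
score is macro one-vs-rest AUC. Arms are compared with the corrected
resampled t-test: the paired-t variance is inflated by `n_test/n_train` to
account for overlapping training sets across resamples; it reduces to the
classical paired t-test as `n_test/n_train → 0` and returns t = 0, p = 1
for identical score vectors.

## Feature learnability (`radiofusion.learnability`)

For each target radiomic feature (either chosen explicitly or the top-k of
the permutation-importance ranking), a regression CNN is trained per
resample to predict the feature's z-scored value (standardized on the
development portion only) from the masked volume, and scored by Pearson
correlation on the held-out test subjects. On the complementary-signal
cohort the size-coupled `surface_to_volume_ratio` reaches mean r ≈ 0.96
while the normalization-style texture feature `glrlm_glnn` stays near 0 —
the pattern that explains why fusing the two representations helps.

## Pipeline and determinism (`radiofusion.pipeline`)

A single validated config (YAML or dict) selects arms A (CNN), B
(radiomics), C (combined) and/or D (learnability). Six stage seeds are
spawned from the master seed at fixed positions (cohort, split plan,
classification, importance, learnability plan, learnability), so toggling
one arm never shifts another arm's randomness. All tables are written with
fixed float formatting (`%.12g`); a rerun with the same master seed
reproduces every output byte for byte.

## Scaled problem sizes

Experiments in the test suite and acceptance script run at deliberately
reduced scale — 150-subject cohorts at 32³ voxels, 5–10 resamples, CNNs
trained for 4–8 epochs — chosen so the full suite completes on a single CPU
in tens of minutes while every qualitative property (fusion benefit,
learnability contrast, null behavior, determinism) is still exercised.
These sizes are the package's own choices for desk-scale verification, not
estimates of clinical-scale performance.

## Limitations

- Synthetic cohorts cannot certify clinical performance; they certify that
  the machinery measures what it claims to measure.
- The NumPy CNN is small and CPU-bound by design; it is not a substitute
  for a GPU training stack at realistic resolutions.
- Texture features are computed on the primary channel only, and the GLRLM
  aggregation averages features over directions (one common convention
  among several).
- The Random Forest per-tree "sample proportion" is implemented as bootstrap
  `max_samples` (sampling with replacement), not subsampling without
  replacement.
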