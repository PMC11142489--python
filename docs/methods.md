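# Methods

## Overview

`gliopipe` implements a knowledge-embedded, multi-branch classifier that
labels a co-registered multi-sequence MR study (FLAIR, T1CE, T2 plus a
lesion label map) as glioblastoma (GBM) or non-GBM.  Four branches each
produce the probability of the GBM class:

1. **Attention network (Score 1)** — a 3D CNN whose blocks concatenate a
   convolutional path with a channel- and spatial-attention-weighted
   copy, `F = Conv(f) || [CAM(Conv(f)) ⊙ SAM(CAM(Conv(f)))]`.
2. **Curriculum network (Score 2)** — a shared trunk first trained to
   identify which MRI sequence an input is, then transferred to grading
   with per-voxel lesion weights ω_mask (1.5 on the sequence-relevant
   lesion regions, 1 elsewhere).
3. **Radiomics forests (Score 3)** — first-order, GLCM-texture and shape
   features over filtered images (original, LoG, stationary wavelet
   sub-bands, squared), extracted for six sequence×mask combinations
   (FLAIR/T1CE/T2 × TC/WT), one random forest per combination, fused by
   a weighted (default uniform) mean.
4. **Volumetric diagnostics (Score 4)** — four ratio features of the
   compartment volumes,
   `F3 = (V_ET+N)/(V_ET+V_NCR/NET+N)`, `F4 = (V_ET+N)/(V_ET+V_ED+N)`,
   `F1 = ln F3`, `F2 = ln F4`, scored by ridge-regularized logistic
   regression.

The final call is soft voting: the mean of the available branch scores,
GBM iff it is at least 0.5.  A 3D U-Net trained with a combined
soft-Dice + cross-entropy loss can supply the lesion label map when no
reference segmentation is available (`use_unet_masks=True`); by default
the branches consume the reference masks so that their contracts can be
tested independently of segmentation quality.

## Synthetic phantoms

The generator emulates the statistical structure the pipeline assumes,
not anatomy: a brain ellipsoid containing nested tumor compartments —
an NCR/NET core inside an enhancing rim (together the tumor core TC),
surrounded by an edema shell (whole tumor WT).  Compartment boundaries
sit on quantiles of the ellipsoidal radius, so realized voxel fractions
match their targets to counting precision.  Intensities are Gaussian
per tissue class with sequence-specific contrast (edema bright on FLAIR
and T2, enhancing tumor bright on T1CE, necrotic core dark on T1CE and
bright on T2) plus additive noise; the skull-stripped background is
exactly zero.

Grade-conditional morphology encodes the radiological picture as a
controllable effect size.  Defaults per grade (sampled uniformly per
phantom):

| parameter | GBM | non-GBM | meaning |
|---|---|---|---|
| `et_fraction` | 0.35–0.60 | 0.02–0.15 | ET share of WT |
| `necrosis_fraction` | 0.20–0.50 | 0.55–0.85 | NCR/NET share of TC |
| `tc_radius_mm` | 8–11 | 5–7.5 | tumor-core scale (scaled with grid extent) |

GBM phantoms thus carry extensive enhancement with substantial necrosis
and a thin edema margin; non-GBM phantoms show limited enhancement — a
core dominated by non-enhancing tumor with proportionally wide edema.
The non-GBM `necrosis_fraction` band is set high deliberately: F3 is
(up to the guard N) one minus the NCR/NET share of TC, and the clinical
rule "limited enhancement in low grades" means exactly that the tumor
core of a low-grade lesion is mostly non-enhancing.  With these bands
F3 and F4 both separate the grades with a gap, by construction; the
effect sizes are modeling choices, not claims about clinical data.

Since `et_fraction` ≤ 1 − `necrosis_fraction` must hold for nested
compartments, the cohort sampler draws `necrosis_fraction` first and
caps `et_fraction` accordingly; `generate_phantom` raises on infeasible
pairs rather than truncating.

What the phantoms do **not** model: anatomy, bias fields, multi-center
intensity variation, partial-volume effects, irregular tumor shapes,
infiltrative margins.  Passing tests therefore demonstrate that the
pipeline recovers a planted, separable signal end to end — they do not
certify clinical performance.

## Normalization choices

* Volumes are z-scored over the brain (nonzero) support; background
  stays zero.  The support choice matters because skull-stripped data
  have exact-zero backgrounds.
* The curriculum branch normalizes each study's three sequences with
  **jointly pooled** brain statistics.  Per-volume z-scoring would erase
  precisely the between-sequence intensity statistics that the phase-1
  pretext task (sequence identification) discriminates on; pooling
  standardizes the study's scale while preserving relative sequence
  contrast.
* Radiomics follows the common convention of z-score × 100 before
  gray-level discretization, so the default bin width of 25 yields a
  few tens of levels.  A plain z-score with bin width 25 would collapse
  the histogram to one or two levels.

## Network and training choices

All three networks run on a compact reverse-mode autodiff engine over
numpy (`gliopipe.nn`): elementwise ops, matmul, reductions, im2col 3D
convolution, pooling, nearest-neighbor upsampling, softmax/CE, instance
normalization.  Gradients are verified against central differences in
the test suite.

* **U-Net** — encoder-decoder (default depth 2, base 8 filters) with
  skip connections, instance norm + LeakyReLU(0.01) after every
  convolution, softmax head over 4 classes.  The normalization is
  essential at this scale: with plain ReLU the heavy background/lesion
  imbalance drives the trunk into a dead-unit collapse.  The loss sums
  soft Dice over **all** classes including background (making the loss
  well-defined as a single per-voxel class distribution) with the
  cross-entropy term; probability floor 1e-7 inside the log; ε = 1e-5.
  Long volumes are split along z into `chunk_z`-deep sub-volumes for
  training.  Two empty masks score DSC 1.0 (perfect agreement).
* **Attention block** — CBAM-style internals extended to 3D: channel
  weights from a shared bottleneck MLP on global max+avg descriptors,
  spatial weights from one convolution on channelwise max+mean maps,
  sigmoid squashing; the "dot product" in the block formula is
  elementwise multiplication with broadcasting (a literal vector dot
  product is dimensionally inconsistent with the concatenation).  SAM is
  applied serially to CAM's output.  Blocks downsample by stride-2
  convolution; the head global-average-pools into a linear classifier.
* **Curriculum trunk** — stride-2 convolutions with global avg+max
  descriptor pooling (max pooling keeps small-lesion evidence that
  spatial averaging dilutes).  Phase 1 consumes single-sequence inputs
  replicated to the 3-channel width; the best-validation-accuracy trunk
  is checkpointed and transferred bitwise into phase 2.  ω_mask is
  applied to the input intensities per sequence (the earliest "in the
  network" point); `weight_features=True` instead applies the pooled
  weight field to the first feature map.  The 50/180 phase split is
  preserved proportionally when scaled down.
* **Learning rates** — the reference schedule values (U-Net 15e-4,
  branch networks 5e-4) remain the config defaults where they work at
  desk scale; the curriculum branch defaults to 2e-3 and the U-Net desk
  preset (`SegConfig.desk()`) uses 3e-3 with 12 epochs, because tiny
  nets trained for tens of steps need larger steps to move at all.
* Desk problem sizes: 64³ grids, 40-phantom cohorts, 30-ish epochs for
  the deep branches; the segmentation example runs 10 phantoms at 32³.
  All sizes are configuration.

## Radiomics details

The feature catalogue is a deliberately compact, oracle-testable set:
six first-order statistics (mean, population sd, skewness, Pearson
kurtosis, energy, entropy over discretized levels), five GLCM statistics
(joint energy, entropy, contrast, correlation, homogeneity) from a
symmetric matrix aggregated over the 13 unique unit offsets restricted
to within-mask pairs, and three shape descriptors (volume, exposed-face
surface area, maximum diameter between surface voxel centers).  Further
texture families (GLRLM, GLSZM, NGTDM, GLDM) are extension points, not
defaults.  Discretization is `floor((x − min)/width) + 1`; sparse
intensity sets can leave unoccupied levels, which simply carry zero
co-occurrence mass.  The LoG filter is Gaussian smoothing followed by a
spacing-aware discrete Laplacian (exactly zero on constants); wavelet
sub-bands come from the level-1 stationary transform so they keep full
resolution and masks apply directly; the squared image is rescaled onto
the original intensity range to keep bin semantics stable.  GLCM
correlation of a constant region is defined as 1.

## Statistics

* Feature screening: Pearson correlation against the binary grade and
  Welch's two-sample t-test; zero-variance features are flagged, not
  propagated as NaN.
* Method comparison: a paired permutation test whose statistic is the
  accuracy difference, null built by swapping the two methods'
  predictions per study.  The default p-value uses +1 smoothing and is
  therefore conservative (super-uniform) — the statistic is discrete
  and ties carry mass, so its null ECDF sits below the diagonal by
  design; this is a property of any discrete permutation statistic, not
  an implementation artifact.  `randomized=True` breaks ties uniformly
  at random, which makes the null p-value distribution exactly uniform
  and is the right choice for calibration studies; both forms are valid
  p-values.
* Degenerate report ratios (zero denominators) are `None`, flagged
  explicitly.

## Known limitations

* The autodiff engine is single-threaded numpy; it is sized for the
  desk-scale networks here, not for full-resolution clinical training.
* Phantom separability is planted; accuracy bounds in the tests are
  regression bounds against that planted signal.
* The U-Net's held-out Dice is reported on small cohorts (wide variance
  across seeds is expected); the staging branches consume ground-truth
  masks by default.
* No dropout or data augmentation; overfitting control at desk scale
  comes from small capacity and the ensemble itself.
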