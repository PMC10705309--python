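# Methods

## Problem and approach

Gliomas are delineated on four co-registered MRI modalities (T1, T1ce, T2,
FLAIR) into three nested evaluation regions: enhancing tumor (ET, BraTS
label 4), tumor core (TC, labels 1+4) and whole tumor (WT, labels 1+2+4).
No single segmentation formulation dominates: a softmax network over the
mutually exclusive labels (multi-class), a sigmoid network over the three
overlapping regions (multi-label), and one sigmoid network per region
(binary) each make different errors, and intensity standardization
(Z-score vs. Nyul histogram matching) interacts with all of them.

Region-focused selection (RFS+) treats this as a model-selection problem
per region: train one candidate per (approach × normalization) cell,
score every candidate on an internal held-out split by Dice similarity
(DSC) for the target region, keep the top three, and fuse their per-voxel
region probabilities with DSC-proportional weights

    w_i = DSC_i / (DSC_1 + DSC_2 + DSC_3),

thresholding the weighted mean at 0.5.  The predecessor strategy (RFS)
combines the three thresholded member masks by voxelwise union instead.
Heterogeneous members are aligned on the target region before weighting:
a multi-class softmax output contributes the *sum* of its constituent
class probabilities (e.g. p(TC) = p(NCR) + p(ET)), while multi-label and
binary members contribute their region channel directly.

## Networks

All candidates are canonical U-nets: `depth` encoder stages of
(3×3 conv → batch-norm → ReLU) ×2 followed by 2× max-pooling, a bottleneck
stage, and a mirrored decoder using 2× transposed convolutions with
channel-concatenation skip connections, closed by a 1×1 convolution and
the head (softmax for multi-class, sigmoid otherwise).  Feature widths
start at `base_channels` and double per pooling; the full-size
configuration (base 64, depth 4) gives encoder widths 64/128/256/512 and
a 1024-channel bottleneck.  "Same" padding keeps the output grid equal to
the input grid; inputs must be divisible by 2^depth per spatial axis.

Three variants share this skeleton: 2D (one axial slice, 4 modality
channels), 2.5D (the previous/current/next slice of each modality,
12 channels, modality-major order, zero slices at the volume ends), and
3D (volumetric kernels on a single brain-centroid-centered patch,
zero-padded where the volume is smaller than the patch).

The layers and their backward passes are implemented in NumPy
(`rfseg.nn`), with convolutions expressed as einsums over sliding-window
views so the contraction work lands in BLAS.  Each layer's gradient is
verified against central finite differences of a smooth objective in the
test suite; the composed network is additionally checked functionally
(finite gradients, steady loss descent), because finite differences on a
composed ReLU/max-pool net are unreliable near its kinks.  Weights use
He initialization, and sigmoid-head final-layer biases start at -4
(roughly the logit of the tumor-voxel prior): tumor regions occupy a few
percent of the voxels, and starting the output probabilities near that
prior instead of 0.5 removes the large initial background gradient that
otherwise traps a fraction of random inits in an all-background basin for
the rare ET/TC channels.  The per-candidate init seed is derived
deterministically from the training seed and the candidate's grid cell,
so a grid's score table does not depend on training order.  Checkpoints
are compressed `.npz` arrays next to a JSON sidecar (config, approach,
normalization id, seed, training log).

## Losses and training

Multi-class candidates minimize categorical cross-entropy over the
one-hot label channels; binary candidates minimize binary cross-entropy;
multi-label candidates average the three per-region binary
cross-entropies.  All losses are means over pixels with probabilities
clipped to [1e-7, 1-1e-7].  Optimization is Adam; paper-scale defaults
are 100 epochs / batch 16 / lr 1e-4 for the slice variants and 150
epochs / batch 4 for 3D.  Augmentation (independent horizontal and
vertical flips at p=0.5 and a rotation uniform in ±15°, nearest-neighbor
for targets so encodings stay binary) is available for 2D/2.5D training.
The final-epoch weights are the candidate's checkpoint; the validation
split is used for monitoring only.

## Normalization

Statistics are computed over the brain mask (nonzero foreground of
skull-stripped volumes) and applied per modality, per patient; background
voxels are 0 on output.

* **Z-score**: subtract the foreground mean, divide by the foreground SD.
  Stateless, hence exactly invariant to positive affine intensity changes.
* **Nyul**: foreground percentiles at ranks {1, 10, 20, …, 90, 99} are
  mapped affinely so each training volume's outer landmarks hit the
  standard range (0, 100); the standard scale is the per-rank mean,
  tie-adjusted to stay strictly increasing.  Application maps a volume's
  own landmarks exactly onto the standard scale with linear interpolation
  between landmarks and linear extrapolation outside (clipping optional).
  The ranks and range are configurable; the defaults follow the common
  configuration in the intensity-normalization literature.

Nyul states are fitted on the training split only; every trained model
records the patient ids its normalizer was fitted on, and the evaluator
refuses to score a model on any of those patients (leakage guard).

## Evaluation metrics

DSC, sensitivity and specificity are voxel-count ratios; DSC of two empty
masks is defined as 1 (a correct delineation of "nothing"), and
sensitivity/specificity return NaN when their denominator is empty rather
than an arbitrary 0 or 1.  HD95 computes, for every positive voxel of
each mask, the Euclidean distance (voxel centers scaled by the mm
spacing, via exact distance transforms) to the other mask's positive set,
and combines the two directed 95th percentiles (linear-interpolated) by
max; a pooled-percentile variant is available by keyword.  HD95 is NaN
when either mask is empty.  All four are checked against explicit-loop
brute-force oracles on random small grids in the test suite.

## Phantom cohorts

The phantom generator provides cohorts with the geometry and contrast
structure the pipeline depends on, without clinical data.  Each patient
is an ellipsoidal brain (semi-axes 0.45× the grid) containing nested
axis-aligned tumor ellipsoids — WT ⊃ TC ⊃ NCR core, with ET as the TC
shell — so the region nesting holds by construction.  The WT volume is a
random fraction (default 3–10%) of the brain, with volume-preserving
anisotropy jitter; TC is 0.55–0.75 of WT and the core 0.45–0.70 of TC
(floored at ~1 voxel so every label is non-empty at 64³).

Intensities are per-tissue means (defaults put ET at 160 on T1ce vs 90 on
T1, and ED/ET at 130/120 on FLAIR vs 70 for healthy brain — only these
orderings are normative), multiplied by a smooth random-quadratic bias
field (±10%), plus IID Gaussian noise (SD 5), plus a per-scanner affine
gain/offset (gain 0.8–1.2, offset ±10; patients are assigned round-robin
to 3 scanners).  The affine scanner effect is the minimal model of
inter-scanner intensity variation, and is exactly what Nyul/Z-score
normalization should undo; `apply_scanner_affine` lets tests build
affinely related volume pairs directly.  Everything is deterministic
given (seed, patient index).

What the phantoms do *not* emulate: anatomy (gyri, ventricles, tissue
texture), partial-volume effects, infiltrative tumor margins,
inter-modality misregistration, or non-affine scanner differences.
Passing phantom tests therefore demonstrates that the pipeline's
machinery (encodings, normalization, training, selection, ensembling,
metrics) is correct and that the networks can learn strong contrast cues
— not that the configuration reaches clinical accuracy on real MRI.

## Splits and desk-scale study conditions

Cohorts are split at patient level 70% / 15% / 15%
(train / validation / internal test), round-half-up on train and
validation with the remainder to test; candidate selection and ensemble
weights use the internal test split.

The default experiments in the tests and `scripts/acceptance.py` run at
desk scale on one CPU: 15 phantoms of 64×64×32 (split 11/2/2), the full
six-candidate grid, tiny 2D U-nets (base 8, depth 3), 8 epochs, batch 16,
lr 1e-2, no augmentation, target region TC.  The learning rate is two
orders above the paper-scale default because these runs take ~250
gradient steps instead of tens of thousands.  At this scale one grid run
takes a few minutes; ensemble metrics are reported on the internal test
split, since the clinical external dataset the full-scale strategy
targets has no desk-scale counterpart.

## Numerical choices and edge cases

* Probability→mask threshold: 0.5 throughout (configurable in
  `EnsembleSpec`).
* Selection ties: fixed candidate order (approaches multi_class,
  multi_label, binary; normalizations zscore, nyul), approach-major.
* DSC-proportional weights require all three member scores > 0; equal
  weights are an explicit opt-in fallback (`equal_weights`), never
  silent.
* Inconsistent region predictions are repaired OR-downward (ET forces TC
  forces WT) before label-map export, keeping every predicted tumor voxel.
* Z-score and Nyul raise on degenerate (constant-foreground) volumes
  instead of emitting NaNs; tied Nyul landmarks are adjusted by a
  minimal strictly-increasing bump kept inside the standard range.
* Volumes are used in array index space; headers are checked for
  agreement but never reoriented.

## Known limitations

The NumPy engine is single-threaded-CPU oriented: paper-scale
configurations (240×240 slices, base 64, 100 epochs) are expressible but
impractically slow here — the full-scale numbers in the source study are
out of reach without GPU training, which is why acceptance is structural
and oracle-based rather than a reproduction of clinical DSC tables.
3D training uses one brain-centered patch per patient (a random-crop
sampler is a natural extension).  The ensemble selects within one
variant's grid; cross-variant ensembling is out of scope.
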