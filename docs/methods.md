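# Methods

## Problem and model

The toolkit segments one connected region of interest in a 3D grayscale
volume whose edge is blurred by the partial-volume effect.  The working
hypothesis is that a distance map computed from the *edge* of the training
label, largest at the edge and decaying away from it, is a useful per-voxel
learning weight: supervising a dedicated decoder with it, and weighting the
refinement loss by it, pushes the network's capacity toward the edge region
where segmentation errors concentrate.

Training is a two-stage cascade.  Stage 1 (U-Net1) shares one image encoder
between an image decoder (rough segmentation, 2-class softmax) and a
distance decoder (distance-map regression, sigmoid output so predictions
live in `[0, 1]` like the Method A/B targets; a linear output is available
for unnormalised targets).  Stage 2 (U-Net2, same topology minus the
distance decoder) refines the channel-concatenated stage-1 outputs into the
final segmentation.  Stage 1 is trained first and frozen; stage 2 trains on
its outputs (sequential, not joint, optimisation).

## Distance-map generation

Binary labels split voxels into target and background sets; the Euclidean
distance transform assigns each target voxel its minimum distance to any
background voxel (`scipy.ndimage.distance_transform_edt`; exhaustive
all-pairs scans are used as independent oracles in the tests, never in the
library).  Distances are measured in voxel units: the intended data are
isotropic, and every map is min-max normalised, which removes the scale.

- **Method A**: edge image → reverse → EDT (distance of every voxel to the
  nearest edge voxel) → min-max normalise → `1 − map`.  Edge voxels get
  exactly 1, the farthest voxel exactly 0, and values are non-increasing in
  edge distance.
- **Method B**: EDT of the label, reflected about its maximum
  (`|max − D|`), masked by the label; the same on the reversed label;
  each part min-max normalised separately; parts added (disjoint supports,
  so the result stays in `[0, 1]`).  Because each side is normalised by its
  own maximum, intensities at equal distances inside and outside the edge
  are generally asymmetric — a property that plausibly limits this map's
  usefulness as a learning weight.
- **Method C**: the binary edge image itself — the degenerate "all weight at
  the edge" limit.

Numerical/edge-case choices: a constant distance field (min-max
normalisation with `max == min`, including the gray-value conversion to
`[0, 255]`) maps to all zeros rather than NaN, since it carries no weight
information.  The edge is defined as target voxels with at least one
background *face* neighbour; this includes isolated single-voxel targets
(their entire extent is edge), slightly broader than a boundary definition
that excludes them, which would leave such voxels unsupervised.
Out-of-volume neighbours count as background.  Transforms run
volumetrically by default (`3d`); a literal per-slice variant
(`2d_slicewise`, axis 0) is provided, and in that mode slices with no edge
voxel receive weight 0 under Method A and raise for Method B (a reversed
label slice with no background has no defined distance).  Maps are
generated offline before training and cached per case, so they add no
training-time cost.

## Losses

All four objectives share one implementation that runs on numpy arrays and
on autodiff tensors.  Dice loss is `−(2Σpy + ε)/(Σp + Σy + ε)` with
`ε = 1e−5` in numerator and denominator for empty-prediction stability.
Distdice multiplies only the intersection term voxelwise by the distance
map; the denominator stays unweighted — the weighted-denominator reading is
possible but not adopted, since with it a map of small constant value would
rescale the loss without changing its minimiser, and the unweighted form
reduces exactly to Dice when `D ≡ 1` (asserted to 1e−12 in the tests).  The
`D` entering Distdice is the stage-1 distance decoder's *output*, detached
from the gradient path (stage 1 is frozen anyway).  MAE/MSE average over
all voxels of the crop.  Stage-1 total loss is
`dice + distance_loss` with unit weights; no weighting is claimed to be
optimal, it is simply the plainest choice.

## Networks and training

Encoder: initial convolution then three basic modules (convolution module +
downsampling); a convolution module is twice (GroupNorm → ReLU → 3³ conv);
downsampling is a stride-2 convolution by default (max-pool + 1×1 conv as a
config alternative); channels default to 16/32/64/128 (desk scale
4/8/16/32, GroupNorm groups 4).  Decoders mirror the encoder; at each level
the upsampled feature map is concatenated with the same-resolution encoder
input (the feature map entering that level's convolution module) before the
decoder's convolution module.  The image decoder upsamples by learned
transposed convolution, the distance decoder by a fixed trilinear kernel —
implemented as a depthwise transposed convolution with the separable kernel
`[1,3,3,1]/4` per axis, which reproduces exact factor-2 linear
interpolation in the volume interior (borders are zero-padded and slightly
attenuated).  Skip connections use concatenation, the U-Net convention the
architecture extends.

The stage-2 input is the ordered channel concatenation (segmentation
probability, distance prediction); a config flag
(`TrainSpec.stage2_include_image`) appends the raw image as a trailing
channel — the "automatic context" cascade variant in which the refiner also
sees the original intensities.  The reduced-scale study uses this variant;
see "what the desk scale shows" below.

Optimisation: Adam, batch size 1, per-epoch polynomial LR decay
`α₀(1 − e/N)^0.9` (full-scale defaults `α₀ = 1e−4`, `N = 110`).  Volumes
are z-scored per volume (a constant volume maps to zeros with a warning);
one uniformly random crop window per step is applied identically to image,
label, and map, with symmetric zero-padding when a volume is smaller than
the crop.  No other augmentation.  Training is bit-reproducible under a
fixed seed on a fixed platform: all randomness (phantoms, weight init, crop
draws, case order) flows from `numpy` generators seeded from the specs.

The whole engine — reverse-mode autodiff, im2col 3D convolutions, and their
gradients — is implemented in numpy (`dtseg.nn`) and verified against
central-difference numerical gradients in the test suite.  float64
throughout; networks of desk size train at roughly 3–5 steps/s on one CPU.

## Synthetic phantoms

A phantom label is a union of overlapping ellipsoidal lobes (each secondary
lobe centred inside the principal one, so the union is a single
face-connected component, qualitatively mirroring blob-like atrial
anatomy); the image is the label scaled to foreground/background intensity,
Gaussian-blurred (partial-volume surrogate), plus i.i.d. Gaussian noise.
Labels keep a 2-voxel margin from the volume border so edge extraction is
unambiguous; impossible placements raise an error naming the offending
axis, and cramped secondary lobes retry with offsets shrunk toward the
principal centre.  Per-case seeds are `seed + index` for auditability.

What the phantoms do *not* emulate: MRI physics (bias fields, Rician noise,
anisotropic resolution), multi-object scenes, pathology, and inter-rater
label noise.  Passing tests therefore demonstrate the machinery is correct
and the training dynamics behave as designed — not clinical performance.

## Reduced-scale study ("desk spec") and what it shows

The desk configuration (`dtseg.desk`) fixes the study conditions for all
CPU-scale experiments: phantoms 32×32×16 at 0.625 mm with blur σ = 2.0 and
noise sd 0.8 (80 % of the contrast — edge localisation is genuinely hard),
10 cases split 7/3, network widths 4/8/16/32, crop 24×24×16, 20 epochs,
Adam `α₀ = 2e−3`, three replicate seeds, stage 2 seeing the raw image
alongside the bridge.  These sizes were chosen so a full three-configuration
ablation (one-stage, plain cascade, Method A + MSE/Distdice cascade) runs
in about five minutes on one CPU.

At this scale the *distance-map* effect reproduces directionally: Method A
supervision with MSE distance loss and Distdice refinement consistently
improves mean validation Dice over the plain cascade (about +0.5 to +1.5 %
across probed conditions).  The *cascade-versus-one-stage* effect does
not: the refiner lands slightly (≲1 %) below the one-stage baseline.  With
only seven training phantoms, stage 1 overfits them, so stage 2 trains on
near-perfect probability inputs, learns to pass them through, and at
validation time inherits stage-1's errors plus its own approximation
noise.  Full-scale cascade pipelines avoid this train/validation input
mismatch by generating stage-1 predictions with cross-validation, which is
out of scope here (a disjoint stage-1/stage-2 data split was evaluated and
merely starves both stages at this dataset size).  The corresponding
directional assertion is kept in the acceptance tests as specified and is
expected to fail at desk scale; the distance-map assertion passes.

## Known limitations

- The numpy engine is single-threaded apart from BLAS matmuls; full-scale
  crops (232×232×32, widths 16–128) are far outside its practical range.
- Method B in slice-wise mode requires every slice to contain both
  foreground and background (see above); use `3d` mode for general labels.
- ASSD uses voxel-centre surface points with face-connectivity surfaces;
  sub-voxel surface models (marching cubes) would give slightly different
  absolute values.
- Only binary (single-foreground) segmentation is supported.
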