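# Methods

## Problem setting

Aeroponically grown cassava plants are photographed with their roots hung
over a dark background (nominal capture resolution 960×720).  The trait of
interest is the number of storage roots — thick, tapered roots descending
from the stem — which are partially occluded by many thin fibrous roots of
similar colour.  Root systems younger than about 2.5 months ("young") have
thinner, less distinct storage roots than older ones ("old"), which makes
the two age groups different analysis problems.

The package frames counting as *direct image-to-count classification*: a
CNN with one softmax output per possible count (0–6, i.e. arity 7, by
default; the arity is configurable since whether a zero class is needed
depends on the data).  Inference is two-stage: a 2-way age classifier
picks which of two identically-shaped count models (trained on "old" and
"young" data respectively) sees the image.  Age-model errors deliberately
propagate into count-model selection — that is how the deployed system
behaves — but an oracle-age mode is available for ablation.

## Networks

All networks run on the package's own numpy engine (`rootcount.nn`): a
reverse-mode autograd over NCHW arrays with convolution, transposed and
depthwise-separable convolution, batch normalization, max-pooling that
records argmax indices, and Adam.  Gradients of every op are verified
against central differences in the test suite.

**Classifiers.**  DenseNet-style with the dense blocks cut to
[3, 6, 12, 8] units.  Each unit is BN→ReLU→1×1 conv (4·growth channels)
→BN→ReLU→3×3 *depthwise-separable* conv (growth channels), concatenated
onto its input; transitions compress by 0.5 and average-pool.  The stem is
a standard 3×3 stride-2 convolution followed by 2×2 max-pooling; the head
is BN→ReLU→global average pool→dense softmax.  Growth 32, stem 64 and
compression 0.5 follow DenseNet-121 conventions; 1×1 convolutions and the
stem stay standard because separating a 1×1 *adds* parameters
(k²·c_in·c_out vs k²·c_in + c_in·c_out is only a saving for k > 1).
Default input 256×256, batch size 32, Adam 1e-3 (the classifier optimizer
is an engineering choice, exposed in the API).

**Lite-SegNet.**  A four-block VGG-16-style encoder (2-2-3-3 convolutions,
filters [64, 128, 256, 512]) with BN+ReLU after every convolution and 2×2
max-pooling recording indices; the decoder unpools with those indices —
each pooled maximum returns to its exact location — and mirrors the
convolutions.  All convolutions are separable except the very first.
Output is a per-pixel 2-class softmax (background vs storage root).
Default input 640×480, batch size 2.  Segmentation-based counting
thresholds the probability map (0.5), applies morphological opening
(disk radius 1) and counts 8-connected components with a pixel-area floor
(50 px² at 640×480, scaled down for smaller inputs).  8-connectivity is
used because roots are diagonal-heavy curves; opening, the element and the
area floor are exposed parameters, since only "morphological operations"
is prescribed by the underlying method.

**Conditional GAN.**  pix2pix-style: the generator is a U-Net whose
encoder is C64⇒C128⇒C256⇒C512×7 and decoder D512×6⇒D256⇒D128⇒D64 (two
blocks deeper than the original eight), all 4×4 stride-2 convolutions;
encoder blocks are conv→LeakyReLU(0.2)→BN (no BN on the first), decoder
blocks transpose-conv→dropout(0.5, first three blocks)→BN→ReLU with mirror
skip concatenations, and a tanh output rescaled to [0, 1] to match the
dataset normalization.  Because ten halvings would collapse small inputs,
encoder depth is capped where a spatial dimension stops halving exactly,
and surplus blocks are skipped symmetrically in the decoder; the U-Net is
fully convolutional, so a trained generator also accepts any
depth-compatible mask size at native resolution (preferred, since
resizing thin binary masks fragments them).  The discriminator is a
PatchGAN — D64⇒D128⇒D256⇒D512 then a 1-channel 3×3 head — whose output
grid is input/16: 60×45 patches at 960×720.  Training: alternating updates,
Adam lr 2e-4, β₁ 0.5, β₂ 0.999, batch 2 (reference schedule: 900 epochs);
generator objective = adversarial BCE + λ·content, λ = 100 (the
adversarial/content weighting follows the pix2pix convention as it is not
otherwise specified).

**Content loss.**  Mean squared difference of feature maps of a fixed
network (`vgg16_features` default, `vgg19_features` selectable — both
readings of the method are supported) with `mse_pixels` as the plain-pixel
degenerate mode.  When pretrained VGG weights cannot be loaded, the loss
falls back to `random_features`, a fixed random-weight two-layer
convolutional feature extractor, with a logged warning; random conv
features still measure structural (not just pixel-wise) discrepancy and
keep the artifact fully offline-buildable.  Which VGG layer feeds the loss
is unspecified in the source method; the fallback sidesteps the question.

**Batch-norm recalibration.**  After short trainings the running BN
statistics (momentum 0.1) lag the weights badly, which at toy scale costs
tens of accuracy points at inference.  After each epoch the running
statistics are therefore re-estimated as the exact average of per-batch
statistics over the (un-augmented) training set — the inference procedure
of the original batch-norm formulation.  This is cheap (one extra forward
pass per epoch) and has no effect on the trained weights.

## Data

**Real data layout.**  RGB PNG images, 8-bit grayscale {0, 255} mask PNGs
binarized at >127, and a CSV manifest (sample_id, path_image, path_mask,
count, age, provenance, split).  Splits follow the 80/20 train/test rule
with a further 80/20 train/validation split of the training portion
(16% of the total), rounding half up on the test draw first; images are
normalized to [0, 1]; labels are one-hot encoded for training.
Augmentation (training split only): zoom range 0.2, brightness scaling
0.2–1.0, rotation ±10°, horizontal flip.

**Procedural generator.**  Because the field dataset is not public, the
`synthdata` module emulates its structure: storage roots are tapered
quadratic Bézier strokes hanging from an anchor band at the top of the
frame (base width drawn from a per-age range, tapering to ~15% at the
tip), fibrous roots are thin jittered random walks drawn under and over
them, the background is near-black with additive Gaussian noise.  "Young"
presets have thinner, dimmer storage roots, more fibrous roots and higher
occlusion than "old" presets, encoding the observation that young storage
roots are hard to tell from the fibrous roots that occlude them.  Age is a
generator parameter (metadata), not something computed from images.

Non-overlap placement is the default so the mask's 8-connected component
count equals the count label: anchor slots are stratified across the width
(permuted), each root's lateral extent is confined to its slot, and
placement is rejection-sampled against a dilated footprint of the roots
already placed (clearance `min_separation`, default 2 px); deadlocked
placements restart the whole sample, keeping generation deterministic per
(config, count, seed).  An `allow_overlap` flag generates the harder
occluded regime where components may merge.  All randomness flows from
explicit integer seeds; identical inputs give bit-identical images.

What the generator does *not* emulate: photorealistic texture, genotype
differences, lighting gradients, camera noise statistics, or the ambiguity
of bulking roots near the young/old boundary.  Tests passing on this data
show the algorithms and training loops are correct and learnable-from; they
do not certify field accuracy.

## Metrics

Segmentation is scored from the c×c pixel confusion matrix n(i, j):
pixel accuracy Σnᵢᵢ/Σnᵢⱼ; MeanIoU, average precision and average recall as
class averages of nᵢᵢ over (row+col−diag), column and row sums.  A class
absent from both rasters contributes a perfect 1 to a class average; a
class present on only one side contributes 0 (a fixed policy so the
2-class scores are deterministic on degenerate inputs).  Counting is
scored with PercentAgreement (exact-match rate), signed CountDiff and
AbsCountDiff (mean and SD; population SD with divisor N by default,
`ddof=1` available), and MSE.

## Scaled-down study conditions

The reference experiments run at desk scale, chosen once as the smallest
sizes at which every stage trains meaningfully on one CPU:

- classifiers: 64×64 input, dense blocks (1,1,1,1), growth 16, stem 16;
  age model 10 epochs, count models 35 epochs, Adam 3e-3, batch 8;
- easy dataset: counts {1,2,3}, 50–60 samples per count per age, wide
  well-separated roots (old 7.5–9 px, young 5.5–7 px at 64 px width,
  4 px clearance, no storage-root occlusion);
- Lite-SegNet: filters (16,32,64,64), 8–10 epochs, Adam 3e-3, on a
  class-balanced ~120-image subset; counting with min_area 15 px² at 64²;
- GAN: 32×32 pairs, encoder (32,64,128,128,128), 30 epochs, batch 2,
  `random_features` content loss;
- GAN quality gate: a segmenter trained on procedural images must score
  GAN output within 0.10 absolute MeanIoU of held-out procedural images —
  the same train-on-real/test-on-synthetic methodology used at full scale,
  without claiming full-scale numbers.

Under these conditions the end-to-end system reaches ≥90% counting
agreement and ~100% age accuracy on easy synthetic test sets, the
segmentation baseline degrades sharply on high-occlusion sets (its known
failure mode: merged masks and spurious segmentations), and the GAN gate
gap is well inside 0.10.  The test-suite thresholds (0.9 for classifier
accuracy and the CNN count route, 0.8 for the segmentation count route on
the easy set, 0.6 MeanIoU for the toy segmenter) were pinned after
verifying these conditions across seeds.

## Numerical and design notes

- "Separable" means depthwise-separable (depthwise k×k then pointwise
  1×1), the MobileNet/Xception reading; the parameter-count helpers
  document the arithmetic for both the standard and factorized forms.
- Argmax tie-breaks take the lowest index, everywhere.
- Masks combine by horizontal translation only: roots hang vertically
  from a shared anchor, so vertical shifts would break the geometry.
  Component-sum selection does a randomized depth-first search over
  available counts (≤6 parts).
- Degenerate inputs: empty masks count 0; an all-zero confusion matrix
  raises; empty prediction lists raise; opening with radius 0 is the
  identity.
- Training determinism holds for fixed seeds under single-threaded BLAS;
  checkpoints store float32 weights plus float64 BN running statistics.
- Known limitations: no instance separation of touching storage roots
  (merged components count as one); the GAN at toy scale produces
  blurry, colour-correct root shapes rather than realistic texture; the
  procedural age cue (brightness/width) is stronger than in real imagery,
  so the age task saturates more easily than field data would.
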