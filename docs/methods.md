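# Methods

## Architecture

AIM-Unet is a four-stage U-Net with an inception module on every skip
connection. The encoder uses 64/128/256/512 filters (two 3×3 convolutions per
stage, then 2×2 max-pooling), the base 1024, and the decoder mirrors the
encoder with transposed 2×2 convolutions for upsampling. Each inception
module runs its input through four parallel branches — 1×1; 1×1→5×5;
1×1→3×3→3×3; 3×3 stride-1 max-pool→1×1 — concatenates the branch outputs,
repeats the four-branch block once, and closes with two 3×3 convolutions.
Every convolution inside the modules carries batch normalization and ReLU;
all convolutions use stride 1 and "same" padding so the modules preserve
spatial dimensions, and the network as a whole maps an H×W input to an H×W
single-channel sigmoid probability map for any H, W divisible by 2^depth.

### Fixing the free widths

The published description of this architecture pins the encoder/decoder/base
filter counts and the module *topology*, but not the widths of the sixteen
convolutions inside each module, the batch-normalization placement, or the
upsampling operator. The published totals — 41,695,169 parameters, of which
41,672,129 trainable and 23,040 non-trainable, across 188 layers — are the
only quantitative constraints, and they are surprisingly restrictive:

* 23,040 non-trainable parameters means exactly 11,520 batch-normalized
  channels (two running statistics per channel).
* The widely reproduced reading of the filter table — module output width
  2× the encoder width (128/256/512/1024), with the skip concatenating
  encoder features, module output and upsampled features — is
  *arithmetically impossible*: the two closing 3×3 convolutions at those
  widths alone cost ≈25M parameters, pushing any such configuration far past
  the printed total. An exhaustive closed-form search over branch/tail
  widths (all four branches at width b, tails at width T, per level)
  confirmed no solution exists under that wiring.
* A full search over wiring × BN placement × upsampling × per-level widths
  has exact solutions. The shipped default is the solution in which the
  widths grow monotonically with depth and the tails are at least as wide as
  the branches:

  | skip level | encoder width | branch width b | tail width T |
  |-----------:|--------------:|---------------:|-------------:|
  | 1          | 64            | 72             | 80           |
  | 2          | 128           | 136            | 136          |
  | 3          | 256           | 152            | 160          |
  | 4          | 512           | 176            | 192          |

  together with: the skip connection carries the module output (the encoder
  features enter the module rather than bypassing it), transposed 2×2
  convolution upsampling, and batch normalization after every module
  convolution, every decoder 3×3 convolution and every transposed
  convolution (none in the encoder or base). This reproduces all four
  printed numbers exactly and is what `NetworkConfig()` builds. Every width
  and the BN scope remain configurable through `IMPSpec`/`NetworkConfig`.

### Layer-counting convention

A "layer" is one graph node of kind input, convolution, batch normalization,
max-pool, upsample, concatenation or output. ReLU/sigmoid activations are
fused into their convolution records, as deep-learning frameworks commonly
list them; counting activations separately would exceed 230 nodes for every
candidate wiring, so the fused convention is the only one consistent with
the printed 188. Under it: 1 input + 82 convolutions + 1 output convolution
+ 76 batch norms + 12 pools + 4 upsamples + 12 concatenations = 188.

## Training protocol

Adam (β₁ = 0.9, β₂ = 0.999), learning rate 10⁻³, batch size 3, binary
cross-entropy with predictions clipped to [10⁻⁷, 1−10⁻⁷], up to 100 epochs,
a 0.20 validation division of the training pairs, optional early stopping on
validation loss with patience 5 (off by default). Dice, IoU, recall and
precision are tracked per epoch on the held-out fraction with predictions
thresholded at 0.5; the weights with the best validation loss are restored
at the end. Dropout is absent by default (the published tuning never states
a final value; it adds no parameters either way).

One deliberate deviation from framework defaults: batch-normalization
running statistics use momentum 0.9 and are seeded from the first batch.
With the Keras default (0.99) the running statistics lag the batch
statistics so badly over a few hundred CPU-scale steps that evaluation-mode
output collapses even when training-mode output is nearly perfect; momentum
0.9 removes the train/eval gap at the training lengths this package is
designed to run, and has no effect on parameter counts.

## Preprocessing

Fixed order: HU windowing to [−100, 200] → global histogram equalization →
resize to 256×256 → affine normalization to [0, 1]. Equalization maps every
pixel to the normalized cumulative histogram of its 256-bin quantized
intensity, computed over the slice's own windowed range; it is monotone
non-decreasing (rank-preserving) and sends a constant slice to a constant.
Images resize bilinearly, masks by nearest neighbour (preserving {0, 1}).
Normalization maps [min, max] affinely to [0, 1]; a constant slice becomes
all zeros.

Augmentation produces exactly six extra views per training pair: center crop
(87.5%, resized back), ±15° rotations, 5×5-cell grid distortion (magnitude
0.3), vertical flip, and random brightness/contrast (±0.2). Geometric
transforms use identical parameters for image (bilinear) and mask (nearest,
zero-filled borders); the photometric transform never touches the mask.
Magnitudes are package defaults — the source names the six transforms but
not their parameters — and all are configurable. Augmentation applies to
training pairs only.

Patient-level split: 10% of patients to test, then 30% of the remainder to
validation and 70% to training, whole patients only. Test and validation
each take at least one patient so that the smallest sensible cohorts (three
patients, as in the smoke pipeline) still populate all three sets; with 50
patients this gives the canonical 5 test patients. The within-training 0.20
validation division used by the optimizer is a separate, slice-level split.

## Phantoms: what they emulate, what they do not

The generator emulates the statistical structure the pipeline needs: one
bright, connected, roughly elliptical liver per slice (60 ± 10 HU) whose
boundary is perturbed by bounded low-frequency harmonics (total radial
perturbation ≤ 6%, keeping the area within analytic bounds of π·a·b);
darker cluttered background (−100–0 HU ellipses); optional hypodense tumors
(offset −30 HU) fully contained in the liver; additive Gaussian noise
(σ = 5 HU); per-patient stacks whose liver area follows a smooth axial
profile (small at the ends, largest mid-volume, emulating ~73-slice
clinical stacks). Randomness is counter-based (Philox keyed by seed,
patient, slice), so any slice is reproducible in isolation and generation
order never matters.

Phantoms do **not** emulate organ texture, neighbouring organs of similar
density, partial-volume effects, scanner physics or anatomical shape
variation beyond the perturbed ellipse. A green phantom test therefore
establishes that the pipeline's machinery — geometry, gradients, bookkeeping,
determinism — is correct; it says nothing about segmentation accuracy on
clinical CT, which requires the real cohorts and GPU-scale training that are
out of scope here.

## Numerical choices and degenerate inputs

* Thresholding: strictly greater than 0.5 is foreground; exactly 0.5 is
  background (the tie rule the source states for binarization).
* Both-empty-mask convention: Dice = Jaccard = 1, flagged as degenerate, so
  liver-free slices do not poison averages; zero-denominator recall and
  precision return 0, flagged.
* The printed loss formula places prediction and truth inside the logarithm
  in a way that is undefined for binary truth; the implementation uses
  standard binary cross-entropy (truth weights the log-probability), which
  is the only well-defined reading.
* Aggregated tables report mean ± population standard deviation, formatted
  as percentages with two decimals; both across-slices and
  per-patient-then-across-patients aggregation are provided (the source does
  not say which its tables use).
* Mask files binarize as nonzero → 1 on read (annotation tools commonly
  store 0/255); written masks store exact {0, 1} PNGs, which round-trip
  bit-identically.
* DICOM reading is a minimal explicit-VR little-endian parser (rescale
  slope/intercept applied to HU; slices ordered by axial position, instance
  number as tie-break) because no full DICOM library is available in the
  runtime environment; undefined-length sequences are unsupported.

## Known limitations

* The NumPy network trains at CPU scale only; the full-size 41.7M-parameter
  configuration is buildable and runnable but not practical to train here.
* Single-head binary segmentation; liver and tumor models are trained
  separately (a predicted tumor mask can optionally be clipped to the
  predicted liver).
* 3-D surface extraction/smoothing of the stacked prediction volume is out
  of scope; the voxel stack is exported as NIfTI for external renderers.
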