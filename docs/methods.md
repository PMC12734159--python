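# Methods

## The model

`stripfuse` implements a two-scale convolutional classifier for 4-class
brain-MRI-style images. The design combines three ideas:

1. **Shallow spatial blocks** (VGG style). Each is a 3×3 same-padded
   convolution, batch normalisation, and ReLU; the first block is followed by
   2×2 max pooling and the second by 2×2 average pooling (both stride 2), so
   a 224×224 input reaches the third block at 56×56. These layers capture
   local, fine-grained structure — edges, texture, lesion boundaries.

2. **Deep residual blocks** (ResNet style). Four blocks, each with two 3×3
   convolutions. The first convolution carries batch norm and ReLU; the
   second carries only a ReLU, and the branch output is added to a shortcut
   (identity when the shape is preserved, a strided 1×1 projection
   otherwise). Note the deliberate deviations from canonical ResNet: there
   is no batch norm after the second convolution and no post-addition ReLU,
   so a block whose weights are all zero is *exactly* the identity — a
   property the unit tests pin. Downsampling in the deep half uses strided
   convolutions (strides 1, 2, 2, 2), taking 56×56 to 7×7.

3. **Strip-pooling attention heads** at two tap points: after the third
   spatial block (56×56×128) and after the fourth residual block (7×7×512).
   For an input feature map Z ∈ ℝ^{C×H×W}, strip pooling computes per-row
   means hᶜₕ = (1/W) Σⱼ Zᶜₕⱼ and per-column means vᶜⱼ = (1/H) Σₕ Zᶜₕⱼ. Each
   directional vector goes through a channel-mixing 1-D convolution
   (kernel 3, same padding) and batch normalisation, is broadcast back to
   H×W, and the two directions are fused by elementwise summation. A 1×1
   convolution and a sigmoid turn the fused map into a gate G ∈ (0,1)^{C×H×W}
   and the module outputs Z ⊙ G. Because each gate element aggregates an
   entire row and an entire column, elongated anisotropic structures —
   which square pooling windows dilute with background — influence the gate
   coherently along their full extent.

   A **combination head** wraps the attention module: strip attention →
   global average pooling → dropout (rate 0.3, training only) → fully
   connected layer producing a length-D vector (D = 256 by default). The
   heads are *side branches*: the backbone passes the raw spatial-block-3
   output to the residual blocks, and the two head vectors are concatenated
   (2D features) before a single linear classifier and softmax over the four
   classes.

### Widths and the parameter budget

The architecture targets roughly 9.8 M trainable parameters. Channel widths
are (32, 64, 128) for the spatial blocks and (128, 256, 384, 512) for the
residual blocks with D = 256, giving 10,067,908 parameters (within ±10 % of
the target). The third residual stage is 384 rather than the 512 a textbook
doubling schedule would suggest; with 512 there, the channel-mixing 1-D
strip convolutions push the total to ~12.1 M, outside the budget.

### Ablation variants

The variant builder reproduces the standard component ablation:
A = spatial blocks + plain head (global average pool + FC);
B = A with the shallow strip-pooling combination head;
C = residual blocks + plain head; D = C with the deep strip head;
E = full backbone with two plain heads; F = the complete model. Variants
differ only in the component under test — the plain head is exactly the
combination head minus strip attention and dropout.

## Training

Defaults: AdamW (β = 0.9/0.999, ε = 1e-8) with learning rate 1e-4 and
decoupled weight decay 1e-4, batch size 32, cross-entropy loss, dropout 0.3,
50 epochs. After every epoch the internal-validation accuracy is evaluated
in deterministic eval mode and the parameters are snapshotted whenever it
improves; the returned checkpoint is always the best-validation model.
Adam, RMSprop and SGD are available through the config for optimizer
comparisons. No learning-rate schedule is used. Class imbalance is left
unweighted.

Training-time augmentation (each transform independently with probability
0.5): rotation within ±15°, horizontal flip, translation up to 10 % of the
side, brightness and contrast within ±10 %. Augmentation never runs at
evaluation.

All randomness flows from a single root seed: stage seeds are derived as
`crc32(stage_name) XOR root mod 2^31`, and two runs with the same seed
produce bit-identical training histories on the same machine.

## Data handling

Images live in class-named folders (`glioma`, `meningioma`, `pituitary`,
`notumor`) and are tracked by a manifest (tab-delimited text) holding a
globally unique ID, the original source ID, path, class label and split.
Merging multiple sources assigns fresh global IDs and drops records whose
source ID matches an earlier record (first occurrence wins), so the same
underlying image can never appear in two splits.

Splitting is stratified per class: round-half-up of 70 % of each class is
the training portion, the remainder is the test set, and round-half-up of
15 % of the training portion becomes the internal validation set. The
round-half-up rule is load-bearing: for class sizes 1621/1645/1757/2000 it
yields training portions 1135/1152/1230/1400 and test portions
486/493/527/600 (totals 4917 / 2106), exact to the reference partition of
the public four-source MRI collection.

## Preprocessing

The fixed chain is resize → grayscale → unsharp mask → Sobel enhancement.

* Resize: bilinear, anti-aliased when downscaling, to side × side
  (default 224).
* Grayscale: luminance weights (0.299, 0.587, 0.114). The network's first
  convolution takes one input channel.
* Unsharp mask: `clip(img + amount·(img − blur(img)))` with a Gaussian blur
  of σ = radius/3 truncated at 3σ (default radius 100 px, amount 1). A
  "radius" names the kernel's footprint, not its σ; the σ = radius/3
  convention is the common one.
* Sobel: `clip(img + weight·√(Gx²+Gy²))` with the standard 3×3 kernels and
  weight 0.5. The edge magnitude is *added* to the image (sharpening), not
  substituted for it.

Every step clips to [0, 1] where it can leave the range, and the chain is
deterministic.

## The phantom generator

Real multi-source MRI data cannot ship with the package, so the whole stack
is exercised on synthetic phantoms: an elliptical soft-edged "brain" (semi-
axes ≈ 0.40·s and 0.34·s with per-seed jitter) on a dark background, smooth
Gaussian-filtered texture inside (base 0.32, amplitude 0.12, ceiling 0.60),
additive Gaussian noise (σ = 0.02 by default), and one of four lesion
classes at intensity 0.85:

* **elongated** — a quadratic-Bezier strip, roughly axis-aligned, length
  ≈ 0.46–0.56·s, jagged half-thickness ≈ 0.018–0.028·s, perpendicular sag
  ≈ 0.015–0.035·s. Its bounding box is at least 3:1 (typically 5–9:1) —
  the anisotropic shape strip pooling is built for.
* **compact** — a disc of radius 0.055–0.085·s near the brain boundary.
* **central** — a disc of radius 0.030–0.045·s near the centroid.
* **none** — texture only; no pixel reaches the lesion intensity.

The generator retains its exact binary lesion mask, so rendered images can
be checked against ground truth, and is byte-reproducible under a fixed
seed (per-image seeds derive deterministically from the dataset seed).

**What the phantoms do and do not show.** They preserve the *geometric*
distinctions the architecture targets (anisotropy, peripheral vs central
position, lesion presence) and make the task learnable by a small model in
minutes, which is what the tests need. They have none of the difficulty of
real MRI — no acquisition physics, bias fields, partial-volume effects,
anatomical variability, or inter-scanner intensity shifts — so passing the
synthetic tests demonstrates that the implementation trains and
discriminates as designed, not that the model reaches any particular
accuracy on clinical data.

## The reduced validation task

The desk-scale study conditions used by the test-suite and the acceptance
script: widths divided by 4 (spatial 8/16/32, residual 32/64/96/128,
D = 64), 96×96 inputs, 100 phantoms per class, 15 epochs, learning rate
1e-3. Two choices deserve note:

* 96 px is the smallest input the full model admits: the deep tap point
  sits after a /32 downsampling and strip attention needs a ≥3×3 map.
* The learning rate is 1e-3 rather than the full-scale 1e-4 because the
  reduced schedule has only ~120 optimisation steps (vs ~7700 at full
  scale); the full-scale default remains 1e-4.

Under these conditions the full model reaches 100 % internal-validation
accuracy within 15 epochs across seeds, and the seed-mean test accuracy
ordering of the ablation variants (F ≥ E, B ≥ A) matches the direction the
architecture predicts: both strip-pooling heads help, and the two-scale
backbone dominates either half alone.

## Evaluation

All scalar metrics derive from the K×K confusion matrix via one-vs-rest
reduction. Conventions: precision/recall/F1 are 0 when their denominator is
0 (so macro averages stay totals over classes); macro averages are
unweighted; both "macro F1" readings (mean of per-class F1, and the harmonic
mean of macro-P and macro-R) are reported because they differ in the fourth
decimal; rounding to four decimals happens only at printing time. ROC
curves are threshold sweeps with trapezoid-rule AUC; the micro-average
curve pools all (label, score) pairs across classes first. A class absent
from the truth gets a missing AUC, not zero.

## Numerical choices

* Batch norm: ε = 1e-5, momentum 0.1, unbiased running variance; training
  mode backpropagates through the batch statistics, eval mode is a fixed
  affine map.
* Max-pool ties: the first occurrence (row-major within the window)
  receives the gradient.
* Convolutions are cross-correlations (no kernel flip), He-normal
  initialised; linear layers use uniform ±1/√fan_in.
* Dropout is inverted (survivors scaled by 1/(1−p)); identity at eval.
* Float32 tensors throughout training; gradient checks run in float64.
* The softmax cross-entropy is a fused primitive with the exact
  (softmax − onehot)/N gradient; probabilities are clamped away from zero
  by the dtype's tiny value before the log.

## Limitations

* The numpy training stack is single-threaded CPU code; full-scale (224 px,
  10 M parameter) training is possible but slow, and the validated regime
  is the reduced task above.
* Only 2-D single-channel rasters are supported — no volumes, DICOM/NIfTI,
  or MRI physics simulation.
* Transfer-learning initialisation is out of scope; all training starts
  from random weights.
* The exact per-stage spatial sizes of the reference design are a reasoned
  reconstruction (pooling in the shallow half, strided convolutions in the
  deep half); alternative downsampling plans would also satisfy the stated
  block counts.
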