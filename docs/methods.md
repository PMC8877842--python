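# Methods

## Problem and model

Blastocyst-stage embryo micrographs are segmented into five classes —
background, zona pellucida (ZP), trophectoderm (TE), blastocoel (BL) and
inner cell mass (ICM).  The segmentation network, SSS-Net, is a shallow
fully-convolutional encoder–decoder whose design goal is a small trainable
parameter budget at competitive accuracy.

**Encoder.**  Four sprint convolutional blocks (SCBs) interleaved with
three 3×3/stride-2 convolutions; the bottleneck sits at 1/8 of the input
resolution, so input height and width must be divisible by 8 (the library
raises otherwise; the CLI can pad and crop back).  Inside an SCB a 1×1
point-wise convolution G feeds three stride-1 branches — 1×3 and 3×1
asymmetric kernels and a plain 3×3 — while a depth-wise separable branch
(depth-wise 3×3 then point-wise 1×1) taps the block input directly.  The
two asymmetric outputs are concatenated, batch-normalised and rectified;
the 3×3 and separable outputs are normalised/rectified individually; the
three results are concatenated and fused by a 1×1 bottleneck (+BN+ReLU).
All branches use same-padding, so concatenation is always well defined.

**Decoder.**  Four 3×3 bridge convolutions at the bottleneck, then three
4×4/stride-2 transposed convolutions (the 4/2 combination avoids the
checkerboard artifacts of odd-kernel upsampling).  After each upsampling,
the encoder feature of matching resolution (the tensor entering each
strided convolution) is merged:

* *residual* variant — the skip is projected by a 1×1 convolution to the
  stage width, added element-wise, and fused by a second 1×1 convolution;
* *dense* variant — the skip is concatenated and a single 1×1 convolution
  projects back to the stage width.

Residual merging spends `skip·u + u²` weights (projection + fusion), dense
merging `(skip+u)·u`; the totals are identical by construction, matching
the published equality of the two variants' parameter counts.  A 3×3
convolution with bias (the only biased convolution — every other
convolution is followed by batch norm, which would absorb a bias) emits one
score channel per class; probabilities are a per-pixel softmax.  A 1×1
head was tried and discarded: without that final spatial context the
residual variant's trophectoderm class fails to converge at desk scale.

**Reference width schedule.**  The per-layer widths of the original
network are not published; only the 4.04 M total is.  We fix stage widths
64 → 80 → 112 → 240 (SCB internal widths: point-wise = stage width,
asymmetric/3×3/separable = half the stage width), a 240-channel bridge and
decoder widths 112/80/64, found by a scripted search constrained to
monotone growth; the total is 4 038 448 parameters = 4.04 M for both
variants.  `small_spec()` (stage widths 8/16/24/32, ≈96 k parameters) is
the desk-scale schedule used by the tests and examples.  Its decoder keeps
16 channels at full resolution rather than mirroring the 8-channel first
encoder stage: with an 8-channel merge the residual variant's TE/ICM
separation stalls at desk scale, while 16 channels let both variants learn
it.

**Initialisation.**  He-uniform convolution kernels, BN scale 1 / shift 0,
BN ε = 1e-5, momentum 0.1; a single integer seed makes construction,
batch order and therefore whole training runs bit-reproducible (the NumPy
and numba execution paths may differ from each other by float32 rounding,
but each is deterministic).

## Objective and evaluation

Training minimises `1 − T̄` where T̄ averages the per-class Tversky index

    T_c = (Σ p_c g_c + ω) / (Σ p_c g_c + ω + α Σ (1−p_c) g_c + β Σ p_c (1−g_c) + ω)

over the five classes (sums over all batch pixels).  α = 0.7, β = 0.3
weight false negatives harder, countering the foreground/background
imbalance; ω = 1e-6 guards the division (its magnitude is a free choice —
anything ≪ 1 pixel behaves identically).  At α = β = 0.5 and binary
predictions the loss reduces to Dice loss; tests assert this.  The
published formula is written for a single foreground; we compute the index
per class and average *before* complementing, the natural multi-class
reading.  As printed, the expression is maximal (1) at perfect prediction
although it is called a loss; we therefore minimise its complement.

Evaluation uses the Jaccard index `JI_c = TP_c/(TP_c+FP_c+FN_c)` from
confusion counts pooled over all test pixels (accumulate-then-divide, not
a per-image mean — the definition is stated in pixel counts, without
per-image averaging), and the unweighted five-class mean.  The printed
version of the denominator repeats FP where FN is clearly intended (the
surrounding definitions introduce FN); we implement the standard Jaccard.
A class absent from both prediction and ground truth scores 1.0 and is
flagged in the report rather than penalising a correctly-empty mask.

Optimisation: Adam, learning rate 1e-4 (constant — only an *initial* rate
is specified, so no decay), ε = 1e-6, mini-batch 20, reference run length
11 200 iterations, gradient clipping by global L2 norm with threshold 1.0
(the clipping mode is named in the training setup; the threshold is not —
1.0 is the customary default).  Batches reshuffle the training indices
each epoch under the config seed.  Network input is `(pixel − 127.5)/127.5`.

## Data pipeline

Ground truth is colour-coded: background black, ZP green, TE red, BL
yellow, ICM blue; label maps use this fixed order (background = 0).
Decoding assigns each pixel its nearest palette colour (Euclidean RGB)
within a tolerance (default 10 of 255, absorbing anti-aliased label edges);
out-of-tolerance pixels raise an error naming the offending colours.
Label maps round-trip losslessly through paletted PNG.

The augmentation plan is a fixed, ordered list of 16 deterministic paired
transforms — horizontal/vertical/both flips, rotations ±5°, ±10°, ±15°,
translations of 10 px along each axis and the two diagonals, and one
flipped rotation — so 200 sources become exactly 3 200 pairs (the
transformed copies do not include the originals).  The original augmentation
recipe is cited to an unavailable reference; the operation families and the
16× count are fixed, the exact magnitudes are this package's choice.
Images interpolate bilinearly with edge replication; label maps use
nearest-neighbour with background fill, so augmentation can never invent a
class.  Dataset splitting is a seeded permutation with
`round(n × fraction)` training items (235 at 0.85 → 200/35); the original
file-level assignment is unknown, so splits are seed-deterministic and
recorded in the manifest.

## Synthetic phantoms

`generate_phantom` renders a blastocyst-like scene with exact ground
truth: a bright ZP annulus (elliptical radius
`ρ = sqrt((e·dy)² + dx²)`), a TE band scalloped by overlapping cell-like
discs, the BL cavity filling the interior, and an ICM disc tangent to the
inner TE boundary at a configurable angle.  TE and ICM gray levels are
clamped within `te_icm_contrast` (default 8 of 255) of each other,
emulating the near-identical appearance of the two tissues that makes the
real task hard.  A low-order polynomial ramp (amplitude default 18) models
non-uniform illumination; pixel noise is Gaussian (dataset default drawn
from σ ∈ [6, 10]); RGB is the gray image with small per-channel offsets.
The ground truth derives from the geometry *before* any intensity effect,
and at `noise_sigma = 0` the texture and channel jitter are also disabled
so the image is exactly piecewise-constant — the analytic limit used by
the geometry tests.

What the phantoms do not emulate: Hoffman-relief shading, optical blur and
depth-of-field, cell-boundary texture inside the ICM, debris, or ZP
thinning asymmetries.  Passing the learning tests therefore shows the
implementation trains and generalises on images with the right topology,
intensity ambiguity and illumination bias — not clinical-grade accuracy on
real micrographs.

## Morphometrics and visualisation

Component areas are exact pixel counts with image fractions; centroids are
unweighted means of class pixels.  ZP thickness is estimated as 2 × the
mean Euclidean distance transform sampled on the medial axis of the ZP
mask (parameter-free; validated within 1 px on analytic annuli), with a
per-angle profile about the ZP centroid.  Blastocoel "formation" is a
simple area-fraction threshold (default 1 %), a tool parameter rather than
a clinical criterion.  The error overlay paints agreement in class
colours, missed foreground (false negatives) pink and foreground predicted
on background black; black collides with the background colour by
construction of the published convention, so FP pixels are only separable
from correct background via the masks.

## Numerical engine

No deep-learning framework is used: layers, backprop and Adam are
implemented in NumPy (float32, NHWC), with convolutions lowered to one
BLAS matmul over an im2col matrix and, for narrow stride-1 layers, direct
numba-compiled kernels that avoid the column-matrix memory traffic (the
two paths agree to float32 rounding; numba is optional).  Transposed
convolutions are the exact adjoint of the stride-2 convolution — tests
assert `⟨conv(x), y⟩ = ⟨x, convᵀ(y)⟩`.  Large intermediates live in
per-layer scratch buffers reused across iterations.

## Scale of the shipped experiments

The test suite trains both variants of the `small_spec` network on 64
phantoms at 128×128 (batch 20, reference optimiser settings) and evaluates
on 16 held-out phantoms; 400 iterations take the mean Jaccard index from
~0.1 (untrained) through 0.70 around iteration 300–350 to ≈0.89–0.90 at
400 for both variants.  These sizes are the package's chosen desk-scale
defaults; the reference 11 200-iteration, 3 200-pair protocol is expressed
by the same code path with different config values.

## Known limitations

* The reference width schedule reproduces the parameter total, not
  necessarily the unpublished per-layer layout; FLOP reports (≈24 GFLOPs
  per 256² forward at 2 ops per multiply–add) are provided for inspection
  but not asserted against any external figure.
* Skip endpoints, transposed-convolution geometry and the classification
  head kernel are inferred from the architecture's constraints (three
  halvings, matching-resolution merges) rather than a published table.
* Batch-norm uses mini-batch statistics in training and running averages
  at inference; very small batches make early validation noisy.
* The phantom generator is a statistical stand-in (see above), not an
  optics simulation.
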