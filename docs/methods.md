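# Methods

## Problem and model

The package classifies 16-frame video windows into four fall phases
(standing, falling, fallen, other). The design rests on two ideas: (i)
motion can be made *spatial* by false-color fusion — assigning two
temporally adjacent grayscale frames to complementary color channels turns
inter-frame change into chroma while static content stays gray — and (ii)
a small multi-stream CNN in which each stream reads one fused image learns
phase-specific spatio-temporal features with far fewer parameters than a
fine-tuned generic backbone.

### Fusion operator

`fuse(a, b)` assigns the earlier frame to green and the later frame to red
and blue. It is a pure channel reassignment: no arithmetic blending, hence
no clipping, and the output range is exactly the input range. Identical
inputs produce an achromatic image (per-pixel chroma, max−min over
channels, is zero exactly where a = b); this is the invariant the test
suite checks. Because the published description never defines the operator
algebraically, the green–magenta composite was chosen as the convention
that reproduces the qualitative behavior shown for fused frames (motion →
color); pixel-exact agreement with the original figures is not claimable
and not claimed.

Level-2 fusion needs single-channel inputs, so level-1 RGB outputs are
reduced to BT.601 luminance first. With G←a, R=B←b, the luminance of a
level-1 image is 0.587·earlier + 0.413·later — a mild temporal low-pass
that preserves per-pixel locality. Each final image B₁…B₄ therefore
depends on exactly four consecutive frames, a property tested directly.

### Preprocessing

Grayscale conversion uses ITU-R BT.601 weights (0.299, 0.587, 0.114); the
source material states only "grayscale". Resizing to 128×128 uses exact
block (area) averaging when the native size is an integer multiple of 128
— for a 2× downscale this is the area-interpolation kernel and preserves
local means exactly — and anti-aliased bilinear interpolation otherwise.
Pixels live in float [0, 1] internally; 8-bit quantization happens only at
file boundaries so the two fusion levels accumulate no rounding error.

### Windowing

The "overlapping factor" (default 5) is interpreted as the stride between
window start indices — the only reading consistent with the count formula
`floor((N − 16)/factor + 1)`; a trailing remainder shorter than 16 frames
is discarded. Windows are anchored at frame 0 of each single-phase clip.
The count formula is property-tested against brute-force start-index
enumeration for all clip lengths up to 200 and strides up to 16.

### Architecture

The layer enumeration (input; 4 splitting layers; per branch 3×(conv,
batchnorm, ReLU) interleaved with 3 max-pools, then GAP; concatenation;
2×(FC, batchnorm, ReLU); final FC; softmax; classification output) totals
67 layers and is frozen in a golden test together with every feature-map
shape and the 1,560,228-parameter total. Conventions adopted where the
published description is ambiguous or silent:

* The nominal 3-D kernels (e.g. 3×3×64 over 64 channels) have depth equal
  to the incoming channel count, so each collapses to a full-channel 2-D
  convolution — the only interpretation consistent with the printed output
  shapes. The layer table still reports the nominal sizes.
* Valid (no) padding everywhere, forced by the 128→63 and 31→15
  arithmetic.
* The third max-pool uses a 2×2 window on its 5×5 input (yielding the
  stated 4×4 pre-GAP map); the published prose ties the window parity to
  the incoming side, but its own layer table contradicts that rule here,
  and the table wins.
* Weight initialization is Glorot-uniform from a seedable generator;
  batchnorm uses per-channel statistics, momentum 0.9, ε = 10⁻⁵. Neither
  is specified in the source material.
* The classification loss is unweighted softmax cross-entropy.

### NumPy engine

No deep-learning framework is a dependency: convolution, batchnorm,
max-pooling, GAP, fully connected layers, softmax cross-entropy and Adam
are implemented directly on NumPy. Feature maps are NHWC; convolution is
im2col with stride-tricks patch gathering and a BLAS matmul, and its
backward pass scatters gradients with a loop over kernel offsets, which
handles overlapping receptive fields exactly. Max-pool ties break to the
first element in row-major window order, deterministically. Every layer's
backward pass, and the assembled network, are verified against central
finite differences in float64 (agreement ~10⁻⁸); production training runs
in float32. Training is deterministic given the seed: initialization,
shuffling and the label-permutation control all derive from
`numpy.random.default_rng`.

### Optimization

Adam with learning rate 0.001, β₁ = 0.9, β₂ = 0.999, L2 regularization
10⁻⁴ applied to conv/FC weight matrices only (biases and batchnorm
scale/shift are exempt, matching the common framework behavior), minibatch
8. The reference protocol trains 100 epochs; desk-scale runs use 10 epochs
on a few hundred windows, which suffices on the synthetic data. The
published wording "gradient decay factor of 0" would literally set β₁ = 0
(degenerating Adam's momentum); it is read as a misreported default and
standard β₁ = 0.9 is used. Validation (≈10% of the non-test data, whole
clips) is used for best-accuracy checkpoint selection; whether the
original protocol used it for early stopping or monitoring is unstated.

### Cross-validation and metrics

Folds are grouped by source clip so windows of one clip never straddle
train/test. Clips are shuffled deterministically, partitioned into k
balanced groups, and each fold's test set is trimmed to at most
floor(N/k) samples by moving whole clips to that fold's training side —
matching the reference arithmetic (6392 sequences → 2130 test, 3836
train, 426 validation per fold, which silently drops two samples from
testing; they are kept in training here). A consequence is that a few
samples may appear in no test fold.

Accuracy is the correctly classified fraction of the test set; chance
level for four balanced classes is 25%. Sensitivity, specificity and
precision are one-vs-rest per class and macro-averaged, since the
reference reports single values for a 4-class problem without stating an
averaging rule; ratios with zero denominators are excluded from the macro
mean with a warning. (The published metric-definition table is
typographically scrambled — e.g. sensitivity printed as a misclassified
fraction; the standard TP/TN/FP/FN definitions its framing intends are
implemented.) ROC curves and AUC are one-vs-rest on the softmax scores via
scikit-learn. Information density is accuracy (%) divided by learnable
parameters in millions; for the default model that denominator is 1.5.

## Synthetic data: what it does and does not show

The simulator renders a bright ellipse silhouette (half-axes 55×16 px in a
240×320 scene) on a dark background: lateral sway for standing (a slow
sinusoid plus a 1-px alternation so adjacent frames always differ, as a
live silhouette's edges do), a linear 90°→0° topple over 24 frames
(~0.8 s) with a drop toward the floor for falling, a static horizontal
pose for fallen, and a sit-down (vertical half-axis shrinking to 60%) for
"other". Gaussian pixel noise σ = 0.02 (~5 of 255 8-bit counts) is added;
clip lengths are drawn from 63–144 frames, the range the method assumes.
Classes are balanced by construction, and a closed-form check — the
chroma-mass centroid of B₄ separates standing from fallen perfectly on
noiseless renders — guarantees the learning benchmark is solvable by
design.

What passing on this data shows: the fusion encoding carries phase
information, the network can extract it, gradients reach all four
branches, and the harness measures honestly. What it does not show:
robustness to real-video nuisances — occlusion, shadows, illumination
change, clothing variation, multiple people, camera motion — none of
which the simulator renders. Accuracy figures on synthetic data are not
comparable to accuracy on real fall footage.

## Problem sizes and numerical choices

The bundled learning benchmark trains the full (1.5 M-parameter) model
for 10 epochs on 400 synthetic windows (10 clips per class, 63 frames
each, giving 100 windows per class) with one clip-grouped held-out fold,
plus an identically trained label-permuted control; these sizes keep a
single-CPU run in the minutes range while leaving a wide margin between
the real run (≈100% held-out accuracy) and the control (≈25%). The fold
harness itself is exercised at the full published sample count (6392)
with singleton clips, where the split sizes reproduce 2130/3836/426
exactly.

Degenerate inputs are defined errors, not crashes: empty images,
non-finite pixels, mixed frame sizes, wrong window lengths, unlabeled
clips, non-positive feature maps, and folds whose training side is
missing a class all raise typed exceptions.

## Known limitations

* The fusion operator's channel convention cannot be validated
  pixel-exactly against the original figures (no algebraic definition was
  published); only its qualitative invariants are guaranteed.
* Single person per scene, no segmentation or localization — inherited
  from the method itself.
* Video-container decoding depends on the available imageio plugins;
  frame directories are the dependable interchange format.
* The NumPy engine targets CPU-scale experiments; the 100-epoch reference
  protocol on real datasets is configuration-reachable but impractical
  without hardware acceleration.
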