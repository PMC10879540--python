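# Methods

## Model

The default network (`ercp_net`) maps a 3×416×416 RGB image to 38 class
scores through:

| stage | operation | output |
|---|---|---|
| stem | 7×7 conv, stride 2, BN, ReLU | 16×208×208 |
| stem | 3×3 max-pool, stride 2 | 16×104×104 |
| stage 1 | CER block + ACA block | 48×52×52 |
| stage 2 | CER block + ACA block | 144×26×26 |
| stage 3 | CER block + ACA block | 432×13×13 |
| fusion | BIF block | 1296×13×13 |
| head | global average pool, fully connected | 38 |

**CER block.** The expansion stage is three parallel max-pools (windows 3,
5, 9; stride 2; paddings 1, 2, 4 so all branches emit the same spatial
size) concatenated along channels: C → 3C with zero learnable parameters.
An aggregation path (1×1 → 3×3 → 1×1 convolutions at 3C channels, each
conv→BN→ReLU except no ReLU after the last BN) refines the concatenation; a
stride-2 1×1 convolution + BN projects the block input to 3C for the
residual; the block output is ReLU(aggregation + residual). The pooling
windows' stride is 2 so each stage halves the spatial dimensions — with
stride 1 throughout, the published per-stage tensor sizes (52→26→13 from a
104-pixel stem output) cannot be produced, so halving is built in.

**ACA block.** Channel descriptors from global average- and max-pooling
pass through a *shared* pair of single-lane 1-D convolutions (ReLU between
them, none after; padding (k−1)/2, no channel reduction); the branch sum is
squashed by a sigmoid into per-channel weights w ∈ (0,1)^C. Spatial
attention stacks the channel-wise mean and max maps and applies one 7×7
convolution + sigmoid. Two composition modes are implemented:

* `multiplicative` (default): F′ = F + M_S(w⊙F) ⊙ (w⊙F). Gating by
  multiplication is the convention this attention family inherits, and the
  leading residual term keeps an exact identity component in the Jacobian.
* `additive`: F′ = F + w + M_S(F), the literal additive composition, kept
  behind a flag because the additive reading is defensible and testable.

The kernel size k comes from inverting the Gaussian density at
y = C / N: k = nearest-odd(√(−2σ² ln(y·σ·√(2π))) + μ), floored at 1, ties
rounded away from zero (odd kernels give symmetric padding). Interpreting y
as the raw channel count would put every realistic C outside the density's
range (ln of a value > 1 makes the radicand negative), so the channel count
is normalized by N = 2048 by default; μ = 0 and σ = 1. All three are
configurable, and channel counts with y·σ·√(2π) > 1 raise an explicit
error naming the offending count. Under the defaults the stage widths 48,
144 and 432 all receive k = 3, and k is weakly decreasing in C across the
valid domain (1 ≤ C ≤ 816).

**CBAM baseline.** For ablation, a standard convolutional block attention
module: shared C → C/r → C perceptron on the pooled descriptors (r = 16),
sigmoid channel gate, then the same spatial gate, applied sequentially and
multiplicatively, without a residual.

**BIF block.** With P2 (144×26×26) and P3 (432×13×13): upsample P3 ×2
(nearest by default; bilinear available), concatenate with P2 (576×26×26),
3×3 max-pool stride 2 back to 13×13, concatenate with P3 again (1008
channels), and expand with a 1×1 convolution + BN + ReLU to 1296 channels.
Pure concatenation yields 1008 channels; the trailing 1×1 expansion to
3 × 432 = 1296 is this package's design for matching the published head
width, and `out_channels` is configurable.

**Head and variants.** Global average pooling feeds a fully connected layer;
training consumes raw logits with cross-entropy (numerically standard),
softmax is applied at inference. `er_net` omits attention and fusion (head
width 432); `er_net_cbam` and `erc_net` attach a CBAM or ACA block after
every CER stage including the third; `ercp_net` adds the BIF block. No
dropout is used anywhere. Initialization is fan-based uniform
(Kaiming-style), drawn from a single `numpy` generator seeded by
`NetworkConfig.seed`, so builds are bitwise reproducible.

## Numerical engine

All blocks run on a small reverse-mode automatic-differentiation engine
over numpy arrays (float64). Convolution uses im2col/col2im; max-pooling
routes gradients to the arg-max (ties split equally); batch normalization
keeps running statistics (momentum 0.1, ε = 1e−5) and is differentiated by
composing primitive operations; bilinear ×2 upsampling is expressed as a
cached sparse interpolation matrix so its transpose gives the backward pass.
Every backward pass was validated against central finite differences (atol
1e−5 at ε = 1e−6), including end-to-end through a full reduced network.

## Training harness

SGD with momentum 0.9 and classic L2 weight decay 1e−4 on mean
cross-entropy; batch size 16, initial learning rate 0.01, 100 epochs by
default. After every epoch the validation accuracy drives a plateau
schedule: a strict improvement over the best-so-far resets a stall counter;
three consecutive non-improving epochs multiply the learning rate by 0.3
and reset the counter (floor 1e−8). "Does not improve" is read as
not-strictly-greater against the best so far rather than the previous
epoch, which is the standard plateau-monitor convention. Data order,
augmentation and initialization all derive from explicit seeds; identical
seeds give identical histories.

Metrics are computed from the K×K confusion matrix (rows = true class):
accuracy = trace/total; per class, precision = TP/(TP+FP) and recall =
TP/(TP+FN) one-vs-rest; macro values are unweighted means. A zero
denominator yields 0 for that class and the class index is flagged as
degenerate rather than silently dropped.

## Data handling

Folder ingestion reads class-per-subdirectory PNG/JPEG trees; the
vocabulary is the lexicographically sorted directory list, so loading is
order-stable. Augmentation applies, in order, a horizontal flip (p = 0.5),
a vertical flip (p = 0.5), a rotation drawn uniformly from [0°, 35°]
(bilinear interpolation, edge-value fill, shape preserved), and additive
Gaussian noise with σ = 0.01 of the dynamic range, clipped to [0, 1]. Flip
probabilities, the noise scale and the interpolation/fill policy are not
pinned down by convention anywhere, so they are defaults, all configurable.
Splitting is stratified per class at 6:2:2: after a seeded shuffle,
⌊0.2n⌋ samples go to validation and to test and the remainder to train,
keeping small synthetic runs balanced. Augmentation is applied on the fly
to training batches rather than by materializing an enlarged dataset.

## Synthetic generator

Each image is a soil-toned canvas with a green leaf ellipse (seeded color
and geometry jitter) stamped with the class's lesion motif: class k fixes a
motif kind (spots, stripes or rings, cycling with k), a lesion color from a
fixed palette of disease-like tones (necrotic brown, chlorotic yellow,
powdery grey, rust red/orange, dark mold, pale blight), and per-image draws
of lesion count (5–9) and radius (6–14 % of the image side). Those lesion
densities correspond to a moderately-to-severely diseased leaf and make the
classes separable by first-order color statistics — verified by an
independent nearest-centroid color-histogram classifier reaching > 0.9
held-out accuracy — which is what lets a small network overfit a tiny set
quickly and makes training tests meaningful. The generator is byte-
deterministic under a spec.

What it does *not* emulate: photographic texture, lighting variation,
occlusion, background clutter, intra-class lesion diversity, or class
imbalance. Tests passing on this generator therefore demonstrate that the
architecture, gradients, training loop and metrics are correct and that the
network can fit separable image classes — not that any accuracy level
carries over to real leaf-disease corpora.

## Problem sizes

The test suite and the acceptance script run at desk scale by design: the
full 416×416 architecture is exercised for one traced forward pass (shape
contract), while training tests use reduced networks (stem width 4, inputs
32–64 px) on synthetic sets of tens of images — e.g. the overfit check
trains 50 epochs on a 2-class × 16-image set at 64×64. Full-scale corpus
training is out of scope here and would require the original datasets.

## Known limitations

* CPU-only and float64: throughput is adequate for the reduced problem
  sizes above, not for full-scale corpus training.
* Batch normalization with very small batches (or batch 1) gives noisy
  statistics; the harness evaluates in running-statistics mode to keep
  inference deterministic.
* The BIF wiring that reaches 1296 channels is one reasonable
  reconstruction (trailing 1×1 expansion); alternatives (e.g. wider merge
  paths) would satisfy the same outer contract.
* The additive attention mode composes gates as broadcast additions and is
  provided for completeness; the multiplicative mode is the supported
  default.
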