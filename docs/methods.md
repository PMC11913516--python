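# Methods

This note documents the models and procedures implemented in `mondnet`,
the parameter choices that matter, and what the synthetic benchmark does
and does not demonstrate.

## Problem setting

The package addresses two-class screening of directionally-encoded-color
(DEC) tractography renderings: images in which white-matter fiber bundles
appear as striped, orientation-colored structures (red left–right, green
anterior–posterior, blue through-plane). The screening question is
whether an image shows a normal fiber architecture or the degraded
appearance associated with motor-neuron disease, in which entire motor
pathways lose streamline density and coherence. Clinical DTI data are
not distributed with the package; a synthetic generator supplies
class-labelled stand-ins so every stage is exercised end to end.

## Synthetic data generator

Each image is a dark background plus three striped bundles (one per
orientation color), each with a randomly drawn center line, width,
sinusoidal wobble and stripe phase, plus a uniform tissue baseline and
i.i.d. Gaussian pixel noise (`noise_sd`, default 8 intensity units on the
0–255 scale). Defaults: 78 normal and 52 abnormal images of 64×64
pixels — the reference composition at a desk-friendly raster size.

**Abnormality model.** In an abnormal image one bundle, chosen at
random, undergoes tract-wide degeneration: its intensity envelope is
scaled by `1 − c·(0.45 + 0.4·core)` where `c` is `lesion_contrast` and
`core` is a Gaussian focal mask (radius 15–25% of the image side), and
zero-mean noise proportional to `c` (25% of peak envelope) disrupts the
stripe pattern along the tract. This models disease of a whole motor
pathway — diffuse loss with a focal core — rather than an isolated
blob; the global color and texture histograms the pipeline extracts are
sensitive to exactly this kind of change. At `c = 0` every
abnormal-class effect vanishes and the two classes are draws from the
same distribution, giving a null control.

All randomness descends from one integer seed via `SeedSequence`
spawning (one child per image), so identical specifications produce
byte-identical datasets. Lesion parameters are drawn regardless of
contrast so the zero-contrast classes are statistically exchangeable.

**Augmentation.** The policy produces exactly `factor` shape- and
label-preserving variants per original; the default 24 comes from the
reference bookkeeping 78→1872 and 52→1248 (both ×24). The default
transform bank crosses six geometric operations (identity, rotations by
90/180/270, horizontal and vertical flips) with four photometric ones
(brightness ×0.8, ×1.2, additive Gaussian noise σ=6, brightness ×1.1 +
noise), yielding 24 distinct non-identity compositions. 90/270 rotations
are only used on square rasters, since they would otherwise change the
shape.

**What the generator does not emulate:** diffusion physics, fiber
tracking, anatomy, partial-volume effects, scanner artifacts, or the
appearance statistics of real DEC maps. Passing the end-to-end benchmark
shows the pipeline recovers a known class-generating signal under
realistic nuisance variation — not that it detects disease in clinical
images.

## GAB denoising

The Gaussian adaptive bilateral filter weights each window neighbor by
`exp(−‖v−u‖²/σ_z²)·exp(−(I_v − G_u)²/σ_s²)` and normalizes weights to
sum to one per pixel (both kernels use σ², not 2σ², in the denominator).
The guidance image `G` defaults to the input itself, recovering the
classical bilateral filter; an external-guidance hook is kept. Defaults
σ_z = 1 px, σ_s = 30 intensity units, window radius 2: mild smoothing
that suppresses the generator's σ=8 pixel noise while leaving stripe
edges (contrast ≫ 30) intact. RGB images share a single range kernel
computed on the interband average so the three channels are filtered
coherently. Borders are mirror-padded without repeating the edge pixel.
The implementation is the exact O(H·W·r²) evaluation, vectorized over
pixels but not approximated; limits are verified in tests (σ_s → ∞ gives
the truncated Gaussian blur, σ_s → 0 returns the input, constants are
preserved exactly).

## CIF color features

Blocks default to 8×8 px, which at 64×64 gives an 8×8 quantizer grid —
enough blocks (64) for stable histograms while keeping each block small
enough to be locally uniform. Per block and channel the minimum and
maximum colors are recorded (`s_min ≤ s_max` holds channelwise by
construction; partial edge blocks are kept).

Color reduction is an octree (balanced color tree) quantizer: colors are
inserted along their RGB bit paths to depth 8; parents whose children
are all leaves are collapsed — deepest first, least-populated first,
insertion order as the final tie-break — until at most k leaves remain;
each palette entry is its leaf's mean color, and entries are sorted
lexicographically. Ties in nearest-entry assignment break toward the
lowest palette index. Defaults k_min = k_max = 16.

The palettes are built **once per image collection** from the pooled
block quantizer colors of all images, then every image is histogrammed
against that shared codebook. This is essential: a per-image palette
adapts to each image's own gamut and removes precisely the inter-image
color shifts the descriptor is meant to measure. Palette construction
uses no labels, so no supervision leaks into the features.

The CIF convolutional micro-block (pointwise 1×1 convolution → channel
shuffle → depthwise 3×3 convolution → channel reorder, spatial size
preserved) is implemented for arbitrary NHWC maps — e.g. the stacked
min/max quantizer maps — with the reorder defaulting to the inverse
shuffle permutation. It is not part of the default feature path, whose
output is the pair of histograms.

## LBP texture features

Default configuration s = 8 neighbors, radius 1: neighbors are the eight
3×3 grid pixels taken clockwise from the top-left, and the threshold is
`step(x) = 1 for x ≥ 0, else 0`, so ties with the center count as 1 and
a flat patch codes as 255. Other (s, r) sample the radius-r circle from
the up-left diagonal clockwise with bilinear interpolation. Histograms
cover all pixels at least ⌈r⌉ from the border; un-normalized bins sum to
the number of coded pixels. Because only difference signs enter,
adding a constant to or positively rescaling the whole image leaves all
codes unchanged. A local ternary pattern variant (threshold t splits
differences into ≥ t / ≤ −t upper and lower binary patterns) is exposed
through the same interface but is not in the default pipeline.

## Classifier

The fused feature vector (16 + 16 CIF bins + 256 LBP bins = 288 values)
is reshaped row-major into a 17×17 single-channel map (zero-padded) and
fed to: one standard 3×3 convolution (16 filters) → three
depthwise-separable blocks (32, 64, 128 channels, stride 2, each
depthwise 3×3 → BN → ReLU → pointwise 1×1 → BN → ReLU) → global average
pooling → dense softmax over {normal, abnormal}. The stem convolution
uses stride 2 on inputs of 32 px or larger and stride 1 otherwise.
About 13k parameters — deliberately small enough to train on a single
CPU in seconds.

The preprocessed image tensor can optionally be included
(`MondNet(images=...)`, pipeline `train.use_images`): the histogram map
is then zero-padded to the image size and stacked as a fourth channel.
This is off by default — on the synthetic task the raw-pixel path
memorizes the small training sets and generalizes worse than the
histogram-only input.

Training: softmax cross-entropy, SGD with momentum 0.9, learning rate
0.02 under cosine decay, weight decay 10⁻⁴ on convolution and dense
weights (not biases or BN parameters), batch size 32, default 100 epochs
(the end-to-end benchmark uses 30). Initialization is He-normal from a
seeded generator; batch shuffling uses the same generator, so a fixed
seed reproduces loss curves bit for bit. Batch-norm running statistics
(momentum 0.9, ε = 10⁻⁵) are used at inference, making predictions
independent of batch composition. Ties in the argmax go to "abnormal" —
the conservative call for a screening tool.

The engine is a self-contained numpy implementation (forward and manual
backward passes for standard/depthwise/pointwise convolution, batch
norm, ReLU, GAP, dense). At these input sizes exact loop-over-offset
convolutions vectorized over the batch are fast and keep the arithmetic
transparent.

**Cost accounting.** For output spatial size H_o/p, kernel H_ip, k input
and l output channels: standard cost H_o/p²·k·l·H_ip², separable cost
H_o/p²·k·H_ip² + k·l·H_ip²; the ratio is identically 1/l + 1/H_o/p²,
checked in exact `Fraction` arithmetic on every call.

## Evaluation

Standard 2×2 tally with "abnormal" positive. Accuracy is reported in
percent; precision, recall, specificity and F1 as fractions with a
percent toggle. Zero denominators yield 0 with a logged warning; F1 is 0
when precision + recall = 0. The per-class table re-computes all metrics
with each class as the positive one, which makes recall of one class the
specificity of the other — an identity the tests assert.

## Pipeline and determinism

Stages (`generate`, `augment`, `preprocess`, `extract`, `train`,
`evaluate`, `all`) communicate only through files (PNGs + manifest CSV,
features CSV, `model.npz`, `split.json`, `metrics.json`), so each stage
is independently runnable; a missing upstream artifact raises an error
naming the producing stage. Each run writes its fully-resolved YAML
config next to its outputs. The single config seed derives the
generation seed, augmentation seed (+1) and split/training seed (+2),
fixing the whole chain. The train/validation split is stratified 80/20.

The end-to-end reference run (and `scripts/acceptance.py`) uses 100
images per class, 30 epochs and no augmentation stage — sizes chosen so
the whole chain, including the zero-contrast control arm, completes in
about a minute while leaving the held-out set (40 images) large enough
to be informative.

## Numerical and degenerate-input conventions

- Filter weights sum to 1 per pixel within 1e−9; outputs clip to [0, 255].
- Nearest-palette and argmax tie-breaks are deterministic (lowest index /
  "abnormal") and documented where they occur.
- Empty datasets propagate as empty outputs for augmentation; empty
  inputs to quantizers, histograms or metrics raise contract errors.
- Block partition keeps trailing partial blocks; an oversized block size
  degrades to a single block, not an error.
- Softmax subtracts the row max before exponentiation; cross-entropy
  clips probabilities at 1e−12.

## Known limitations

- The synthetic benchmark demonstrates signal recovery under the
  generator's nuisance model only; no claim transfers to clinical data.
- Octree reduction cannot produce between 2 and 7 palette entries when
  colors span more than k top-level octants (it collapses to the root);
  palette sizes of 8+ behave as expected.
- The CNN engine is CPU-bound numpy; it is sized for hundreds of
  images, not thousands at high resolution.
- Uniform/rotation-invariant LBP mappings and attention mechanisms are
  out of scope.
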