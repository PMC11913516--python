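# mondnet

Two-class screening of color-coded medical images — normal versus abnormal
motor-pathway appearance on DTI tractography renderings — with a *duple*
(color + texture) feature front end and a compact depthwise-separable
convolutional classifier. The package is aimed at method developers who
need the full chain to be runnable, seeded and testable without any
clinical data: a synthetic-image module emulates orientation-colored
tractography with a tunable, class-defining degeneration signal.

## The method

The pipeline has five stages:

1. **Denoising** — a Gaussian adaptive bilateral (GAB) filter

   f(v) = (1/Nor_f) Σ_u exp(−‖v−u‖²/σ_z²) · exp(−(I_v − G_u)²/σ_s²) · I_u

   where G is a guidance image (the input itself by default) and Nor_f
   normalizes the weights per pixel. Edges survive because neighbors at a
   different intensity get negligible range weight.

2. **Color information feature (CIF)** — the image is tiled into blocks;
   each block is reduced to its channelwise minimum and maximum colors
   s_min(u,v), s_max(u,v). The pooled quantizer colors of the collection
   are reduced to small palettes T_min, T_max (octree / balanced color
   tree), and each image is described by the relative frequencies
   CIF_min(c), CIF_max(c) of its blocks' nearest palette entries.

3. **Local binary pattern (LBP)** — on the interband average
   P = (R+G+B)/3, each interior pixel gets the s-bit code
   LBP_{s,r}(u,v) = Σ_α step(t_α − t_center)·2^(α−1); the 2^s-bin code
   histogram is the texture descriptor. Codes are invariant to monotonic
   grayscale changes.

4. **Fusion + classification** — the flattened CIF and LBP histograms are
   concatenated, reshaped to a square map and fed to a small CNN: one
   standard convolution, then depthwise-separable blocks (depthwise 3×3 →
   BN → ReLU → pointwise 1×1 → BN → ReLU), global average pooling and a
   softmax over {normal, abnormal}. A depthwise-separable layer with l
   output channels and H×H output costs exactly 1/l + 1/H² of its
   standard counterpart — verified in rational arithmetic by
   `mondnet.cost_report`.

5. **Evaluation** — confusion counts and accuracy (percent), precision,
   recall, specificity and F1, with "abnormal" as the positive class.

## Worked example

```python
from mondnet import (SyntheticSpec, generate_dataset, preprocess_batch,
                     GabParams, extract_features, MondNet, TrainConfig)

data = generate_dataset(SyntheticSpec(n_normal=100, n_abnormal=100,
                                      seed=0, lesion_contrast=0.5))
data = preprocess_batch(data, GabParams())
table = extract_features(data)            # 288 feature columns per image

model = MondNet.from_dataframe(table.iloc[:160])
results = model.fit(TrainConfig(epochs=30, seed=0))
print(results.summary())
```

prints

```
MondNet fit results
================================================
Model:                 MondNet (depthwise-separable CNN)
Classes:               normal / abnormal
Feature length:        288
Input:                 histogram map
Architecture:          conv3x3(16) + dw-sep blocks [32, 64, 128]
Parameters:            13218
Training examples:     160
Epochs:                30
Batch size:            32
Final train loss:      0.0938
Final train accuracy:  0.9938
```

i.e. a 13k-parameter network fitted to 160 fused feature rows;
`results.predict` then labels held-out images. Running the same chain
through the pipeline's stratified 80/20 split (`mondnet all`) yields
92.5% held-out accuracy at seed 0 — and chance-level accuracy when the
generator's `lesion_contrast` is 0, confirming the classifier learns the
class signal and not an artifact.

The same chain runs from the shell:

```bash
mondnet all --config config.yaml --seed 0 --out run/
cat run/metrics.json
```

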