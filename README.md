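# dmffnet

A dual-encoding, multiscale-feature-fusion segmentation network for
low-contrast grayscale medical images — implemented, trained and
evaluated entirely in NumPy, with a synthetic phantom generator so the
whole pipeline runs and is testable without clinical data.

The motivating problem is lesion segmentation in abdominal CT, where the
lesion's intensity differs only slightly from surrounding tissue and
fine boundary detail is what matters clinically. The model reads each
image at two resolutions: a full-resolution view through an encoder path
of **single dense aggregation blocks** (chains of 3×3 convolutions whose
every output is concatenated once, at the chain's end) and a
half-resolution view through a path of **bottleneck residual blocks**.
At every encoder level a **multiscale fusion block** cross-concatenates
the two paths' features together with a pooled carry of the previous
level's fusion,

    O1_i = proj(concat[I1_i, I2_i, down(O1_{i-1})])
    O2_i = proj(concat[I2_i, I1_i, down(O2_{i-1})]),

and the decoder applies **coordinate attention** — gates built from
per-row and per-column average-pooled descriptors — after each skip
concatenation. Training minimizes the smoothed soft-Dice loss

    loss = 1 − (2 Σ xᵢyᵢ + 1) / (Σ xᵢ² + Σ yᵢ² + 1)

with SGD (momentum 0.9, weight decay 1e-4, batch 8) under the poly
schedule `lr = 0.001 · (1 − iter/6500)^0.9`. Evaluation reports DSC,
Jaccard, sensitivity, specificity and accuracy from per-pixel confusion
counts, DSC distribution summaries, and paired Wilcoxon signed-rank
comparisons between models.

There is no deep-learning framework underneath: convolutions, batch
normalization, pooling, bilinear upsampling and their backward passes
are implemented over NumPy in a small reverse-mode autodiff core
(`dmffnet.autodiff`), each gradient verified against finite differences
in the test suite.

## Worked example

Generate 100 phantoms (low-contrast slices with known lesion masks),
inspect the reference architecture, and train a small configuration:

```sh
dmffnet generate --n 100 --out data/ --seed 7
dmffnet params
```

`dmffnet params` prints the per-module trainable-parameter breakdown of
the reference configuration (4 levels, widths 64→512, dense-chain depth
L = 10, growth 142):

```
sdab_blocks     9,136,496
decoder         5,292,400
fusion          2,217,280
bottleneck      1,050,624
rb_blocks         372,800
trans_rb          173,824
trans_sdab        173,824
stem_high             704
stem_low              704
head                   65
total          18,418,721  (18.42 M)
```

18.42 M trainable parameters, of which half sit in the dense-chain
encoder path. Dropping the chain depth (`dmffnet params --sdab-layers 4`)
gives 13.24 M; each ΔL = 2 adds exactly 1,726,720 parameters.

In Python, the low-contrast phantoms respond to the masked-histogram
CLAHE enhancement, and a reduced network overfits them quickly on CPU:

```python
import numpy as np
from dmffnet import phantoms, preprocess, engine
from dmffnet.network import NetworkConfig, build_network

img, mask = phantoms.generate_phantom(phantoms.PhantomSpec(seed=7))
enhanced = preprocess.clahe(img, preprocess.ClaheParams())
span = lambda a: np.subtract(*np.percentile(a, [99, 1]))
print(f"1-99% intensity span: raw {span(img.pixels):.3f} "
      f"-> enhanced {span(enhanced.pixels):.3f}")
# 1-99% intensity span: raw 0.621 -> enhanced 0.717

spec = phantoms.PhantomSpec(image_height=64, image_width=64,
                            lesion_radius_range=(5.0, 12.0))
data = phantoms.generate_dataset(spec, 32, seed=11)
net = build_network(NetworkConfig(base_width=8, sdab_layers=4,
                                  sdab_growth=8, carry_width=16,
                                  bottleneck_width=128, ca_reduction=8,
                                  seed=1))
cfg = engine.TrainConfig(initial_lr=0.05, max_iter=300, batch_size=8,
                         seed=1, eval_every=0)
net, history = engine.train(net, data, cfg)
report = engine.evaluate_model(net, data)
print("training DSC:", report.format_row("DSC"))
# training DSC: 96.9 ± 0.7
```

The mean training Dice score of 96.9% shows the reduced network
memorizing 32 phantoms in 300 iterations (~90 s on one CPU core) — the
standard smoke test that the architecture, loss and optimizer interact
correctly.

Other subcommands: `dmffnet preprocess` (crop + CLAHE a directory),
`dmffnet train` (full loop with fold management and checkpointing),
`dmffnet evaluate` / `compare` (metric reports and paired Wilcoxon
tests), `dmffnet ablate` (train a grid of architecture variants: fusion
off, attention off, either encoder path replaced by plain convolutions,
chain depth swept).

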