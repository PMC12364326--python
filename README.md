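# heeseggan

Edge-enhanced adversarial segmentation of pulmonary nodules on 3-slice
pseudo-color CT composites, packaged as a tested, configurable
training/inference framework with a synthetic phantom-CT generator so every
mechanism runs on one CPU without any data download.

The framework pairs a holistically-nested U-Net generator (4-level
encoder/decoder, per-level side outputs, softmax attention fusion across
levels, optional inverted-residual input stem with channel attention)
against a four-layer convolutional critic with weight clipping, feature
matching and Gaussian-kernel minibatch discrimination. Supervision combines
an absolute-gap adversarial loss, class-balanced multi-level BCE on the mask
pyramid, a multi-level edge loss on boundary pyramids, and Dice.

Because no deep-learning framework is assumed, the networks run on a small
numpy reverse-mode autodiff core (`heeseggan.nn`) written for this package:
NCHW convolution (grouped/depthwise), max pooling, bilinear resampling,
batch norm, dropout, Adam and cosine annealing — each gradient-checked
against finite differences in the test suite.

## Layout

| Module | Role |
|---|---|
| `heeseggan.phantom` | seeded synthetic thoracic-CT phantoms (solid/GGO nodules, 3-slice-spanning vessels) |
| `heeseggan.preprocessing` | HU windowing, centroid ROI, RGB 3-slice encoding, edge maps, max-pool label pyramids |
| `heeseggan.generator` | HED-U-Net generator with attention fusion and inverted-residual stem |
| `heeseggan.discriminator` | stride-2 conv critic, minibatch discrimination, weight clipping |
| `heeseggan.losses` | adversarial / balanced-BCE / edge / Dice terms and aggregates |
| `heeseggan.training` | alternating adversarial optimization, ablation matrix, checkpoints |
| `heeseggan.metrics` | IoU / DSC / SEN / PRE from pixel confusion counts |
| `heeseggan.io`, `heeseggan.config`, `heeseggan.cli` | MetaImage/NIfTI/NPZ/PNG formats, strict YAML config, CLI |
| `heeseggan.nn` | numpy autodiff core (tensors, layers, optimizers) |

## CLI

```bash
heeseggan simulate   --n 4 --out sim/ --seed 0 --kind solid --png
heeseggan preprocess --volume sim/phantom_000.mhd --mask sim/phantom_000_mask.mhd \
                     --out comp.npz --size 128
heeseggan train      --config run.yaml --out run/
heeseggan predict    --checkpoint run/checkpoint.npz --composite comp.npz --out pred/
heeseggan evaluate   --pred pred_masks.npz --truth truth_masks.npz --out eval/
```

`run.yaml` holds nested sections `data / preprocessing / generator /
discriminator / losses / training / evaluation`; unknown keys are rejected
and every run writes a resolved config snapshot plus its hash. Defaults
follow the training protocol: batch 64, Adam(0.001, 0.9, 0.999), cosine
annealing, discriminator weights clipped to [-0.012, 0.012].

Ablation configurations (plain U-Net, HED-U-Net, GAN, GAN+MB, GAN+MB+IR and
the three loss combinations) are constructible via
`heeseggan.training.ablation_config(name)`.

Real thoracic CT volumes in MetaImage (`.mhd/.raw`) or NIfTI format with
binary mask volumes go through the same `preprocess`/`train` path; nothing
in the test suite requires them.

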