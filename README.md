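# nanobarcode

Pixel-wise identification of combinatorial protein **nanobarcodes** in
multichannel fluorescence microscopy.

## The problem

Proteins of interest are genetically tagged with an on/off combination of
small epitopes; each epitope slot is detected in a single staining step by a
nanobody carrying a distinct fluorophore (DyLight405, Atto488, Atto565,
Star635P). With *n* epitope slots there are 2ⁿ − 1 nonempty codes — 15
distinguishable protein classes for the 4-slot scheme — all read out in one
acquisition of 11 frames per field: every useful excitation × emission-window
combination (10 fluorescence frames, so bleed-through becomes signal rather
than artifact) plus one brightfield frame.

Decoding is a per-pixel classification problem: map the 10-vector of channel
intensities **x** to a class in {blank, code₁ … code₁₅}. The classifier is a
residual multi-branch multilayer perceptron,

&nbsp;&nbsp;&nbsp;&nbsp;P(**x** ∈ Cᵢ; **θ**) = softmax(**y**)ᵢ, **y** = f_θ(**x**),

trained by minimizing the mean negative log-likelihood
L = −(1/N) Σₙ log P(**x** ∈ C_{i(n)}; **θ**) with AdamW (initial learning
rate 5·10⁻⁴, step decay 0.9 every 20 epochs, batch 458), stochastic
per-entry contrast augmentation in [0.5, 1.5], an 80/10/10 stratified split
and early stopping on validation accuracy. The reference architecture
(width 128, 4 parallel branches of 3 residual blocks, batch normalization)
has 624,144 trainable parameters. The whole network, including batch norm,
AdamW and backpropagation, is implemented directly in NumPy — the model *is*
the package's core, and the explicit implementation also provides input
gradients for test-time adaptation.

The package covers the complete loop:

- **simulate** — synthetic 11-frame acquisitions of single-transfect fields
  with bleed-through, Poisson + Gaussian read noise, log-normal per-cell
  expression, and ground truth;
- **masking** — foreground/background separation by single-component kernel
  PCA (fitted on 4,000 random pixels) with a relative threshold at 0.8 of
  the transformed range, then gathering of up to 10,000 labeled pixels per
  case plus blank samples;
- **network / training** — the residual classifier and its training
  protocol;
- **inference** — whole-image classification with an optional per-image
  *contrast modifier* (per-channel scale + shift, 20 parameters) fitted
  without labels by minimizing the mean output entropy for 50 steps;
  false-color rendering from probability-weighted palette colors;
- **evaluation** — confusion-matrix metrics (precision/recall/F1,
  false-call shares), leave-one-class-out ablation, and shallow 2-D
  embedding baselines (Isomap, kernel PCA, t-SNE, spectral).

## Worked example

```python
import numpy as np
import nanobarcode as nb
from nanobarcode.pipeline import (build_training_dataset,
                                  train_pixel_classifier,
                                  image_precision_experiment)

barcodes = nb.enumerate_barcodes(4)          # 15 codes: '0001' ... '1111'
matrix   = nb.default_response_matrix()      # 4 fluorophores x 10 channels
sim      = nb.SimConfig()                    # 128x128, Poisson + read noise

ds = build_training_dataset(barcodes, matrix, sim, images_per_class=2,
                            cap=2500, blank_ratio=0.4, n_blank_images=4,
                            seed=11)
net = nb.NetworkConfig(n_classes=ds.n_classes, width=64)
model, history, splits = train_pixel_classifier(
    ds, net, nb.TrainConfig(max_epochs=40, seed=11), seed=11)
report = nb.evaluate_holdout(model, splits[2])
print(f"hold-out accuracy {report.accuracy:.3f}")

results = image_precision_experiment(model, barcodes, matrix, sim,
                                     n_images=20, adapt_steps=50, seed=12)
print(f"mean image precision "
      f"{np.mean([r['precision'] for r in results]):.3f}")
```

prints

```
hold-out accuracy 1.000
mean image precision 0.997
```

i.e. essentially every held-out labeled pixel is assigned its true class
under this simulation's noise settings, and on fresh whole images of known
single transfects 99.7% of the non-blank pixel calls name the correct
barcode after 50 steps of entropy-minimizing contrast adaptation. A command-line interface mirrors the same pipeline
(`nanobarcode simulate | mask | train | predict | evaluate | ablate |
search`); every run directory contains the resolved config snapshot and seed
for exact reproduction.

## Layout

```
src/nanobarcode/     barcodes, simulate, masking, network, training,
                     inference, evaluation, pipeline, io, cli
src/nanobarcode/data/response_matrix.yaml   versioned reference spectra
docs/methods.md      model, assumptions, parameter choices, limitations
tests/               pytest suite (unit, property and acceptance tests)
```
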