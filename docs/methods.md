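# Methods

## Barcode model and spectral forward model

A nanobarcode is a nonempty on/off vector over 4 epitope slots, in fixed
slot order mCherry(Y71L), GFP(Y66L), syn87, syn2, written as a code string
such as `1100`. The all-zero pattern is not a barcode: it is the *blank*
class, carried as class index 0 in every dataset and classifier head.
Enumeration is lexicographic in the code string, giving 2ⁿ − 1 classes
(15 for n = 4).

Each slot is detected by one fluorophore (DyLight405, Atto488, Atto565,
Star635P). The acquisition records 11 frames per field: 405 nm × CH1–CH4
(frames 1–4), brightfield (frame 5), 488 nm × CH2–CH4 (frames 6–8),
561 nm × CH3–CH4 (frames 9–10), 633 nm × CH4 (frame 11), with emission
windows CH1 416–485 nm, CH2 494–554 nm, CH3 572–632 nm, CH4 641–730 nm.
The brightfield frame is routed out of the classifier input on read and is
used only for overlay rendering.

The expected signal of a barcode is the linear superposition of the
response rows of its set slots, scaled by an expression amplitude. The
4 × 10 **spectral response matrix** is shipped as a versioned YAML file:
each row peaks at 1.0 in its matched excitation/emission frame, with
off-frame bleed-through entries in [0.02, 0.3] chosen to represent typical
emission tails and cross-excitation. No measured bleed-through magnitudes
were available, so the reference matrix is a modeling choice, fixed in the
package data for reproducibility; it has rank 4, so all 15 noise-free
signatures are distinct. Users with calibrated spectra can load their own
matrix from YAML.

## Synthetic data generator

The simulator emulates single-transfect confocal fields:

- **Cell shapes**: a Gaussian-smoothed random field (σ = 6 px) thresholded
  at the (1 − foreground-fraction) quantile gives blob-shaped regions;
  default foreground fraction 0.15 of the frame. The method is strictly
  pixel-wise, so blob realism beyond "contiguous bright regions" is not
  required.
- **Expression heterogeneity**: one log-normal amplitude per connected
  cell (median 120 expected photons at the matched frame, log-σ 0.5),
  mirroring transfection-level variability.
- **Noise**: detected intensity per channel is
  gain · Poisson(amplitude · signature) + N(0, σ_read) + background,
  clipped at 0; defaults gain 1, σ_read 2 counts, background 5 counts.
  This is the standard confocal shot + read-noise decomposition; the source
  protocol states no noise parameters, so the defaults are calibration
  choices exposed in `SimConfig`, set so that a median cell has per-channel
  SNR ≈ 10 in its bright frames while dim tails of the amplitude
  distribution approach the background.
- **Blank fields**: untransfected fields carry background noise only in the
  fluorescence frames (cells remain visible in brightfield). These provide
  the blank-class training pixels — sampling blanks from out-of-mask pixels
  of protein images instead would contaminate the blank class with dim true
  signal below the mask threshold, and measurably teaches the classifier to
  call pure background a barcode class.
- All randomness flows through one seeded NumPy generator per call;
  identical inputs and seed give bit-identical stacks.

What the generator does **not** model: optics (PSF, pixel correlations),
photobleaching, 3-D structure, autofluorescence spectra, chromatic
aberration, or spatial label correlations beyond cell blobs. Passing tests
on this generator therefore demonstrate the correctness and internal
consistency of the pipeline under its stated noise model, not performance
on real micrographs.

## Foreground masking

Per case (one barcode, one expression window), a kernel-PCA model with a
single retained component is fitted on exactly min(4000, available) pixels
drawn uniformly without replacement across the case's images. The kernel is
RBF with the bandwidth set by the median pairwise distance of the fit
sample (a linear kernel can be swapped in; with it the component equals the
classical first principal component up to sign). The component's sign is
arbitrary, so it is oriented so that larger scores correspond to larger
total fluorescence, making the threshold rule well-posed.

A pixel is foreground iff its oriented score is at least
min + 0.8 · (max − min), min/max taken per stack (a pooled variant is a
flag). The rule is invariant to affine rescaling of the scores. Degenerate
inputs (constant pixels, zero score range) raise explicit errors rather
than returning an implicit mask. One caveat measured on synthetic fields:
because the threshold is relative to the *range*, a very bright cell can
push a dim cell below the cut; across the default noise sweep the
mask/ground-truth agreement averages ≥ 95% with occasional fields near 90%.

Gathering collects per class up to 10,000 foreground pixels (uniform,
without replacement, pooled over the case's images) plus blank pixels at a
configurable blank:foreground ratio; the ratio default is 10, the most
literal reading of "10 blank samples per protein sample". Blank emphasis
matters: with blanks reduced to one class's worth (a fully balanced
dataset), the early-stopped model can sacrifice blank recall at some
training seeds and then calls pure background a barcode on whole images.
The desk-scale experiments therefore keep every class at ≥ 2,000 pixels
but give the blank class 0.4 × the total foreground yield (15,000 blank
pixels against 2,500 per barcode class, drawn from dedicated blank
fields) — a scaled-down version of the protocol's strong blank emphasis
that keeps the overall accuracy metric from being blank-dominated.

## Classifier

Input is the pixel's 10-vector scaled by the recorded bit depth to [0, 1].
The architecture: a dense stem 10 → width; `branch_count` parallel branches
(cardinality) each a stack of residual blocks — three dense width × width
layers, each followed by batch normalization and ReLU, plus an identity
skip summed at the block output; branch outputs summed; optional post-merge
dense layers; a final dense layer to the class logits and softmax.
Normalization sits after each dense transform and before the activation
(placement was an open choice). Reference configuration: width 128,
4 branches, 3 blocks per branch, 1 post-merge layer, 16 classes — 624,144
trainable parameters, with a closed-form count available for any
configuration. A fully degenerate configuration (no blocks, no post-merge,
no normalization) collapses to softmax regression.

Everything is explicit NumPy (float32): forward, backward, batch-norm
statistics, AdamW (decoupled weight decay 10⁻², applied to weight matrices
only — biases and normalization parameters are exempt, the optimizer
family's usual convention). The explicit backward pass also returns the
gradient with respect to the *input*, which test-time adaptation needs; in
inference mode batch-norm backs propagate through frozen running statistics.

One numerical point deserves emphasis: because every training batch is
contrast-augmented, the running statistics tracked during training describe
the *augmented* input distribution, whose variance is inflated relative to
clean inputs; through a dozen stacked normalization layers the mismatch
compounds and inference-mode accuracy becomes erratic. The running
statistics are therefore recalibrated after every epoch as the mean of
per-batch statistics over clean (unaugmented) training features — the
population-statistics estimate of the original batch-normalization
procedure — before validation scoring and checkpointing.

## Training protocol

80/10/10 stratified split (classes with < 3 members go wholly to train,
with a warning); batch size 458; initial learning rate 5·10⁻⁴ with step
decay ×0.9 every 20 epochs (so 4.5·10⁻⁴ from epoch 20); at every batch
access each (sample, channel) entry is multiplied by an independent uniform
draw from [0.5, 1.5] (per-entry granularity chosen as the stronger
regularizer). Training stops at 100 epochs or after 10 epochs without a
validation-accuracy improvement, and the returned model is the
best-validation-epoch checkpoint. Seeded runs reproduce metrics to 4
decimals.

## Inference and contrast adaptation

Whole images are classified pixel-by-pixel (chunked for memory); the argmax
label map breaks ties toward the lowest class index. The per-image
**contrast modifier** is a per-channel affine map x′ = s·x + t (20
parameters, identity-initialized), fitted for exactly 50 Adam steps against
the mean per-pixel Shannon entropy (natural log) of the classifier output
with the classifier frozen. Two numerical choices matter:

- **Scale-aware steps.** The shift is parameterized in units of the
  per-channel intensity spread of the image. Entropy minimization has a
  degenerate global optimum — push every pixel into one confident class —
  and with inputs of order 10⁻³ an absolute step of 10⁻² reaches it in one
  step. Relative steps (default 10⁻², i.e. ≈ 1% of a channel's spread per
  step) keep the 50-step trajectory in the useful regime where background
  pixels become confidently blank.
- **Best-iterate return.** Adam is not monotone in the objective, so the
  returned modifier is the lowest-entropy iterate of the trajectory; the
  adapted image's mean output entropy therefore never exceeds the
  unadapted one.

The mean (not the sum) over pixels makes the objective
resolution-independent. On fields of known single transfects, adaptation
consistently removes spurious non-blank calls on background (sparsity), at
the cost that it is label-agnostic: it cannot fix, and can occasionally
amplify, a wrong-but-confident foreground assignment.

False-color maps assign each pixel the probability-weighted sum of per-class
palette colors, blank mapped to black, clipped to the display range; an
optional overlay composites a median-filtered, background-subtracted
brightfield underneath.

Per-image precision on a known transfect counts non-blank predictions that
match the known barcode over all non-blank predictions; an all-blank map
raises an explicit undefined-precision signal rather than scoring 0 or 1.

## Evaluation

Per-class metrics use the one-vs-rest reduction of the multiclass confusion
matrix (rows = target): precision TP/(TP+FP), recall TP/(TP+FN),
F1 = 2/(P⁻¹+R⁻¹), per-class accuracy (TP+TN)/total; empty denominators
yield NaN markers, never silent zeros. False-positive/negative shares
express each class's off-diagonal column/row mass as a percentage of all
false predictions. Macro-averages exclude the blank class by default.
The ablation study retrains from scratch with one class removed from all
partitions, per-run seeds derived from a master seed; a failed run is
recorded and the study continues. Shallow 2-D embeddings (Isomap, kernel
PCA, t-SNE, spectral; scikit-learn) are evaluation-only baselines — no
classifier is built on them beyond nearest-centroid reading used to
quantify how far they fall short of the deep classifier.

## Desk-scale experiment sizes

The packaged experiments are sized for a single CPU: training corpus of
15 barcodes + blank at 2,500 foreground pixels per class (15,000 blanks)
gathered from two 128×128 fields per case through the kernel-PCA masking
path; classifier width 64
(other reference dimensions unchanged), at most 40 epochs; whole-image
evaluation on 20 fresh 128×128 single-barcode fields with 50 adaptation
steps each. Smaller fixtures (64×64 fields, widths 16–32, ≤ 25 epochs) are
used for unit-level checks. The hyperparameter search harness is a plain
grid/random search over width, branch count, depth, batch size and learning
rate scored on the validation split.

## Known limitations

- Mixed pixels are assigned their dominant class only; fractional
  abundance unmixing is out of scope.
- The response matrix is a modeled, not measured, bleed-through pattern.
- The relative-range mask can drop dim cells in fields with extreme
  brightness ratios (see masking caveat above).
- Entropy adaptation is self-supervised and can entrench a confidently
  wrong foreground class on rare fields; it is bounded by the best-iterate
  rule but not guaranteed to improve precision per image.
- Batch-norm running statistics make training-mode and inference-mode
  outputs differ slightly; all reported metrics use inference mode.
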