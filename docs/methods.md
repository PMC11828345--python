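# Methods

## Problem and model

High-resolution esophageal manometry (HREM) renders pressure along the
esophagus over time as a color topography (red = high pressure, blue = low,
green = moderate).  Clinicians read these images to diagnose six motility
categories: Achalasia type II, diffuse esophageal spasm (DES),
esophagogastric junction outflow obstruction (EGJOO), ineffective esophageal
motility (IEM), hypercontractile (Jackhammer) esophagus, and the normal
swallow.  This package implements a mixed attention ensemble (MAE) classifier
for such images: several independently trained CNN base models, each enhanced
by a channel-and-spatial attention module (CSAE) before its decision layer,
fused by weighted soft voting whose weights come from a mixed voting
mechanism.

### CSAE attention

For a backbone feature map `f` of shape `C×H×W`, two descriptors are pooled:
`c_avg[k]` (spatial mean of channel `k`, length `C`) and `c_max[p]`
(channel-wise maximum at position `p`, length `H·W`, row-major).  Each passes
through a learnable single-filter bias-free 1-D convolution and a softmax,
giving simplex attention vectors `w_c` (channels) and `w_s` (positions).  The
enhanced map is

    out[k, p] = w_c[k] · f[k, p] + w_s[p] · f[k, p].

Design choices:

* **Padding.** The attention convolutions use *edge-replicate* padding rather
  than zero padding.  With zero padding a constant descriptor is not mapped
  to a constant (edge positions see padded zeros), so the module's defining
  closed form — a constant map of value `v` comes out as
  `v·(1/C + 1/(H·W))` everywhere, for *any* filter weights — would fail at
  the boundary.  Edge replication preserves constants exactly and makes
  softmax shift-invariance (`attention(x + c) = attention(x)`) hold for every
  filter, not only the delta filter.  The generic `conv1d_same` primitive
  still offers zero padding.
* **Kernel size** defaults to 3; the module then adds exactly 6 trainable
  parameters per model.  Filters are initialized to the delta filter, so the
  untrained module is plain softmax attention over the raw descriptors.
* **Magnitude.** Because each softmax sums to 1, output magnitude shrinks as
  `C` and `H·W` grow; `rescale_attention=True` multiplies `w_c` by `C` and
  `w_s` by `H·W` to restore unit-mean attention.  Default off, keeping the
  literal softmax form; the linear classifier after global pooling absorbs
  the scale.
* The channel branch reads only `c_avg` and the spatial branch only `c_max`
  — the one reading consistent with computing both descriptors and applying
  "the same method" along each axis.

### Voting

With per-model validation accuracies `A_i` (fractions in `[0,1]`):

* **Individual voting.**  For each model `k` in turn as *primary*, a weight
  vector is fitted from the primary-heavy prior (0.55 on the primary,
  0.45/(n−1) elsewhere) by the multiplicative update
  `w_j ← w_j A_j / Σ_m w_m A_m` per epoch, keeping the trajectory point with
  the best fused validation accuracy (earliest epoch on ties).  The `n`
  fitted vectors are blended with exponential-accuracy coefficients
  `α_i = exp(A_i) / Σ_j exp(A_j)` into `W_i`.
* **Group voting.**  32 flat-Dirichlet draws on the simplex are each evolved
  by the accuracy-proportional update once per epoch; every trajectory point
  is a candidate and the one with the highest fused validation accuracy is
  `W_g`.  The update is renormalized to the simplex — a uniform rescale that
  cannot change the argmax — so downstream convexity invariants hold.
* **Mixed voting.**  `W = β₁·W_g + (1−β₁)·W_i` with `β₁ = 0.2` by default.
  (The source experiment's prose at one point suggests a 4:1 ratio of group
  to individual weight, while its own parameter sweep selects `β₁ = 0.2`,
  i.e. 1:4; the default follows the sweep and the contradiction is noted
  rather than resolved.  `mae sweep-beta` reproduces the sweep on any run.)

Accuracies enter the exponential on the fraction scale: percent-scale
exponents would make the coefficients nearly winner-take-all and risk
overflow.  A `temperature` option rescales the exponents for users who want
sharper weighting.

Fusion operates on softmax probabilities (`fused = Σ_i w_i p_i`), keeping the
fused vector a distribution; argmax ties break to the lowest class index.
Base models are trained independently first and frozen during weight search;
validation accuracy drives every weight update (including the `standard`
ablation mode, which uses validation-accuracy shares) and the test split is
evaluated exactly once, at the end.

### Metrics

All metrics derive from the K×K confusion matrix through one-vs-rest
reductions: per-class accuracy `(TP+TN)/N`, error rate `1 − accuracy`,
precision `TP/(TP+FP)`, recall `TP/(TP+FN)`, F1 harmonic mean, with `0/0`
defined as 0 and a warning for zero-support classes.  Micro, macro and
support-weighted aggregations are always reported and explicitly labeled,
because published tables in this area mix conventions: on the reconstructed
reference test matrix the published headline "recall" of 99.26% is the macro
*precision*, and the per-class "accuracy" column is the one-vs-rest recall.
The report never imitates that ambiguity.

## Reference study design

`mae.study` records the reference experiment's design: 2,315 images over the
six classes (178 / 339 / 240 / 483 / 100 / 975), split 6:2:2 per class, the
training split expanded eightfold, and seven reported test
misclassifications (1 Achalasia II→Normal, 1 IEM→DES, 5 IEM→Normal out of
461 test images).  The floor rule `|val| = |test| = ⌊0.2 n⌋`, train taking
the remainder, is the only rounding consistent with every published
per-class count.  Reconstructing the implied confusion matrix reproduces the
published 98.48% accuracy, 97.14% Achalasia II recall, 93.75% IEM recall and
97.01% Normal precision.

## Data pipeline

* **Eightfold expansion** is interpreted as original + 7 augmented copies
  (the published arithmetic, 108→864 etc., is consistent with either
  reading; keeping originals preserves clean signal).  `copies_per_image`
  is configurable.
* **One transform per copy**, drawn uniformly from {brightness ×(1.6–2.0),
  contrast+saturation ×(2.1–2.5), rotation ±10°, scale 0.5–0.9, Gaussian
  noise, salt-and-pepper noise}; a `compose` flag applies all six in
  sequence instead.  Noise magnitudes are not pinned by the protocol;
  defaults are σ = 0.02 of the dynamic range and a 0.01 pixel fraction.
* **Geometric fill** uses border replication, avoiding black corners that
  would trivially separate augmented from original images.
* Augmented records never enter validation or test splits, and each carries
  its source path (`augmented_from`) and draw seed.

## Synthetic data generator

The generator emulates the *appearance* of HREM color topographies, not
esophageal physiology: a latent pressure field in `[0,1]` on an S×S grid
(rows = position, columns = time) with UES and LES/EGJ horizontal bands, a
class-specific peristaltic diagonal (continuous and moderate for Normal,
broken high-amplitude for DES, faint for IEM, triple high-amplitude bursts
for Jackhammer), a panesophageal pressurization column and elevated LES for
Achalasia II, and a strongly elevated LES with normal wave for EGJOO;
additive Gaussian noise (σ = `noise_level`, default 0.03) on the latent
field; then a piecewise-linear blue→green→red colorization with fixed stops
at p = 0, 0.25, 0.5, 0.75, 1.  All class parameters live in one editable
table (`mae.synth.CLASS_PARAMS`).

The classes are deliberately caricatured and linearly separable (a logistic
probe on 16×16 grayscale downsamples exceeds 99% cross-validated accuracy),
so passing end-to-end tests demonstrates that the training, attention and
voting machinery works — it says nothing about accuracy on clinical images,
which exhibit anatomical variability, device artifacts and class overlap the
generator does not model.  Achalasia types I/III are not simulated.

## Backbones and training

The registry ships compact CPU-trainable CNN backbones (`tiny_cnn`,
`tiny_cnn_small`, `tiny_cnn_wide`): three 3×3 conv / ReLU / 2×2 max-pool
stages (widths e.g. 8-16-32), optional CSAE on the final feature map, global
average pooling and a linear head.  They run on a small NumPy reverse-mode
autodiff engine written for this package (im2col convolution, gradient-
checked against central differences), trained with cross-entropy and Adam.
Ensemble diversity comes from differing widths and independent
initializations.  The configuration defaults mirror the reference protocol
(100 epochs, batch 16, learning rate 0.001, 224×224 inputs); the end-to-end
smoke experiments in the tests and the acceptance script use the package's
standard smoke scale — 64×64 synthetic images, 60 per class (216/72/72
train/val/test), two backbones, 10 epochs — which trains in well under a
minute on one CPU and reaches perfect test accuracy on the separable
synthetic classes.

Determinism: one master seed fans out to named streams (synthesis, split,
augmentation, per-model init and batch shuffling, group search) via hashed
stream names, so modules draw independent but fully reproducible randomness;
two runs with the same config produce identical reports modulo timestamp.

## Numerical choices and degenerate inputs

* Softmaxes use max-subtraction; the exponential-accuracy coefficients were
  verified against a 50-digit decimal evaluation.
* Simplex membership is enforced at construction (`Σw = 1 ± 1e−6` on input,
  renormalized; negatives beyond 1e−9 rejected).
* `group_update` rejects all-zero accuracy vectors; `metrics_from_confusion`
  rejects empty matrices; unknown class labels and backbones are errors that
  name the offending value and the valid vocabulary.
* Max-pool gradients route to the first argmax on ties; confusion argmax
  ties break to the lowest class index.

## Known limitations

* Synthetic classes are far easier than clinical HREM; reported synthetic
  accuracies are machinery checks, not clinical performance estimates.
* Backbones are compact CNNs; the ensemble abstraction is pluggable but no
  large pretrained backbones are bundled, and `pretrained` weights are not
  downloaded.
* The parameter-size accounting reports exact counts × 4 bytes; it does not
  attempt to reproduce any published ensemble size figure, whose derivation
  is not reconstructible.
* Per-model weights are scalars (one weight per model), not per-class.
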