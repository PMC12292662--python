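# Methods

`cordseg` segments a 2-D B0-contrast spinal-cord slice into nine classes
(background + eight anatomical ROIs: dorsal, lateral and ventral white-matter
columns and gray matter, each split left/right) and evaluates the result both
with standard overlap metrics and with a DTI-specific consistency index based
on fractional anisotropy (FA). This note records the models, defaults, and
design choices, and what the synthetic experiments do and do not show.

## The segmentation model

The network is a classical U-shaped encoder–decoder. The encoder is an input
module (two plain 3×3 conv + batch-norm + ReLU layers at the base width)
followed by four feature-extraction modules that each halve the spatial
resolution and double the channel count. Each feature-extraction module stacks
two residual bottleneck blocks — 1×1 squeeze, 3×3 (stride 2 in the first
block), 1×1 expand, each conv followed by batch normalization, with ReLU after
the residual addition — so most of the network's capacity sits in cheap 1×1
convolutions. The decoder mirrors the encoder with four decoding modules:
×2 upsampling (a 2×2 transposed convolution by default; nearest-neighbor + 1×1
conv as a config alternative), concatenation of the matching encoder feature
map, and two bottleneck blocks halving the width. A 1×1 convolution and
per-pixel softmax produce the nine probability maps.

Defaults: base width 32 (so 32→64→128→256→512 at the bottom), squeeze factor
4, depth 4 (inputs must be divisible by 16). The published architecture this
family follows does not state its channel schedule, squeeze ratio, or
upsampling operator, so complexity figures are not expected to match any
particular reference; `count_complexity` reports the exact parameter and MAC
counts of what is built here (≈2.0 M parameters and ≈1.9 GMACs at 128×128 for
the defaults — well below a VGG19-backbone U-shape built from the same
primitives, which is the relevant ordering). Convolutions feeding a batch
norm carry no bias term, since the normalisation would cancel it exactly and
the parameter would never receive gradient.

All layers, backpropagation, and the Adam optimiser are implemented in the
package's own `nn` module on numpy (im2col convolutions over BLAS matmuls,
hand-derived backward passes, verified against central differences). Forward
passes in evaluation mode use batch-norm running statistics and are
deterministic, which is what makes pipeline outputs bit-reproducible.

## Loss

Training minimises a class-weighted focal loss with focusing exponent γ = 2:

    L = −(1/N) Σ_pixels w(true class) · (1 − p_true)² · log p_true

with weights 1 for background and 3 for every cord ROI. Normalisation is by
pixel count N only, not by the weight sum — the printed form of the loss we
follow divides by N, and either convention only rescales the learning rate.
The weight multiplies each true-class term; probabilities are clamped at 1e−7
before the logarithm. Setting γ = 0 recovers weighted cross-entropy and is
exposed as a test hook. The ROI up-weighting empirically trades precision for
recall on the small anatomical regions (the directional effect is asserted in
the training tests), which is the clinically preferred direction: including
extra boundary background in an ROI is cheaper than missing cord tissue.

## Training regime

Adam with initial learning rate 1e−4, first-moment coefficient 0.9, batch
size 16, 500 epochs, and polynomial learning-rate decay
`lr = lr0·(1 − epoch/epochs)^0.9` are the full-scale defaults. Two sources in
the reference regime disagree on the learning rate (1e−4 in the text, 1e−10
in the parameter table); 1e−10 cannot move a network off its initialisation
in 500 epochs, so it is treated as a typographical slip and 1e−4 adopted. The
decay form and the model-selection rule are unstated in the reference; we use
the common polynomial(0.9) segmentation default (step and cosine available)
and keep the checkpoint with the best validation mean foreground Dice. No
data augmentation is applied.

Small-scale runs (tests, the acceptance script) use 64×64 phantoms, base
width 16, and learning rates around 5e−3–1e−2 for a few hundred optimisation
steps: these are the problem sizes at which CPU-only training converges in
minutes, and the phantom task is easy enough that held-out Dice exceeds 0.9
within a dozen epochs.

## Evaluation

All reported metrics use hardened argmax masks (ties break toward the lowest
class index, favoring background). Per class i, TP/FN/FP are pixel counts and
precision, recall, and Dice = 2TP/(2TP+FN+FP) follow. A class absent from
both prediction and reference in a slice is flagged undefined and excluded
from that slice's aggregation; a class that exists but is completely missed
scores 0. Metrics are computed per slice and aggregated as mean ± std across
slices; the "mean" row averages the eight cord ROIs. The confusion matrix is
row-normalised by true class.

The Mean FA Error of class i compares region-level FA summaries:
FA_label = mean FA over the reference mask of i, FA_measured = mean FA over
the predicted mask of i, error = |FA_measured − FA_label| / FA_label. Two
interpretation choices are deliberate: the absolute value (all reported
errors are magnitudes) and the region-mean comparison (rather than a
per-pixel sum, which the symbolic form leaves ambiguous) — this reproduces
the semantics of "labeled mean FA" vs "measured mean FA" columns in
radiological reporting, and makes the index invariant to uniform rescaling
of the FA map. Background is reported separately from the 8-ROI mean.

## The phantom generator

Real cervical-cord DTI training data (the modality this tool targets) is not
publicly deposited, so the package ships a synthetic phantom: an elliptical
cord (semi-axes 0.32/0.25 of the image side) on dark background, a
butterfly-shaped gray-matter core built from two mirrored lobed polygons, and
six white-matter wedges (dorsal < 55°, lateral 55–125°, ventral > 125° from
the dorsal direction, each split at the midline). Geometry is defined
analytically in cord-normalised coordinates; the left/right split tests
|u| so the unjittered phantom is exactly mirror-symmetric, and "left" means
lower column index in image coordinates (the radiological vs. image
convention is never stated in the clinical protocol this emulates; ours is
documented here and in the module docstring).

Per-region FA means default to values typical of healthy cervical cord
(dorsal/lateral/ventral columns 0.54–0.60, gray matter ≈0.544, background
0.1812); pixel FA adds Gaussian noise (sd 0.05, a choice — no noise model is
published) clipped to [0,1]. B0 uses three grayscale levels (background 0.05,
white matter 0.75, gray matter 0.55, noise sd 0.03) chosen so tissue
boundaries are clearly visible, matching the qualitative observation that B0
delineates ROI boundaries better than FA-value images. Each sample gets a
small random affine jitter (rotation ≤ ~3.4°, translation ≤ 3 px, scale ±5 %
at jitter = 1). FA and B0 values are quantised to their PNG storage grids at
generation time so disk round-trips are exact.

What the phantom does *not* emulate: partial-volume boundary mixing, EPI
distortion, coil-intensity inhomogeneity, pathology-dependent FA drops,
inter-subject anatomical variability, and slice-to-slice correlation within
a patient. Passing the synthetic-generalisation tests therefore demonstrates
that the architecture, loss, optimisation, metrics, and pipeline are wired
correctly and can learn this class of geometry — not that clinical-grade
Dice would be achieved on patient data.

## Data handling

Slices are stored as PNG: 8-bit grayscale B0, 16-bit FA scaled by 10000
(preserving four decimals), 8-bit masks holding raw class ids 0–8. Splits
follow the pooled-slice protocol: all slices permuted under a seed and
partitioned 81 % / 9 % / 10 % with largest-remainder rounding. Because the
unit is the slice, multiple slices of one synthetic "subject" could in
principle straddle partitions; the protocol we follow pools slices before
splitting, which on clinical data would carry a patient-leakage caveat.
Arbitrary-size inputs are standardized by central square crop followed by
isotropic bilinear rescale to 128×128 (nearest-neighbor for masks, so no
fractional labels are invented); the crop rule keeps the aspect ratio exact
rather than approximate.

## Numerical choices and degenerate inputs

* Probability clamp 1e−7 in the loss; batch-norm ε = 1e−5, momentum 0.1.
* He-normal initialisation, seeded; all randomness flows from explicit seeds
  (phantom geometry/noise, splits, batch shuffling, init).
* Argmax ties → lowest class index; empty ROI classes are flagged, never
  silently averaged as zeros; configs whose geometry would rasterise an
  empty region are rejected.
* Largest-remainder rounding resolves split sizes (10 ids → 8/1/1).
* Checkpoints are npz archives embedding the model config, so they are
  self-describing and architecture mismatches fail loudly.

## Known limitations

* CPU-only numpy training: minutes at phantom scale, impractical for the
  full 500-epoch 128×128 clinical regime.
* Single-slice 2-D segmentation; no 3-D context across slices.
* The phantom's B0/FA contrast is idealised (see above), so reported metric
  levels on phantoms should not be read as clinical performance estimates.
* Batch statistics make training-mode forward passes batch-size dependent;
  only evaluation-mode outputs are guaranteed reproducible bit-for-bit.
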