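# Methods

## Pixel classification model

The segmentation problem is posed as binary classification of individual
pixels. Each pixel inside the circular field of view (FOV) receives a
15-dimensional feature vector; a supervised classifier maps it to a vessel
probability in [0, 1]; thresholding the probability map yields the binary
vessel mask. No spatial regularization or post-processing is applied: all
spatial context enters through the features.

### Gabor features

Vessels are elongated ridges, darkest in the green channel. The working
channel is therefore the inverted green channel scaled to [0, 1] (vessels
become bright ridges); plain green and Rec. 601 luminance are available as
alternatives. The channel is convolved with a bank of real even-symmetric
Gabor kernels

    g(x, y) = exp(−(x′² + γ² y′²) / (2σ²)) · cos(2π x′ / λ + ψ),
    x′ = x cosθ + y sinθ,  y′ = −x sinθ + y cosθ,

over 18 orientations θ = 0°, 10°, …, 170° and 4 scales σ = 3, 5, 7, 9 px
(72 kernels). Defaults γ = 0.5 (envelope elongated along the ridge),
λ = 2σ, ψ = 0; each kernel is mean-subtracted so constant regions give
exactly zero response, and truncated at radius ⌈3σ⌉ (>99 % of the Gaussian
envelope; side length 2⌈3σ⌉+1). A cosine-phase (even) kernel with λ = 2σ
has a central excitatory lobe flanked by inhibitory lobes — a matched
ridge detector whose preferred ridge width grows with σ, covering the
1–7 px calibre range of retinal vessels. Convolution is FFT-based on a
reflect-padded image, which matches direct spatial convolution to ≈1e−12
and leaves no zero-border artifacts.

For each scale, the per-pixel maximum response over the 18 orientations is
taken. This maximum is orientation-invariant (a vessel scores the same
whatever its local direction) and is the feature that carries the ridge
evidence; keeping the four scales separate preserves calibre information.

### Color features

RGB is converted to CIE 1976 L\*u\*v\* (sRGB primaries, D65 white), a space
that separates luminance from chrominance. A 3×3 window is centred on the
pixel; the 9 L\* values enter in row-major window order, plus the centre
pixel's u\* and v\*. The Luv map is reflect-padded so border pixels are
classifiable. Total dimensionality: 4 + 9 + 2 = 15. The decomposition of
the 15 inputs (scale-maxima + windowed lightness + per-pixel chrominance)
is this package's design; the window size, number of scales and whether
chrominance is windowed are all configurable through `FeatureLayout`.

All features are z-scored column-wise using statistics fitted on the
training partition only — KNN and the perceptron are scale-sensitive, and
Gabor responses and L\* live on very different scales.

### Training data

A class-balanced set of pixels is drawn uniformly without replacement,
pooled across images (no per-image quota): by default 12,500 vessel and
12,540 non-vessel pixels from 20 images, with non-vessel pixels restricted
to the FOV. These counts are one-tenth of the 125,000/125,400 a full-size
fundus study uses; at 256×256 phantom resolution they keep the benchmark
run in the minutes range while leaving ≈16 k training rows — ample for a
15-D problem. The set is split 65:10:25 into train/validation/test,
stratified by class with largest-remainder rounding (each fraction exact
to ±1 per class). Sampling and splitting are keyed on sorted
(image_id, row, col) order before shuffling, so results are independent of
file ordering and bit-reproducible for a given seed.

### Classifiers

*Quadratic Gaussian (QG).* Gaussian class-conditional densities with
class-specific ML means/covariances and empirical priors; the vessel
probability is the normalized class likelihood. Covariances get
1e−6·trace(Σ)/D added to the diagonal, guarding the near-singular case of
locally constant color. Discriminants are evaluated via Cholesky solves.

*K-nearest-neighbor (KNN).* Exact brute-force Euclidean search, K = 5
(odd, so votes cannot tie); the score is the vessel fraction among the K
nearest training pixels. Equal distances rank by lower training-row index,
making predictions fully deterministic. No approximate index is used —
exactness is part of the contract and is what the tests verify.

*Multilayer perceptron (MLP).* 15 → H → 1 with logistic sigmoids, H ∈
[2, 20]. Weights start uniform(−r, r), r = √(6/(fan_in+fan_out)), from a
seeded generator; biases start at zero. Training is mini-batch gradient
descent (batch 128, learning rate 0.05) on mean binary cross-entropy —
with a sigmoid output the back-propagated output delta is simply p − y,
the probabilistic reading of the output node. After every epoch the mean
cross-entropy on the validation partition is evaluated; the weights of the
best validation epoch are kept, and training stops after `patience` epochs
(default 20; the benchmark config uses 15 with max_epochs 300, the
library default being 1000) without improvement. Validation error is
monitored as cross-entropy rather than misclassification rate because it
is smooth — it moves every epoch, so early stopping does not stall on a
flat 0/1 loss. Architecture selection trains one network per H and keeps
the lowest validation error, ties to the smallest H.

A training run that produces a non-finite loss aborts with advice to
reduce the learning rate. With a fixed seed, training is bit-reproducible
run-to-run on the same platform.

### Operating threshold and evaluation

The default operating point is 0.5 on the probability output; optionally
the threshold maximizing Youden's J = TPR − FPR on the *validation* ROC is
selected instead (ties to the more specific point). Metrics — sensitivity,
specificity, accuracy — and the ROC curve are computed over FOV pixels
only (the convention for fundus benchmarks; a flag includes the full
frame). The ROC collapses tied scores into single steps, starts at (0,0)
and ends at (1,1); A_z is the trapezoidal integral and is checked in the
tests against the Mann–Whitney pair-counting identity
A_z = U/(n₁·n₀) to 1e−12.

## Phantom generator

Phantoms exist so the pipeline is exercisable and testable end-to-end
without redistributable fundus data. A phantom emulates exactly the image
properties the features respond to:

- a reddish background (RGB ≈ 0.80, 0.45, 0.24) under a linear
  illumination ramp of ±12.5 % across the disc in a random direction;
- a circular FOV (radius 0.92·min(H,W)/2) with black surround;
- vessels as curvature-limited random walks entering from the disc margin
  (heading perturbed by N(0, 3°) per 1-px step), width tapering linearly
  from up to 7 px to ≥1 px, with a Gaussian cross-section intensity drop
  of peak depth 0.45 applied with channel weights (0.35, 1.0, 0.25) — the
  green channel darkens most, as in real fundus images;
- optional thinner branches (probability 0.02 per step), additive Gaussian
  noise (sd 0.02 on the [0,1] scale), and a "hard" preset that adds a
  bright optic-disc-like region and exudate-like blobs to reproduce the
  strong-contrast structures that cause false positives on real images.

The ground-truth mask marks pixels within the realized half-width of any
centerline sample — generated alongside the image, never recovered by
thresholding, so it is exact by construction. Default densities were
calibrated once so a generated set averages ≈11–12 % vessel pixels inside
the FOV (5 primary vessels per 256×256 image), matching typical retinal
vessel density of 8–14 %.

What phantoms do **not** model: vessel-calibre/brightness correlation,
central light reflex, texture and vignetting of real retinas, JPEG-like
noise, pathology beyond the bright-blob preset. Passing the phantom
benchmark therefore demonstrates that the machinery — features, training,
selection, thresholding, evaluation — recovers known structure under
realistic contrast, noise and illumination; it does not certify clinical
performance. Phantom scores (A_z ≈ 0.99) run higher than what the method
achieves on real data (A_z ≈ 0.97 regime), which is the expected direction
for cleaner inputs.

## Numerical choices and degenerate inputs

- Mask binarization on load is value > 0, handling both {0,1} and {0,255}
  annotation dialects.
- A constant feature column standardizes with sd treated as 1 (warning),
  passing through centred.
- Splitting refuses ratios that leave a partition empty for a nonempty
  class; sampling refuses requests exceeding the available pixels,
  reporting both counts.
- ROC refuses single-class truth; metrics with an empty class report NaN
  for the undefined ratio with a warning.
- Whole-image segmentation assembles features in tiles (default 65,536
  pixels) to bound memory; results are tile-size-invariant by
  construction, and non-FOV pixels score 0 with label 0.
- Model files are versioned JSON (arrays via full-precision decimal
  round-trip), so load(save(m)) predicts bit-identically and a version
  bump fails loudly.

## Problem sizes used by the tests and the acceptance script

The benchmark run is 20 phantoms at 256×256 with the default
contrast/noise, 12,500 + 12,540 sampled pixels, and MLP selection over all
H ∈ 2…20 — about one to two minutes on one CPU. Unit tests use smaller
phantoms (96–128 px, hundreds to a few thousand pixels) chosen so each
property is exercised at the smallest scale at which it is meaningful; in
particular, the null-phantom false-positive check needs the training set
to contain enough FOV-margin background pixels for the classifier to learn
the margin ring (6 images / 1,500 pixels per class suffice).

## Known limitations

- The classification is purely per-pixel; thin-vessel continuity breaks
  that connectivity-aware methods would bridge are not addressed.
- No illumination pre-correction is applied before filtering; the
  classifier must absorb the background trend (the phantom's ±12.5 % ramp
  shows it does, but stronger field inhomogeneity may need preprocessing).
- Brute-force KNN is exact but O(N_train) per query; segmenting whole
  images with KNN is substantially slower than with QG or the MLP.
- The back-propagation trainer is plain mini-batch gradient descent by
  design; no momentum or adaptive optimizers.
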