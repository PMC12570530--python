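# Methods

`adstage` implements a five-stage pipeline for detecting Alzheimer's
disease (AD) in 2-D structural-MRI slices and grading detected cases as
mild or advanced. This note documents the model, the choices made where
the design was genuinely open, and what the synthetic benchmark does and
does not demonstrate.

## Gabor texture preprocessing

Each input slice is min-max normalized to [0, 1], resized to the working
resolution (bilinear, anti-aliased), and convolved with a bank of
even-symmetric Gabor kernels

    GK(x, y) = exp(-[(x1/s)^2 + (y1/s)^2] / 2) * cos(2*pi*f_c*x1),
    x1 = x cos(theta) + y sin(theta),   y1 = y cos(theta) - x sin(theta).

The per-kernel responses (same-size, reflective border) are fused by a
per-pixel maximum over signed responses and rescaled to [0, 1]. Default
bank: spatial factor `s = 1`, frequency factors `{1, 2, 3, 4}`,
orientations over the half-open range [-90°, 90°) in 1° steps — exactly
180 kernels per frequency, 720 in total.

Numerical choices:

- The Gaussian envelope is isotropic with scale `s`. The carrier
  frequency is `f * freq_scale` cycles/pixel with `freq_scale = 0.1` by
  default: integer factors taken literally as cycles/pixel would alias
  on a discrete grid, so the scale maps them into a representable band.
  Both are configurable.
- The orientation range is half-open so the sweep contains 180 distinct
  orientations; -90° and +90° would be redundant anyway because the
  cosine carrier makes kernels 180°-periodic in theta.
- Kernel support is a fixed square of half-width `support_radius`
  (default 7 px; the envelope is below 1e-3 beyond ~3 s).
- Because the kernels satisfy w(x, y) = w(-x, -y), correlation and
  convolution coincide; the implementation uses correlation.
- Fusion can optionally run per frequency (`per_frequency=True`),
  yielding one fused image per frequency factor instead of one overall.

## Directional augmentation

Training sets are expanded 5x with single-pixel-accurate translations
(left/right/up/down) at a fixed offset, zero-filling vacated strips —
translations preserve anatomy where rotations or elastic warps would
not. The offset defaults to 8 px at a 256-px working resolution and is
scaled proportionally at other resolutions (floor 1 px). Augmentation
runs only inside `fit`; prediction paths never augment.

## Multi-path feature extractor

The extractor is a directed graph rather than a chain:

    input -> Conv1(512 @ 5x5) -> { Pool1, Conv2(1024 @ 7x7) }
    Conv2 -> Pool2 -> Pool3
    Pool1 -> Conv3(512 @ 7x7) -> Pool4
    { Pool2, Pool3, Pool4 } -> Feature Integrator

All convolutions are stride-1 with same zero-padding and ReLU; all four
pools are 2x2 stride-2 max. The Feature Integrator global-average-pools
each tapped map per channel and concatenates in the order (Pool2, Pool3,
Pool4): 1024 + 1024 + 512 = 2560 features at full scale. Design points
that were open:

- The three tapped maps have mismatched spatial sizes (Pool2 at half
  resolution, Pool3/Pool4 at quarter), so concatenating raw maps is
  ill-defined; global average pooling then concatenation is
  scale-agnostic and yields a fixed-length vector.
- Pool2 and Pool3 are stacked sequentially off Conv2 so the integrator
  receives two abstraction levels of the deep path plus the refined
  shallow path.
- A `scale` factor in (0, 1] multiplies all filter counts
  (ceiling-rounded) so the same graph runs at desk scale; the printed
  full-scale counts remain the defaults.

The implementation is pure NumPy: im2col + matmul convolutions with an
explicitly written backward pass, verified against central-difference
gradients in the test suite. Single-threaded runs are bitwise
reproducible under a fixed seed.

### Training the extractor

The classification head proper is a clusterer (below), which provides
no gradient signal, so convolution weights are learned through a
*temporary* linear softmax head on the integrated feature vector:
cross-entropy loss, Adam (default lr 3e-3, 5 epochs, batch 16), He-style
seeded initialization, zero biases. Head inputs are standardized per
batch (batch normalization without a learned affine): raw
global-average-pooled channels differ in scale by orders of magnitude,
and without normalization the gradient either vanishes (tiny channels)
or explodes (dividing by near-zero fixed statistics). The head is
discarded after training; only the convolution weights are kept.

## Fuzzy C-means classification head

Integrated feature vectors are z-scored with training-set statistics
(Euclidean clustering is otherwise dominated by high-variance channels)
and clustered by fuzzy C-means with the canonical alternating updates,
fuzzifier m = 2, tolerance 1e-5 on the largest membership change, and a
100-iteration cap. Memberships are initialized as a seeded random
row-stochastic matrix. Distances are floored at 1e-12; a sample
coinciding with a center receives hard membership there.

Clusters are anonymous, so a majority vote over argmax assignments maps
each cluster to a class label; an empty cluster takes the globally most
frequent class. The default cluster count is 4, deliberately larger
than the 2 detection classes: the AD class contains two morphological
sub-populations (mild and advanced), and with only 2 clusters the mild
sub-population straddles the cluster boundary — observed directly as a
detection-accuracy drop with linearly separable features. Extra
clusters sub-divide the classes and the majority vote absorbs them.
Prediction computes a membership row against frozen centers; the hard
label is the class of the argmax cluster, ties breaking toward the
lowest index.

## Morphological segmentation and staging

Detected AD images are segmented by a flat grayscale morphological
gradient: dilation and erosion with a disk structuring element of
physical radius 0.5 mm (pixel radius `round(0.5 / spacing_mm)`, floored
at 1 — the default 1 mm/px spacing gives the radius-1 plus-shaped
disk), replicated borders so the image frame does not register as an
artificial edge. The affected-pixel (AP) mask thresholds the gradient;
the default threshold is Otsu's variance-maximizing split, with a
manual override, and a constant image yields an empty mask rather than
an error.

Staging trains a second extractor + FCM stack on AP-masked images
(image x mask, full frame so input geometry is fixed) of mild vs
advanced training cases. Staging is only defined for images the
detection stage labelled AD; routing anything else raises. An empty
mask still yields a label (all-zero input), which callers should treat
as low-confidence.

## Synthetic phantoms

Real scans are not required: the generator renders an axial-slice
caricature — elliptical head, bright cortical ribbon, mid-intensity
tissue, two dark midline ventricle lobes — with atrophy emulated by the
two canonical visual AD signatures, ventricular enlargement
(`ventricle_scale`, area factor: 1.0 healthy, 1.4 mild, 2.2 advanced)
and cortical-ribbon thinning, plus optional smooth boundary roughening.
Lobe centres stay fixed while the axes scale, so enlargement grows
around the healthy outline; the ground-truth AP mask is exactly that
enlargement band. Additive Gaussian noise is applied last and clipped
to [0, 1]. Every phantom is a pure function of its seed; dataset seeds
are spawned from a master seed, so label structure is seed-invariant.

What the phantoms are *not*: anatomically realistic. There are no gyri,
no bias field, no Rician noise floor, no registration error, and the
class signal is deliberately strong. Passing the benchmark therefore
demonstrates that the pipeline's stages compose correctly and recover a
known morphological signal — not that the pipeline reaches any
particular accuracy on clinical data.

## Evaluation

Detection metrics use AD as the positive class: Se = TP/(TP+FN),
Sp = TN/(TN+FP), pr = TP/(TP+FP), Acc = (TP+TN)/total, plus the
detection-rate pair ADDR (correct AD / total AD) and NADDR (correct
non-AD / total non-AD). ADDR ≡ Se and NADDR ≡ Sp; the identity is
asserted at run time. Zero-denominator metrics are reported as absent,
never as 0. Reports round to 2 decimals in percent.

Cross-validation is stratified with seeded shuffling (default k = 5).
The deterministic imaging front end is computed once and shared across
folds; training (with augmentation) and testing (without) run per fold
with fold-derived seeds.

## Benchmark problem sizes

The packaged benchmark (`scripts/acceptance.py`, and the end-to-end
tests) uses the easy regime: noise 0, contrast 1, 50 phantoms per group
(150 total; 100 AD for staging), working resolution 32 px, a 48-kernel
bank (15° steps, support half-width 5), filter counts scaled by 1/64
(8/16/8, 40-long feature vector), 5 epochs, 5 folds. These sizes were
chosen as the smallest configuration that exercises every stage of the
full-scale design.

## Known limitations

- Full-scale (512/1024/512 at 256 px) training is supported by the same
  code paths but is slow in pure NumPy; the scale factor exists for
  exactly this reason.
- FCM cluster count is fixed per run; no automatic selection.
- Phantom realism as discussed above; Rician noise is not modelled.
- Single-slice 2-D only; NIfTI volumes contribute their middle axial
  slice.
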