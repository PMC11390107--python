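# Methods

## Deuteranopia simulation

Simulation uses the Machado et al. physiologically-based transfer
matrices for deutan color-vision deficiency, published at severity steps
of 0.1 from 0 (identity) to 1 (complete deuteranopia); severities
between steps are linearly interpolated between the two adjacent
matrices. The matrices are row-stochastic (rows sum to 1), so
achromatic colors are fixed points — this is what the grayscale-identity
tests rely on. The default severity is 0.8: high enough to expose weak
contrasts, while acknowledging that many deuteranomalous observers do
not have complete deuteranopia.

The matrix is applied to **gamma-encoded sRGB** channel values by
default, matching the operational behavior of the widely used R
`colorspace` simulation tools (their historical default), rather than to
linearized RGB as colorimetric purity would suggest. A `linear_rgb`
flag (CLI: `--linear-rgb`) provides the linear-light alternative.
Out-of-gamut simulated channels are clipped to [0, 1], the convention of
the simulation tools, not rescaled. The package's matrix transcription
is verified entrywise against the published severity-0.8 table in the
acceptance checks.

## Color difference

Color differences use CIEDE2000 on CIE L\*a\*b\* (D65 white point, 2°
observer; conversion via linearized sRGB → XYZ → Lab). Parametric
weights are kL = kC = kH = 1. CIEDE2000 is symmetric and zero exactly
on identical colors but is not a metric (the triangle inequality can
fail), so no test asserts it. The in-package implementation is checked
against the full published 34-pair verification set to ±1e-4 and against
an independent library implementation on random Lab pairs. ΔE₀₀ is
defined on Lab coordinates; descriptions of it as an "RGB distance" in
the figure-accessibility literature are operational shorthand, and this
package always converts to Lab first.

## Preprocessing

Images are decoded to sRGB with alpha composited over white (journal
figures render on white backgrounds); ICC-profile handling is left to
the decoder. Each image is scaled to a height of 300 px (bilinear,
width rounded, floor 1 px, upscaling permitted) and then quantized —
resize-then-quantize, in that order, so palette statistics are computed
at the standardized scale.

Quantization is a deterministic median cut over the unique colors
weighted by pixel counts: split the box with the largest single-channel
range (ties: R before G before B, then box creation order) at the
count-weighted median; each cell's palette entry is its weighted mean
color rounded to 8 bits (which stays inside the cell's bounding box);
colliding rounded representatives are merged. If the image already has
≤ 256 distinct colors the palette is exactly those colors. Determinism
was prioritized over matching any particular imaging tool so that tests
can be exact. No dithering.

An image is flagged grayscale when every *palette* color has a max
pairwise channel spread ≤ 10/255 — defined on the quantized palette so
JPEG chroma noise cannot defeat it. The same spread tolerance (10 8-bit
units, configurable) defines which palette entries count as achromatic
and are excluded from pair enumeration.

## Metrics: numerical choices

- **Mean pixel-wise distance** is divided by 100 so magnitudes sit on a
  0–1-ish scale comparable to published summaries; ratios are
  scale-invariant and unaffected.
- **Ratios** divide by `max(dist_sim, 1e-6)` and are capped at 1e6 to
  keep a zero simulated distance from producing infinities.
- **`max_ratio`** selects the pair with the largest *original* distance
  (its title reading); the alternative — the largest ratio over all
  pairs — is also computed (`largest_ratio`) since summaries in this
  literature are ambiguous between the two.
- **High-ratio threshold** is 5, strict inequality.
- **Spatial distance** is the unweighted mean of per-pair mean
  cross-color pixel distances, in pixel units of the resized image
  (heights are standardized to 300, so units are comparable across
  images; no diagonal normalization). Pooling all cross pairs across
  color pairs instead is available behind `pool_cross_pairs=True`.
  When a color pair has more than 10⁵ cross pixel pairs (exact
  enumeration can reach 10⁸), a seeded uniform subsample of 10⁵ index
  pairs (drawn with replacement) is used; tests confirm <1% deviation
  from the exact mean on block fixtures.
- When an image has no high-ratio pair the spatial metric is **NaN**
  rather than 0 — zero would falsely signal maximal proximity — and
  ranking places NaN as least problematic.

Ranking uses average ranks for ties; rank 1 is most problematic
(largest value for the four contrast-loss metrics, smallest for spatial
distance). The combined score is the arithmetic mean of the five ranks
and is only computed in batch runs, because ranks are corpus-relative.

## Feature classifiers

Training uses only `definitely_problematic` vs `definitely_okay`
examples (the "probably" labels and grayscale are excluded).
Logistic regression (liblinear solver) and random forests use
`class_weight='balanced'`; k-NN uses k = 5 and no weighting; all other
hyperparameters are library defaults. Two artifact-side choices where
the protocol is silent on how undefined features entered models:
NaN spatial distances are imputed with the training split's maximum + 1
(an "infinitely far apart" reading), and features are standardized —
both fitted on training data only, per fold, which a mutation test
enforces.

Cross-validation is three iterations of seeded stratified five-fold;
the published fold assignments are not available, so reproduction is
statistical rather than bit-exact. Summary AUROC/AUPRC are the mean
over iterations of the per-iteration median over folds. AUROC is the
trapezoidal ROC area (equal to the concordant-pair/Mann-Whitney
statistic, which the tests verify by brute force); AUPRC is the
precision-recall step integral, whose random-score baseline is the
minority-class frequency. Folds whose test split contains a single
class are skipped with a warning and the summary uses the remaining
folds.

Article-level labels aggregate image labels: any definitely-problematic
image makes the article problematic; otherwise any definitely-okay image
makes it okay; otherwise no label.

## CNN baseline

Eight 3×3 convolutional layers with batch normalization and ReLU. The
published width progression names six values (32 … 64, 128, 256, 512,
728) for eight layers; this implementation duplicates the first and last
widths — 32, 32, 64, 128, 256, 512, 728, 728 — and keeps the literal
728 (whether it was meant to be 768 cannot be resolved). The
downsampling schedule is unstated; stride-2 convolution at every width
increase is used (any schedule consistent with the widths would do), so
224-px inputs reach 7×7 and 64-px inputs 2×2 before global average
pooling, optional dropout, and a one-unit sigmoid head. Training is
Adam at 1e-3, binary cross-entropy, 30 epochs, batch size 16.

Configurable techniques: inverse-frequency minority-class weighting
(90/10 ⇒ minority weight 9); early stopping on internal-validation
AUROC (20% stratified split, patience 5 epochs — split fraction and
patience are artifact choices) with best-epoch weight restoration;
random horizontal flips plus random rotation, where the rotation
threshold (0.2 or 0.3) is a fraction of a full turn, applied to
training batches only; dropout (0.2 or 0.5) before the dense head;
transfer learning from a frozen base with global pooling into the dense
head, and an optional fine-tuning phase (unfreeze, 15 epochs at 1e-5,
refreeze). The 22-entry configuration grid enumerates each technique
and pairing family once; the exact published combination list is not
recoverable from the text.

The implementation is pure numpy (explicit im2col-style forward,
adjoint-verified backward, Adam, running batch-norm statistics); its
gradients are validated against float64 central differences and an
exact transposed-convolution reference. ImageNet-pretrained
ResNet50/MobileNetV2 weights require a one-time local download and are
deliberately outside the default test path; the freeze/fine-tune
mechanics are exercised using a locally trained checkpoint as the base.
The desk-scale profile (64-px inputs, halved widths, 10 epochs, class
weighting and early stopping on) is a first-class configuration used by
the test suite and the acceptance script; it trains the 200-image
synthetic corpus in tens of seconds on one CPU.

## Synthetic fixtures: what they do and do not show

Fixtures emulate the *chromatic* structure reviewers flag — confusable
red/brown-vs-olive/green combinations, contrast, spatial separation,
within-image labels — with flat color blocks at the pipeline's native
300-px height (so the resize step is the identity and certificates are
exact; PNG round-trips are lossless for these palettes). Each fixture's
promised facts are recomputed with the metrics module at generation time
and generation fails if they do not hold: the presence of particular
color combinations does not by itself make an image problematic, so the
promises are checked, not assumed. "Separation" in the block fixtures
widens the two color fields (growing centroid distance) rather than
inserting an achromatic gap, so the every-pixel-in-a-high-ratio-pair
certificate and the spatial-distance monotonicity property hold on the
same fixture family.

Labeled corpora draw jittered palettes from certified confusable and
friendly families (with a seeded fallback to the unjittered base when a
jitter fails certification), include a fraction of grayscale images
among the okay class, and hit their label counts exactly. A colorless
image cannot pose a deutan-contrast problem, so grayscale corpus images
carry the okay label; the separate `grayscale` review-label value exists
for the review vocabulary and is excluded from classifier training.

Fixtures contain no text, axes, anti-aliased edges, photographic
texture, or compression artifacts. Consequently, passing tests
demonstrate that the metrics, protocol, and training loops are correct
and that the classifiers can recover a clean chromatic signal — they say
nothing about performance on real figures, whose published benchmarks
require the original corpora and human labels.

## Problem sizes

The test suite and acceptance script use: the 34-pair CIEDE2000 set;
100 random images for simulation identities; ~30 images ≤ 8×8 with ≤ 6
palette colors for brute-force metric equivalence (spatial distance
uncapped); 50-vector corpora for rank checks; a 500-image certified
corpus (10% problematic) for the CV protocol and its permutation null;
1000 random instances for AUROC equivalence and n = 2000 for the AUPRC
baseline; a 200-image corpus for desk-scale CNN training; and a
30-image corpus for the CLI end-to-end run.

## Known limitations

- Deutan only; protan/tritan matrices are not included.
- The gamma-encoded matrix application is an operational convention,
  not colorimetric ground truth.
- Severity interpolation is linear between published steps.
- The CNN is CPU-oriented; no GPU path, no pretrained weights shipped.
- Metrics ignore spatial structure other than pairwise distance (no
  texture, labels, or legend awareness), and the quantized palette can
  merge perceptually distinct but nearby colors in very colorful
  images.
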