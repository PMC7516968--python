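# Methods

## Segmentation model

The segmentation stage assumes one pigmented lesion per image, darker
than the surrounding skin and interior to the frame. The chain is:
Gaussian blur (default σ = 3 px, chosen for 450×600-px frames: wide
enough to suppress fine hair, narrow enough to keep the lesion border) →
sRGB → CIE L\*a\*b\* (D65) → per-channel mean thresholding (1 where the
channel value ≥ its mean) → pixelwise AND → 5×5 median filter
(zero-padded) → lesion resolution → bounding box → crop.

Mean thresholding marks bright skin as 1 in all three channels, so the
lesion appears as an interior *background* component of the combined
mask. Because the thresholding never declares which polarity is the
lesion, the lesion is resolved structurally: the largest 8-connected
component, of either polarity, that does not touch the image border.
If every component touches the border (e.g. a uniform image, or a lesion
clipped by the frame) the largest component overall is returned with a
warning. Thresholding runs on the *blurred* channels (the blur exists to
stabilize it); the returned RGB/Lab crops are taken from the original
image so color and texture statistics see unsmoothed data.

Coordinates are 0-based, half-open, row-major. A mean threshold on a
blurred edge crosses ~1σ outside the true boundary (the exact distance
depends on the lesion's area fraction), so recovered boxes inflate by
roughly 2–3 px per side at σ = 3; downstream features are computed on
the mask, not the box, and are insensitive to this.

## Handcraft features (43 slots)

Fixed order: `symmetry, area, perimeter, circularity, diameter,
eccentricity`, then `{min,max,var,mean} × {R,G,B,L,a,b}` (24), then 13
texture statistics.

* **Symmetry** — principal axes from the second central moments of the
  mask; for each axis the centroid-centered pixel coordinates are
  reflected (Householder), resampled to the grid by nearest-neighbor
  rounding, and scored 1 − FS/A (A union area, FS symmetric-difference
  area); the two axis scores are averaged. Exactly 1 for a bilaterally
  symmetric shape; low for shapes whose reflection barely overlaps.
  Note that a reflection about an axis through the centroid always
  overlaps the original somewhat (mass lies on both sides of any line
  through the centroid), so 0 is a limit, not an attainable value.
* **Shape** — area is the lesion pixel count; perimeter uses the
  Crofton-formula contour length (4 directions), which is nearly
  unbiased for smooth digital shapes where chain-segment counting
  overestimates a disc's perimeter by ~5% and would bias circularity to
  ~0.9; diameter and eccentricity come from the image-moment ellipse
  (eigenvalues of the second-central-moment matrix). One-pixel-wide
  masks clamp eccentricity to 1 with a warning.
* **Color** — population variance (moment convention); statistics are
  computed over lesion-masked pixels by default (`lesion_only=False`
  switches to the whole rectangular crop; masked is the default because
  the features describe the lesion, not its surroundings).
* **Texture** — GLCM of the crop's luminance quantized to 32 levels,
  distance 1, angles {0°, 45°, 90°, 135°}, accumulated symmetrically,
  each offset matrix normalized to sum 1; the 13 statistics (ASM,
  contrast, correlation, variance, IDM, entropy, sum average, sum
  variance, sum entropy, difference variance, difference entropy, and
  the two informational measures of correlation) are computed per
  offset and averaged. Natural logarithms throughout, 0·log 0 := 0;
  IMCorr2 uses the square-rooted form, keeping it in [0, 1];
  correlation of a single-level (zero-variance) matrix is defined as 0.
  The classical 14-feature set is truncated to these 13 (the maximal
  correlation coefficient is omitted); sum average completes the count
  where only twelve statistics are spelled out elsewhere, since
  1 + 5 + 24 + 13 = 43 is the only consistent decomposition.
  By default only pixel pairs with both endpoints inside the lesion
  mask are accumulated (GLCM is implemented in-package for this;
  `skimage.feature.graycomatrix` cross-checks the unmasked path in the
  tests); when the lesion is thinner than the offset the whole crop is
  used with a warning.

## Deep-feature contract

A pretrained CNN in feature-extraction mode is a deterministic map from
an ROI to a fixed-length vector; the registry pins the standard
penultimate-layer dimensions (VGG16/19 → 4096, ResNet-50 / Inception v3
/ Xception → 2048, MobileNet v1 → 1024, v2 → 1280, DenseNet-201 → 1920).
Real backbones are optional plugins (requesting one without its deep-
learning backend raises an error naming the backend). The surrogate
extractor — `dim` seeded random 7×7×3 filters applied at stride 2 to the
bilinearly resized 32×32 ROI, rectified at zero, globally averaged — is
a pure function of its seed, nonnegative, and sensitive to lesion color
and texture. It stands in for the contract in all tests; it is not a
trained network and its features carry no semantic priors. Fusion
concatenates the deep block first, then the 43 handcraft slots.

## Mutual-information fusion

Per-column MI against the binary label uses Ross's mixed
discrete/continuous kNN estimator (k = 3 by default, the standard choice
for this estimator family): for each point, the Chebyshev distance to
its k-th nearest neighbor *within its own class* defines a radius; m
counts all points strictly inside that radius (self included, the k-th
neighbor excluded); then I = ψ(N) − ⟨ψ(N_x)⟩ + ψ(k) − ⟨ψ(m)⟩, clamped at
0. Columns with duplicate values receive deterministic tie-breaking
jitter at 1e−10 of their range, seeded from a checksum of the column
bytes so duplicated columns score identically. Constant columns score
exactly 0. A class with ≤ k members raises an error advising a lower k.
An equal-width binned plug-in estimator is provided for naturally
discrete data; both report nats. Selection keeps features whose score
strictly exceeds the mean score; if none qualifies, the single
highest-scoring feature is kept (lowest index on ties). MI, like every
other fitted statistic, is computed on the training partition only.

The implementation is verified column-for-column against
`sklearn.feature_selection.mutual_info_classif` (same estimator) and
against quadrature oracles in the tests. One consequence worth knowing:
with p = 1000 columns of which 10 are informative at ~0.5 nats, the mean
threshold sits less than one estimator-standard-deviation above the
noise scores' mean, so 15–20% of pure-noise columns pass selection at
n = 2000, k = 3, even though every informative column outscores every
noise column. The mean-threshold rule is a coarse filter, not a
false-discovery control.

## Balancing, normalization, splitting

SMOTE oversamples the minority class to exact parity: each synthetic
point is x_i + u·(x_nn − x_i), u ~ U[0,1], x_nn one of the k = 5 nearest
minority neighbors (Euclidean). Synthetic rows are provenance-flagged
and carry their parent indices and mixing coefficient, making the
convex-combination property exactly checkable. Z-score normalization
estimates μ, σ (population) on the training partition only; zero-σ
columns pass through with a warning. The split is stratified 75/25.

Stage order in the pipeline is fixed to prevent leakage: split →
z-score (train-fit) → MI selection (train-only) → SMOTE (train-only) →
train → evaluate on the untouched test partition. Published pipelines
are often ambiguous about whether balancing precedes the split;
balancing before splitting leaks synthetic copies of test neighborhoods
into training, so the leakage-free order is used and recorded in the
run report.

## Evaluation

Melanoma (label 1) is the positive class. Metrics follow the standard
confusion-table formulas; F-score = 2tp/(2tp+fp+fn); MCC with the
square-rooted denominator; undefined ratios are reported as NaN with a
warning. G-mean = √(sens·spec), dominance = sens − spec,
IBA = (1 − dominance)·G². "AUC" is reported twice to avoid conflation:
`auc_roc` (rank-based Mann–Whitney area under the ROC of the continuous
scores, ties ½) and `balanced_accuracy` ((sens+spec)/2), because
published AUC columns are frequently the latter. Published G-mean/IBA
columns are not always consistent with the formulas applied to the
printed sensitivity/specificity; the formulas are authoritative here and
such discrepancies are surfaced, not reconciled. The relevance vector
machine is exposed as an optional classifier kind but has no bundled
backend; logistic and SVM kinds are always available (SVM defaults
C = 1, γ = 1/p).

## Synthetic fixtures

The image generator emulates: lighter skin (default RGB (224,172,144)),
a darker elliptical lesion (default semi-axes 140×95 px in a 450×600
frame, ~15% of the image — typical dermoscopy framing, and large enough
that mean thresholding localizes the border well), 1–6 palette colors
assigned by a Voronoi mosaic of seeded sites, smooth interior intensity
modulation, additive Gaussian noise (σ = 2 intensity units), and
hair-like quadratic Bézier arcs. Bilateral asymmetry is a one-sided
radial perturbation (sin²θ bump over half the boundary) whose amplitude
monotonically decreases measured symmetry. Hairs carry the skin's
melanin chroma at low lightness (as real hair does): 70% fine 1-px
strokes at opacity 0.35–0.6 and 30% coarse 3-px strokes at 0.25–0.45.
Fully opaque chromatically foreign strokes would defeat any
blur-plus-median chain; the rendering reflects artifact levels the
method can plausibly handle, and that limitation is inherited from the
method, not hidden by the generator.

What passing tests on these fixtures shows: the geometry, color
statistics, information flow and bookkeeping of every stage are correct,
and the end-to-end pipeline separates classes that differ along the
ABCD axes. What it does not show: performance on real dermoscopy data,
which has vastly more appearance variation (gels, rulers, vignetting,
multi-component lesions, low contrast) than the generator emulates.

The table generator draws informative columns as N(effect·y, 1) and
noise as N(0, 1), with a fixed-count minority fraction.

## Reproducibility and problem sizes

All pipeline randomness flows from one master seed through named
substreams (split, SMOTE, surrogate weights, classifier); reruns are
bit-identical up to the report timestamp. The test suite and the
acceptance script run entirely on generated data at desk scale:
450×600-px images (up to 40 per run), 2000×1000 feature tables — sizes
at which every stage completes in seconds while the statistical checks
(MI estimator accuracy to ±0.02–0.05 nats, selection behavior,
classification sanity) are well-resolved.

## Known limitations

* One lesion per image; no hair inpainting (DullRazor-style), no
  multi-lesion handling, no occlusion robustness beyond blur + median.
* The mean-MI selection rule admits a substantial fraction of noise
  features in wide, sparse-signal regimes (see above).
* The surrogate extractor validates the extractor contract, not the
  representational power of pretrained CNNs.
* Binary classification only; the clinical TDS utility is a scoring
  helper, not part of the learned pipeline.
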