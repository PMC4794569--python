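# Methods

This note documents the models, conventions and design choices behind
`hep2cad`, in the order data flows through the pipeline.

## Synthetic well generator

The generator emulates the phenomenology of ANA reading on HEp-2 slides
well enough to exercise segmentation, feature extraction and
classification with exact ground truth. It does **not** attempt
photorealism, serum-dilution chemistry, or optics beyond brightness and
noise.

**Wells and images.** One image per negative well, three per positive
well; positive wells share one pattern and one non-negative intensity
across their images. The default negative fraction is 0.10 of all wells,
the usual negative rate in routine ANA workloads. Every positive image
contains at least one mitotic figure by default (`guarantee_mitosis`), so
the well-discard rule is exercised deliberately rather than accidentally.

**Cells.** An interphase nucleus is an ellipse (axis ratio 0.75–1.0,
random orientation) whose interior texture keys on the one visual trait
standard ANA nomenclature attributes to its class:

| pattern | texture rule |
|---|---|
| homogeneous | uniform fill |
| fine_speckled | many 1–2 px granules on a dim base |
| coarse_speckled | fewer 3–6 px granules |
| nucleolar | 1–5 bright round blobs (radius 3.4–5 px) on a dark interior |
| centromere | 30–60 discrete 2–3 px dots |
| nuclear_dots | 2–10 dots |
| nuclear_pore_complex | bright 2.5 px rim, dim interior |

The texture rules themselves are this package's design: clinical atlases
describe the patterns qualitatively and no generative model exists, so
each rule is the minimal parametric realization of the class's defining
trait, with granule sizes, counts and amplitudes exposed in
`SimulatorConfig`. The nuclear-pore-complex rim rule follows the standard
ANA nomenclature (rim staining) rather than any quantitative source.

**Intensity.** Each cell's unit texture (values in [0, 1]) is scaled by a
class amplitude: 36 (negative), 95 (intermediate), 185 (positive) gray
levels. Because the texture is fixed given the seed, mean brightness is
strictly monotone negative < intermediate < positive. Negative cells are
dim but present (amplitude 36, below the 45-gray-level negative ceiling),
mirroring real negative sera rather than empty frames. Textured patterns
use a base level of 0.25 × amplitude under their bright structures.

**Mitoses.** A mitotic figure is an ellipse with a central
collapsed-chromosome mass (0.55/0.50 of the cell radius). Negative
mitosis: body at 0.95, mass at 0.25 of the class amplitude; positive
mitosis: 0.28 and 0.95. The mass is deliberately large enough to survive
the downstream minimum-area filter on its own, because the weakly
fluorescent body of a positive mitosis often falls below the segmentation
threshold — exactly as in real images, where the chromosome mass is the
conspicuous structure. Mitotic radii are drawn from the top of the
interphase radius range.

**Frames.** Default 320 × 320 px, 8 interphase + 1 mitotic cell. Cells
are placed by rejection sampling (200 attempts per cell; failure raises,
naming the density limit — silent under-filling would corrupt ground
truth). Fluorescence lives in the green channel; red and blue receive a
5% bleed, matching FITC imagery. A constant background (8 gray levels)
and additive Gaussian noise (sd 4) model the camera; JPEG artifacts are
not simulated and images are written as lossless PNG by default. Every
generator is a pure function of its arguments including the seed;
manifests are byte-identical across reruns.

**What passing tests on this generator do and do not show.** The
synthetic classes are cleaner and better separated than clinical
material: no focus drift, no overlapping cells beyond what the placement
allows, no artefacts, no continuous intensity spectrum, and textures are
stationary within a class. End-to-end accuracy on synthetic wells
therefore demonstrates that the pipeline's plumbing, schemas and decision
logic are correct and that the stages learn what they are pointed at —
not that the same accuracy would be obtained on patient material.

## Segmentation

Classical and deliberately shared across classes: Gaussian smoothing
(sigma 2 px) of the green channel, thresholding, morphological opening
(radius 2), hole filling, and a watershed on the distance transform with
peaks at least 16 px apart to split touching nuclei. Regions under
200 px or touching the frame border are dropped; output is sorted by
bounding-box corner. The threshold is the **lower threshold of a
three-class multi-Otsu**: patterns dominated by bright substructures
(nucleolar, centromere) have trimodal histograms — background, dim
nuclear interior, bright structures — and plain Otsu splits the upper
two modes, losing the nucleus. Hole filling recovers the dark chromosome
mass inside negative-mitosis bodies. An all-uniform frame yields an
empty region list, not an error.

Coordinates are 0-based, row-major (row, col); bounding boxes are
half-open. Region contours are Moore-neighbour boundary traces; the
perimeter is the closed chain length with axial steps 1 and diagonal
steps √2 (a 20 × 20 square has perimeter 76 under this convention).

## The 108-value descriptor

27 features per quantization level at 256, 128, 64 and 32 gray levels
(`floor(v·levels/256)`; 256 is the identity on 8-bit input),
concatenated levels-major. Names follow `L{levels}.{group}.{feature}`.

* **Intensity (9):** mean, sd, sd/mean (0 when the mean is 0), Shannon
  entropy of the level histogram (bits), moment of inertia of the
  intensity distribution about its own centroid (normalized by total
  intensity), skewness, excess kurtosis (both 0 for constant regions),
  entropy of the gradient-magnitude histogram restricted to the mask
  boundary, and the median level. The group is specified as nine values;
  the ninth is defined here as the median quantized level, a robust
  central-tendency companion to the mean. The boundary-gradient entropy
  is computed on boundary pixels only (mask minus its erosion), with the
  same 16-bin histogramming as the HAG feature.
* **Geometry (8):** mean/sd/max of centroid-to-contour radii, sd/mean of
  radii, circularity 4πA/P², anisotropy 1 − minor/major axis of the
  second-moment ellipse, box-counting fractal index of the contour
  (box sizes 2–32, least-squares slope of log N vs log 1/s), and the
  ellipse eccentricity.
* **Shape (8):** area, chain perimeter, convex area, convex deficiency,
  solidity, compactness P²/A, roundness 4A/(π·major²), and the Euler
  number (8-connected foreground, 4-connected background).
* **Descriptors (2):** entropies of the histogram of oriented gradients
  (9 unsigned bins over 0–180°, magnitude-weighted) and the histogram of
  amplitude gradients (16 bins over [0, max magnitude]). Bin counts are
  the conventional defaults and configurable. Gradients are central
  differences (one-sided at patch borders); an all-zero gradient field
  has entropy 0 by convention.

Geometry and shape are recomputed per level on a mask re-derived from the
quantized patch (level > 0 within the cell mask, largest connected
component) — otherwise 16 of the 27 features would be duplicated four
times over, contradicting the per-level structure of the descriptor. When
quantization annihilates the cell (everything maps to level 0, as happens
for dim cells at 32 levels) the segmentation mask is used unchanged. All
quantities are mask-relative, so the descriptor is invariant to the
cell's position in the frame. Entropies are base-2 throughout; empty
histogram bins contribute zero.

## Classifier stages

* **Intensity cascade** — two RBF-kernel SVMs with standardized inputs:
  negative-vs-rest, then intermediate-vs-positive, applied to a per-image
  summary (mean and sd of the image's cell descriptors plus six global
  green-channel statistics). The three-class problem is realized as a
  cascade because the triage decision (negative vs not) is the clinically
  primary one and gates all later stages. C is selected from {0.1, 1, 10}
  by stratified 3-fold cross-validation maximizing mean class accuracy.
* **Pattern stage** — seven one-vs-all SVMs (RBF, standardized features,
  C from {1, 10} by the same MAC-driven cross-validation), each emitting
  a [0, 1] membership score via a logistic squashing of the decision
  function. The one-vs-all family is not dictated by any external
  constraint; margin classifiers with per-model standardization were
  chosen for determinism and small-sample robustness, and the family is
  configurable. Per-class "differentiated processing" is realized as
  per-model feature standardization plus optional per-class feature
  masks in the configuration — not per-class segmentation, for which no
  specification exists. Training cells are capped at 600 per pattern
  (seeded subsample) to bound the quadratic SVM cost.
* **Mitosis stage** — two feed-forward networks (one hidden layer of 16
  units, seeded initialization): positive-mitosis-vs-rest and
  negative-mitosis-vs-rest, trained on all matched cells of non-negative
  images with interphase cells as the rest class. Scores are
  probabilities in [0, 1].
* **Fusion** — a K-NN in the 9-dimensional score space (7 pattern + 2
  mitosis scores), Euclidean metric; K odd, selected from {3, 5, 7, 9}
  by cross-validated MAC. Ties are broken by the smallest summed
  neighbour distance, then by canonical pattern order. The fusion
  consumes exactly nine inputs; any other width is a schema error.

**Decision flow.** An image is triaged first; a negative image gets no
pattern call and no pattern or mitosis model is evaluated for it. For
non-negative images every segmented cell is scored and fused per cell
(fusion operates per cell, with the image call a majority over cells —
the aggregation level was an open choice and per-cell fusion keeps the
fusion stage's training signal at the granularity the scores exist at).
Cells whose maximum mitosis score exceeds 0.5 set the image's mitosis
flag and abstain from the pattern vote (their texture reflects mitotic
chromatin, not the serum's interphase pattern), unless every cell is
flagged. Image-majority ties resolve to the highest mean fused-class
score. Well intensity is the majority over images with ties resolved
toward the more positive class; well pattern the majority over
non-negative image calls with ties resolved by canonical order; a
non-negative well with no mitosis-flagged image is discarded with reason
"no mitosis detected". An optional rejection floor on the fused
confidence can emit "no pattern" (an *other* call); it is off by default
because no training definition of an eighth class exists.

**Training data harvesting.** Detected regions inherit ground-truth
annotations by majority ownership of the predicted mask (≥ 50% of the
region's pixels inside one truth cell) rather than symmetric IoU, because
a positive mitosis legitimately segments as its chromosome mass alone.
The test-harness matcher (`match_regions`) is stricter: greedy one-to-one
matching at IoU ≥ 0.5.

**Serialization.** A bundle round-trips through a directory (JSON
metadata with a schema version, joblib blob for the fitted models) with
bit-identical predictions.

## Statistics

CCR, Accuracy and MAC are defined on a labeled confusion matrix with rows
as the reference axis. MAC averages over classes that have reference
examples; empty classes are excluded and reported — this matches how a
published per-class table with an empty class row must be averaged to
reproduce its own printed MAC. For two-reader agreement tables, CCR is
reported in both directions since neither reader is canonical. Cohen's
kappa uses the standard chance-corrected form; χ² drops empty rows and
columns before testing; McNemar's exact mode is the two-sided
binomial(b, b+c, ½) tail (default when b + c < 25), the corrected mode
the continuity-corrected χ²; both are exposed because printed p-values in
the literature rarely state the variant. Zero discordance yields p = 1 by
convention. Fixture comparisons round to the precision conventionally
printed: integer percent for concordance, two decimals for kappa, one
decimal for MAC.

The reader + CAD combination (the "second reader" workflow) has no
canonical definition, so it is a pluggable policy with three built-ins:
`never` (reader unchanged), `always` (CAD call adopted), and the default
`confidence` (the reader keeps their call unless the CAD disagrees with
confidence above a threshold, default 0.5).

## Problem sizes and numerical choices

The shipped end-to-end check trains on 30 wells per pattern and tests on
10 per pattern (with the default 10% negative wells), roughly 870 images
and 8,000 cells — enough for every stage to have hundreds of training
examples per class while a full run stays in the minutes range on one
CPU. Deterministic seeds propagate from one `RunConfig.seed` into every
stochastic component (generator, subsampling, cross-validation shuffles,
network initialization). Feature values are validated finite; degenerate
denominators (zero mean, zero sd, zero perimeter, empty histograms)
return 0 rather than NaN, and genuinely unusable inputs (empty masks,
regions under 4 px for geometry) raise.

## Known limitations

* The generator's class separability is optimistic; accuracy numbers on
  synthetic wells are upper bounds on clinical behaviour.
* Segmentation is shared across classes and classical; heavily
  overlapping cells beyond a two-cell watershed split are out of scope.
* Pattern calls for wells where all cells are mitosis-flagged fall back
  to using all cells, which is the right behaviour for dense mitotic
  fields but untested against real ones.
* Weighted kappa and multi-rater (> 2) agreement are not implemented.
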