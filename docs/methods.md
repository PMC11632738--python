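# Methods

## Landmark schema and coordinate conventions

Thirteen soft-tissue landmarks are indexed 0–12 with fixed names:
menton (0), lower border of the lower-lip vermilion (1), stomion inferius
(2), stomion superius (3), right/left Cupid's-bow peaks (4, 5), subnasale
(6), right/left alar bases (7, 8), right/left medial canthi (9, 10),
right/left medial brow points (11, 12). "Right" is the subject's right.
Bilateral pairs (4,5), (7,8), (9,10), (11,12) swap under a horizontal
mirror; the remaining five points lie on the facial midline.

Coordinates are 0-based with the origin at the top-left pixel centre, x
rightward, y downward. Annotations are serialised as JSON keyed by the
landmark names at 0.01 px precision; a flat CSV mirror exists. The
binarized-mask format (one small disc per landmark) is supported as an
export/import path with a sidecar ordering record, because a mask alone
cannot encode landmark identity; coordinates are the canonical annotation.

## Network

Input: a face-centred square crop resized (bilinear) to 40×40 RGB, scaled
to [0, 1]. Trunk: four convolutional stages, 3×3 kernels with same
padding, channel widths 16-32-64-128, tanh activation, 2×2 max-pool
(stride 2) after each stage; the final 128×2×2 response is flattened to
512 features. Heads: one per landmark — fully connected 512→64 (tanh) then
64→2 with a logistic output, so each landmark owns its regressor and the
output pairs lie in [0, 1]², normalised by the crop frame. ~471k
parameters in the heads plus ~97k in the trunk. The specialised-head
design follows the small tweaked-CNN family for facial landmarks; kernel
sizes, widths and activations are this package's choices where the family
leaves them open.

Training: mean squared error on the normalised coordinates; Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e-8) with base learning rate 1e-3 and batch
size 1. Because single-example updates leave a high stochastic noise floor
at a constant step size, the learning rate follows a cosine decay from the
base rate to 5% of it over the epochs; this roughly halves the final
landmark error in our runs without changing anything else. A mild
decoupled weight decay (1e-2 of the current learning rate, applied to
weight matrices only) limits head overfitting — with 512→64 parameters
per landmark head the model can memorise a small cohort outright. Two
epoch presets define the program versions: version 1 = 200 epochs,
version 2 = 1000 epochs ("epoch" = one presentation of every training
image).

Augmentation draws independently per presentation: with probability 0.5 a
horizontal mirror (pixels flipped, x → (width−1)−x, bilateral indices
swapped), otherwise a saturation jitter — HSV saturation scaled by a
factor uniform in [0.6, 1.4]. Input stays RGB precisely because the
saturation channel carries augmentation signal.

Everything is seeded (`numpy.random.default_rng`); forward, backward and
the Adam update are plain numpy, so a fixed seed reproduces training
bit-for-bit when run single-threaded (BLAS threading can reorder
reductions on some builds).

Evaluation reports the Euclidean landmark error divided by the subject's
true intercanthal distance (indices 9–10), per landmark and averaged; this
face-scale normalisation makes errors comparable across image scales.

## Fiducial calibration

A 10 mm circular silicone pad on the forehead provides the pixel-to-mm
scale. Detection: Euclidean RGB distance to the configured pad colour
(default a saturated blue absent from skin/lip/background tones, threshold
80), connected-component labelling inside the search region (default the
upper third of the frame), area ≥ 40 px, circularity 4πA/P² ≥ 0.8; the
largest surviving component wins, and a second candidate within 90% of its
area raises an ambiguity error. The equivalent diameter 2√(A/π) is used
rather than a bounding-box width because it is robust to anti-aliased
rims; on rendered discs the recovered scale is within ~1% of truth.
A per-image `mm_per_px` manifest override covers images without a visible
pad.

## Measurements

Each of M1–M9 is the Euclidean distance between two endpoints — a landmark
or the midpoint of a bilateral pair — times mm/px, reported at 0.01 mm
(digital-caliper resolution). The registry: M1 midpoint(11,12)→6 (the
brow-inner midpoint serves as a glabella proxy), M2 6→0, M3 9→10, M4 7→8,
M5 6→3, M6 midpoint(4,5)→3, M7 2→0, M8 2→1, M9 3→2. Euclidean (not
vertical-projection) distances are used throughout, matching what a
two-jaw caliper measures between surface points; the interlabial gap is
therefore ≥ 0, ≈ 0 for lips in contact. The registry is data-driven
(JSON override) because endpoint pairing is the one place where published
soft-tissue definitions admit alternatives.

These definitions make every measurement invariant to rigid motion and to
the mirror-with-index-swap map, and equivariant under joint rescaling of
coordinates and mm/px — properties the test suite checks to 1e-9.

## Agreement analysis

Differences are oriented reference − automated (CM − AM). For each
measurement and program version: mean and sample SD (n−1) of the paired
differences, the paired t statistic d̄/(s_d/√n), df = n−1, and the
two-sided p from the t distribution; flags at α = 0.05 and α = 0.01; no
multiple-testing correction. Degenerate inputs follow the conventions
p = 1 when all differences are zero and p = 0 (infinite t) when s_d = 0
with a non-zero mean. Both comparison columns are computed as paired
tests. An alternative entry point rebuilds the full report from published
summary statistics (mean ± SD of differences at a given n), which is how
the reference clinical tables are re-derived without subject-level data.

## Synthetic cohort

The generator emulates an adult orthognathic-clinic population on a
1024×1024 canvas. Per subject, the nine measurements are drawn from normal
distributions with the clinical reference cohort's caliper means ± SDs
(e.g. middle third 62.47 ± 5.05 mm, intercanthal 32.02 ± 2.41 mm,
interlabial gap 2.20 ± 0.93 mm truncated at 0), and the landmark layout is
constructed so those values hold exactly: midline points share the face
midline, vertical spacings equal the drawn measurements, bilateral pairs
are mirror-symmetric up to a jitter ≤ 3 px (default 1.5 px). A deformity
fraction (default 0.25, matching 5 of 20 in the clinical test group)
receives an exaggerated lower third (+15–35%), thicker lower vermilion and
a widened interlabial gap. The capture scale mm/px is uniform in
[0.18, 0.22] — a 10 mm pad spans 45–56 px — floored per subject so the
face fits the canvas margins.

Rendering uses soft-edged shaded ellipses: face outline (bottom edge at
the menton), brow arcs ending on the medial brow landmarks, eye outlines
whose medial edge is the canthus, a nose wedge whose base shadow ends at
the subnasale with alar wings whose outer tips are the alar landmarks, and
two vermilion ellipses separated by an interlabial seam spanning exactly
the true gap (a hairline seam remains when lips touch). The alignment of
every drawn cue with its landmark is deliberate: the generator's contract
is an exact appearance-to-landmark mapping, which is what makes synthetic
training and the localization-error criterion meaningful. The fiducial
disc is drawn fully visible on the forehead, never overlapping landmarks.
Additive Gaussian pixel noise (σ = 4/255 by default) is applied last.

The synthetic "conventional measurement" is the noiseless ground truth
(computed from the true landmarks and true scale) plus Gaussian caliper
noise, σ = 0.3 mm, emulating manual measurement error; the noiseless table
is also written for oracle checks. Datasets are split 80/20 train/test by
default.

What the generator does **not** emulate: photographic texture, hair,
facial hair, specular skin, occlusions, pose/expression variation, camera
perspective, or inter-rater caliper bias. Passing the synthetic pipeline
criteria therefore demonstrates that the architecture, training loop,
calibration and statistics are correct and well coupled — not that the
network would reach clinical accuracy on photographs, which requires the
kind of clinical database the original workflow was built on.

## Problem sizes and numerical choices

The package's standing learning experiment uses 240 subjects (200 train,
40 held out) and the version-1 preset (200 epochs ≈ 40k Adam steps,
~5 min on one CPU core); the same generator scales to arbitrary n.
Measured on that experiment, the held-out mean intercanthal-normalised
landmark error is just under 0.1 (roughly half an input pixel at the
40×40 network resolution) and per-measurement mean biases versus ground
truth stay within about 1 mm — both recomputed by `scripts/acceptance.py`
and the acceptance test suite rather than quoted from any fixed table.

Ties and degenerate cases: max-pool breaks ties toward the first index;
crop padding is black; bilinear resize with edge mode and no anti-alias
(deterministic); landmark sets must contain exactly 13 finite points, and
mask import requires exactly 13 components. Checkpoints are single-file
`.npz` with a version header and the architecture descriptor embedded as
JSON.

## Known limitations

- Schematic appearance only; no transfer claim to photographs.
- The pad detector assumes a colour pad distinguishable from skin tones;
  a grey pad would need a different threshold configuration.
- Strict bit-reproducibility of training assumes single-threaded BLAS.
- The crop centre comes from the manifest (faces are assumed centred at
  capture, as in the clinical protocol); no face detector is included.
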