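# Methods

This note documents the models and procedures implemented in `dermoscan`,
the parameters that matter, the numerical choices made where the design
was open, and what the synthetic experiments do and do not demonstrate.

## Scale-space key-point detection

The detector follows the classic SIFT construction. Intensities are
normalized to [0, 1] (division by 255 for 8-bit input) before the pyramid
is built, so the low-contrast threshold has a fixed meaning across
images. Each octave holds six Gaussian planes at scales `σ0·k^l`
(`σ0 = 1.6`, `k = 2^(1/3)`), giving five DoG planes; extrema are searched
on the three interior DoG planes, which tile the scale axis contiguously
across octaves (`k¹…k³`, then `2k¹…2k³`, …). Four octaves are built by
default, each starting from the previous octave's `σ`-doubled plane
subsampled by two. Fewer DoG planes per octave leave a gap in searched
scales at octave seams — blobs whose characteristic scale falls near
`2σ0` are then never interior extrema — which is why the minimal
three-plane configuration is not the default.

A candidate must be strictly larger (or smaller) than all 26 neighbours
in the 3×3×3 cube spanning its own and both adjacent DoG levels. Taylor
localization solves the 3-D stationary condition `H x̂ = −∇D`; when an
offset component exceeds 0.5 the candidate is re-anchored to the next
cell (up to five times), with the anchor clamped to the interior sampling
range. An offset that keeps oscillating just above 0.5 between two
adjacent cells means the extremum lies essentially on the shared cell
boundary; such candidates are accepted with the offset clamped to ±0.5
rather than discarded — plain rejection measurably loses blob key points
sitting exactly at octave seams.

Rejection thresholds: `|D(x̂)| < 0.03` (low contrast) and
`tr(H)²/det(H) ≥ (r+1)²/r` with `r = 10` (edge response), where `H` is
the 2×2 spatial Hessian estimated by central differences. One deliberate
property of this construction: an isolated single-pixel impulse has a DoG
magnitude that decreases monotonically with scale (its characteristic
scale lies below `σ0`), so it produces *no* interior scale-space
extremum; the smallest features the detector can represent are blobs of
roughly `σ0` extent.

Orientation assignment uses the gradient operators
`m = √((L(x+1,y)−L(x−1,y))² + (L(x,y+1)−L(x,y−1))²)` and
`ϕ = atan2(L(x,y+1)−L(x,y−1), L(x+1,y)−L(x−1,y))` (the two-argument
arctangent keeps the full quadrant, matching the (−π, π] codomain), with
a 36-bin histogram over the 3×3 neighbourhood weighted by
`m · exp(−d²/2σ²)`. Every peak at or above 80 % of the maximum bin
produces one oriented key-point copy. The 3×3 support is much smaller
than common SIFT practice; it is kept as specified, and the test fixtures
use anisotropic (shaded) blobs because a perfectly isotropic blob's
orientation is genuinely undefined (its histogram has four symmetric
peaks). Descriptors are the standard completion: a 16×16
orientation-aligned neighbourhood, 4×4 areas × 8 orientation bins,
L2-normalized 128-vector; a flat patch yields the zero vector
unnormalized.

## Key-point filters

*Background*: reference photos of the empty scene are run through the
detector and each key point stored as (rounded position, pixel color). A
scene key point is deleted when a stored entry lies within `pos_tol = 2`
px per axis *and* the scene color is within `color_tol = 20` per channel —
exact matching would be brittle under sensor noise and lighting changes.
*Palette*: the 3×3 median color around a key point must be within a
per-channel tolerance (default 40) of at least one anchor of a 12-tone
skin palette; the shipped palette is an explicit stand-in the user is
expected to override. *Elongation*: the same-intensity region around the
key point is grown (capped at 4096 px — larger regions are area-like, not
line-like) and the key point is dropped when the region bounding box has
aspect ratio above 5. All filters preserve order, are idempotent, and
never add key points.

## Cluster extraction

The crop window is `⌈0.15 w⌉ × ⌈0.15 h⌉`, shifted (not shrunk) at image
borders. The window is simplified by grayscale conversion
(`⌊(R+G+B)/3⌋`), gamma correction (γ = 1.5, round-half-up then clamp) and
a strong contrast stretch (ω = 128, clamped to [0, 255] — a literal
modulo-255 reading of the stretch formula would wrap clipped values and
re-introduce the small structures the step exists to remove). Region
growth is an explicit-queue flood fill, 4-connected, accepting pixels
within tolerance 10 of the *seed* intensity; 4-connectivity is chosen
because 8-connectivity leaks through diagonal pixel chains on noisy
fixtures, and the seed-relative criterion makes the region a well-defined
connected component, independent of visit order.

A key point is rejected when its region covers more than 30 % of the
*crop-window* area (it sits on homogeneous background) or fewer than 9
pixels (isolated noise). The window-referenced threshold is the only
coherent reading: a 15 % × 15 % window holds at most 2.25 % of the full
image, so a threshold referenced to the full image area could never fire.
Accepted regions are cropped to their bounding box, the original colors
restored, and the crop resized (pure bilinear, no aspect-preserving
padding) to 64×64. Clusters whose regions overlap by more than half of
the smaller region are duplicates of one mark; the one with the larger
detector response is kept.

## Histogram screening

Each cluster is summarized by four unit-mass 256-bin histograms (gray,
R, G, B) and compared against stored exemplars by histogram
intersection `Σ min(aᵢ, bᵢ)` averaged over channels — symmetric, bounded
in [0, 1], equal to 1 exactly at identical normalized histograms, and
insensitive to cluster size. A cluster is forwarded when its best
similarity to a nevus exemplar is at least `margin` (default 1.0) times
its best similarity to a plain-skin exemplar; near-ties (gap < 0.02) are
forwarded, since the system's purpose is high-sensitivity alerting.
Comparison happens on the un-blurred cluster; forwarded clusters are then
blurred with the exact binomial kernel (1/16)[1 2 1; 2 4 2; 1 2 1] before
classification. The default database is seeded from the generator's
labeled clusters plus plain-skin patches; users may import their own
exemplars (JSON).

## Convolutional network

Architecture (defaults, configurable): conv(8 filters 3×3, stride 1,
valid) → 3×3 max pool → conv(16) → pool → flatten → dense(32, tanh) →
dense(2, tanh), on 64×64 RGB input scaled to [0, 1]. Convolution layers
are linear filter banks over all input planes (output side
`⌊(N−m)/S⌋+1`); the named blur and emboss kernels are available both as
fixed filters and as initializations, but by default all kernels are
trainable weights initialized uniform(−0.1, 0.1) from the seed. Pooling
replaces each non-overlapping 3×3 tile by its maximum (or by
`μ1·max R + μ2·max G + μ3·max B`, `Σμ = 1`, for RGB stacks; when selected
this weighted mode is applied once, directly on the RGB input). Sides not
divisible by 3 are padded by edge replication; the pad's gradient is
folded back onto the replicated edge pixel, which keeps the analytic
gradient exact.

Loss is mean squared error over the two tanh outputs with targets ±0.9
(targets strictly inside the tanh range keep `ϕ′ = 1 − tanh²`
well-conditioned). Backpropagation is the plain chain rule: dense layers
propagate `δ·(1−y²)`; convolution weight gradients are correlations of
input windows with the output error and input gradients are the
transposed convolution (stride handled by zero-dilation); pooling holds
no trainable parameters and routes gradients to the argmax positions
(scaled by μ in weighted mode). The entire gradient is verified against
central finite differences (max relative error < 1e-4) in the test suite
and the acceptance script. Training is full-batch-shuffled mini-batch
gradient descent (lr 0.05, batch 16), bit-reproducible from the seed.
Prediction maps the two outputs through `(y+1)/2`, renormalizes to sum 1,
and takes the larger; an exact 0.5 tie resolves to benign.

## Synthetic data

`make_scene` renders a frame whose right 70 % is skin (base tone
(210, 160, 125) with low-frequency sinusoidal variation ±10 and Gaussian
noise σ = 2) and left 30 % a cool blue-gray wall with clutter rectangles;
clutter is kept strictly inside the wall strip so that the empty-room
render and the scene agree on every background feature. Nevi are
ellipses with horizontal semi-axis `r` and vertical half-axes
`b(1 ± asymmetry/2)` (so the mask area stays at the analytic
`πr²(1 − asymmetry/2)`), a fuzzy-border alpha ramp straddling the nominal
outline (the half-opacity contour preserves the area for any fuzz), and
angular sectors of distinct shades for color variegation. The label rule
mirrors the clinical signs: suspicious iff diameter > 6 mm, asymmetry
> 0.5, or ≥ 3 shades. Criterion E is available as a paired-scene mode
(same seed, `enlarge > 1`); the pipeline itself does no temporal
comparison.

The pixel scale is an explicit convention: 10 px/mm for dermoscopy-like
cluster crops (so the 6 mm criterion is 60 px), 4 px/mm for room-scale
scenes (the camera is farther away; a suspicious nevus must fit inside
the 15 % crop window). Cluster datasets are rendered on a 96×96 skin
patch, cropped to the mask bounding box and resized to 64×64 — the same
crop-and-resize path the pipeline applies to real clusters, so training
and deployment distributions match. Benign clusters are near-round,
single-shade, sharp-bordered, 2.5–4 mm; suspicious ones asymmetric
(0.55–0.9), fuzzy (0.4–0.9), multi-shade (3–5), 4.2–5.8 mm; the diameter
ranges are parameters, so class separation is controllable.

What the generator does *not* emulate: hair, specular highlights,
shadows, perspective foreshortening, camera noise beyond i.i.d. Gaussian,
and the full diversity of real nevus morphology. Passing the synthetic
experiments therefore demonstrates that the pipeline's stages are
individually and jointly correct under controlled conditions — not that
the trained classifier generalizes to clinical photographs. Training on
real data (e.g. the PH2 dermoscopy set via `pipeline.load_ph2`, with
common/atypical nevi mapped to benign and melanoma to suspicious — an
explicit, configurable mapping) is required for any claim about real
images.

## Evaluation

Confusion counts follow the one-vs-rest definitions for the suspicious
class; the nine derived measures are accuracy, precision, sensitivity,
specificity, fall-out, false-negative rate, negative predictive rate,
false-discovery rate, and F-measure. Ratios with zero denominators are
reported as NaN, never as 0, and the identities `precision + FDR = 1`,
`Se + FNR = 1`, `Sp + fall-out = 1` and the F harmonic relation are
enforced by construction and asserted over randomized confusion matrices.
Train/test experiments use a seeded stratified 70/30 split (the split
protocol is this package's choice). Problem sizes in the shipped
experiments — 200-cluster training sets, 384×288 scenes, ten scene seeds —
were chosen so the full suite runs comfortably on a single CPU while
leaving the class structure non-trivial.

## Known limitations

* The 3×3 orientation support makes orientations noisier than standard
  SIFT's σ-scaled window; rotation invariance is verified at 90°
  multiples, not arbitrary angles.
* The screening database and skin palette defaults are synthetic
  stand-ins; real deployments must build both from their own data.
* The classifier is a small from-scratch network trained by plain
  gradient descent; it is the method under study, not a
  state-of-the-art melanoma classifier.
* Region growth assumes the contrast/gamma simplification flattens a
  mark into a near-uniform region; heavily textured marks can fragment.
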