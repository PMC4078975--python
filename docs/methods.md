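# Methods

This note records the model, the defaults and the numerical choices behind
`cellsift`, and what the synthetic experiments do and do not demonstrate.

## Dense SIFT extraction

Gradients are central differences (`numpy.gradient`; one-sided at the image
border), with magnitude `hypot(gx, gy)` and orientation `atan2(gy, gx)`
wrapped to [0, 2π). A descriptor is the 4×4-cell × 8-orientation-bin
histogram of gradient magnitude over a half-open patch
`[r, r+patch) × [c, c+patch)`; patches step by `stride` from (0, 0), so an
H×W image yields `⌊(H−patch)/stride+1⌋ × ⌊(W−patch)/stride+1⌋` grid
positions. Defaults: `patch_size=16` (4-px cells), `stride=4` — dense,
overlapping coverage; both configurable.

Two binning modes exist. **soft** (default, standard SIFT): magnitude is
split linearly between the two nearest orientation bins (bin centers at
k·π/4), spread bilinearly over the four nearest cell centers, and weighted
by a Gaussian window (σ = patch/2) centered on the patch. **hard**: each
pixel contributes wholly to its enclosing cell and to bin
`⌊θ/(π/4)⌋ mod 8`; hard mode exists because it is unambiguous to verify
against a brute-force per-pixel oracle, which the tests do.

Non-zero raw histograms are ℓ2-normalized, clamped component-wise at 0.2 and
renormalized (illumination robustness); after the second normalization a
component may exceed 0.2 but never 1. The zero flag is decided on the *raw*
histogram, since normalizing a zero vector is undefined. A descriptor is
retained when its patch-center pixel is foreground; a minimum
foreground-fraction criterion is available but off by default, since the
masks only mark stain and no finer rule is canonical.

Keypoint detection (difference-of-Gaussian extrema) is deliberately not
implemented: dense sampling replaces it throughout.

## Resolution pyramid

Four levels by default. Level r is level r−1 smoothed with a Gaussian
(σ = 1) and decimated by 2; the factor-2 pyramid is this package's choice of
"multiple resolutions" — any fixed decimation scheme would do. Masks are
decimated with an any-contributing-pixel-foreground rule so coarse levels
never lose foreground entirely. 128 px is the smallest image for which the
coarsest level still holds one 16-px patch.

## Descriptor pool and codebooks

The pool targets P = 100,000 non-zero descriptors. In balanced mode each of
the task's two classes gets a quota of ⌊P/2⌋ (remainder to the first class);
within a class the quota is divided equally across images by water-filling,
so an image with too few descriptors contributes everything it has and its
deficit is spread over its siblings. Sampling is without replacement and
seeded; when supply is below quota everything available is taken with a
warning. The pool is a single total, partitioned by resolution level for the
per-level codebooks.

k-means is Lloyd's algorithm on the squared-Euclidean objective
("summed within-cluster distance" is read as inertia): init by uniform
sampling of distinct pool points, at most 300 iterations, stop when the
relative objective decrease is ≤ 1e-4, empty clusters reseeded to the point
farthest from its assigned center. Three restarts (seeds seed, seed+1,
seed+2); the restart with the smallest final objective wins. If a level
supplies fewer than m points, that level's word count is reduced to the
supply with a warning. `max_per_level` optionally subsamples a level's pool
(seeded) before clustering, which bounds the cost of desk-scale runs.

Quantization assigns each non-zero descriptor to the ℓ2-nearest center at
its own level, ties to the lowest center index (deterministic and
oracle-friendly); zero descriptors increment the level's extra zero bin.
Histograms are raw counts; a per-level relative-frequency normalization is
available behind `relative_frequencies`. With m = 500 and 4 levels the
single-section feature has (500+1)×4 = 2004 components. For two-section
concatenation the per-level word count drops to 250; under the zero-bin
layout this gives (250+1)×4×2 = 2008 components, not 2004 — the layout rule
is applied literally and the four-dimension difference is accepted rather
than silently dropping zero bins. All indices are 0-based, so the level-0
zero bin of an m=250 layout is index 250 (the 251st component).

## Tasks and splits

A gene is enriched in type T at threshold t iff it has a record
(gene, T, fold) with fold **strictly** greater than t. Six binary tasks:
each type against the negative set (genes with no enrichment record of any
type) and each pair of types. Genes qualifying for both sides of a pairwise
task are excluded and logged — multi-type genes exist but would make labels
ill-defined. Canonical thresholds are 1.5, 10 and 20.

Train/test partitions put 2/3 of the data in training. By default splits are
grouped by gene (all images of a gene on one side; prevents leakage between
a gene's image series) and stratified by class (avoids degenerate test
sets); both are explicit package choices and can be disabled for a plain
row-wise split. Per-stratum training counts are rounded to nearest, clipped
to leave both sides non-empty.

## Classification and evaluation

The ℓ2 penalty is implemented as the squared norm λ‖w‖₂² — the standard
convex form — and the bias is never regularized. ℓ2 fits use L-BFGS on the
exact objective with analytic gradients (gradient tolerance 1e-8 by
default); ℓ1 fits use FISTA (accelerated proximal gradient with
function-value restart, step 1/L with L = 0.25·‖[X 1]‖₂²), whose
soft-threshold step makes zeros in w exact. AUC is the Mann–Whitney rank
statistic (tie pairs half credit). The protocol runs 30 repetitions; in
each, λ is selected over a 7-point log grid 10⁻³…10³ by stratified
cross-validated AUC on the training side — 5 folds, capped at the smaller
class count so small gene sets degrade gracefully (with a single-λ fallback
and warning when even 2-fold is impossible) — then the model is refit on the
full training side and scored on the test side.

The Wilcoxon signed-rank test discards zero differences, midranks ties in
|d|, and uses the exact null distribution of W⁺ (computed by convolution
over the doubled ranks — equivalent to enumerating all 2ⁿ sign patterns)
for effective n ≤ 25, otherwise a normal approximation with tie and
continuity corrections.

## Stability selection and traceback

B = 100 subsamples of size ⌊n/2⌋ drawn without replacement (a draw missing
a class is redrawn, up to 100 attempts); along a decreasing λ grid an ℓ1
path is fit per subsample (warm-started), and feature j counts as selected
when |w_j| > 1e-8 — the solver's numerical zero. The default grid has 15
log-spaced points from λ_max down to 0.01·λ_max, where λ_max is computed
from the null-model gradient max_j |Σ_i x_ij r_i| at w = 0,
b = prior log-odds. λ_max is inflated by a relative 1e-4: exactly at λ_max
the null solution sits on the subgradient boundary and a first-order solver
reaches it only asymptotically; the strict margin makes w = 0 exact. The
score of a feature is its maximum selection probability across λ; ranking
ties break to the lower index.

Traceback maps a ranked feature index through the layout to (section,
level, word), then scans the pool entries of that level for the descriptor
closest to the word's center (ties to the earliest pool entry) and reports
its source image, gene and patch location. Zero-bin features have no center
and return a typed no-center result. The pipeline traces only features with
positive selection probability: at desk scale a task may be separable with
a handful of words, and tracing a feature no subsample ever selected would
visualize noise. Overlays draw the patch outline on the image and a zoomed
panel with the 4×4 grid and one arrow per non-empty orientation bin, length
proportional to bin magnitude.

## Synthetic data: what it emulates, and what it does not

Each gene gets one image per section type ("coronal"/"sagittal": two
independent renderings sharing the gene's class texture but with different
elliptical masks — emulating complementary section planes). Inside the mask
all images carry an isotropic smoothed-noise base texture (sd 0.15);
enriched genes additionally carry a sinusoidal stripe texture
(amplitude 0.35, class-specific angle and frequency: astrocyte 0°/0.22,
neuron 60°/0.18, oligodendrocyte 120°/0.28 cycles/px) confined to a fixed
known quadrant, giving ranking traceback a planted ground truth. The signal
is carried by local gradient orientation, not global intensity, so it is
discoverable by SIFT but not by a mean-intensity classifier. Defaults:
5 genes per enriched class, 10 negatives, one image per gene per section,
128-px images, mask coverage 0.6, noise_sd 0, folds drawn uniformly on
(1.5, 30]. Uniform fold draws cannot *guarantee* that every threshold in
{1.5, 10, 20} has positives for every class at 5 genes/class; the coverage
property is asserted under a fixed seed.

What passing tests show: the implementation recovers a planted,
orientation-coded class signal end to end, conserves counts exactly, and
matches brute-force oracles on every quantitative primitive. What they do
not show: performance on real atlas imagery — real ISH images have
anatomical structure, registration error, staining variability and far
weaker class signal, so the AUC = 1.0 achieved on noise-free synthetic data
says nothing about absolute performance on real data, only that the
machinery is correct.

## Problem sizes

Desk-scale defaults were chosen so a full pipeline run (two tasks, two
representations, 30 repetitions, ranking with 100 subsamples) completes in
about two minutes on one CPU: 128-px images, 64 words per level
(32 combined) in the demo configuration. The acceptance script uses 256-px
images and 42 task images so that the coarsest pyramid level alone supplies
more than 500 descriptors for its full-size 500-word codebook, and caps
k-means input at 3000 points per level.

## Known limitations

- Grayscale only; no registration; no keypoint SIFT; no soft quantization,
  tf-idf or spatial-pyramid weighting (out of scope by design).
- Codebooks are fit per task on the pooled task images (standard
  bag-of-words practice here); features are therefore not shared across
  tasks.
- Stability-selection error control (per-family bounds) is not implemented;
  scores are used for ranking only.
- The two-section concatenated feature is 2008-dimensional, not equal in
  length to the 2004-dimensional single-section feature (see above).
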