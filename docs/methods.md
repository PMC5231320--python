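# Methods

This note documents the models, conventions and numerical choices behind
`ifcml`, in the spirit of a methods appendix: what each stage computes,
which knobs matter, and what the synthetic validation does and does not
demonstrate.

## Data model and container

A cell is a set of spatially registered 2-D grayscale frames, one per
channel (bright-field `BF`, dark-field/side-scatter `DF`, optional
others). In memory intensities are float64 in [0, 1]; on disk they are
16-bit unsigned (quantization scale 65535, declared in
`container.json`), which brackets the 12-bit dynamic range of typical
imaging cytometers with headroom. The container is deliberately plain —
one multi-page TIFF per cell plus a CSV manifest (`cell_id,file,label`)
— so that any image tool can read it; no proprietary formats are parsed.

Montage tiling packs cells row-major into square-ish grids
(`cols = ceil(√n)`, at most `tile_capacity` cells per tile, default
1000), because batch image tools process one large frame far faster than
thousands of tiny files. Within a tile, frames are centered in slots of
the tile's maximum frame size; each cell's original height/width and
offset are recorded in the slot table, so unpacking is pixel-exact by
construction (this is asserted as a property test). Bright-field frames
are padded with their border median (BF background is bright and
non-zero; zero padding would create artificial dark edges that corrupt
texture and edge-intensity features downstream); other channels pad with
zero. How variable frame sizes are reconciled inside a tile is not
standardized anywhere; centering plus recorded offsets is this package's
choice.

## Quality gating

Gates run in a fixed order — focus, then area, then aspect ratio — and a
rejected cell carries the first reason that failed
(`OUT_OF_FOCUS`, `DEBRIS`/`TOO_LARGE`, `CLUMP`).

**Focus.** The score is an illumination-normalized gradient RMS of the
BF frame: `sqrt(mean(Gx² + Gy²)) / mean(I)` with central differences
over interior pixels. Constant frames score 0 by convention. Commercial
gating software exposes a similarly named score without publishing its
formula; no equivalence is claimed beyond monotone agreement with
defocus (blurring strictly lowers the score, asserted in tests).

The threshold can be a number (analysts usually set it by eye on the
histogram), a fixed population percentile (`PERCENTILE` mode,
`auto_percentile` default 10), or `AUTO`: an Otsu split of the
population's scores, accepted only when the upper mode's mean is at
least 2× the lower mode's mean. The guard exists because defocus
attenuates the gradient RMS multiplicatively (a blur of σ ≈ 3 px roughly
halves it or worse) while in-focus texture differences between
phenotypes stay well under 2×; without it, any unimodal population
would be split in half. A fixed percentile was rejected as the default
because it mislabels by construction whenever the true defocused
fraction differs from the chosen percentile.

**Area and aspect.** Mask area below `area_min` (default 50 px²) is
debris, above `area_max` (default 2500 px²) oversized. The aspect ratio
is minor/major axis from the mask's second central moments; doublets of
round cells score ≈ 0.45, so `aspect_min = 0.6` separates them from
single round cells. Note the intrinsic trade-off: genuinely elongated
mitotic figures (metaphase plates, anaphase/telophase dumbbells) also
score low, so an aspect gate that removes doublets removes them too.
The package default is therefore a permissive `aspect_min = 0.15` (keeps
all phases); the strict 0.6 setting is appropriate for predominantly
round populations, which is also how the QC validation is run (an
interphase-only population with planted contaminants).

## Segmentation

Bright-field polarity is fixed by the container convention (cells darker
than background; a flag flips it for other instruments). The pipeline
is: invert, global Otsu threshold, morphological closing with a disk of
radius 2 (bridges telophase necks down to 1 px), fill holes, keep the
largest 8-connected component (ties broken by the top-most, left-most
pixel), and report EMPTY if nothing reaches `min_area` (default 9 px).
Otsu was chosen over adaptive thresholding because each frame contains a
single cell on a near-uniform background; the result is deterministic
and invariant to linear intensity rescaling. Equivalence with any
specific segmentation tool's masks is not claimed; fidelity is instead
asserted against the generator's ground-truth masks (IoU ≥ 0.9 across
all phases at default noise).

## Feature bank

Features follow the `{CHN}_{Family}_{Name}[_{image}][_{suffix}]` naming
convention with BF features prefixed `BF_` and dark-field features
`SSC_` (image tag `DF_image`). Shape features are computed once from
the mask; intensity, radial, granularity and texture features per
channel. Conventions that needed fixing:

* **Perimeter** is the boundary chain length from Moore-neighbor
  tracing, √2 per diagonal step. On rasterized circles this
  overestimates the true circumference by a few percent, which is why
  the compactness of a disk (P²/(4πA), circle-normalized to 1) is
  asserted in [1.0, 1.15] rather than at 1 exactly.
* **Axis lengths** are 4·√(eigenvalues) of the second-central-moment
  matrix (no pixel-extent correction); eccentricity √(1−(b/a)²).
* **MaxFeretDiameter** is the maximum pairwise distance between convex
  hull vertices taken at pixel centers, so a 40 × 20 rectangle gives
  exactly √(39² + 19²).
* **Zernike magnitudes** map the mask to the unit disk centered at the
  centroid with radius = farthest mask pixel, and are normalized by the
  number of grid points inside that disk so a solid disk yields
  Z₀₀ = 1. Orders run to n = 9 (30 values). The implementation uses
  the explicit factorial radial polynomial; tests cross-check it
  against an independent Jacobi-polynomial route.
* **Radial distribution** uses the normalized interior distance
  transform r = 1 − DT/DT_max rather than centroid rays, so rings are
  well defined for non-star-shaped dumbbells. RadialCV is the SD/mean
  of per-wedge **mean** intensities over 8 angular wedges (half-open
  modular binning so each wedge owns exactly one boundary ray).
  Count-normalization matters: wedge pixel counts in small inner rings
  fluctuate 10–30% from rasterization alone, so a CV of raw totals
  would report angular structure where there is none.
* **Granularity** background-corrects the masked image by subtracting
  its grayscale opening with a disk of radius `bg_radius` (default 10
  px), then reports g_k = 100·(S_{k−1} − S_k)/S₀ for opening radii
  k = 1…8, computed without downsampling (frames are small). Flat
  full-frame images give exactly zero; flat rasterized cells give
  near-zero (discrete openings shave a few boundary pixels of shapes
  that are not open w.r.t. the disk element).
* **InfoMeas2** quantizes masked pixels to 8 equal-width bins over the
  masked min–max range and accumulates a symmetric co-occurrence matrix
  over pixel pairs at offset (0, 3) — read as scale 3, direction 0° —
  with both pixels in-mask; the statistic is √(1 − e^(−2(HXY2 − HXY))),
  0 by convention for constant regions. It approaches its maximum
  √(1 − e^(−2·HX)) for perfectly dependent pairs and 0 for independent
  ones.

Orientation (and any location/center feature) is registered but flagged
excluded-by-default: positional features carry no phenotype information
and would let a classifier overfit plate layout.

## Imbalance-aware learning and evaluation

Cell-cycle populations are extremely imbalanced because class frequency
tracks phase duration — the default study conditions put 300 interphase
cells against 15 anaphase and 25 telophase cells. Training sets are
balanced by undersampling: classes above `cap` (default 100) are
subsampled to the cap without replacement (seeded); minority classes
keep every member. The cap value is a free parameter surfaced in
config.

Two learners are provided with fixed, surfaced defaults: gradient
boosting (300 stages, depth 3, learning rate 0.1, multiclass log-loss)
and random forests (500 bootstrapped trees, √p features per split).
Class order is fixed to [Int, Pro, Meta, Ana, Telo] everywhere,
including argmax tie-breaking.

Evaluation reports a row-normalized percentage confusion matrix — entry
(i, j) = 100·|true=i ∧ pred=j| / |true=i|, rows with no support left
blank and excluded from macro averages — whose diagonal is the
per-class true positive rate. Cross-validation is stratified 10-fold
with round-robin per-class fold assignment after a seeded shuffle, so a
class with fewer members than folds (anaphase at n = 15) contributes to
exactly as many folds as it has members. `score_all` predicts every
cell not in the training set, excluded by id. Because undersampling at
cap 100 places *all* minority-class members in the training set, the
held-out test set of the default population contains only interphase
cells; rare-class recovery is therefore read from the cross-validation
report, which is also the evaluation the protocol prescribes for the
training set.

Feature importances are the ensembles' impurity-based scores, ranked
descending with lexicographic tie-breaks.

## The synthetic population

The generator emulates the *statistical structure* of a label-free
cell-cycle experiment, not Jurkat-cell optics. Phases differ in exactly
the feature families that drive the real classification: size,
elongation, lobe count, and chromatin-condensation texture expressed as
dark-field granularity. Defaults (pixel units, frame 56 × 56, additive
sensor noise SD 0.01):

| phase | geometry | radius (px) | texture |
|---|---|---|---|
| Int | near-circular disk (e ≤ 0.25) | 8.0 ± 0.5 | smooth, low amplitude (grain 3.0, amp 0.05) |
| Pro | disk, same size | 8.0 ± 0.5 | fine strong speckle (grain 0.9, amp 0.30) |
| Meta | ellipse, e ∈ [0.88, 0.92] | 9.5 ± 0.5 | intermediate |
| Ana | dumbbell, lobe sep. 22, neck 5 | 7.0 ± 0.5 | intermediate |
| Telo | dumbbell, lobe sep. 30, neck 2 | 6.5 ± 0.5 | intermediate |

Bright-field renders a bright background (0.8) with a darker body
(0.45) carrying multiplicative speckle at half the nominal amplitude;
dark-field renders a flat baseline plus positive speckle whose grain
and amplitude track condensation, so prophase granularity g₁ clearly
exceeds interphase. Cell radii sit safely below the granularity
background-correction radius (10 px) — when the two are comparable, the
background opening alternates between removing and keeping the cell and
the spectrum becomes bistable. Contaminants (debris: disk < 3 px;
doublet: two touching interphase disks; defocus: Gaussian blur σ = 3)
replace exact counts `round(frac·n)`, assigned uniformly at random, so
tests can assert exact numbers. One seeded RNG stream drives
everything; identical configs give byte-identical containers.

These defaults were chosen so that every phase pair is separated by at
least 3 population SDs in at least one of {granularity g₁,
eccentricity, Feret diameter, |Z₂₂|} (asserted at n = 50/phase). That
is a *design property of the simulation*, and it is why the pipeline
recovers phases essentially perfectly on synthetic data. Passing these
tests demonstrates that the plumbing, features, imbalance handling and
evaluation are correct — not that real Jurkat phases are this
separable; published confusion matrices on instrument data show
substantially lower prophase/metaphase rates. The generator also omits
optical point-spread realism, fluorescence channels (ground-truth
labels are emitted directly, standing in for marker-based gating), and
any claim about actual Jurkat morphology parameters.

## Problem sizes

Default validation scales were chosen to keep a full run on one CPU in
the minutes range: a 394-cell default population (≈ 96 features × 394
cells, ~30 s end-to-end including 10-fold cross-validation), 200-cell
QC populations, and 80-cell fixtures for feature-selection checks. All
stages scale linearly in cell count and are embarrassingly parallel
over cells if larger studies need it.

## Known limitations

* Single-object segmentation only: one primary mask per frame; no
  multi-object or fluorescence-seeded segmentation.
* The Haralick set is limited to InfoMeas2 (the one texture feature the
  classification workflow ranks); no bit-compatibility with any
  specific feature-extraction tool is claimed anywhere.
* The AUTO focus gate assumes defocus at least halves the gradient-RMS
  score; milder defocus requires a manual threshold.
* RUS-style boosted undersampling is not implemented; imbalance is
  handled by training-set undersampling only.
* Aspect-ratio gating cannot distinguish elongated mitotic figures from
  doublets (see Quality gating); gate strictness must match the
  population being gated.
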