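# Methods

This note documents the models, parameter choices and numerical conventions
behind `leukoseg`, and what the synthetic-scene experiments do and do not
demonstrate.

## Segmentation model

Segmentation is purely rule-based on raw 8-bit RGB values; there is nothing
learned in this stage. The three region rules are evaluated per pixel with
strict inequalities:

* background: all three channels `> threshold_1`;
* erythrocyte: blue `< threshold_2` **or** red `>` blue;
* leukocyte: the complement of both.

The background and erythrocyte rules are not mutually exclusive — a bright
pixel whose red exceeds its blue satisfies both — so the three raw masks are
exhaustive but only the leukocyte mask is guaranteed disjoint from the other
two. Where a strict partition is needed (display, region statistics),
`region_partition` applies the precedence background → erythrocyte →
leukocyte.

**Thresholds.** Defaults are `threshold_1 = 182` and `threshold_2 = 150`,
the dataset-level values for this kind of stained-smear imagery. In
`mode="otsu"` both are recomputed per image by exhaustive maximization of
between-class variance over all 256 candidate cuts, `threshold_1` from the
rounded Rec.601 luminance histogram and `threshold_2` from the blue-channel
histogram (the blue channel is what the erythrocyte rule thresholds). On a
plateau of maximizers the smallest is returned, deterministically. A
single-intensity histogram returns that intensity with a warning rather than
erroring mid-pipeline; an empty histogram is an error.

**Morphology.** Dilation, erosion and opening are implemented from their
set definitions as vectorized shift-OR / shift-AND over the structuring
element's offsets. Outside-image pixels count as false for both the erosion
containment test and the dilation overlap test, so erosion shrinks at the
border and dilation never invents pixels there. The default noise-removal
element is a disk of radius 5, large enough to erase the isolated
leukocyte-colored specks the scene generator plants and small enough to
leave a 35-pixel-radius cell essentially intact; it is configurable
(`--se-radius`). scipy's binary morphology is used only as an independent
cross-check in the test suite.

**Component selection and cropping.** Connected components use
8-connectivity. The component with the most pixels wins; ties break toward
the component whose bounding-box corner `(row_min, col_min)` is smallest in
row-major order, making the result deterministic. Boxes are 0-based and
half-open. The crop is a fixed `128x128` window centered on the box center,
clamped to the image; images smaller than the window are padded with gray
200 — a value that satisfies the background rule at the default threshold,
so padding can never introduce leukocyte pixels.

## Augmentation

Five operations: horizontal/vertical flip, brightness shift (default
±40 intensity units), contrast scaling about mid-gray 127.5 (default
[0.7, 1.3]), rotation (±20°) and horizontal shear (±0.2), applied in the
order flips → rotation → shear → contrast → brightness. Geometric warps use
nearest-neighbor sampling about the image center with out-of-frame pixels
filled with background gray, which keeps outputs exact uint8 images and
makes 90°/180° rotations exact pixel permutations (testable bit-for-bit).
Bilinear sampling was deliberately not made the default: it blurs the
sharply quantized synthetic colors across region boundaries, and exactness
is worth more here than smoothness. Ranges were chosen mild enough that the
centered cell stays in frame. Each source image gets an independent
`SeedSequence`-spawned stream, so the augmented dataset is a pure function
of `(dataset, config)` and is unchanged by processing order.

By default augmentation runs after the train/test split and only on the
training share, preventing near-duplicates of one image from appearing on
both sides of the boundary; `augment_before_split=True` restores the
augment-first ordering for users who want it.

## Classifier

The four-block topology is fixed: block 1 has 3 convolutions (32 filters),
2 batch-norms, 2 ReLUs, dropout and the only 2×2 max-pool; block 2 mirrors
it at 64 filters without pooling; block 3 has 2 convolutions at 128 filters
with 2 batch-norms and 2 ReLUs; block 4 has 3 convolutions, 2 batch-norms,
2 ReLUs and dropout. The blocks carry three dropout layers; the fourth sits
in the head after global average pooling, giving the census 11 conv / 8 BN /
8 ReLU / 4 dropout. Convolutions are 3×3, valid (no padding), stride 1;
pooling has stride 2. Global average pooling makes the head independent of
spatial size, so the same topology accepts any sufficiently large input.
The hidden dense layer (default width 64) carries no activation — all eight
ReLUs live in the blocks — and feeds the 4-way softmax output. Block-4
filter count defaults to 128 (monotone progression) and the dropout rate to
0.25; both are configurable.

Training minimizes categorical cross-entropy with Adam (default learning
rate 1e-3, betas 0.9/0.999), batch size 32, 12 epochs. Weight init is
He-normal. Everything — shuffling, dropout masks, initialization — draws
from explicitly seeded numpy generators, so a run is a pure function of
(data, architecture seed, training seed) up to the determinism of the BLAS
in use.

**Batch-norm calibration.** Twelve epochs at a few hundred images means
only ~100 optimizer steps, far too few for exponential moving averages
(momentum 0.9) of the batch statistics to converge; stale averages can
collapse inference-mode accuracy to chance while training-mode accuracy is
high. After training (and before each recorded validation point) the
running statistics are therefore recomputed by streaming the training set
through the network with batch statistics and dropout disabled, and storing
the averaged batch moments. This is a standard recalibration and is part of
the documented determinism contract.

**Parameter accounting** follows the closed forms: convolution
`(k·k·c_in + 1)·c_out`, dense `(n_in + 1)·n_out`, batch-norm `2C` trainable
(scale, shift) plus `2C` non-trainable (running mean, variance). The default
architecture totals 787,268 parameters (785,860 trainable + 1,408
non-trainable); these totals follow mechanically from the stated block
widths and are verified against the closed forms in the tests rather than
asserted as constants.

## Evaluation

Confusion matrices are rows = truth, columns = prediction, class order
(NE, EO, LM, MN). Per-class metrics are one-vs-rest; any 0/0 ratio is
reported as `None` with a warning, never silently coerced to 0, and macro
averages skip undefined entries (coercion would bias macro-averages
downward exactly when a class is absent). Accuracy is `trace/total`.
Cohen's kappa uses `PO = trace/total` and
`PE = Σ_c (row_c/total)(col_c/total)`; `PE = 1` (all mass in one
row-column pair) makes kappa undefined and is reported as an explicit
error (or `None` inside the aggregate report).

## Synthetic scenes

`generate_scene` renders a gray background (all channels uniform in
[190, 230]), `n_erythrocytes = 10` brown ellipses
(R [180, 220], G [120, 160], B [110, 145]) and exactly one leukocyte
ellipse (cytoplasm R [118, 140], G [88, 110], B [188, 210]; nucleus
R [100, 120], G [60, 80], B [160, 180]) at 256×192 by default. Every range
sits ≥ 5 intensity units inside its rule's decision region, so rounding can
never flip a pixel's region. The leukocyte radius is drawn from 0.18–0.28
of the scene's short side (≈ 35–54 px at default size) with erythrocytes
roughly half that — the proportions of a close-up smear field, where the
white cell dominates the frame. Erythrocytes are rejected from a clearance
zone around the leukocyte, matching the pipeline's one-dominant-cell
assumption. `noise_fraction` (default 0.01) of the non-leukocyte pixels are
flipped to isolated leukocyte-colored singletons to exercise opening;
ground-truth masks never include noise pixels.

Classes differ only by nucleus morphology: neutrophils 3–5 small dark lobes
on a ring (lobe geometry chosen so lobes cannot touch), eosinophils 2
larger lobes plus a bright granule speckle over 10% of the cytoplasm,
lymphocytes one round nucleus covering ~72% of the blob, monocytes one
kidney-shaped nucleus (disk minus an offset bite). A deliberately crude
baseline — counting 8-connected components of pixels with green below 85 —
separates lymphocytes from neutrophils almost perfectly, demonstrating the
signal is present before any learning happens.

**What this does and does not show.** The generator reproduces the
three-region color structure, the one-cell-per-frame composition, salt
noise, and class-specific nucleus shape. It does not model staining
variation, cell overlap, out-of-focus blur, uneven illumination, or the
intra-class diversity of real smears; colors are piecewise-uniform rather
than textured. Passing the end-to-end test therefore shows the pipeline's
stages compose correctly and the classifier can learn shape/texture
distinctions of this kind — it does not certify real-smear accuracy, which
must be measured on real data.

## Problem sizes

The test suite and acceptance script run desk-scale versions of every
experiment: oracle comparisons on 8×8–16×16 rasters (where exhaustive
per-pixel and flood-fill evaluation is feasible), 50 scenes for
segmentation IoU, and 400 scenes (100 per class) for the end-to-end
learnability run. For that run the `compact()` architecture variant is
used: identical four-block topology and layer census, filter widths
8/16/32/32, hidden width 32, and crops resized 128→48 before the network.
At these widths the synthetic task trains to ≥ 0.95 held-out accuracy
within the standard 12 epochs on a single CPU core in about two minutes;
the full-width 128-input architecture is exercised structurally (census,
parameter closed forms, forward-pass shape and softmax normalization) in
the same suite. Full-width training on real data is supported through the
same `train` API and the CLI, just slower.

## Known limitations

* The erythrocyte rule `(B < t2) | (R > B)` classifies *any* pixel with red
  above blue as erythrocyte, including bright background-like pixels; the
  pipeline is insensitive to this because the leukocyte mask only needs the
  complement, but the raw erythrocyte mask over-counts on bright images.
* One leukocyte per image by construction: the largest-component rule
  silently discards additional white cells.
* Nearest-neighbor warps alias at large rotation angles; acceptable for
  augmentation, not for measurement.
* The numpy network is CPU-bound and single-threaded apart from BLAS; it is
  a reference implementation for reproducibility, not a performance target.
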