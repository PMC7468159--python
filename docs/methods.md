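# Methods

`gliamorph` reconstructs, as tested and reusable code, a quantile-based
glial-morphometry workflow: somata of immunolabelled microglia or astrocytes
are located as bright connected regions of a fluorescence micrograph,
processes are traced outward from each soma, eight morphological parameters
are extracted per cell, genotype groups are compared with normality-gated
two-sample tests, and Western-blot band densities are normalized to a
loading control. Because no raw images accompany the published group values,
validation rests on a synthetic field generator whose ground truth is exact
by construction.

## Synthetic fields and their ground truth

A field stands for one 20x confocal field of one channel: a 424 um x 424 um
square (0.1800 mm^2), by default 1024 x 1024 px at 0.415 um/px. Each cell is
an elliptical soma (semi-axes `a >= b`) plus a tree of straight process
segments: every primary branch leaves the soma boundary at a set direction
and may bifurcate up to twice (a node with two daughters is a branch point;
a single daughter is a kink). Rendering paints the soma and constant-width
process ribbons at three intensity levels (background < process < soma),
convolves with an isotropic Gaussian point-spread function, adds white
Gaussian noise and clips at zero. Defaults: process width 1.5 um, background
200, process 1200, soma 3000 arbitrary units, PSF sigma 0.3 um.

Every reported quantity has a closed form on the specification, never on the
raster: soma area `pi*a*b`; soma eccentricity `sqrt(1 - (b/a)^2)`; total
branch length the sum of segment lengths; branch points the number of
bifurcation vertices; cell radius the furthest process vertex from the soma
centre; cell area approximated as soma area plus ribbon area. Ground truth
is therefore invariant to the seed and to the noise level.

Regime defaults follow the published hippocampal ranges: soma area
~48-57 um^2, eccentricity 0.79-0.87, 4-6 primary branches, 3-6 branch
points, total branch length ~97-204 um, 4-14 cells per field. The default
mutant effect scales total branch length by 96.8/167 ~ 0.58 and branch
points by 2.87/5.84 ~ 0.49, the published dentate-gyrus astrocyte
reduction; density effects are expressed by scaling the cells-per-field
range. The "moderate noise" condition used in validation sets the noise
sigma to one fifth of the process contrast (SNR 5).

The sampler keeps every segment longer than ~5 um (so genuine terminal
branches sit far above the spur-pruning length), keeps non-adjacent segments
of one cell at least ~2.5 um apart (so distinct processes never merge in the
raster), and places cells on a jittered grid so bounding discs never
overlap. Two things real tissue has that these fields deliberately lack:
overlapping/abutting cells and structured background (out-of-focus light,
uneven illumination). Passing recovery tests therefore demonstrates the
correctness of the measurement chain, not robustness to crowded or uneven
real micrographs. A consequence of strict non-overlap is a packing limit:
~16 full-size astrocytes fit in one field, so very high planted densities
require shorter-reach cells.

## Segmentation

Thresholds are empirical intensity quantiles of the whole image (linear
interpolation convention). Two modes exist:

* **quantile** (explicit): soma and background cuts at configured fractions
  (defaults 0.995 and 0.90). A fixed quantile is only correct when the soma
  pixel fraction happens to match it, which is why the original workflow
  adjusted these levels manually per sample.
* **auto** (default in the pipeline): a per-image stand-in for that manual
  adjustment. The background cut is the triangle threshold of the intensity
  histogram -- appropriate when signal occupies a small fraction of the
  field -- and the soma cut is Otsu's threshold restricted to foreground
  pixels, separating the process class from the soma class. Both cuts are
  reported with their equivalent quantile levels.

Somata are 8-connected components at or above the soma cut with at least
`min_size_px` pixels (default 150; the conventional range is 100-200 px and
values outside it warn). Components are labelled in raster-scan order;
border-touching components are flagged, counted in density by default and
excluded from morphology means (both switchable). Soma shape comes from the
second-central-moment ellipse; eccentricity is `sqrt(1 - minor^2/major^2)`,
0 for a disc, and a degenerate (<2 px) region is flagged with eccentricity 0.
A constant image yields coinciding cuts, is flagged, and produces no somata.

The foreground mask is everything at or above the background cut, a superset
of the soma mask. Before tracing, the pipeline smooths the image slightly
(Gaussian, 0.8 px) ahead of thresholding and cleans the mask: one binary
opening (cross element), removal of components under 25 px, filling of holes
under 25 px. Each step targets a specific noise artifact -- boundary bumps
that become skeleton spurs, speckle islands that become orphan fragments,
pinholes that open loops and hence phantom branch points. On noiseless
fields the speckle/hole passes are no-ops and the opening only shaves
isolated anti-aliased corner pixels. These defaults presume process ribbons
at least ~3 px wide; at coarser pixel sizes the opening should be disabled.

## Process tracing and the eight parameters

The cleaned foreground is topologically skeletonized (Zhang thinning).
Every mask pixel is assigned to the soma it reaches through the mask
(multi-source breadth-first search seeded at the soma regions -- geodesic
connectivity); foreground components containing no soma are ignored, and a
component containing several somata is split at the geodesic midline with
all involved cells flagged ambiguous rather than silently attributed.

Skeleton pixels outside the soma region form a weighted pixel graph: unit
steps cost `pixel_size`, diagonal steps `sqrt(2)*pixel_size`, and a diagonal
edge is dropped when its two pixels share a 4-connected skeleton neighbour
(staircase corners are not double-counted). Terminal paths shorter than the
pruning length (default 2 um) are removed iteratively until no short
endpoint-terminated path remains; anchors -- skeleton pixels touching the
soma region -- are protected terminals, so pruning can never delete a
genuine primary branch longer than the pruning length.

* **Primary branches**: clusters of anchor pixels that carry at least one
  edge into the skeleton (distinct crossings of the soma boundary).
* **Branch points**: clusters of skeleton pixels of degree >= 3, outside
  the soma.
* **Total branch length**: sum of edge weights, excluding any intrasomatic
  skeleton. The 8-connected chain length overestimates true Euclidean length
  by up to ~8% at unfavourable angles (zero at multiples of 45 degrees),
  which dominates the ~10% accuracy of length recovery.
* **Cell radius**: furthest skeleton point from the soma centroid. The
  published workflow does not define this quantity; a hull-style alternative
  (furthest assigned foreground pixel) is available as `radius_from: mask`.
  A process-free cell reports its soma's own radius and is flagged.
* **Cell area**: `pixel_size^2` times the foreground pixels assigned to the
  cell (soma plus processes), not a convex hull -- published astrocyte areas
  of ~170-310 um^2 against 23-39 um radii are only consistent with the mask
  reading.
* **Soma area / eccentricity**: from the detection.
* **Cell density**: somata per mm^2 of field, an exact quotient at field
  level.

On synthetic fields at the published regimes (ten non-overlapping cells,
zero noise and SNR 5), detection and branch/junction counts recover ground
truth exactly, total length within 10%, cell radius within 5% and soma
eccentricity within 0.03. Thinning is not exactly symmetric under 90-degree
image rotation, so skeleton length is invariant under quarter turns only to
well under 1% (and under arbitrary rotations to ~5%, the raster tolerance).

## Statistics

The protocol reproduces the study design with the animal as the sampling
unit (per-animal means over cells; no mixed-effects modelling of cells
within animals):

* **Normality screen**: Kolmogorov-Smirnov distance against a normal with
  mean and SD estimated from the sample; p from the Dallal-Wilkinson
  approximation for the Lilliefors correction (rescaled above n = 100,
  clipped to [0, 1]; the formula was fitted for p <= 0.10, so mid-range
  values are indicative only -- immaterial for gating at alpha = 0.05, where
  the simulated type-I error is 0.05 +/- 0.005). Zero-variance samples are
  declared non-normal and flagged. Groups with n < 4 cannot be screened and
  fall back to the t-test with a warning.
* **Student's t**: two-tailed, unpaired, pooled variance, df = n1 + n2 - 2
  (Welch available behind `use_welch`, never the default, since the
  reconstructed protocol specifies Student's test). Zero pooled variance
  with equal means gives p = 1; with unequal means it is an error.
* **Mann-Whitney U**: used whenever either group fails the screen. For
  pooled n <= 12 the two-tailed p is exact by full enumeration of the
  C(n, n1) group assignments (ties handled exactly); beyond that, the normal
  approximation with tie correction. The cut-off keeps the exact branch
  instantaneous (<= 924 assignments) while covering the study's 5v5 and 6v6
  designs.
* **Summary t-test**: `t = (m1 - m2)/sqrt(sem1^2 + sem2^2)` on printed
  mean +/- SEM rows; identical to the sample-level pooled t for balanced
  groups. Recomputing the published dentate-gyrus rows gives p = 0.0077 for
  astrocyte branch length (printed 0.007), p = 0.0058 for astrocyte cell
  area (printed 0.005) and p = 0.022 for microglial density (printed 0.018
  from raw data; one-digit SEM rounding fully accounts for the gap, so this
  recomputation is reported as a cross-check, not asserted as equal).
* **No multiplicity correction** anywhere, matching the reconstructed
  protocol; across ~8 parameters x 2 regions the family-wise error at
  alpha = 0.05 is ~0.56 under the global null, and reports say so.

**Densitometry**: per lane, target intensity / beta-actin intensity; per
blot (and target/region), percentages of the wild-type mean ratio, making
the WT group mean exactly 100 by construction; genotypes compared with the
pooled t-test on percentages. Missing or non-positive actin lanes and blots
without a WT lane are errors naming the offender.

## Numerical and design choices

* Quantile convention: linear interpolation (the original method's
  convention is unknown; this one is stated and tested).
* Connectivity: 8-connectivity for components and skeletons; tie-breaks in
  the geodesic assignment go to the lower soma label, deterministically.
* Per-image thresholding (not per-batch); the original's batching is
  unstated.
* Intrasomatic skeleton is excluded from branch length; whether the original
  included it is unstated.
* Spur pruning default 2 um, logged in every report; increasing it can only
  remove branch points and length (tested monotonicity).
* Determinism: a fixed seed makes simulated images bit-identical, and all
  outputs embed a configuration hash; re-running measurement or comparison
  on the same inputs is byte-identical.

## Problem sizes used in validation

Recovery runs use one 1024^2 field with 10 cells per condition; calibration
uses 2000 normality simulations (n = 25) and 1000 null group comparisons
(5 vs 5); the rendered group study uses 2 genotypes x 5 animals x 1 field;
densitometry recovery uses 200 simulated blots (6 + 6 lanes). These sizes
give Monte-Carlo errors comfortably below the tolerances they are tested
against.

## Known limitations

* 2-D only; no z-stacks, no multi-channel co-localization.
* No illumination-field correction or deconvolution; fields with strong
  background gradients would need flattening upstream.
* The non-overlap constraint caps plantable density; real tissue shows
  touching cells, which the splitter flags rather than resolves.
* Eight published parameters only -- no Sholl analysis or fractal measures.
* The Dallal-Wilkinson p is an approximation; decisions at conventional
  alpha levels are well calibrated, but mid-range p-values should not be
  over-interpreted.
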