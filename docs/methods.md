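# Methods

This note documents the models and procedures behind `wingmorph`, their
assumptions, the parameters that matter, and the numerical choices made
where the design was genuinely open.

## Conventions

Images are 8-bit grayscale grids indexed `(row, col)`, 0-based, origin
top-left; a pixel occupies 1 px^2 and continuous coordinates (polygon
vertices, true trichome centers) refer to pixel centers. RGB input is
converted with ITU-R 601 luminance weights (0.299, 0.587, 0.114), the
convention 8-bit microscopy software inherits; >8-bit input is linearly
min-max rescaled per image. Resizing is bilinear with a Gaussian prefilter
when downscaling (plain bilinear subsampling would alias the trichome
texture away at the 4x shrink to working resolution); resizing to the
source size is the identity.

## Trichome detection

Trichome bases are slightly darker than the surrounding blade, so
detection runs on the photometric inverse `255 - v`, where bases become
local maxima. The detector is the classic noise-tolerance ("prominence")
maxima criterion:

* **Candidate**: a maximal 8-connected set of equal-valued pixels, none of
  which has a strictly greater 8-neighbor.
* **Acceptance**: a candidate of value *v* is accepted at tolerance *t* iff
  every 8-connected path to any strictly higher pixel passes through a
  pixel of value <= *v - t*.
* **Merging**: equal-valued candidates mutually reachable through pixels of
  value > *v - t* emit one point (the one with the smallest rounded
  centroid in row-major order).
* **Emission**: each accepted plateau emits its pixel centroid rounded to
  the nearest pixel, exact halves rounding toward the smaller row/col;
  output is sorted by (row, col).
* **Border rule**: a global-maximum plateau touching the image border is
  suppressed. A flat field contains no identifiable spot, so a constant
  image yields zero points; interior peaks and ordinary border-adjacent
  maxima are unaffected.

The implementation is a union-find sweep over pixels in decreasing
intensity (ties in raster-scan order): when the component containing a
candidate first touches a component holding a strictly higher value, the
touch level is exactly the candidate's best saddle, which decides
acceptance. This is O(n alpha(n)) and wholly integer/comparison based —
identical inputs give identical outputs on every platform. The test suite
holds it to *exact* agreement with an independently written brute-force
path-search oracle on random images across tolerances, including 0.

The working tolerance default is 10 on the 8-bit scale, the empirical
operating point for wing micrographs shot at maximum condenser contrast;
it is exposed everywhere (`noise_tolerance`).

ROI counting always detects on the full image and then filters points by
the ROI: detection on a crop would change tolerance comparisons near the
crop border and make counts depend on the selection.

## ROI geometry and density

A square ROI of side *s* is centered on the click; an even side extends one
extra pixel down/right. Polygon area is the shoelace formula on continuous
vertices; simplicity is validated (via shapely) and the shoelace value is
cross-checked against an independent exact computation in the tests.
Point-in-polygon uses the even-odd rule with boundary points counted as
inside. Density is defined as trichomes per px^2 of subtended area — the
only dimensionally coherent reading of "density per pixel" — so
`density * area_px2 == count` holds exactly, and doubling the image
resolution quarters the density (counts invariant, area x4).

## Spacing cells (segmented particles)

The spacing heat map needs one cell per trichome. Seeds are the accepted
maxima; the inverted image is flooded in decreasing intensity with a
*level-synchronous* rule: all queued pixels at the current level are
decided simultaneously from the pre-wave state; a pixel 4-adjacent to
exactly one basin joins it, and a pixel claimed by two basins (or adjacent
only to boundary) becomes boundary (label 0). Synchronous waves were chosen
over the usual sequential priority flood deliberately: sequential
tie-breaking hands contested plateau pixels to whichever basin is visited
first, which breaks image symmetries — with the synchronous rule a
mirror-symmetric image yields a mirror-symmetric partition with exactly
equal cell areas. One consequence: two basins meeting simultaneously at
equal level can be directly adjacent with no boundary pixel between them;
cells plus boundary still tile the image exactly, each cell is 4-connected
and contains exactly one seed. A test cross-checks cell counts and >95%
label agreement against an independent library watershed on smooth images.

## Vein segmentation

The classifier works at a fixed 512 x 380 working resolution (segmentation
needs vein-scale context, not trichome-scale detail, and the fixed size
makes models portable across capture resolutions). Each pixel gets 15
features: raw intensity; Gaussian smooths at sigma 1, 2, 4, 8, 16;
gradient magnitude at sigma 1, 2, 4; differences of Gaussians (1,4) and
(2,8); and the larger/smaller Hessian eigenvalues at sigma 2 and 4 (veins
are dark elongated ridges, which the Hessian spectrum captures). All
filters use reflective boundaries so a constant image has exactly zero
derivative features.

Three classes — vein+margin, intervein, background — rather than two,
because blade and slide are both pale: border-touching background must
remain distinguishable from intervein tissue. The forest is 100 trees,
bootstrap sampling, sqrt(15) candidate features per split, deterministic
given its seed; it needs >= 50 labeled pixels per class and must reproduce
>= 95% of its own training labels (a model that cannot memorize 600
scribbles will not segment anything). Prediction is per-tree argmax with
majority vote, ties to the first class in (vein, intervein, background)
order, executed from the package's own serialized node tables so that a
model loaded from its JSON file is bit-identical to the in-session one.
The predicted map is despeckled once with a 3 x 3 modal filter.

Particle analysis takes the 4-connected components of the intervein class
and applies three *per-component predicates*: hole-filled mask, filled
area >= 200 px at working resolution, and no contact with the image border
(border-touching intervein is background leaking through the margin).
Because the predicates are evaluated per component, no filter ordering can
change the outcome. The 200 px minimum is small enough that the smallest
genuine region (a marginal-cell analog, ~1400 px at working resolution on
synthetic wings) survives with an order-of-magnitude margin while
speckle does not. Survivors are labeled 1..k by decreasing area; masks are
upscaled to the source resolution by nearest neighbor (interpolation would
create phantom labels), where region area and trichome counts are
measured.

## Heat maps

Region/cell values are normalized as `(v - value_min) / (value_max -
value_min)`, clamped to [0, 1], and mapped through a fire-like ramp (black
-> blue -> red -> orange -> yellow -> white) that is monotone in perceived
lightness, so "hotter is larger" reads correctly in grayscale too. The
range defaults to the per-image observed min/max (zero-configuration);
pinning `value_min`/`value_max` puts several genotypes on one scale. The
legend labels the exact range endpoints. Rendering is a pure function of
(values, spec): re-rendering is bit-identical.

## Synthetic wings

The generator emulates a transmitted-light micrograph at 2080 x 1544: pale
slide (240), slightly darker blade (225), dark veins and margin (120),
smoothed with a sigma-2 Gaussian (optics blur). The blade is an ellipse;
five longitudinal veins fan from a hinge to the margin and two cross veins
connect neighbors, partitioning the blade into 7 intervein regions at the
default dimensions (the geometry is fixed; the seed drives everything
stochastic). The posterior compartment is the set of regions whose
centroid lies below the blade midline; `rate_ratio` scales its trichome
rate, emulating a posterior-driver transgene.

Trichomes are placed by a jittered triangular lattice — a hard-core,
quasi-regular point process matching the appearance of the real trichome
array — with spacing chosen to realize the requested rate (default
0.0115/px^2, ~65 trichomes per 75 px square). The lattice rate is boosted
by area/eroded-area (capped at 1.25) so that realized counts match
rate x full region area even though bases keep 9 px clear of veins; the
cap keeps slim regions from ever violating the hard-core spacing. Each
base is a Gaussian-profile dark blob (diameter ~5 px, contrast 28-42) with
a short brighter shaft; the inverted-image prominence of a normal trichome
is therefore ~28-42, comfortably above tolerance 10. The two failure
classes: a stated fraction of trichomes (default 2%) gets a duplicate at a
sub-diameter offset — the two blobs merge into a single maximum, so the
pair counts once, exactly like coincident dorsal/ventral trichomes — and a
stated fraction (default 3%) is rendered at half diameter with contrast
8-14, straddling the tolerance so roughly half are missed. Gaussian pixel
noise (default sigma 4) and dark dirt specks are added last. All draws
come from one seeded generator: a (params, seed) pair is bit-reproducible.

What the generator does **not** emulate: defocus and illumination
gradients, mounting artifacts (folds, bubbles), dust on the optics, and
real vein corrugation. Passing tests therefore validate the pipeline for
the geometry and contrast regime of well-prepared slides, not for every
pathology of a bad prep.

A property of the noise model worth knowing: additive sigma-4 noise on the
open blade creates occasional spurious maxima at tolerance 10 at a roughly
constant rate per open px. In a *sparse* compartment there is more open
blade per true trichome, so false positives inflate its measured density
proportionally more, biasing density *ratios* toward 1 (a ratio generated
at 0.5 measures ~0.56 at sigma 4 and 0.50 clean). The density-ratio
recovery experiment is therefore run on clean renderings, isolating the
measurement chain; detector behavior under noise and failure classes is
audited separately by the accuracy-envelope protocol. For real images the
lesson is the paper-trail one: compare compartments at matched focus and
contrast, and treat densities measured near the noise floor with care.

## Detection audit protocol

`evaluate_detection` matches predictions to ground truth greedily in
increasing distance order (each point used at most once) within a 4 px
radius. The audit protocol generates three wings at the failure-class
conditions (2% coincident, 3% small-faint, noise sigma 4, no dirt), takes
five 75 px squares per wing — each centered at the deepest interior point
of one of the five largest intervein regions, so squares never overlap —
and pools matched/missed over the ground truth inside the squares
(~1,100 trichomes). Typical results: ~96-97% counted, ~3-4% missed, with
the misses almost entirely the planted failure classes (one member of each
merged coincident pair; the faint half of the small-faint class).

## Problem sizes

Tests and the acceptance script run the full protocol at the native
2080 x 1544 scale (a wing carries ~20,000 trichomes); structural unit
tests use 544 x 400 wings, which render the same trichome/vein scale over
a smaller field. The detector's union-find sweep and the watershed flood
are numba kernels, so a full-scale wing takes a few seconds end to end.

## Known limitations

* No sub-pixel localization and no trichome shape/orientation analysis;
  detections are pixel-centroid points.
* The classifier is texture/intensity based; it has no notion of wing
  anatomy and will not name regions (users identify "the third posterior
  cell" by position in the region table).
* Heat-map colors reproduce orderings, not any specific historical lookup
  table.
* The generator's vein layout is one fixed topology; it does not model
  vein-patterning mutants.
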