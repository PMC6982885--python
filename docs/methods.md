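# Methods

## Pipeline overview

One "line" (cultivar) is one board: up to 100 seeds in 4 rows of 25,
imaged once from the top and once per row from the side. Processing per
board:

1. **Tag cropping.** The scale tag and color tag are cut out at
   operator-supplied pixel boxes (0-based, half-open) and their regions
   refilled with the median border color. Supplying boxes in the run
   configuration mirrors the manual region selection of an interactive
   workflow and keeps runs reproducible; automatic tag detection is out
   of scope.
2. **Scale calibration.** The scale tag sub-image is Otsu-thresholded;
   the largest dark component's axis-aligned extents are averaged into
   the tag side in pixels, and `mm_per_pixel = tag_mm / side`
   (default tag 16 mm). Extents differing by more than 10% indicate a
   mis-cropped tag and raise a calibration error.
3. **Color correction (optional).** The color tag is a horizontal strip
   of patches with known reference RGB. Patch means (central half of
   each patch, after trimming surrounding background) are regressed per
   channel onto the reference with a least-squares affine map
   (gain + offset). Affine is the smallest model a ≥2-patch tag
   identifies; a gamma term would need more patches than the tag
   carries. The fit is exact under a synthetic global gain in
   [0.7, 1.3] provided no patch clips at 255.
4. **Segmentation.** RGB is split into red, green, blue and Rec. 601
   luma; by default the channel with the largest Otsu between-class
   variance is thresholded (most separable foreground/background), with
   fixed thresholds available for reproduction. Foreground polarity
   defaults to the minority class. Components are 8-connected;
   components with area < 100 px (strictly) are discarded as noise —
   smaller than any seed at the working resolution of 0.1 mm/px.
   Survivors are sorted into board order: centroid-y values are split
   into rows at up to `n_rows − 1` gaps wider than 0.8× the mean region
   height (the height gate keeps partially filled boards from having
   real rows fragmented), then by centroid x within rows.
5. **Morphometry.** See below.
6. **Top/side matching.** Side views carry one row each; profiles
   sorted by centroid x pair index-for-index with the row's top-view
   seeds. Any per-row count mismatch aborts that board with an error
   naming the rows, rather than silently mis-assigning thickness.
7. **Color analysis and classification.** See below.

## Shape descriptors

Let *A* = pixel count of the region, *P* = length of its outline, and
(*a*, *b*) the major/minor axis lengths of the ellipse sharing the
region's second central moments (orientation-free, so a seed's length
and breadth do not depend on how it lies on the board; the axis-aligned
bounding box would not have this property).

* circularity = 4πA/P², roundness = 4A/(πa²), aspect ratio = a/b,
  solidity = outline area / convex-hull area.
* **Outline and perimeter.** The outline is the marching-squares
  contour at level 0.5, smoothed with a circular Gaussian (σ = 2
  vertices). The raw contour zigzags along the pixel lattice and
  overestimates smooth perimeters by ~6%, which deflates a rasterized
  disk's circularity to ≈0.89 and its polygon/hull solidity to ≈0.989;
  after smoothing, a disk measures circularity 0.998 and solidity
  0.999, and a 42 × 30 px digital ellipse's perimeter lands within 0.1%
  of its Ramanujan approximation. σ = 2 was fixed a priori from the
  geometry: it suppresses single-pixel staircase steps while a 1 mm
  bite (~20 contour vertices at 0.1 mm/px) is essentially untouched.
  Hull area is computed on the smoothed polygon in continuous
  coordinates; the rasterized convex image was rejected because it
  biases a disk's solidity to 0.987.
* Circularity and roundness are clipped at 1.0 (discretization can push
  a near-perfect disk marginally over).
* Thickness is the vertical pixel extent of the side-view profile times
  the scale; the profile's horizontal extent is redundant with the
  top-view length and is ignored.
* Regions whose fitted minor axis is under 2 px are rejected as
  degenerate rather than measured.

## Classification

* Roundness: elongated for 0.4 ≤ r ≤ 0.5, round for r ≥ 0.8, typical
  otherwise (the un-named middle band gets the neutral label).
* Defective: solidity < 0.97, strict (0.97 exactly is sound). Smooth
  convex seeds measure ≥ 0.99; a single 1 mm bite drops every seed in
  the supported size range below 0.97.
* Trait distribution tables use 5 upper-edge-labeled half-open classes:
  class 1 is (−∞, e₁), class *i* is [eᵢ₋₁, eᵢ); values at or above the
  last edge are counted in class 5 so counts always sum to the number
  of lines. Default edges are the conventional soybean panel edges;
  an `auto` mode derives equal-width edges from the observed range.

## Color analysis

Per seed, 256-bin histograms of R, G, B and luma over the mask pixels
only.

* **Envelope outliers.** Within a line, per-bin mean and sample sd
  across seeds form the band mean ± k·sd (k = 2 by default). A seed is
  flagged when the fraction of its *occupied* bins (bins where the seed
  or the line mean has mass) strictly outside the band exceeds
  `excess_fraction` (default 0.05). Normalizing by occupied bins rather
  than all 256 makes the statistic meaningful for narrow histograms:
  a flat-colored recolored seed occupies ~2 bins, both outside, giving
  fraction ≈ 1 instead of 2/256. The detector assumes outliers are a
  small minority of a line; if a substantial fraction of a line shares
  the same atypical color, they inflate the per-bin sd and shield each
  other (at 20% identical contamination detection fails, at ≤ ~5% it is
  exact).
* **Log micro-analysis (hilum search).** Histograms are transformed
  bin-wise by log(1 + count) and the band is rebuilt in log space. Only
  "micro" bins — line-mean count below 1% of the mean seed pixel count —
  are inspected, so the bulk coat color cannot trigger the flag; a seed
  is flagged when the fraction of its occupied micro bins outside the
  log band exceeds `excess_fraction`. Seeds whose histogram-mode gray
  is below `min_brightness` (default 80/255) are excluded: a dark coat
  occupies the same low-gray bins the detector inspects, making the
  signal unreliable, so dark-coated lines should be judged by the
  envelope analysis only.
* **Representative color and HTML codes.** Per-channel histogram mode;
  a channel falls back to its median when two peaks are within 80% of
  each other's height (ambiguous mode). The representative RGB is
  mapped to the nearest of the standard HTML/CSS named colors by
  Euclidean RGB distance (alphabetically first name on exact ties). A
  seed is bicolor when its smoothed gray histogram has two peaks ≥ 40
  levels apart whose smaller/larger mass ratio (split at the inter-peak
  valley) is ≥ 0.25; its pixels are split at the valley and each
  cluster's mean RGB is coded separately, dominant cluster first.

## Synthetic boards and what they do (not) show

The generator emulates the imaging protocol: an A4-sized field
(210 × 297 mm) at 0.1 mm/px, a 16 mm black scale tag, a reference patch
strip, seeds on the 4 × 25 grid, four side views showing per-seed
profiles whose vertical extent equals the seed's thickness, optional
sub-100 px noise specks, and exact ground truth per seed. Seed outlines
are superellipses |x/b|ⁿ + |y/a|ⁿ = 1 with n ∈ [1.8, 2.5] — ellipse-like
shapes with closed-form area (4ab·Γ(1+1/n)²/Γ(1+2/n)) that vary
circularity and solidity realistically. Sampling defaults span the
observed cultivated-soybean ranges: length 5.7–11.7 mm, breadth
3.4–8.5 mm, thickness 5.0–9.9 mm. Side profiles are rectangles with
semi-elliptic tops, width-capped below the grid pitch so neighbors
never touch. Bite defects subtract a circle of the given radius whose
center is inset from the outline by 0.7·r: feeding damage is a crater,
not a graze, and this depth makes one 1 mm bite a genuine concavity on
even the largest supported seeds. Illumination is uniform (the physical
rig removes shadows with backlighting); coat color is flat by default
with optional Gaussian jitter (`coat_noise_sigma`).

Passing tests on these boards demonstrate the measurement chain —
calibration, segmentation, descriptor math, matching, color logic — not
robustness to real-world nuisances the generator deliberately omits:
texture, specular highlights, shadows, touching seeds, lens distortion,
or camera noise. Watershed splitting of touching seeds is explicitly
out of scope because the board layout guarantees separation.

## Problem sizes and determinism

The validation experiments use one 100-seed board for counting (plus 20
specks), 200 seeds across two boards for dimension recovery (Pearson r
per dimension ≈ 0.996–0.9998, minimum reported), and 100 seeds for the
solidity floor — sizes at which every statistic is stable to the third
decimal across seeds. All randomness flows through
`numpy.random.default_rng` seeded from the board spec or the script's
`--seed`; regenerating with the same seed is byte-identical, and batch
CSV outputs use fixed 3-decimal formatting and fixed row order so
reruns are reproducible bit-for-bit.

## Known limitations

* The perimeter estimator is tuned for smooth, seed-like shapes; on
  deliberately fractal or single-pixel-wide structures the σ = 2
  smoothing underestimates boundary length.
* Envelope detection needs ≥ 3 seeds per line and honest minority
  contamination (see above).
* The micro-analysis brightness gate trades recall on dark coats for
  precision; it will not find a black hilum on a black seed (neither
  would the histogram).
* Color correction is per-channel affine; channel cross-talk or gamma
  drift is not modeled.
* ROI archives store masks, positions and areas; derived measurements
  are recomputed on load rather than persisted.
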