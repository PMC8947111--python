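# Methods

This note documents the models, parameter choices and numerical conventions
behind `myometrics`, and what the synthetic-data validation does and does
not demonstrate.

## Intensity model and thresholding

All grayscale images are floats on [0, 1]; 16-bit inputs are divided by
65535 on load, 8-bit by 255.  Both threshold families operate on a fixed
256-bin histogram of [0, 1] and are solved by exhaustive search:

* **Three-class Otsu** maximizes the between-class variance of the
  partition {≤ t1, (t1, t2], > t2} over all 256² ordered bin pairs
  (vectorized via prefix sums).  The middle-intensity class can join either
  side: for membrane detection it joins the *background* (only the
  unambiguous membrane signal survives); for collagen detection it joins
  the *foreground* (the red signal comprises bright and faint components).
* **Minimum cross-entropy (Li)** minimizes
  −(S_b·log μ_b + S_f·log μ_f), S the summed intensity mass and μ the mean
  of each side, over all 255 bin boundaries.

Foreground tests compare *quantized* values (`bin(v) > t`), never raw
floats, so sub-quantum numerical dust cannot cross a threshold.  Degenerate
inputs: a constant region yields all-background with a warning; an image
with exactly two gray levels degrades three-class Otsu to the two-class
threshold (the middle class is empty) so binary-valued inputs still
threshold sensibly.

**Adaptive scope** tiles the image into `window_px` squares, thresholds
each tile, inherits the global threshold in degenerate tiles, and
bilinearly interpolates threshold values between tile centers.  On an image
whose tiles share one histogram, adaptive and global outputs are identical.
The **log-transform** option computes thresholds on log(v + 1e−4), rescaled
to [0, 1]; since the map is monotone the decision is applied in that domain
directly.

## Membrane enhancement

* *Unsharp mask*: `clip(img + (img − gaussian(img, σ)))`, σ = 2 px by
  default (the blur scale is not pinned by the reference protocol and is
  exposed in config, flagged unverified).
* *Line structures*: orientation **contrast** of grayscale openings with
  width-1 linear elements (length 5 × line width, 12 orientations):
  `max_θ(opening) − min_θ(opening)`.  A thin line survives the opening
  along itself and vanishes perpendicular to itself (full response); an
  isotropic blob responds identically in every orientation, so the contrast
  cancels *at any blob size*.  A plain orientation-maximum was rejected:
  every pixel of a blob of diameter ≥ element length lies on a long chord,
  so the maximum retains blobs wholesale; lengthening the element instead
  breaks membrane junctions.  The 12-orientation set is closed under 90°
  rotation, making the operator exactly rot90-equivariant away from
  borders.  The kernel is a package choice and is swappable in config.
* *Tubeness*: negated most-negative Hessian eigenvalue at scale σ = 1 px
  (Gaussian derivatives, reflect boundary), clipped at 0 and rescaled to
  [0, 1]; invariant to constant offsets.

The fiber chain boosts each enhanced image (gain 2, clipped — the platform
this mirrors does not print its gain) and averages them unweighted, then
applies a grayscale closing (disk radius 2) and a disk-median filter
(radius 2; not pinned by the reference protocol, config-exposed).  By
default both enhancement branches consume the rescaled image; feeding the
unsharp-masked image instead is a config switch (`enhance_input`).

## Object model

Objects are 8-connected, background holes 4-connected; every label-map
operation returns contiguous labels 1..n.  Identification thresholds the
image, splits the foreground by seeded watershed, applies an
equivalent-diameter gate (2·√(area/π) within the configured range) and
discards border-touching objects.

**Declumping.**  Seeds are plateau-connected local maxima of the smoothed
intensity (or of the Euclidean distance transform for shape-based seeding)
within a disk of radius `min_seed_distance` (default: half the minimum
diameter).  Dividing lines come from watershed on inverted smoothed
intensity or on the negated distance transform.  After watershed, any
fragment smaller than the minimum diameter is merged into its largest
touching neighbor: declumping must not manufacture objects below the
smallest size being looked for.  Without this, micro-peaks along
constant-intensity ridges (e.g. ring-shaped marker objects) shatter one
object into sub-gate arcs.  Isolated undersized objects are left to the
diameter gate.

**Shape measures.**  Perimeter uses the Crofton formula with 4 directions —
nearly unbiased on smooth digital shapes (a digital disk of radius 20 has
form factor 1.008, where contour-length estimators bias it 5–10% low).
Solidity divides the pixel area by the rasterized convex image area, so
convex digital shapes score ~1 (a corner-point-hull denominator would
depress it by a half-pixel rim, ~1 − 1/(2r)).  The **minimum Feret
diameter** runs rotating calipers on the convex hull of the pixel *corner*
points: the minimum width of a convex polygon is attained with one edge
flush, so it is the minimum over hull edges of the farthest-vertex
distance.  Coordinates are first reduced to boundary pixels (projection
extremes are unchanged).  The filter rule keeps an object iff area ≥ 40 px²
AND form factor ≥ 0.32 AND solidity ≥ 0.75 (all inclusive).

**Resizing.**  Shrinking erodes each object independently with a discrete
disk (equivalently: keep pixels whose distance to the complement exceeds
the radius; neighboring labels and the image border count as complement),
so labels never merge and objects may vanish.  Expansion assigns background
pixels to their nearest object (`expand_labels`), never overwriting.
Shrink-to-point keeps the centroid pixel, or the nearest object pixel if
the centroid falls outside.  Overlap masking keeps a child, unclipped, iff
(child ∩ mask)/child ≥ the overlap fraction; a one-point child with
fraction 1 therefore requires its pixel to lie on the mask — the reading
used for CNF detection.  Parent assignment is by majority pixel overlap,
ties to the lowest parent label.

## Pipelines

* **Fibers**: rescale → enhancement (above) → closing → median → 3-class
  global Otsu, middle→background (or adaptive with a 500-px window as the
  uneven-illumination variant) → binary closing + hole filling (holes
  ≤ 300 px², a size chosen to absorb capillary-scale lumina) → invert →
  identify (global minimum cross-entropy, intensity seeds, shape divides,
  diameter 18–2000 px, border discard) → filter (40 px² / 0.32 / 0.75) →
  measure, with CSA = area·(μm/px)² and MFD in μm.
* **Nuclei**: rescale → median → white top-hat (disk of diameter 10 px, the
  typical nucleus) → identify (adaptive Li, 20-px window, intensity seeds
  and divides, 6–20 px, border discard).  CNF/PNF: fibers shrunk 5 px,
  nuclei to points, points masked to shrunken fibers, related, classified;
  a fiber that vanishes under the shrink is PNF.  `pct_pnf` is computed as
  `100 − pct_cnf` so the two always sum to exactly 100.  Shrunken-fiber
  labels are mapped back to the original fibers by overlap (shrunken ⊂
  original makes this exact).
* **Macrophages / any marker**: rescale → median → white top-hat (100 px)
  → identify (adaptive Li, 100-px window, log transform, intensity seeds,
  shape divides, 8–100 px) → nuclei expanded 2 px → positive iff expanded
  overlap ≥ 0.1 of the *nucleus* footprint (child-relative).  The reported
  percentage divides positive nuclei by **all** segmented nuclei — the
  denominator is stated here because published percentages often leave it
  implicit.  Marker objects without a nucleus stay in the label map but
  never enter the counts.
* **ECM**: optional flat-field correction → color deconvolution (od =
  −log10(max(I, 1/255)); concentrations solve od = c·M for the stain
  matrix M whose rows are the unit Fast-red/Fast-blue/DAB absorbance
  vectors from the standard tables; clipped at 0; each channel rescaled to
  [0, 1] unless the stain is absent, in which case it stays zero rather
  than amplifying numerical dust) → 3-class Otsu on the red channel,
  middle→foreground → positive pixels counted inside the tissue section.
  The section mask thresholds summed white-referenced optical density
  (white point = per-channel 99th percentile, making the mask invariant to
  uniform brightness changes; floor 0.08).  Both the tissue-relative and
  whole-image fractions are reported, explicitly named.  μm² conversion:
  0.2289 μm²/px by default, from the acquisition calibration.

**Flat-field correction** divides each channel by its heavily
Gaussian-smoothed self (σ = 60 px for ECM) and normalizes by the 99.5th
percentile (clipping at 1) so halo pixels cannot compress the range.  This
estimator assumes the *structure* in the image is smaller than the
illumination scale; it is well-posed for sections larger than the field of
view and cannot help when a single tissue disc fills the frame, because
tissue and gain then share one spatial scale.  The generator's
`full_field` mode exists to exercise the former regime.

## Synthetic data

`MosaicSpec` defaults define the validation conditions: a 512×512 field,
30 Poisson-disc-sampled Voronoi fibers (minimum seed spacing 60 px, giving
equivalent diameters ~50–150 px, inside the 18–2000 gate), membrane width
4 px at intensity 0.8 with 10% of membrane pixels deleted and Gaussian
noise sd 0.05 on the membrane channel, nuclei of radius 4 px (detected
diameter ~8–10 px, inside the 6–20 gate) rendered as quartic
super-Gaussian profiles, 30% of interior fibers given a central nucleus
and 30% a peripheral one, 12 extra interstitial nuclei on the membrane
network, and 5 macrophage blobs (radius 8 px, irregular multi-disc shapes,
or non-touching rings for the expansion experiment) around designated
interstitial nuclei.  Peripheral nuclei sit 2–3 px inside the fiber
boundary, so the 5-px shrink rule *must* classify them PNF.  Everything is
a deterministic function of the spec including its RNG seed; the truth
tables are pixel-consistent with the emitted images.  Truth MFD values
come from a dense 3600-angle projection sweep with bracket refinement
around the coarse minimum — refinement is necessary because the
width-vs-angle profile has a linear kink at its minimum, so uniform
sampling alone converges only linearly — and this sweep is algorithmically
independent of the rotating-calipers code it cross-validates.

Sirius-red images are built through the forward stain model (transmittance
10^(−c·M)) on an irregular tissue disc (or the whole frame in `full_field`
mode): DAB-like density 0.5 in muscle, red density 1.0/0.55 (strong/medium,
block-assigned) on collagen ribbons dilated from Voronoi boundaries and
trimmed pixel-exactly to the requested area fraction, plus an optional
horizontal gain ramp for illumination experiments.

Idealizations to keep in mind when transferring conclusions to real data:
the DAPI and marker channels are rendered noise-free (only the membrane
channel carries noise); membranes have uniform intensity and gaps are
single-pixel deletions rather than correlated tears; nuclei are round and
non-overlapping except where tests construct overlaps explicitly; stain
vectors in the Sirius generator match the unmixing vectors exactly, so
unmixing error on real slides (vector mismatch, scattering) is not
modeled.  Passing these tests demonstrates correctness of the algorithms
and their integration, not robustness to every histological artifact.

## Validation scale and runtime choices

The test suite and the acceptance script validate on 512×512 mosaics with
30 fibers, 5 seeds per condition, 100 random images for threshold-oracle
agreement and 50 random convex polygons for MFD agreement — sizes chosen
so the full suite completes in a couple of minutes while every check stays
statistically meaningful (66 fibers across seeds for recovery rates, ~25
nuclei per mosaic).  CLI and batch tests run on 256×256 ten-fiber mosaics.

## Known limitations

* No interactive object editing; the programmatic `remove_labels` hook is
  the editing surface, and downstream stages consume the edited map.
* Declumping of heavily overlapping nuclei relies on distinct intensity
  peaks; equal-intensity nuclei fused without an intensity saddle will
  merge.
* The ECM tissue mask assumes near-white glass; slides with strongly
  tinted background need an adjusted OD floor.
* Single-scale tubeness (σ = 1 px) targets membrane-width ridges; much
  thicker boundaries would need the scale raised in config.
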