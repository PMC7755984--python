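# Methods

## Problem and approach

Experimental agriculture plants cereals in dense grids of small rectangular
plots (microplots) separated by narrow soil or plough-line divisions. Scoring
hundreds of varieties requires delineating every plot in a UAS orthomosaic or
photogrammetric DSM, which is tedious to digitize by hand. `cropseg` segments
the plots by detecting the *divisions* rather than the vegetation: divisions
are straight, occur in two near-perpendicular families, and remain partially
visible even at emergence, so a constrained line detector needs no training
data and almost no parameters.

The chain is: rasterize the user's field polygon (AOI) → collapse to one band
→ detect edge primitives (Canny or phase congruency) → estimate the field's
major/minor axis orientation from the AOI mask → standard Hough transform
restricted to normal angles near each axis → draw the detected lines across
the full extent and merge → 4-connected components of the line-free interior
→ discard components outside an area window (m²) → trace the survivors into
map-coordinate polygons → optional per-segment refinement (morphological
Chan–Vese or Otsu) → pixel precision/recall/F<sub>β</sub> against a
validation layer.

## Grid and coordinate conventions

Pixels are 0-based (row, col) with row 0 at the top; the geotransform is
north-up with negative y-resolution; conversions use pixel centers.
Rasterization is pixel-center-inside everywhere (AOI, prediction and truth
masks), so the evaluation is self-consistent. The tool never reprojects; CRS
mismatches are hard errors, because silent reprojection corrupts the m²
pixel-area bookkeeping the area filter depends on. Angles are handled in
array coordinates internally (x = col, y = row downward, CCW in [0°, 180°));
under a north-up transform an array angle `a` equals map angle `(−a) mod 180`.

## Edge detection

Both detectors operate on a single band min–max rescaled to [0, 255] within
the AOI (DSMs included), so hysteresis thresholds live on one fixed scale.
Canny uses the classic 2:1 hysteresis convention: given only an upper
threshold, the lower is exactly half. With no threshold at all, both are tied
to the observed Sobel gradient maximum (upper = 0.2·max, lower = 0.1·max),
which adapts across scenes without per-site tuning. Detection runs on the
full array; the mask is applied afterwards and edges within 2 px of the mask
boundary are dropped, since the AOI outline itself is a strong false edge.

Phase congruency follows Kovesi's log-Gabor formulation (nscale = 4,
norient = 6, min_wavelength = 3 px, mult = 2.1, σ_onf = 0.55, noise
multiplier k = 2): per orientation, energy is amplitude-weighted phase
agreement across scales, thresholded by a Rayleigh noise estimate and
penalized for narrow frequency spread; orientations combine into a covariance
whose maximum moment is the edge strength and whose principal axis gives the
edge normal used for non-maximum suppression. Two adaptations matter:

* **The PC "σ" scales the filter bank, not the input.** Gaussian
  pre-smoothing concentrates all amplitude in the coarsest filter, and the
  frequency-spread weight then suppresses genuine step edges almost entirely.
  Instead σ multiplies the smallest wavelength (`min_wavelength · max(1, σ)`),
  the frequency-domain analogue of widening the Canny envelope.
* **Noise-floor guard.** On (near-)noise-free imagery the Rayleigh estimate
  collapses and orientations with negligible amplitude report spuriously
  perfect congruency. The noise threshold is floored at 2 % of the peak
  filter-bank energy; the floor scales linearly with contrast, so contrast
  invariance is preserved (verified exactly on two-height step fixtures).

PC hysteresis defaults are relative to the moment maximum (upper = 0.3·max),
again contrast-invariant; absolute values can be set explicitly. Per-axis
edge detection (independent parameter sets for the major and minor axis) is
available for fields whose division frequency differs by direction.

## Axis estimation and constrained Hough

The field axes come from the minimum-area rotated bounding rectangle of the
AOI mask's convex hull; the longer side defines the major axis (first side
wins on exact ties, deterministically). On rasterized rectangles the
estimate is accurate to well under 0.5°.

Line detection is the standard (non-probabilistic) Hough transform, voting
only over normal angles within ±5° of the selected axis normal at 0.5° steps
(1 px r-bins, r referenced to pixel (0,0)). Peaks need votes ≥ 0.25× the
accumulator maximum and above an absolute floor of 5 % of the image diagonal
(the floor rejects stray coincidences when an axis has no true lines at all).
Deduplication uses the line's perpendicular offset at the *image center*:
different (r, θ) bins of one physical line share that offset, while distinct
lines in one axis family are parallel and separated by the plot pitch, so
candidates within `min_r_sep_px` (default 3 px) of an accepted line's center
offset are duplicates. Candidates are visited by descending votes with |r|
then θ as tie-breaks, making output deterministic. Both sides of a division
(each gap produces two parallel edge chains) are deliberately *kept*: the
thin strip between them is diced by the perpendicular lines and removed by
the area filter, which keeps segment boundaries unbiased instead of snapping
to one side of the gap. Detected lines are rendered across the full extent
with a point-to-line distance rule (pixel center within width/2; default
width 1 px) and unioned.

## Segments, areas, polygons

Connected components of `mask AND NOT lines` use 4-connectivity so 1 px
diagonal line crossings still separate cells. Areas are always m² from the
geotransform — never raw pixel counts — so the published minimum-area presets
transfer across resolutions. Only a minimum area is required; a maximum is
supported but unset by default. Segments touching the AOI boundary are kept.
Polygons trace exact pixel boundaries (unit boundary segments assembled into
faces, with a union-of-pixel-squares fallback whenever the face bookkeeping
cannot reproduce the pixel count), so each polygon's geometric area equals
its pixel count times the pixel area exactly, and repeated runs are
byte-identical GeoJSON.

## Refinement (off by default)

Refinement operates per segment inside its bounding box padded by 10 px, so
neighbouring plots cannot capture each other's pixels; any overlap left
afterwards goes to the segment with the nearer centroid. ACWE is the
morphological Chan–Vese variant (50 iterations, smoothing 1, λ₁ = λ₂ = 1)
initialized from the rasterized footprint; Otsu takes the largest
above-threshold component overlapping the footprint. A guard returns the
input unchanged when refinement empties the segment or grows it beyond 4×.
Neither refiner improves results consistently on typical fields, hence the
opt-in flag.

## Evaluation

Prediction and truth are rasterized on the evaluation grid with the same
pixel-center rule, restricted to the AOI, and compared pixel-wise:
precision = tp/(tp+fp), recall = tp/(tp+fn),
F<sub>β</sub> = (1+β²)·P·R/(β²·P+R), with commission = 1−P and
omission = 1−R also reported. β defaults to 1 — the balanced harmonic mean —
and is configurable; note that β = 0.5 would *not* weight precision and
recall equally under this formula, and every published field score this
package reproduces is consistent with β = 1.

## Synthetic scenes

The generator emulates the two survey products the pipeline consumes, on a
synthetic UTM grid (EPSG:32630) so every geospatial code path runs without
real data. Study conditions (generator defaults): a 6×10 grid of
1.5 m × 3.0 m plots (4.5 m²) separated by 0.10 m plough-line divisions,
0.8 m soil margin, 2.5 cm ground sampling distance. Optical mode renders
canopy at 180 DN over soil at 60 DN with Gaussian texture noise (sd 8),
1 px optical blur, and an optional multiplicative illumination ramp
(strength 0.5 in the shadowed variant, i.e. brightness falls to half across
the field diagonal). DSM mode renders 0.30 m plateaus with a 0.10 m sinusoidal
canopy crown over a ground plane with 2 cm noise. `emergence_frac` < 1 thins
the canopy to a random speckle, emulating emergence-stage fields where only
part of each plot carries plant signal. Exact plot rectangles, the AOI
polygon, and every division centerline (plus the outer grid boundary lines)
are exported as ground truth.

What the generator does *not* emulate: perspective/mosaicing artifacts, weed
pressure, lodging, curved or missing divisions, and radiometric variation
beyond a smooth ramp. Passing the synthetic suite therefore demonstrates the
geometry and bookkeeping of the chain and its behaviour under contrast
degradation — not performance on arbitrary real imagery, which still depends
on choosing σ to match the division frequency.

Problem sizes used by the test suite and the acceptance script — scene
rasters of roughly 1000×1000 px (about 1 Mpx), 12–30 scenes per sweep, and
10 random rectangle orientations for axis recovery — were chosen so the whole
suite completes in about a minute on a laptop-class core while every scene
still contains all 60 plots at full GSD.

## Numerical choices and degenerate inputs

Constant images yield empty edge maps (not errors); empty edge maps yield
empty line sets with a warning; an all-line interior yields zero segments
with a warning. Images smaller than the largest log-Gabor wavelength are
rejected for PC. Ties in Hough peak selection break deterministically
(votes, |r|, θ). Otsu agrees exactly with exhaustive between-class-variance
maximization on 8-bit windows. The Chan–Vese region energy is non-increasing
across morphological iterations on clean blob fixtures; this is checked per
iteration in the tests.

## Known limitations

* Divisions must be straight and in two near-perpendicular families; curved
  or fanned layouts are out of scope.
* One σ per axis must roughly match the division frequency; the tool does not
  yet estimate σ from the imagery.
* Vector I/O is GeoJSON only, and CRS handling is an EPSG tag comparison, not
  a full CRS engine.
* Pixel-based scores only; no per-plot IoU matching.
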