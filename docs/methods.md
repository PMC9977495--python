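# Methods

## Coordinate and calibration conventions

All analysis is strictly 2D. Pixel coordinates are 0-based `(row, col)`
indices with the origin at the center of the top-left pixel; physical
coordinates are `x_um = col * pixel_size_um`, `y_um = row * pixel_size_um`
with an isotropic, user-supplied pixel size. Calibration is never parsed from
TIFF metadata — resolution tags vary across microscope TIFF dialects, and a
silently misread calibration corrupts every downstream distance, so the pixel
size is an explicit argument everywhere.

## Puncta detection

Single-molecule FISH signal is modeled as isotropic Gaussian puncta of
roughly known diameter over a slowly varying background. Detection is:

1. **Band-pass.** Scale-normalized Laplacian of Gaussian with
   `sigma = (expected_diameter_um / pixel_size_um) / (2 * sqrt(2))`, the scale
   at which the LoG response of a Gaussian blob of that diameter peaks.
2. **Robust threshold.** Local maxima of the response (minimum separation
   `min_separation_um`, default 1 μm) are kept when they exceed the response
   median plus `contrast_threshold` times the robust background spread,
   defined as `1.4826 * MAD` of the response. The MAD is dominated by
   background pixels even in dense fields, so the threshold is insensitive to
   the puncta themselves and detection is exactly invariant to multiplying
   the image by a positive constant.
3. **Region growth.** Maxima seed a watershed on the smoothed channel; each
   object keeps the pixels of its basin above half the peak's prominence over
   the smoothed background (median), restricted to the connected component
   containing the maximum. Objects are filtered by area bounds
   (`min_area_px`..`max_area_px`, default 1..400 px).
4. **Centroids.** Each object is reduced to its intensity-weighted centroid
   in μm. All distances are measured between these zero-size spot centers;
   a rendered "3-pixel spot" is a display convention, not an analysis object.

Defaults (`expected_diameter_um = 2.0`, `contrast_threshold = 5.0`) were
calibrated on the synthetic renderer, not on any real acquisition; for the
2 μm puncta the simulator draws, the half-prominence footprint of a true
punctum spans roughly 20–30 px, well inside the default area bounds.
Tie-breaks are deterministic: candidate maxima are processed in lexicographic
`(row, col)` order. Spots touching the image border are kept by default (their
centroids may be biased up to half a pixel); `exclude_border=True` drops any
object containing a border pixel. A channel with zero dynamic range returns an
empty spot set rather than an error.

At the default settings a 7-px noise blob occasionally clears the 5-spread
threshold (roughly one per few dozen 600×600 px fields); downstream consumers
are written to tolerate such spurious spots rather than the detector being
tightened to suppress them, since a stricter threshold costs recall on dim
real puncta.

## Nearest-object distances and binning

For each source-channel spot the statistic is the minimum Euclidean distance
to any target-channel spot, computed with a k-d tree but *defined* by the
brute-force O(n·m) minimum; the two agree exactly (no approximate search is
used) and the test suite asserts element-wise equality. Distances are
directional (source → target) and never symmetrized. A field whose target
channel is empty raises a typed error at the single-field level; the pipeline
logs and drops such fields instead of failing the run.

Distances are binned into half-open intervals `[k·w, (k+1)·w)` with
`w = 6 μm` by default, so "percent of signal within 6 μm" is exactly the
first bin and a distance of exactly 6.0 falls in the second. Because the bin
width is a parameter, a cumulative "< 6 μm" readout and the first-bin readout
coincide at the default width; both remain available if a narrower width is
chosen.

**Statistical unit.** Fields are pooled within an animal before summarizing
(mean, median, first-bin percent), and condition comparisons run on the
per-animal values with a two-sided equal-variance (Student) two-sample
*t* test, `df = n_a + n_b − 2`. Testing thousands of spots as if independent
would be pseudoreplication; the per-animal default avoids it, while raw
distances can still be passed to `compare_conditions` directly when a
pooled-spot test is wanted. Degenerate inputs are handled explicitly: fewer
than two values per group, or zero pooled variance with unequal means, raise;
two identical constant groups return `t = 0, p = 1`.

## Cell typing by dilation and intersection

Cytospin fields contain isolated cells, so cell reconstruction does not need
a segmentation model: each *Pdgfra* object is dilated with a discrete
Euclidean disk of radius `round(5 μm / pixel_size_um)` px; dilations that
touch are merged into one cell (a cell's transcripts form several puncta).
DAPI components are folded in: a component overlapping exactly one cell joins
it; one contested by several cells is assigned to the cell whose Pdgfra-signal
centroid is nearer, ties to the lower cell id; DAPI pixels already inside
another cell's dilation stay where they are, keeping footprints disjoint.
Cells with no DAPI overlap are kept but flagged anucleate
(`exclude_anucleate=True` removes them).

A cell is **positive** for a Wnt channel when any pixel of any Wnt object,
dilated by `round(4 μm / pixel_size_um)` px, intersects the cell footprint —
a plain Boolean intersection with single-object sufficiency. No punctum-count
or intensity threshold is applied for positivity; that is the simplest rule
consistent with a binary intersect operation, and a count threshold is left
as future work. Because `skimage.morphology.disk(r)` contains exactly the
integer offsets with `hypot ≤ r`, dilation-based positivity equals the
brute-force rule "minimum pixel distance ≤ 4 μm" up to one pixel of
discretization, which the test suite checks on randomized geometries.

The two flags map to four subtypes (Wnt2+, Wnt5a+, double+, double−);
cohort fractions are computed per animal (pooling the animal's fields) and
conditions are compared per subtype with the same Student *t* test.

## Organoid morphometrics

Organoid images are segmented by Otsu thresholding of the smoothed channel,
hole filling, and removal of specks below 10 μm equivalent diameter; a blank
field yields an empty mask, not an error. "Diameter" is the equivalent
circular diameter `pixel_size_um · 2 · sqrt(area_px / π)`: organoids are
near-spherical in projection and the area-based measure is far less sensitive
to boundary noise than a Feret caliper. An object is a colony when its
diameter reaches 50 μm, and CFE = 100 · n_colonies / n_seeded with the
seeded-cell count supplied by the user (5 × 10³ AT2 cells per culture is the
typical seeding). Touching organoids are not split by default (determinism
over completeness); the rasterized-disk diameter error at 1 μm/px is under
3% for diameters ≥ 30 μm. Note that because the colony filter censors the
lower tail, the median *colony* diameter can move opposite to the full size
distribution when a condition shrinks organoids across the board.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis relies on,
with exact ground truth:

- **Section fields** (default 200 × 200 μm at 0.5 μm/px): Sftpc anchor
  puncta uniform over the field (default 100), Pdgfra puncta uniform (200),
  and per-Wnt-channel puncta (200 each) placed at a uniformly chosen anchor
  plus an isotropic displacement whose radius is exponential with mean
  5 μm (Wnt2) / 9 μm (Wnt5a). The exponential is a single-parameter,
  strictly positive law with enough tail to populate all distance bins; it is
  a modeling convenience, not a biological claim, and is the config's to
  change. Displacements landing outside the field are redrawn, which
  truncates the law slightly.
- **Cytospin fields** (default 300 × 300 μm at 0.5 μm/px, 45 cells/field):
  non-overlapping cells (rejection sampling, 30 μm minimum center
  separation, bounded attempts) with a 4 μm nucleus disk rendered in DAPI,
  8 Pdgfra puncta per cell, and 6 puncta per expressed Wnt channel scattered
  in an 8 μm cell-footprint disk. Subtypes are drawn i.i.d. from a
  probability 4-vector, default (0.30, 0.20, 0.25, 0.25).
- **Organoid fields**: non-overlapping rasterized disks of requested
  diameters, placed largest-first.

Rendering adds each punctum as a Gaussian (σ = 2 px) centered at the true
sub-pixel coordinate on a flat background, then applies Poisson shot noise
and optional Gaussian read noise. At the defaults (amplitude 100 over
background 100) the peak SNR is amplitude/√background = 10.

A hypercapnia-like condition is expressed purely as config deltas — smaller
Wnt5a offset mean and higher Wnt5a count in section mode, probability mass
shifted toward the double-positive subtype in cytospin mode — with no
separate code path.

**Not emulated:** tissue autofluorescence texture, anisotropic or spatially
varying PSFs, photobleaching, overlapping cells, 3D structure, and spot
density gradients other than anchor attraction. Passing tests therefore
demonstrate correctness of the measurement pipeline under a controlled
optical model, not robustness to every artifact of real tissue sections;
detector parameters will need adjustment per real acquisition.

## Reproducibility

Every generator call consumes a single integer seed through one
`numpy.random.Generator`; the pipeline expands its global seed into per-field
substreams via `SeedSequence` spawn keys indexed by (condition, animal,
field), so field simulations are order-independent and a fixed config + seed
reproduces every output table byte for byte (run metadata records the config
hash and library versions, and deliberately omits timestamps).

## Problem sizes

Verification runs use desk-scale sizes chosen to make the statistical checks
well-powered while keeping the full suite quick: 500 × 500 points for the
exact nearest-distance cross-check, 200 puncta per field for detector
fidelity, 3 animals × 3 fields per condition (the study's stated design) for
the spatial contrast, 9 cytospin fields × 45 cells (> 400 cells, matching
the stated per-condition measurement count) for subtype recovery, 50
randomized geometric fixtures for the dilation oracle, and a four-disk
(30/55/80/120 μm) fixture for the colony filter.

## Known limitations

- Overlapping puncta closer than the detector's minimum separation are
  merged; transcript-count deconvolution is out of scope.
- Cell typing assumes isolated cells (cytospin); it is not a tissue
  segmentation method and will merge touching cells.
- Positivity by single-punctum intersection may overcall low-level expression
  relative to a count-thresholded rule.
- Organoid segmentation is global-threshold based and will under-segment
  images with strong illumination gradients; no watershed splitting by
  default.
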