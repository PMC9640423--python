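# Methods

`ripaq` assesses the ecological quality of riparian strips from
very-high-resolution (VHR) multispectral imagery by object-based image
analysis. This note documents the models, the defaults and the reasoning
behind the open design choices. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is
asserted from memory.

## The scoring model

The riparian strip quality index (RSQI) of a station is a weighted
average of land-cover percentages inside the riverine strip,

    RSQI = Σᵢ (%LUᵢ · Wᵢ) / 10

with weights W: forest 10.0, crops 1.9, bare soil 1.7, infrastructure
(built-up) 1.9. Under this table the index ranges from 17 (pure bare
soil) to 100 (pure forest). Scores are categorised as very low (< 40),
low (40–60), moderate (60–80) and high (≥ 80).

Water is excluded from the %LU denominator. The weight table has no
water entry and the strip being scored is the land beside the channel;
including channel pixels would deflate every score by an amount driven
by river width rather than vegetation condition. This is a package
decision — the scoring convention for water is not fixed by the index
definition itself — and it is configurable through the `exclude`
argument of `composition`.

The field-based counterpart (QBR) is modelled structurally: four blocks
scored 0–25 in steps of 5, summed to 0–100, categorised very good
(≥ 95), good (75–90), moderate (55–70), poor (30–50), bad (≤ 25).
Because totals are multiples of 5, the gaps between the published
category edges (e.g. 50–55) are unreachable and every attainable score
has exactly one category. Restoration triage maps the same lattice to
conservation (> 90), recovery (55–90) and restoration (< 55). The
rubric content of the four blocks is field data, not computed here:
block scores enter through a CSV.

## From image to land cover

**Red-edge NDVI.** RE-NDVI = (NIR − RE)/(NIR + RE) with NIR the NIR1
band (770–895 nm, band 7) and RE the red-edge band (705–745 nm, band
6) of the 8-band stack. It saturates later than the classic red-band
NDVI over dense canopies, which is why it drives the vegetation rules.
Pixels with NIR + RE = 0 (or nodata) are nodata.

**Pansharpening.** Only the contract of the commercial pansharpening
used with such imagery is public, so the package implements a
least-squares component-substitution scheme: the PAN band is
block-averaged to the MS grid and regressed on the 8 bands to obtain a
synthetic low-resolution intensity; per-band detail injection uses the
gain cov(band, intensity)/var(intensity). The enforced contract is
Wald-style spectral consistency — block-averaging the sharpened product
back to the MS grid reproduces the input bands, exactly so on noiseless
scenes (tested at RMSE < 1 % of band range) and to within the
regression residual otherwise.

**PCA and the composite.** Principal components come from the
eigendecomposition of the band *covariance* matrix over valid pixels
(covariance, not correlation: the bands share units, and rescaling by
per-band variance would overweight the quiet coastal/yellow bands).
Component signs are fixed by making each eigenvector's
largest-magnitude loading positive, so outputs are deterministic. The
analysis composite stacks PC1–PC3 with RE-NDVI — four bands — each
standardised to zero mean and unit variance over valid pixels so the
segmentation's colour heterogeneity treats them comparably
(`n_pcs` is configurable; PC1 + RE-NDVI gives the two-band variant).
Standardisation before compositing is a package choice. Multi-date
input is handled by preprocessing each date and averaging the
composites band-wise. Nodata is masked, never zero-filled.

**Segmentation.** Bottom-up pairwise region merging with the canonical
Baatz–Schäpe fusion cost: a merge is allowed iff

    shape_w·h_shape + (1 − shape_w)·h_colour < scale²

where h_colour is the growth in size-weighted per-band population
standard deviation (equal band weights) and h_shape blends compactness
(P/√n) and smoothness (P/bounding-box perimeter) terms. Defaults are
scale 25, shape 0.1, compactness 0.1 — the parameterisation published
for this workflow. Merging uses local mutual best fitting swept in
ascending segment id (ids are the row-major index of a segment's first
pixel), ties broken toward the lowest neighbour id, iterated to a fixed
point; pixels are 4-connected and the threshold comparison is strict.
These ordering rules are what make runs reproducible and allow the
brute-force oracle in the tests to reproduce partitions exactly;
commercial implementations do not publish their internal ordering, so
equivalence is claimed at the criterion level only.

The scale parameter is resolution-dependent: with scale 25 the expected
object size is a few hundred to a few thousand pixels, i.e. tens of
square metres at the 0.5-m pansharpened grid but thousands at the 2-m
MS grid. The pipeline therefore segments the pansharpened composite by
default (`sharpen: true`); segmenting at 2 m with the same scale
produces objects too coarse to resolve strip-scale degradation.

**Classification.** A transparent hierarchical threshold cascade rather
than a trained learner — testable, deterministic, and free of training
data: (1) water if object mean RE-NDVI < 0.05; (2) urban if brightness
(mean reflectance over the 8 bands) > 0.20 and RE-NDVI < 0.15;
(3) forest if RE-NDVI ≥ 0.35, else crops. Thresholds are configurable
and can be refitted as midpoints between class centroids of labelled
seed objects (`fit_thresholds`). Objects with undefined features take a
fallback class and are counted.

**Validation.** Reference labels come from the majority ground-truth
class per segment (replacing on-screen interpretation). A stratified
random sample allocates validation objects proportionally to
predicted-class counts with largest-remainder rounding (n = 200 by
default). Agreement is summarised by the confusion matrix (rows =
predicted), overall accuracy (trace/total) and Cohen's kappa; a matrix
is always used exactly as given, with N equal to its own total.

## The synthetic scene generator

Real VHR scenes of this kind are commercial and the field data are not
public, so the generator produces WorldView-2-like scenes with known
truth: 8 bands at 2 m plus a PAN band at a 4:1 ratio (a fixed weighted
sum of the blue–NIR1 class means), iid Gaussian sensor noise
(sd 0.01 reflectance), a smooth random-walk meander rasterised to a
20-m channel, a 30-m riparian forest strip degraded by crop/built-up
intrusions over 35 % of 50-m chainage blocks, and a background
partitioned into coherent patches (a thresholded smoothed random field)
so realised class fractions track the target mix (water 0.05, forest
0.45, crops 0.30, urban 0.20). Class spectra are plausible surface
reflectances chosen so the class structure is well-posed: forest has
the strongest NIR/red-edge contrast (RE-NDVI ≈ 0.47), crops
intermediate (≈ 0.27), built-up bright and weakly vegetated (≈ 0.10),
water dark with negative RE-NDVI. Bare soil has a spectrum and a
weight but is off by default, matching a four-class classification
against a five-entry weight table. The default scene is 256 × 768 MS
pixels (0.5 × 1.5 km), long enough for 15 stations of 100 m.

What the generator does *not* emulate: radiative transfer, atmosphere,
topography, shadows, seasonal phenology, within-class texture, mixed
pixels beyond grid discretisation, or spatially correlated noise.
Passing recovery tests therefore demonstrate that the chain is
self-consistent — segmentation, classification and scoring recover a
known landscape through realistic sensor noise — not that the
classifier thresholds transfer to real imagery, where spectra overlap
far more.

## Stations and geometry

Stations are built from the stream centerline: equally spaced centres,
each footprint the 100-m sub-line (50 m up- and downstream) buffered
50 m to one side, evaluated per bank (left/right by the signed side of
the local direction of travel), so n centres yield 2n scored units.
Rasters use a north-up affine georeference and pixel-centre inclusion
throughout. Raster I/O is TIFF with the affine transform, CRS code and
band names carried as JSON in the image description tag; vectors are
GeoJSON.

## Problem sizes and numerics

The recovery experiments in the test suite run five seeds on
160 × 320-pixel corridors (320 × 640 m, three stations per bank) with
all study conditions at their defaults; this size keeps the whole suite
comfortably interactive while still exercising pansharpening,
0.5-m segmentation (~300 k masked pixels) and scoring end to end.
Observed across those runs: object-level kappa ≥ 0.88 and per-station
RSQI within 1 point of the truth-raster score (the tests assert the
looser ≥ 0.8 and ± 5 bounds).

Numerical notes: per-segment variance uses the sums/sums-of-squares
form (clamped at zero), so "zero" standard deviations are ~1e-8;
equal-cost merge candidates resolve to the lowest id pair; PCA on a
rank-deficient covariance clips tiny negative eigenvalues to zero;
compositions must sum to 100 ± 1e-6; the pipeline clamps the validation
sample size to the number of objects on small scenes and records both.

## Known limitations

- The rule cascade presumes the synthetic class geometry; real scenes
  need refitted thresholds (`fit_thresholds`) or a different backend.
- The segmentation is a faithful but single-level implementation: no
  hierarchy, no tiling, pure-Python merging (fine up to ~10⁶ masked
  pixels, not basin-scale).
- Station footprints assume a centerline that does not self-intersect
  within a footprint length; extreme meanders could overlap banks.
- QBR enters as data; the package never computes field rubric scores.
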