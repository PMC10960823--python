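# Methods

This note documents the models, parameter choices and numerical decisions
behind `wetmap`, and what the synthetic experiments do and do not show
about real imagery.

## Spectral indices

Four indices are computed from six-band surface reflectance
(blue, green, red, NIR, SWIR1, SWIR2, all in [0, 1]):

* `LTideI = (NIR − M) / (NIR + M + L) · (1 + L)` with
  `M = max(blue, green, red, SWIR2)` and stabiliser `L = 0.1`
  (the published recommendation).  Taking the max over the visible/SWIR2
  bands makes the index robust to atmospheric-correction artefacts that
  push single visible bands negative over high-latitude water.  For
  reflectance in [0, 1] and `L > 0` the index is bounded in [−1, 1].
* `mNDWI = (green − NIR) / (green + NIR)`; positive over open water.
* `NDVI = (NIR − red) / (NIR + red)`.
* `LSWI` exists in two circulating forms that differ in the numerator's
  SWIR band.  Default is the self-consistent
  `(NIR − SWIR1)/(NIR + SWIR1)`; the variant `paper_printed`
  reproduces the mixed-band form `(NIR − SWIR2)/(NIR + SWIR1)` that
  appears in print.  The choice is config-exposed
  (`IndexConfig.lswi_variant`) and affects only the 5 LSWI percentile
  bands; neither variant is privileged by any test.

Zero denominators return a 0 sentinel with an optional flag instead of
propagating non-finite values — downstream random forests require finite
features.  `LTideI` never has a zero denominator (`L > 0`).

## The 94-variable feature stack

| block | count | content |
|---|---|---|
| water level | 16 | two 8-band quality mosaics (see below) |
| phenology | 50 | 5 percentiles × (6 bands + 4 indices) |
| texture | 25 | 5 GLCM statistics × 5 NIR percentile bands |
| terrain | 3 | elevation, slope, aspect |

**Quality mosaics.**  Per pixel, the observation maximising LTideI (lowest
water level) contributes its index value, its six reflectance bands, and
its mNDWI; the observation maximising mNDWI (highest water level)
contributes analogously.  The published total of 16 is stated without an
itemisation; including the companion index at the selected observation
(8 + 8) is this package's explicit decision, visible in the band names.
Exact index ties select the earliest acquisition (deterministic and
order-independent).  Pixels with no valid observation are NaN and flagged.

**Percentiles** use linear interpolation between order statistics (the
numpy default), stated so the tests can be exact.  Masked observations are
excluded before ranking; a single valid observation fills all five
percentiles; monotonicity across ranks is guaranteed and tested.  The
0th/100th percentiles are deliberately unused (residual cloud/snow).

**GLCM textures.**  The operator and the five statistics are fixed by the
method; the parameters are not published anywhere, so conventional values
are used and config-exposed: 32 grey levels quantised over the band's
observed range, 5×5 windows, and the four unit offsets (0°, 45°, 90°,
135°).  Pairs are tabulated symmetrically and pooled across offsets into
one normalised matrix per window; entropy uses the natural logarithm.
Degenerate cases are pinned: a constant window has entropy = contrast =
variance = 0, homogeneity = 1, and correlation is given the sentinel 0
(zero variance).  The implementation is a vectorised plane-accumulation;
tests compare it against an independent per-window brute-force tabulation.

**Terrain.**  Central differences on the 4-neighborhood; slope in
degrees; aspect measured clockwise from north toward the downslope
direction, in [0, 360); flat cells get aspect 0 plus a flag.

## Temporally stable sample refinement

Candidate samples representative of a single epoch are certified before
reuse across the mapping period:

* **non-wetland**: removed if any multi-epoch land-cover map labels them
  water or wetland in any epoch;
* **vegetated wetland** (swamp, marsh, mangrove, salt marsh): removed if
  the inter-annual NDVI 90th-percentile series is flagged by the change
  detector below;
* **flats** (tidal, flooded): removed if any year's maximum LTideI is
  negative (a real flat exposes, and scores positive, at low water every
  year); exactly 0 is retained ("less than 0" discards);
* **permanent water**: must be water in every year;
* **saline**: passed through — sparse, regionally concentrated, assumed
  pre-vetted by visual interpretation.

Samples with gaps in a required series are removed with reason
`incomplete-series` rather than imputed: stability cannot be certified on
gaps.  Refinement is idempotent and order-invariant.

**Change detector.**  Production change-detection tools (temporal
segmentation of disturbance trajectories) are here reduced to their
contract — a boolean change flag on a short annual series — implemented as
a greedy piecewise-linear fit (≤ 3 segments, ≥ 2 points each, splits
chosen by maximal SSE reduction).  A series is flagged when any fitted
segment's start-to-end change, or the fitted step between adjacent
segments, exceeds 0.2 NDVI in absolute value.  A secondary trigger on the
RMSE improvement of segmentation over a single line exists but defaults to
disabled: on series of ≤ 23 points a 3-segment fit almost always improves
RMSE substantially by chance, so magnitude is the trustworthy signal.  At
these defaults the detector flags 100% of injected 0.4-NDVI steps and 0%
of stable noisy series (σ = 0.02) in the packaged experiment; real NDVI
series are noisier and less step-like, so those rates are upper bounds.

Note an interaction with observation density: with 12 observations per
year and 20% tidal exposure, a given year has no exposed low-tide date
with probability 0.8¹² ≈ 7%, and over a five-year run some year is
tide-blind with probability ≈ 30%.  In such a year tidal flats are
water-covered on every observed date — unobservable by construction — so
the flat rule legitimately removes the affected samples and the maps of a
tide-blind run lose the tidal-flat class while all other classes stay
near-perfect.  This is the rule and the compositing working as designed
on sparse observations, not a defect; the real archive is denser.

## Local-adaptive classification

The globe is partitioned into 5°×5° tiles, half-open `[min, min+5)` in
both axes so every sample and pixel belongs to exactly one tile.  The
active-tile set is derived from the data (tiles containing ≥ 1 sample or
pixel) rather than from an external land mask.  A tile's training set is
the union of samples in its 3×3 neighborhood (longitude wraps, poles
clip), capped at 24 000 by stratified down-sampling: allocation is
proportional to class availability with largest-remainder rounding
(class proportions preserved to ±1 sample), except that classes whose
share would fall below min(2 000, available) are pinned at that floor
first.  The published description fixes the 2 000–24 000 range but not the
reduction rule; this allocation is the package's declared choice.  The
classifier is a library random forest (100 trees, library defaults,
seeded); everything around it — tiling, pooling, schema checking,
mosaicking — is bespoke.  Per-tile predictions partition space, so
mosaicking needs no blending.

## Spatiotemporal consistency optimization

Per pixel-year, the homogeneity probability is the fraction of the
3×3×3 window (half-sizes `w = (1,1,1)`) sharing the center's label.  `N`
normalises by the in-bounds, non-nodata cell count by default; the stated
window volume (27) is dimensionally ambiguous in print, so a config switch
(`boundary="fixed"`) provides the alternative reading — fixed N = 27 with
boundary pixels left unmodified.

Decision per cell, evaluated simultaneously on the original cube (one
pass, order-independent):

1. `P_exact ≥ 0.5` → keep;
2. `P_exact < 0.5` and `P_group > 1/3` → keep (a within-group flip is a
   water-level state, not a land-cover change);
3. `P_group ≤ 1/3` → relabel to the window-majority label.

The boundary at exactly 1/3 relabels, leaving no dead zone; this is a
documented choice tested explicitly.  Majority ties prefer the label at
t−1, then t+1, then the lowest class code.  Groups are a static partition:
{inland permanent water 180, flooded flat 183, marsh 182},
{ocean 255, tidal flat 187, salt marsh 186}, and singletons for swamp,
mangrove, saline and non-wetland.  Because the label set distinguishes
inland water (180) from ocean (255), no per-pixel coastal flag is needed
to disambiguate "permanent water" between the two groups.  Multi-pass
iteration and soft relabeling are out of scope.

## Accuracy assessment

Sample sizes follow the classical stratified design
`n = (Σ W_i √(p_i(1−p_i)))² / ((d/t)² + Σ W_i p_i(1−p_i)/N)` with
anticipated accuracies `p_i` supplied by the user; per-stratum sizes are
proportional to `W_i p_i(1−p_i)` with largest-remainder rounding so they
sum exactly to the integer total.

The error matrix stores class *proportions* (% of area), reference classes
in rows and map classes in columns.  OA = trace/total;
Kappa = (p_o − p_e)/(1 − p_e); PA and UA are the row- and
column-conditional diagonals.  Published tables carry independently
rounded marginals; when stored, they are used as PA/UA denominators to
avoid compounding cell rounding.  With the packaged 2020 table this
reproduces OA = 86.95% and Kappa = 0.822 exactly at printed precision and
every printed PA/UA to ±0.02 except flooded-flat PA, where the printed
cells (1.747/2.791 = 62.59) are inconsistent with the printed 62.62 at
the table's own 3-decimal precision — a ±0.03 rounding envelope on a
2.8% stratum.  The discrepancy is in the source table, not recoverable by
any estimator reading it.

Standard errors use the stratified-proportion estimator (map classes as
strata) with user-supplied per-stratum counts; the estimator behind the
published ± values is unnamed in print, so SEs are validated for order of
magnitude, not equality.

## Synthetic scenes

The generator produces what the method needs to be exercised, and no more:

* per-class Gaussian band reflectance around fixed means, clipped to
  [0, 1], with well-separated defaults;
* water-level dynamics — tidal classes expose on independent Bernoulli
  dates (tidal flat 0.2, salt marsh 0.6), flooded flats follow a
  deterministic day-of-year sinusoid (half the year inundated), permanent
  water/ocean never expose;
* a sinusoidal growing-season cycle on vegetated classes (NIR up, red
  down, peak ≈ day 120);
* contiguous cloud blobs (thresholded smoothed noise) rather than i.i.d.
  pixel masks, so mask-aware compositing is genuinely exercised;
* a DEM 10 m lower over wetlands with smooth correlated noise;
* step change events (class→class in a region from a given year) to feed
  the change detector and the optimizer.

Defaults: 128×128 pixels, 12 dates/year, 8 years, 10% cloud; the shipped
demo and test configurations use 48–64 px scenes, 8–10 dates and 5–6
years so the full pipeline runs in seconds to minutes on one CPU.  Every
output is a pure function of (config, seed).

Not emulated: radiative transfer, sensor cross-calibration, atmospheric
residuals, spatially textured class interiors, gradual transitions, mixed
pixels.  Consequently the end-to-end accuracies near 1.0 certify the
*machinery* — feature plumbing, schema discipline, seeded determinism,
rule logic — under conditions where failure would indicate a defect; they
say nothing quantitative about accuracy on real imagery, for which the
packaged published error matrix is the reference point.

## Delivery format

Annual maps are written as one-band-per-year GeoTIFFs in geographic WGS84
(pixel-is-area, upper-left origin) with class codes 180–187, 0
(non-wetland) and 255 (ocean), tile names
`<prefix>_<period>_E115N30` from the upper-left corner (longitude
zero-padded to 3 digits, latitude to 2; the parser accepts unpadded
names since the published wildcard does not fix padding).  255 keeps its
ocean semantics: genuinely unobserved pixels go to a sidecar mask file
instead of overloading a label.  Round-trips are bit-exact.
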