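# Methods

## Overview

`tsvf` classifies land cover from a T-date, B-band reflectance stack by
reducing each pixel's per-parameter time series to five vector features,
selecting features by normalized Gini importance with an out-of-bag (OOB)
criterion, and classifying with a random forest. This note records the
model, the conventions chosen where several were defensible, what the
synthetic scenes do and do not emulate, and the problem sizes the default
runs use.

## Time-series vectors and features

A parameter is a spectral band or a vegetation index; its per-pixel values
ordered by acquisition date form the vector V_p of length T (T ≥ 2
required; any non-finite component invalidates the pixel for that
parameter). Against the all-ones reference V_0 the five features are
Max, Min, Ran = Max − Min, Cos and Dis.

Two conventions deserve comment:

* **Cos** is the true cosine similarity, with the square root in the
  denominator, so |Cos| ≤ 1 always holds. A `cosine_literal=True` flag
  computes the un-rooted variant (sum of squares in the denominator) for
  comparison with formulations that omit the radical.
* **Dis** defaults to the *squared* Euclidean distance Σ(V_0 − V_p)².
  For tree-based classifiers a strictly monotone transform of a feature
  changes nothing, so the cheaper squared form is kept;
  `rooted_distance=True` gives the metric distance.

Because V_0 is constant, all five features are invariant to permutations
of the time axis: temporal *ordering* carries no information, only which
acquisitions are included and what values they take. Cos is additionally
invariant to positive rescaling of V_p (it measures trajectory shape
"flatness"), which is why it is robust to the substrate-brightness
variability described below, while Dis/Max/Min/Ran are not.

## Vegetation-index bank

23 indices are registered (SAVI, TSAVI, MSAVI, MSAVI2, DVI, RVI, PVI,
IPVI, WDVI, TNDVI, GNDVI, GEMI, ARVI, NDI45, MTCI, MCARI, S2REP, IRECI,
PSSR, NDVI, NDVI705, EVI, EVI2), with formulas following the Sentinel-2
toolbox conventions on L2A-style surface reflectance. Empirical constants
are configurable with documented defaults: SAVI soil-adjustment L = 0.5,
soil-line slope 0.5 / intercept 0.5 (TSAVI, MSAVI, PVI), TSAVI adjustment
X = 0.08, WDVI slope g = 0.5, ARVI gamma = 1. Aliases IECI→IRECI,
PSSRA→PSSR and REIP→S2REP absorb naming drift between published tables.
All indices are unitless except S2REP (red-edge inflection wavelength,
nm).

Indices can be legitimately undefined: TNDVI's radicand is negative where
NDVI < −0.5 (dark water), and MTCI/S2REP denominators vanish where
adjacent red-edge bands coincide. Index evaluation records these as NaN
with per-index counts. Before feature extraction the pipeline replaces
such NaNs (at otherwise valid pixels) with 0 so no sample row is lost;
for tree classifiers only the consistency of the convention matters, not
the filled constant. Pass `undefined_fill=None` to keep NaNs instead.

## Rasters and normalization

Rasters are multiband TIFFs, one per acquisition date, with grid metadata
(CRS string, GDAL-style affine 6-tuple, band names, nodata) serialized as
JSON in the TIFF description tag; a `date,path` CSV manifest orders them.
Pixel centers carry the map coordinates; rasters are north-up in one CRS.
Dates whose rasters are coarser than the reference grid are resampled
bilinearly (nearest-neighbour by flag). A pixel is valid only if valid at
every date and band — no gap filling is attempted, matching workflows
built on near-cloudless scene selection.

`normalize_bands` offers `scale10000` (divide stored digital numbers by
10 000, the L2A reflectance convention — the default, since the index
formulas assume physical reflectance) and `minmax_per_band` (per-band
min/max pooled over all dates; idempotent; errors on constant bands).

## Importance, grouping and selection

Feature importance is mean decrease in impurity: the Gini impurity drop
credited to a feature summed over every split of every tree, normalized
to S_f with Σ S_f = 1 (hence mean S_f = 1/180 ≈ 0.0056 for the full
table). The implementation delegates the accumulation to the forest's
tree builder, which weights child impurities by child sample fractions —
the standard convention; an unweighted G − (G_L + G_R) variant appears in
some formula listings but is not what library tree builders accumulate,
and the weighted form is used deliberately.

Groups keep features with S_f strictly above each threshold of a
decreasing ladder (default 0.1, 0.04, 0.02, 0), so groups nest. The
thresholds are configuration, chosen by inspection of the ranked-score
curve in the reference workflow; no automatic knee detection is
attempted. On scenes where importance is diffuse the top groups can be
empty; they are dropped with a warning rather than an error.

"Prediction accuracy" for the selection curves is measured on a seeded
stratified 30 % hold-out of the *training* samples, keeping validation
pixels untouched; OOB error is the forest's internal estimate from the
per-tree out-of-bag samples (each bootstrap resample of size n contains
on average 1 − (1 − 1/n)^n → 63.2 % distinct samples; the complement is
out of bag). The selected group maximizes peak prediction accuracy, ties
broken by lower OOB error then fewer features; the tree count is the
smallest on the plateau (within 0.002 absolute accuracy of the peak).
The full tree grid is {50, 100, …, 1000}; the bundled reference pipeline
uses {50, 100, 200, 400} as its selection grid, a choice of problem size
that preserves the plateau behaviour on the default scenes.

## Classifiers

* **Random forest**: bootstrap-sampled trees, majority vote, seeded;
  the model stores its feature-name contract and refuses prediction on
  mismatched columns. Full-scene prediction is tiled (output-invariant).
* **Maximum likelihood** is implemented from first principles (the
  remote-sensing form is not in standard ML libraries): per-class
  Gaussian mean, covariance and prior; classification by the largest
  discriminant g_i(x) = ln π_i − ½ ln|Σ_i| − ½ (x−μ_i)ᵀ Σ_i⁻¹ (x−μ_i),
  computed via Cholesky factors; ties break by class order. Covariances
  receive ε·scale·I regularization (default ε = 1e−6, scale the mean
  diagonal) because per-class sample counts are often below the feature
  dimension; ε = 0 enforces well-conditioned covariances and errors
  otherwise. With equal priors and shared isotropic covariance this
  reduces to nearest-mean classification (asserted in tests).
* **SVM and ANN** are thin adapters over established implementations
  with developer-recommended defaults (RBF SVC and an MLP, both behind a
  standardizing scaler), used as comparators on byte-identical sample
  splits (a checksum of the split is logged).

In the model comparison the comparators consume the stacked multi-date
band values (13 bands × 12 dates) — the standard representation without
engineered temporal features — while the vector-feature forest uses its
selected features. The 6-class scheme (cultivated, woodland, grassland,
water, artificial, bare) has fixed integer codes 1–6 for stable rasters.

## Accuracy assessment

Confusion matrices are oriented rows = reference, columns = prediction,
so producer's accuracy (PA) is row-wise recall and user's accuracy (UA)
column-wise precision; OA = trace/total and kappa = (p_o − p_e)/(1 − p_e)
with p_e from the marginals. Empty reference rows yield NaN PA with a
defined meaning rather than an error. Validation samples off-grid or on
nodata are excluded and tallied. Sub-area evaluation binarizes to
cultivated vs non-cultivated; merging classes before or after counting is
equivalent (asserted). Reports expose proportions internally and
percentages (2 decimals) for presentation.

## Synthetic scenes

The generator emulates one agricultural year over a fragmented
agricultural landscape: 12 monthly acquisitions (October–September), 13
bands, six classes on a seeded Voronoi patch mosaic (default mean patch
≈ 500 px², i.e. ~0.05 km² at 10 m). Per class, reflectance at date t is

    r(t) = b · (1 − v(t)) · background + v(t) · vegetation + noise,

where v(t) is the class's vegetation-fraction trajectory (cultivated:
double-peaked wheat/corn rotation with April and August maxima; woodland:
broad high summer peak; grassland: low summer peak; water, artificial and
bare: zero), `background` is a class substrate spectrum (soil for
cultivated/grassland/bare, darkened soil under woodland, water and
bright-impervious spectra otherwise), b is a per-patch brightness factor
N(1, 0.10) clipped to [0.6, 1.4] modelling substrate variability, and the
noise is i.i.d. Gaussian (default sd 0.02 reflectance) with values
clipped to (0, 1). Pixels within 1.5 px of a Voronoi boundary mix the two
adjacent patches' spectra linearly (truth keeps the nearer class). All
randomness flows from one root seed through named substreams (mosaic,
noise, sampling).

The design makes single-date classification genuinely ambiguous —
off-season cropland is spectrally bare soil, in-season cropland resembles
grassland or woodland, and patch brightness confounds brightness-based
separation — while the annual trajectory of each class is distinctive.
That is precisely the regime the vector features target.

Sampling is stratified and disjoint: by default 10 × B training pixels
per class (130 for 13 bands), capped at 70 for the scarce water and bare
classes, plus 500 validation pixels per class, drawn from pure
(non-boundary) pixels to mirror verified ground-truth points
(`pure_only=False` lifts this).

What the scenes do **not** emulate: atmospheric and cloud artifacts,
sensor PSF and view-angle effects, spatially correlated noise, intra-class
phenological spread (all patches of a class share one trajectory), and
inter-annual variation. Passing tests therefore demonstrate the
correctness and internal consistency of the pipeline and its expected
qualitative behaviour (temporal features beating single-date snapshots),
not accuracy levels attainable on real imagery. On these clean scenes any
classifier given the full multi-date stack — including the MLC/SVM/ANN
comparators — can saturate near 100 %; the discriminating comparison is
against the single-date baseline.

## Problem sizes and runtime defaults

The reference end-to-end run uses a 256 × 256 scene (65 536 pixels, 12
dates, 13 bands, 180 features), 660 training and 3 000 validation pixels,
a 400-tree ranking forest and the {50, 100, 200, 400} selection grid; it
completes in well under a minute on one CPU. Unit tests use 16–64 px
scenes. The bootstrap-fraction simulation uses n = 10 000 with 200
replicates.

## Known limitations

* Per-band (as opposed to per-raster) native resolutions are not
  represented; each date's raster is a single grid.
* The feature table holds all requested pixels in memory; scenes far
  beyond ~10⁶ pixels should be processed in windows (classification
  already tiles).
* Threshold grouping assumes the ranked-score curve has usable structure;
  on diffuse-importance problems groups A/B may be empty and selection
  effectively compares C/D.
* The MLC comparator with stacked multi-date bands relies on covariance
  regularization when class sample counts are below the 156-dimensional
  feature space.
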