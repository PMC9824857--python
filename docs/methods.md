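# Methods

This note documents the models, procedures and design choices in
`yieldreg2d`: what is computed, under which assumptions, and where the
genuinely open decisions were made.

## Problem setting

A field-year pairs an 8-channel covariate raster stack (10 m grid) with an
observed yield raster (bu/ac) over the field cell set *F* (the boolean
mask). Channel order is fixed package-wide: nitrogen (lbs/ac),
precipitation (mm), slope (deg), elevation (m), TPI, aspect (rad), SAR VV
and VH (dB). NoData is NaN internally; yield outside *F* is always NoData.
Models are field-specific: trained and tested on the same field, with
different years — yield response depends strongly on local weather and
soil, so no cross-field transfer is attempted.

## Normalization

Min–max per channel, fitted **only** on masked-true cells of the training
years. Test data is scaled with the stored parameters and *not* clipped: a
test-year precipitation below the training range maps below 0, and the
model is allowed to respond to it — clipping would erase exactly the
out-of-distribution signal the representativeness report is designed to
flag. Degenerate channels (max = min, e.g. precipitation within a single
training year) map to 0. NoData covariate cells become 0 after scaling,
consistent with the zero-valued out-of-field pixels used at prediction
time. Out-of-field zero padding is excluded from the fitted statistics
(mask-only fitting).

## Patch sampling

Training samples are 5×5×*n* covariate windows with a centered *N*×*N*
yield target (the (i,j)-th target pixel maps to window pixel
(i+(W−N)/2, j+(W−N)/2); W−N must be even). Window corners lie on a stride-2
grid: stride 1 would let adjacent windows share 20 of 25 pixels, while
stride 2 caps same-row overlap at 15 pixels — under the 19-pixel overlap
budget that keeps neighboring samples from being near-duplicates. Stride is
config-exposed. A training patch is kept only if all of its yield pixels
are valid (`min_valid_fraction=1.0`); prediction relaxes this, since the
sliding window there visits every field cell regardless.

The validation split is a random 10% of training patches (seeded, patch
level, unstratified). Leave-one-year-out folds assign every observed year
to exactly one test fold; fold A holds out the most recent year. No
test-year value reaches normalization, training or validation.

## Architecture

The network is built exactly as printed in its defining table:

* **3-D feature extractor** — input (5, 5, *n*, 1); four
  Conv3D(32, 3×3×3, padding 1×1×1) + ReLU + BN blocks. After block 2, 3
  and 4 the output is concatenated with everything before it along the
  channel axis: widths 32 → 64 → 96 → 128. The layer order Conv → ReLU →
  BN follows the printed table even though BN-before-activation is the more
  common convention — fidelity over convention.
* **2-D encoder** — the extractor output reshaped to (5, 5, 128·*n*);
  Dropout(0.5); five SepConv2D + ReLU + BN blocks with 512, 320, 256, 128,
  32 channels (3×3 kernels, stride (1,1), padding (1,1)); Dropout(0.5)
  after the second and third blocks. Each separable convolution carries a
  depthwise bias and a pointwise bias. No layer changes the 5×5 spatial
  footprint.
* **Head** — N=5: Conv2D(1, 3×3, pad 1) + ReLU (289 parameters);
  N=3: the same with pad 0; N=1: Conv2D(1, 3×3, pad 0) + ReLU to 3×3,
  flattened into a bias-free FC(9→1) — nine parameters, bias-free to match
  that count; the FC is linear (no activation is printed for it), so the
  N=1 output, unlike the convolutional heads, is not sign-bounded.

The engine behind these layers (`yieldreg2d._nn`) is a compact numpy
implementation with explicit backward passes. Convolutions are evaluated as
sums of shifted channel GEMMs (one per kernel offset), which on the tiny
5×5×*n* volumes involved is substantially faster than materialized im2col.
Every gradient is validated against central finite differences in the test
suite, and Conv3D/SepConv2D forwards are cross-checked against
`scipy.ndimage.correlate`.

Numerical choices: Glorot-uniform initialization with a config-exposed
seed; BatchNorm eps 1e-5, running-statistics keep rate 0.9, biased batch
variance; float32 parameters and activations with float64 optimizer state
and loss accounting. Evaluation-mode forwards are deterministic (dropout
off, running statistics).

## Training

Masked MSE (mean over valid target pixels only) minimized with Adadelta
(rho = 0.95, eps = 1e-6, lr = 1.0 — the published rule, no hand-tuned
learning rate), mini-batches of 96. The epoch budget is not dictated by
the protocol; defaults are max_epochs 500 with early-stopping patience 50
on validation MSE, and the weights returned are those of the best
validation epoch. All of this is config-exposed, and fixed seeds make runs
bit-reproducible on a given platform.

The MLR baseline is ordinary least squares (QR) on per-cell 8-feature
vectors with an intercept; a rank-deficient design (which legitimately
happens when a one-year training set makes normalized precipitation
identically zero) falls back to ridge with lambda = 1e-8 and a warning.

## Map generation

The prediction window slides over **every** masked-true cell (stride 1 —
training-time stride does not apply). Input neighborhoods are taken from
the normalized stack with zeros outside the raster and at out-of-field
cells. Each N×N output window is accumulated at its absolute position into
per-cell sum and count grids; predicted pixels falling outside *F* are
discarded. The final map is sum/count (up to N² = 25 contributions per
cell), NoData exactly off *F*. The accumulator is tested for bit-exact
agreement with a brute-force store-every-contribution oracle. Averaging
overlapping windows is what makes N = 5 maps smoother (lower total
variation) than N = 1 maps from equally trained weights.

## Evaluation

Over *F*: RMSE; RMedSE = sqrt(median of squared errors) — the median
absolute deviation, robust to yield-monitor outliers; Pearson *r* (NaN with
a warning when a map is constant — never a silent 0, since *r* is undefined
there); and the square-error map (M−P)², whose mean over *F* is exactly
RMSE².

SSIM uses uniform (unweighted) w×w windows, constants K1 = 0.01,
K2 = 0.03, and dynamic range L = max−min of the **observed** map over *F*
(the reference image's range; config-exposed). Both maps are zeroed outside
*F* and zero-padded at the raster edge before windowing, so the SSIM map
has the raster's dimensions. This border convention is deliberate: windows
near the field border contain zeros at identical positions in both maps,
which inflates border SSIM relative to a disagreeing interior — a known
artifact of the procedure that the tests reproduce rather than suppress.
SSIM3/SSIM11 are the means of the w = 3 / w = 11 maps over *F*, reported
×100 as SSIM3*/SSIM11*.

## Synthetic field simulator

The simulator emulates the statistical structure of a multi-year OFPE
dataset, not the agronomy of any real field:

* **Terrain** — Gaussian-filtered white noise rescaled to a configured
  relief (default 20 m over a 40×40 grid); slope/aspect from Horn's
  third-order finite differences (the convention of standard DEM products)
  and TPI as elevation minus the 3×3 neighbor mean (simplest standard TPI;
  the neighborhood is config-exposed since no canonical radius exists).
  Border cells replicate edges, which halves gradients along the border —
  terrain identity tests therefore assert on the interior.
* **Nitrogen** — 5×5-cell blocks, each drawing one of the configured rates
  (default 0–150 lbs/ac in six levels), the spatially blocked design of an
  on-farm experiment.
* **Precipitation** — one scalar per field-year broadcast to the raster
  (a 1 km weather product intersected with a small field is effectively
  constant). Defaults 86/130/101 mm for 2016/2018/2020 reproduce a
  realistic wet/dry alternation in which one fold must test on a drier
  year than any it trained on — the data-representativeness failure mode
  the harness flags.
* **SAR** — latent soil moisture = logistic(1.5·precip_z − 1.0·TPI_z +
  smooth noise); VV = −17 + 10·moisture dB, VH = −24 + 6·moisture dB plus
  speckle-like noise. This captures the moisture sensitivity and the
  weaker cross-polarized response; it makes no claim of radiometric
  realism.
* **Yield** — Mitscherlich-type saturating response:
  ymax·N/(N+k) · max(0, 1 + c_p·(precip−ref)) · max(0, 1 − c_t·TPI_z) +
  Gaussian noise, truncated at 0. Defaults: ymax 110 bu/ac, half-saturation
  40 lbs/ac, c_p = 0.006/mm around 100 mm, c_t = 0.15, noise 5 bu/ac.
  Monotone nondecreasing in nitrogen by construction. Any monotone
  saturating form would serve; this one is the agronomic standard and is
  fully config-exposed.
* **Mask** — one connected thresholded-Gaussian blob covering ~85% of the
  raster, shared across years, as is the terrain; nitrogen, SAR and yield
  realizations differ per year. A single seeded generator threads through
  every draw, so a fixed seed reproduces the dataset byte for byte.

What passing tests on this simulator do **not** show: robustness to yield
monitor artifacts, spatial autocorrelation of real soil properties,
growth-stage dynamics, or management effects beyond nitrogen. The
simulator exists to exercise the pipeline's contracts, not to certify
field performance.

## Experiment sizes and protocol choices

The end-to-end leave-one-year-out experiment in the tests and the
acceptance script runs on the default 40×40, 3-year field with low yield
noise (1 bu/ac), 20 training epochs per fold, comparing the N = 5 and
N = 1 heads. Twenty epochs is far short of convergence but suffices for the
qualitative claim under test — the 2-D head's averaged, overlapping
predictions yield lower test-year RMSE and smoother maps than the
single-output head — which is asserted as a majority-of-folds check, not a
per-fold guarantee, because training is stochastic.

The capacity check (overfitting 10 noise-free patches below 1 (bu/ac)²
masked MSE) is run as a capacity check: dropout is disabled — its purpose
is precisely to prevent memorization — and batches of 2 are used so that
500 epochs provide 2500 optimizer steps (a 96-sample mini-batch is
degenerate on a 10-sample fixture and, with Adadelta's conservative
step-size adaptation, plateaus far from the interpolation regime).
Adadelta keeps its default lr = 1.0. Before measuring, BatchNorm running
statistics are recomputed on the fixture in one momentum-0 pass, since the
exponential running average lags the batch statistics by design.

## I/O and formats

Field-years round-trip through two containers: a compressed `.npz` archive
(lossless, bit-identical for finite values) and a multi-band TIFF (bands
1..n covariates in the fixed channel order, band n+1 yield, band n+2 mask)
with a JSON description tag carrying field identity and metadata. Full
CRS/geotransform tags are out of scope; the package consumes already
co-registered rasters and does no reprojection or resampling. Model
checkpoints are `.npz` files with weights, BatchNorm statistics, the
architecture configuration, normalization parameters and a format version
tag.

## Known limitations

* The numpy engine is single-threaded BLAS-bound; training the full-width
  model costs ~1 s per 96-sample batch on one CPU core. Bit-level
  reproducibility holds per platform, not across BLAS implementations.
* The simulator's yield response is smooth and low-dimensional; real
  fields are harder, and the reduced-epoch experiments here demonstrate
  ordering properties, not attainable accuracy.
* SSIM constants and dynamic-range convention follow the standard image
  quality assessment reference; other choices of L would shift SSIM values
  systematically.
* The N = 1 head's linear FC output is not constrained to be nonnegative.
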