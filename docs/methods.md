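# Methods

This note documents the models and procedures implemented in `lfaquant`,
the defaults and why they were chosen, the numerical details, and what the
synthetic-data tests do and do not establish about real assay images.

## Image model and conventions

Images are arrays of shape H×W×C (C ∈ {1, 3}) with values on [0, 1]
regardless of source bit depth: 8-bit input is divided by 255, 16-bit by
65535. Working on a single normalized scale means thresholds, offsets and
extracted signals are comparable across cameras and file formats.
Coordinates are 0-based, row-major, origin top-left; rectangles are
half-open `[row0, row1) × [col0, col1)`. Edits (rotate, flip, crop) are
recorded, not applied destructively; replaying the edit list on the
original reproduces the current image bit-exactly, and `reset` restores the
original. Rotation by multiples of 90° is an exact index permutation; any
other angle uses bilinear interpolation onto the bounding canvas with
zero fill — a choice made for tilted phone photos, at the cost of
interpolation loss (measured ≈ 0.02–0.05 per pixel for a 45° round trip).

## Region-of-interest grid

A region holding S strips with L lines each is tiled into S equal-width
columns and 2L − 1 equal-height rows; rows alternate line / background
starting and ending with a line, so every pair of adjacent lines encloses
one background rectangle (these feed the quantile threshold). Integer
division remainders go to the last row/column, deterministically. Because a
headless tool cannot reproduce interactive grid dragging, irregular band
spacing is supported through explicit boundary fractions
(`row_fractions`, `col_fractions`) in the grid section of the config.

## Background correction

All four methods operate per strip on the [0, 1] scale:

* **Otsu** — maximize between-class variance ω₀ω₁(μ₀ − μ₁)² over the 255
  interior split points of a 256-bin histogram; the threshold is the bin
  *boundary* (k+1)/256. 256 bins matches 8-bit imagers; configurable.
* **Li** — minimum cross-entropy fixed point
  t′ = (μ_low − μ_high)/(ln μ_low − ln μ_high), initialized at the global
  mean, stopped at |t′ − t| < 1e-6 (max 100 iterations; non-convergence
  raises an error carrying the last iterate). Zero-valued pixels would make
  ln μ_low undefined, so all pixels are shifted up by 1/512 before
  iterating and the shift is subtracted from the result.
* **Quantile** — linear-interpolation empirical quantile of the pixels in
  the strip's background rectangles only; default probability q = 0.75
  (an ad-hoc but conservative default: three quarters of the membrane
  pixels fall below the threshold). Unavailable for single-line grids,
  which have no background rectangles.
* **Triangle** — on the 256-bin histogram, the line is drawn from the peak
  bin to the farthest nonzero bin on the longer side; the threshold is the
  center of the bin with maximal perpendicular distance to that line.

Tie-breaks for Otsu and triangle go to the smallest qualifying threshold.
Constant images (or histograms with a single occupied bin) raise a
degenerate-input error rather than returning an arbitrary value. The
user offset is added afterwards and the result clipped to [0, 1].

Pixel pool: Otsu/Li/triangle use every pixel of the strip column (line and
background cells); quantile uses only background cells, per its definition.

## Signal extraction and the monotonicity caveat

Per line cell, signal pixels are those strictly above t; the reported
mean/median is over the background-subtracted values p − t (a raw-value
variant is available via `subtract=False`). Lines with no pixel above
threshold report zeros. This "mean over above-threshold pixels" statistic
is a *mean excess*: it is guaranteed non-increasing in t only when the line
rectangle hugs the band. If the cell includes wide background margins,
raising t past the noise level removes many near-zero excesses and the mean
of the survivors can rise. Consequently the monotonicity guarantee (and its
test) applies to tightly drawn grids — `StripSpec.tight_grid_spec()` builds
one with line cells of half-height 2σ_band around each band center — which
is also how the interactive gridding workflow this tool replaces is used in
practice.

## Intensity tables

Tables are pandas DataFrames with a fixed schema; every row carries its
full provenance (file, strip, line, method, offset, quantile probability,
channel mode, inversion flag). Appending a row with identical keys replaces
the old one with a warning. CSV dialects cover separator (`,`/`;`/tab),
decimal mark (`.`/`,`) and preamble skipping. Merging experiment metadata
is an inner join on user-named key columns; duplicated keys on the
experiment side are an error, unmatched intensity rows are dropped and
counted in the log. Row filtering uses a deliberately restricted predicate
grammar — clauses `column op constant` (`==, !=, <, <=, >, >=, in`)
combined with `and`/`or`/`not` and parentheses — instead of evaluating
arbitrary expressions; this keeps stored configs safe to replay. Line
labels (e.g. `tl`, `cl`) are assigned top-to-bottom at reshape time.

## Calibration

Responses are built per row (ratios first, then any averaging), supporting
a single label, a ratio of two labels, and the share `a/(a+b)`; rows with
vanishing denominators are dropped and logged. Model families:

* **linear** — ordinary least squares via statsmodels;
  R² = 1 − SS_res/SS_tot is reported for this family only.
* **local_poly** — loess: degree-2 weighted polynomial fit at each query
  point over the span fraction (default 0.75) of nearest training points,
  tricube weights, query-centered for conditioning. Implemented in-package
  because the available lowess implementations are locally linear, not
  quadratic.
* **spline_additive** — penalized cubic B-spline regression (basis size
  min(10, #distinct x), knots at quantiles, second-difference coefficient
  penalty) with the penalty λ chosen by generalized cross-validation over a
  29-point log grid from 1e-10 to 1e4.

Linear fits need ≥ 2 distinct concentrations, smoothers ≥ 5. Fitted curves
are probed on a 201-point grid for strict monotonicity; the direction
(+1/−1/0) gates inversion and detection limits. An optional log10
concentration axis is available for assays spanning decades (requires
strictly positive concentrations).

### Detection limits

With ≥ 2 blank (x = 0) replicates, in response units:
LOB = μ_blank + 1.645·σ_blank; LOD = LOB + 1.645·σ_low, where σ_low is the
standard deviation at the lowest nonzero concentration (σ_blank if fewer
than two such replicates); LOQ = μ_blank + 10·σ_blank. The multipliers
(1.645, 1.645, 10) are the standard blank-based convention and are
configurable. Two design choices:

* For a decreasing curve the multipliers are applied downward (in the
  curve's direction), so the limits remain meaningful for responses like
  `cl/tl` that fall with concentration.
* LOQ is floored at LOD. With few replicates σ_low can exceed 5·σ_blank by
  chance, which would put LOD above LOQ; since nothing can be quantified
  below the detection limit, the floor restores the only sensible ordering
  LOB ≤ LOD ≤ LOQ.

Each response-domain limit is inverse-mapped to concentration; a limit
beyond the calibrated range is reported as "> x_max".

## Inverse prediction

Linear models invert in closed form, ĉ = (y − β₀)/β₁ (zero slope is an
error); smoothers by Brent root-finding on [x_min, x_max] with tolerance
1e-8·(x_max − x_min). Responses outside the fitted response range are
clamped to the nearest endpoint and flagged (`above_range` beyond the
high-concentration end, `extrapolated` below the low end) — a conservative
default for a diagnostics context; explicit linear extrapolation is behind
a switch. With detection limits supplied, estimates gain nested
`below_LOQ` ⊇ `below_LOD` ⊇ `below_LOB` flags by concentration comparison.

## Synthetic strip generator

The generator emulates the features the pipeline actually measures: a
uniform membrane background b, per-line bands with Gaussian cross-section
along the flow axis (amplitude a, width σ_band), additive Gaussian pixel
noise, dark or bright polarity, optional RGB tinting, and strips side by
side. Defaults model a small benchtop photo: 120 × 40 px per strip, two
lines (test above control) centered in their grid cells, σ_band = 4 px,
b = 0.85 with dark bands (colorimetric labels), pixel noise σ = 0.02
(≈ 5 gray levels of an 8-bit camera). A calibration series maps
concentration to test-line amplitude through a user function (linear by
default), with 2% multiplicative replicate jitter standing in for
strip-to-strip variability; every image derives deterministically from the
series seed.

Deliberately not modeled: membrane texture, flow fronts, illumination
gradients, lens distortion, and saturation. Passing tests on this
generator therefore establish the correctness of the *computational*
pipeline (segmentation, thresholding, statistics, calibration algebra) and
its noise behavior — not robustness to real-world photographic artifacts,
which requires camera-specific validation.

On noise-free renders the extracted mean signal matches the analytic
Gaussian-profile mean a·σ_band·√(2π)/h (h = cell height) to within 2%, and
the end-to-end pipeline recovers concentrations near-exactly; at default
noise the median relative recovery error at mid-range is ≈ 2–3%.

## Problem sizes

The test suite and the acceptance script use 8-concentration × 3-replicate
series of 120 × 40 px strips, 100-image brute-force threshold comparisons,
and 100-seed simulation ensembles — sizes at which every statistical check
is stable across seeds while the whole suite runs in seconds.

## Known limitations

* No automatic band detection: the grid is user-specified (by design).
* No adaptive/local thresholding or illumination correction.
* No nonlinear parametric calibration families (4PL/5PL) and no
  uncertainty propagation onto predicted concentrations.
* The blank-based limit formulas are one established convention; other
  software may use calibration-slope-based variants and will differ
  numerically.
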