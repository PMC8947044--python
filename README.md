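# lfaquant

Quantitative densitometry for lateral flow assays (LFAs), from strip
photograph to analyte concentration.

Lateral flow assays — immunochromatographic test strips read out as colored
or fluorescent bands — are cheap and fast but, read by eye, only qualitative.
`lfaquant` turns a photo of one or more strips into numbers: it grids the
image into line and background rectangles, removes the membrane background by
intensity thresholding, extracts per-band mean/median signal, fits a
calibration curve against known concentrations with limit-of-blank /
detection / quantification figures of merit, and inverts the curve to
quantify unknowns. A deterministic synthetic strip-image generator with known
ground truth makes the whole pipeline testable without any wet-lab data.

Intended users: assay developers and labs doing image-based readout of
LFAs, gel bands, or similar band-shaped signals, who want a scriptable,
reproducible alternative to interactive densitometry.

## Method

For an image region containing `S` strips with `L` lines each, the grid has
`2L − 1` rows × `S` columns: an extra *background* rectangle is inserted
between consecutive lines (so two lines and three strips give a 3 × 3 grid
with a background middle row). Color images are collapsed to one channel by
the luminance rule `0.2126 R + 0.7152 G + 0.0722 B`, the plain mean
`(R + G + B)/3`, or a single channel; bright-band (fluorescent) images are
inverted, `p → 1 − p`.

Per strip, a background threshold `t` is computed by one of four methods —
Otsu (maximum between-class variance `ω₀ω₁(μ₀ − μ₁)²` over histogram
splits), Li (minimum cross-entropy fixed point
`t' = (μ_low − μ_high)/(ln μ_low − ln μ_high)`), an empirical quantile of the
inter-line background rectangles, or the geometric triangle method — plus an
optional additive offset. Each line's signal is the mean/median of `p − t`
over pixels above `t`, reported top to bottom.

Calibration fits response `y` (a line signal or a normalizing ratio such as
`tl/cl` or `tl/(tl+cl)`) against concentration `x` with a linear model
(`y = β₀ + β₁x`, with R²), degree-2 local polynomial regression (loess), or a
penalized cubic regression spline (GCV-chosen penalty). Detection limits
follow the blank-based convention, in response units
`LOB = μ_blank + 1.645·σ_blank`, `LOD = LOB + 1.645·σ_low`,
`LOQ = μ_blank + 10·σ_blank`, each inverse-mapped through the fitted curve.
Unknowns are quantified by inverting the (strictly monotone) curve, with
range and below-limit flags.

## Worked example

Simulate a calibration series, extract intensities, calibrate, and quantify
an unknown strip — all in-process:

```python
import numpy as np
import lfaquant as lq
from lfaquant import calibration as cal, intensity_table as itab, quantification as quant

# 1. render a calibration series: 8 concentrations x 3 replicates
concs = [0, 0.5, 1, 2, 4, 6, 8, 10]
images, truth = lq.render_calibration_series(
    concs, lambda c: 0.05 * c, replicates=3, seed=7)

# 2. extract band intensities (quantile background correction)
tspec = lq.ThresholdSpec(method="quantile", inverted=True)
table = itab.new_table()
for name, img, grid_spec in images:
    grid = lq.build_grid(grid_spec)
    for tres, lines in lq.analyze_image(img, grid, tspec):
        table = itab.append_records(table, itab.records_from_analysis(name, tres, lines))
print(f"{len(table)} intensity rows from {len(images)} images")

# 3. wide table, tl/cl response, linear calibration
wide = itab.reshape_wide(table, ["tl", "cl"])
conc = truth[truth.line == 0][["file", "concentration"]].drop_duplicates()
wide = itab.merge_experiment(wide, conc, "file", "file")
defn = cal.ResponseDefinition("tl/cl")
data = cal.make_response(wide, defn, "concentration")
model, metrics = cal.fit_calibration(data, "linear", {"response": defn})
b0, b1 = model.params["beta"]
print(f"linear fit: response = {b0:.4f} + {b1:.4f} * concentration, R2 = {metrics.r2:.4f}")
lim = metrics.limits
print(f"LOB = {lim.lob:.3f}, LOD = {lim.lod:.3f}, LOQ = {lim.loq:.3f} (concentration units)")

# 4. quantify an unknown strip
unknown, _, gs = lq.render_strip_image(
    lq.StripSpec(amplitudes=np.array([[0.05 * 5.0, 0.5]]), seed=99))
grid = lq.build_grid(gs)
(tres, lines), = lq.analyze_image(unknown, grid, tspec)
response = lines[0].mean_signal / lines[1].mean_signal
result = quant.invert_calibration(model, response, limits=lim)
print(f"response {response:.4f} -> estimated concentration "
      f"{result.concentration:.2f} (true 5.0), flags: {sorted(result.flags)}")
```

Output:

```
48 intensity rows from 24 images
linear fit: response = 0.0375 + 0.0950 * concentration, R2 = 0.9976
LOB = 0.389, LOD = 0.478, LOQ = 0.865 (concentration units)
response 0.5228 -> estimated concentration 5.11 (true 5.0), flags: []
```

The fitted slope 0.095 is the test/control amplitude ratio per concentration
unit (0.05/0.5 of the generator, slightly offset by the shared background
subtraction); R² = 0.998 and the 2% recovery error reflect the generator's
default pixel noise (σ = 0.02) and 2% replicate jitter. The detection limits
say concentrations below ≈ 0.4 units are indistinguishable from blanks at
this noise level.

The same pipeline is scriptable from the shell:

```sh
lfaquant simulate  --config config.yaml --out-dir sim/ --seed 7
lfaquant analyze   sim/*.png --config config.yaml --out-dir run/
lfaquant calibrate --intensity run/intensity.csv --experiment sim/truth.csv \
                   --config config.yaml --out-dir run/
lfaquant quantify  --intensity wide.csv --model run/model.json --out out.csv
```

`analyze` writes an `intensity.csv` with full provenance (method, offset,
channel, inversion per row) plus a markdown analysis log; `calibrate` writes
`model.json`, a markdown report with the fit, R², and LOB/LOD/LOQ, and a
curve plot.

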