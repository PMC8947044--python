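"""Synthetic lateral-flow-strip images with known ground truth.

The generator renders what a photo of an LFA strip looks like to the
analysis pipeline: a uniform membrane background carrying one band per
signal line with a Gaussian cross-section along the flow direction,
additive Gaussian pixel noise, and optionally several strips side by
side.  Bands are darker than the membrane for colorimetric labels
(``dark_bands``) or brighter for fluorescent ones (``bright_bands``).
Band amplitude is the ground truth the pipeline must recover; a
calibration series makes amplitude a monotone function of analyte
concentration.  Every image is a deterministic function of its seed.

Default geometry and noise emulate a small benchtop photo of one strip:
120 x 40 px per strip, two lines (test above control) of 4 px Gaussian
width, membrane background 0.85, pixel noise sd 0.02 (about 5 gray
levels of an 8-bit camera).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .image_core import RasterImage, Rect, save_image
from .roi_grid import GridSpec


class SpecError(ValueError):
    """A strip spec whose bands do not fit or whose levels leave [0, 1]."""


@dataclass(frozen=True)
class StripSpec:
    """Geometry, photometry and noise of one synthetic strip image."""

    height: int = 120
    strip_width: int = 40
    n_strips: int = 1
    n_lines: int = 2
    #: band center rows, top to bottom; default = midpoints of the line
    #: cells of the implied (2L-1)-row analysis grid
    band_centers: tuple[float, ...] | None = None
    sigma_band: float = 4.0
    #: per-strip, per-line band amplitudes, shape (n_strips, n_lines);
    #: a scalar is broadcast
    amplitudes: object = 0.5
    background: float = 0.85
    sigma_noise: float = 0.02
    polarity: str = "dark_bands"
    #: RGB weights for a tinted 3-channel render; None = single channel
    color_tint: tuple[float, float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.polarity not in ("dark_bands", "bright_bands"):
            raise SpecError("polarity must be 'dark_bands' or 'bright_bands'")
        if self.height < 2 * self.n_lines - 1 or self.strip_width < 1:
            raise SpecError("image too small for the requested line count")
        amp = self.amplitude_matrix()
        if (amp < 0).any() or (amp > 1).any():
            raise SpecError("band amplitudes must lie in [0, 1]")
        if self.polarity == "bright_bands":
            if self.background + amp.max() > 1.0 + 1e-12:
                raise SpecError("background + max amplitude exceeds 1")
        else:
            if self.background - amp.max() < -1e-12:
                raise SpecError("background - max amplitude drops below 0")
        centers = self.centers()
        cell_h = self.height / (2 * self.n_lines - 1)
        for j, c in enumerate(centers):
            lo = 2 * j * cell_h
            hi = lo + cell_h
            if not (lo <= c < hi):
                raise SpecError(
                    f"band {j} center {c} outside its line cell [{lo}, {hi})")

    def centers(self) -> tuple[float, ...]:
        if self.band_centers is not None:
            if len(self.band_centers) != self.n_lines:
                raise SpecError("need one band center per line")
            return tuple(float(c) for c in self.band_centers)
        cell_h = self.height / (2 * self.n_lines - 1)
        return tuple((2 * j + 0.5) * cell_h for j in range(self.n_lines))

    def amplitude_matrix(self) -> np.ndarray:
        amp = np.asarray(self.amplitudes, dtype=np.float64)
        if amp.ndim == 0:
            amp = np.full((self.n_strips, self.n_lines), float(amp))
        elif amp.ndim == 1:
            if amp.size != self.n_lines:
                raise SpecError("1-D amplitudes must have one value per line")
            amp = np.tile(amp, (self.n_strips, 1))
        if amp.shape != (self.n_strips, self.n_lines):
            raise SpecError(
                f"amplitudes shape {amp.shape} != ({self.n_strips}, {self.n_lines})")
        return amp

    @property
    def width(self) -> int:
        return self.strip_width * self.n_strips

    def tight_grid_spec(self, half_height: float | None = None) -> GridSpec:
        """Analysis grid whose line cells hug the bands (center ± 2 sigma).

        This is the grid a careful user would draw: line rectangles just
        covering each band, background rectangles filling the space
        between.  The above-threshold mean of a tight line cell is
        monotone in the threshold, which a loose cell (band plus large
        background margins) does not guarantee.
        """
        hh = 2.0 * self.sigma_band if half_height is None else float(half_height)
        centers = self.centers()
        row0 = max(int(round(centers[0] - hh)), 0)
        row1 = min(int(round(centers[-1] + hh)), self.height)
        region = Rect(row0, 0, row1, self.width)
        bounds: list[float] = []
        for j, c in enumerate(centers):
            if j > 0:
                bounds.append(c - hh)
            if j < self.n_lines - 1:
                bounds.append(c + hh)
        fracs = tuple((b - region.row0) / region.height for b in bounds)
        return GridSpec(region, self.n_lines, self.n_strips,
                        row_fractions=fracs or None)


def render_strip_image(spec: StripSpec) -> tuple[RasterImage, pd.DataFrame, GridSpec]:
    """Render one image: (image, truth table, matching analysis grid spec).

    Pixel value = background ± sum_j a_sj * exp(-(row - center_j)^2 /
    (2 sigma_band^2)) + N(0, sigma_noise), clipped to [0, 1]; the sign is
    minus for dark bands.  The same seed renders a bit-identical image.
    """
    amp = spec.amplitude_matrix()
    centers = np.asarray(spec.centers())
    rows = np.arange(spec.height, dtype=np.float64)
    # (H, L) Gaussian profiles shared by all strips
    prof = np.exp(-((rows[:, None] - centers[None, :]) ** 2)
                  / (2.0 * spec.sigma_band ** 2))
    sign = -1.0 if spec.polarity == "dark_bands" else 1.0
    img = np.full((spec.height, spec.width), spec.background, dtype=np.float64)
    for s in range(spec.n_strips):
        band = (prof * amp[s][None, :]).sum(axis=1)
        c0, c1 = s * spec.strip_width, (s + 1) * spec.strip_width
        img[:, c0:c1] += sign * band[:, None]
    rng = np.random.default_rng(spec.seed)
    if spec.sigma_noise > 0:
        img = img + rng.normal(0.0, spec.sigma_noise, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    if spec.color_tint is not None:
        w = np.asarray(spec.color_tint, dtype=np.float64)
        if w.shape != (3,) or (w < 0).any() or (w > 1).any():
            raise SpecError("color_tint must be three weights in [0, 1]")
        img = np.clip(img[:, :, None] * w[None, None, :], 0.0, 1.0)
    raster = RasterImage(img)

    truth = pd.DataFrame(
        [{"strip": s, "line": j, "amplitude": amp[s, j]}
         for s in range(spec.n_strips) for j in range(spec.n_lines)]
    )
    grid_spec = GridSpec(region=Rect(0, 0, spec.height, spec.width),
                         n_lines=spec.n_lines, n_strips=spec.n_strips)
    return raster, truth, grid_spec


def render_calibration_series(
    concentrations: Sequence[float],
    response_fn: Callable[[float], float],
    spec_base: StripSpec = StripSpec(),
    replicates: int = 3,
    seed: int = 0,
    control_amplitude: float = 0.5,
    replicate_jitter: float = 0.02,
) -> tuple[list[tuple[str, RasterImage, GridSpec]], pd.DataFrame]:
    """Render one image per (concentration, replicate) pair.

    The topmost line is the analyte-dependent test line with amplitude
    ``response_fn(c)``; any further lines (typically one control line)
    get ``control_amplitude``.  Replicates share the concentration but
    differ by seeded multiplicative amplitude jitter (relative sd
    ``replicate_jitter``) and independent pixel noise.  Returns
    ``(name, image, grid spec)`` triples and a truth table with one row
    per (image, strip, line).
    """
    rng = np.random.default_rng(seed)
    images: list[tuple[str, RasterImage, GridSpec]] = []
    truth_rows = []
    for ci, conc in enumerate(concentrations):
        a = float(response_fn(float(conc)))
        if not (0.0 <= a <= 1.0):
            raise SpecError(f"response_fn({conc}) = {a} outside [0, 1]")
        for rep in range(replicates):
            jit = 1.0 + (rng.normal(0.0, replicate_jitter)
                         if replicate_jitter > 0 else 0.0)
            a_rep = float(np.clip(a * jit, 0.0, 1.0))
            amps = np.empty((spec_base.n_strips, spec_base.n_lines))
            amps[:, 0] = a_rep
            if spec_base.n_lines > 1:
                amps[:, 1:] = control_amplitude
            img_seed = int(rng.integers(0, 2 ** 31 - 1))
            spec = replace(spec_base, amplitudes=amps, seed=img_seed)
            name = f"cal_c{ci:02d}_r{rep:02d}.png"
            raster, truth, grid_spec = render_strip_image(spec)
            truth = truth.assign(file=name, replicate=rep, concentration=conc)
            truth_rows.append(truth)
            images.append((name, raster, grid_spec))
    truth_table = pd.concat(truth_rows, ignore_index=True)[
        ["file", "strip", "replicate", "concentration", "line", "amplitude"]
    ]
    return images, truth_table


def write_series(images: list[tuple[str, RasterImage, GridSpec]],
                 truth: pd.DataFrame, out_dir: str | Path) -> Path:
    """Write PNGs + truth.csv + grid.yaml into a directory (CLI backend)."""
    import yaml

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, img, _ in images:
        save_image(img, out_dir / name, bit_depth=16)
    truth.to_csv(out_dir / "truth.csv", index=False)
    grid_spec = images[0][2]
    (out_dir / "grid.yaml").write_text(
        yaml.safe_dump({"grid": grid_spec.to_dict()}, sort_keys=False))
    return out_dir
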