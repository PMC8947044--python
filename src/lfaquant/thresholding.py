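"""Background correction and band-intensity extraction.

A membrane strip has a roughly uniform background with darker (or, for
fluorescent labels, brighter) bands on it.  Background correction picks a
per-strip intensity threshold ``t`` and treats every pixel above ``t`` as
signal; band intensity is then the mean/median of the background-subtracted
signal pixels ``p - t`` within each line rectangle, reported top to bottom.

Four threshold methods are provided, all operating on the [0, 1] scale of a
single-channel image:

* ``otsu`` — maximize the between-class variance w0*w1*(mu0-mu1)^2 over all
  256-bin histogram split points (fully automatic, best for bimodal
  histograms);
* ``li`` — minimum cross-entropy between original and thresholded image via
  the fixed-point iteration t' = (mu_low - mu_high)/(ln mu_low - ln mu_high);
* ``quantile`` — an empirical quantile of the pixels in the background
  rectangles between the lines (semi-automatic);
* ``triangle`` — geometric search on the histogram, best for unimodal
  skewed histograms: the bin farthest from the peak-to-tail line.

An additive offset refines any computed threshold; the result is clipped
back to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .image_core import RasterImage, invert, to_grayscale
from .roi_grid import Grid, cell_pixels, strip_pixels

THRESHOLD_METHODS = ("otsu", "li", "quantile", "triangle")

#: shift applied before Li iteration when zero-valued pixels are present,
#: so that log of the class means is defined; subtracted from the result.
LI_ZERO_SHIFT = 1.0 / 512.0


class DegenerateImageError(ValueError):
    """No separating threshold exists (e.g. constant image)."""


class ConvergenceError(RuntimeError):
    """Iterative threshold search did not converge; carries the last value."""

    def __init__(self, message: str, last_threshold: float):
        super().__init__(message)
        self.last_threshold = last_threshold


class MethodUnavailableError(ValueError):
    """The chosen method cannot run on this grid (e.g. quantile with L=1)."""


@dataclass(frozen=True)
class ThresholdSpec:
    """Settings for one background-correction run."""

    method: str = "otsu"
    offset: float = 0.0
    quantile_prob: float = 0.75
    mode: str = "luminance"  # grayscale conversion: luminance|gray|red|green|blue
    inverted: bool = False
    n_bins: int = 256

    def __post_init__(self) -> None:
        if self.method not in THRESHOLD_METHODS:
            raise ValueError(f"unknown threshold method {self.method!r}")
        if not (0.0 < self.quantile_prob < 1.0):
            raise ValueError("quantile_prob must lie strictly in (0, 1)")
        if not np.isfinite(self.offset):
            raise ValueError("offset must be finite")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


@dataclass(frozen=True)
class ThresholdResult:
    strip: int
    threshold: float
    spec: ThresholdSpec
    n_iterations: int | None = None  # Li only


@dataclass(frozen=True)
class LineIntensity:
    """Signal statistics of one line rectangle (line 0 = topmost)."""

    strip: int
    line: int
    mean_signal: float
    median_signal: float
    n_above: int


class LiThreshold(NamedTuple):
    threshold: float
    n_iterations: int


# ---------------------------------------------------------------------------
# Histogram and threshold methods
# ---------------------------------------------------------------------------

def histogram(pixels: np.ndarray, n_bins: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width histogram of [0, 1] values: (counts, bin centers).

    Pixel p falls in bin floor(p * n_bins); p = 1 goes to the last bin.
    """
    pixels = np.asarray(pixels, dtype=np.float64).ravel()
    if pixels.size == 0:
        raise ValueError("cannot histogram an empty pixel set")
    counts, edges = np.histogram(pixels, bins=n_bins, range=(0.0, 1.0))
    centers = (edges[:-1] + edges[1:]) / 2.0
    return counts, centers


def _check_nondegenerate(pixels: np.ndarray) -> np.ndarray:
    pixels = np.asarray(pixels, dtype=np.float64).ravel()
    if pixels.size == 0:
        raise ValueError("empty pixel set")
    if np.unique(pixels).size < 2:
        raise DegenerateImageError("constant image: no separating threshold")
    return pixels


def threshold_otsu(pixels: np.ndarray, n_bins: int = 256) -> float:
    """Between-class-variance-maximizing threshold.

    Candidates are the interior bin boundaries of the 256-bin histogram;
    the returned t is the boundary (k+1)/n_bins maximizing
    w0*w1*(mu0-mu1)^2, ties broken toward the smallest t.
    """
    pixels = _check_nondegenerate(pixels)
    counts, centers = histogram(pixels, n_bins)
    if np.count_nonzero(counts) < 2:
        raise DegenerateImageError("all pixels fall into one histogram bin")
    total = counts.sum()
    csum = np.cumsum(counts)[:-1].astype(np.float64)        # w0 * N at split k
    cmoment = np.cumsum(counts * centers)[:-1]
    w0 = csum / total
    w1 = 1.0 - w0
    valid = (csum > 0) & (csum < total)
    mu0 = np.where(valid, cmoment / np.maximum(csum, 1), 0.0)
    mu1 = np.where(valid, (cmoment[-1] + counts[-1] * centers[-1] - cmoment)
                   / np.maximum(total - csum, 1), 0.0)
    score = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    k = int(np.argmax(score))  # first maximum = smallest t
    return (k + 1) / n_bins


def threshold_li(pixels: np.ndarray, tol: float = 1e-6,
                 max_iter: int = 100) -> LiThreshold:
    """Minimum cross-entropy threshold (iterative).

    Starting from the global mean, iterate
    ``t' = (mu_low - mu_high) / (ln mu_low - ln mu_high)`` with mu_low the
    mean of pixels <= t and mu_high the mean of pixels > t, until
    |t' - t| < tol.  Zero-valued pixels are shifted up by 1/512 before the
    iteration (the shift is subtracted from the result) so the logs are
    defined.
    """
    pixels = _check_nondegenerate(pixels)
    shift = LI_ZERO_SHIFT if pixels.min() <= 0.0 else 0.0
    p = pixels + shift
    t = float(p.mean())
    for it in range(1, max_iter + 1):
        low = p[p <= t]
        high = p[p > t]
        if low.size == 0 or high.size == 0:
            raise DegenerateImageError(
                "Li iteration produced an empty class; no separating threshold"
            )
        mu_low = float(low.mean())
        mu_high = float(high.mean())
        t_new = (mu_low - mu_high) / (np.log(mu_low) - np.log(mu_high))
        if abs(t_new - t) < tol:
            return LiThreshold(t_new - shift, it)
        t = t_new
    raise ConvergenceError(
        f"Li threshold did not converge in {max_iter} iterations", t - shift
    )


def threshold_quantile(background_pixels: np.ndarray, q: float) -> float:
    """Empirical quantile (linear interpolation) of the background pixels."""
    background_pixels = np.asarray(background_pixels, dtype=np.float64).ravel()
    if background_pixels.size == 0:
        raise ValueError("empty background pixel set")
    if not (0.0 < q < 1.0):
        raise ValueError("quantile probability must lie strictly in (0, 1)")
    return float(np.quantile(background_pixels, q))


def threshold_triangle(pixels: np.ndarray, n_bins: int = 256) -> float:
    """Triangle threshold: bin farthest from the histogram peak-to-tail line.

    The line runs from the peak bin (maximum count) to the farthest nonzero
    bin on the longer side of the peak; t is the center of the bin between
    them with maximal perpendicular distance to that line, ties broken
    toward the smallest t.
    """
    pixels = _check_nondegenerate(pixels)
    counts, centers = histogram(pixels, n_bins)
    nz = np.flatnonzero(counts)
    if nz.size < 2:
        raise DegenerateImageError("all pixels fall into one histogram bin")
    peak = int(np.argmax(counts))
    left_span = peak - nz[0]
    right_span = nz[-1] - peak
    tail = int(nz[-1]) if right_span >= left_span else int(nz[0])
    if tail == peak:
        raise DegenerateImageError("histogram peak coincides with its tail")
    lo, hi = min(peak, tail), max(peak, tail)
    idx = np.arange(lo, hi + 1)
    # perpendicular distance of (i, counts[i]) from the peak->tail segment
    dx = float(tail - peak)
    dy = float(counts[tail] - counts[peak])
    norm = np.hypot(dx, dy)
    dist = np.abs(dy * (idx - peak) - dx * (counts[idx] - counts[peak])) / norm
    best = int(idx[np.argmax(dist)])  # first maximum = smallest t
    return float(centers[best])


def apply_offset(t: float, offset: float) -> float:
    """Shift a threshold by the user offset and clip back into [0, 1]."""
    return float(np.clip(t + offset, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Per-strip pipeline
# ---------------------------------------------------------------------------

def prepare_image(img: RasterImage, spec: ThresholdSpec) -> RasterImage:
    """Grayscale conversion (and optional inversion) ahead of thresholding."""
    out = to_grayscale(img, spec.mode) if img.channels == 3 else img
    if spec.inverted:
        out = invert(out)
    return out


def compute_threshold(img: RasterImage, grid: Grid, strip: int,
                      spec: ThresholdSpec) -> ThresholdResult:
    """Per-strip background threshold, offset applied.

    Otsu/Li/Triangle pool every pixel of the strip column (line and
    background cells alike); quantile uses only the background rectangles,
    and is unavailable for single-line grids, which have none.
    """
    n_iter: int | None = None
    if spec.method == "quantile":
        if not grid.background_rows():
            raise MethodUnavailableError(
                "quantile method needs background rectangles; a 1-line grid has none"
            )
        bg = strip_pixels(img, grid, strip, roles="background")
        t = threshold_quantile(bg, spec.quantile_prob)
    else:
        px = strip_pixels(img, grid, strip, roles="all")
        if spec.method == "otsu":
            t = threshold_otsu(px, spec.n_bins)
        elif spec.method == "li":
            t, n_iter = threshold_li(px)
        else:
            t = threshold_triangle(px, spec.n_bins)
    return ThresholdResult(strip=strip, threshold=apply_offset(t, spec.offset),
                           spec=spec, n_iterations=n_iter)


def extract_line_intensities(img: RasterImage, grid: Grid, strip: int,
                             t: float, subtract: bool = True) -> list[LineIntensity]:
    """Mean/median signal of each line, top to bottom, after background cut.

    Signal pixels are those strictly above ``t``; with ``subtract`` (the
    default) statistics are taken over ``p - t``, otherwise over raw ``p``.
    A line with no pixel above threshold reports zeros.
    """
    out: list[LineIntensity] = []
    for line_idx, row in enumerate(grid.line_rows()):
        px = cell_pixels(img, grid, row, strip)
        above = px[px > t]
        n_above = int(above.size)
        if n_above == 0:
            out.append(LineIntensity(strip, line_idx, 0.0, 0.0, 0))
            continue
        s = above - t if subtract else above
        out.append(LineIntensity(strip, line_idx, float(s.mean()),
                                 float(np.median(s)), n_above))
    return out


def analyze_strip(img: RasterImage, grid: Grid, strip: int, spec: ThresholdSpec,
                  subtract: bool = True) -> tuple[ThresholdResult, list[LineIntensity]]:
    """Threshold one strip of a prepared (single-channel) image and extract lines."""
    tres = compute_threshold(img, grid, strip, spec)
    lines = extract_line_intensities(img, grid, strip, tres.threshold, subtract)
    return tres, lines


def analyze_image(img: RasterImage, grid: Grid, spec: ThresholdSpec,
                  subtract: bool = True) -> list[tuple[ThresholdResult, list[LineIntensity]]]:
    """Run grayscale prep + per-strip analysis over every strip in the grid."""
    prepared = prepare_image(img, spec)
    return [analyze_strip(prepared, grid, s, spec, subtract)
            for s in range(grid.n_strips)]
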