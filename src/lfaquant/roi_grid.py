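"""Region-of-interest grid over a strip image.

A strip image carries ``S`` strips side by side, each with ``L`` signal
lines (bands) stacked top to bottom.  The analysis grid splits the
user-chosen region into ``S`` equal-width columns and ``2L - 1``
equal-height rows: between every two adjacent lines an extra rectangle
is inserted and labelled *background*, so rows alternate
line/background/line/... starting and ending with a line.  The
background rectangles feed the quantile background-correction method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .image_core import GeometryError, RasterImage, Rect

Role = Literal["line", "background"]


@dataclass(frozen=True)
class GridSpec:
    """Region plus line/strip counts; the geometric recipe for a grid."""

    region: Rect
    n_lines: int
    n_strips: int
    #: optional interior boundary positions as fractions of the region height
    #: (length ``2*n_lines - 2``) / width (length ``n_strips - 1``), strictly
    #: increasing in (0, 1); equal subdivision when omitted.
    row_fractions: tuple[float, ...] | None = None
    col_fractions: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_lines < 1 or self.n_strips < 1:
            raise ValueError("n_lines and n_strips must be >= 1")

    @property
    def n_rows(self) -> int:
        return 2 * self.n_lines - 1

    def to_dict(self) -> dict:
        d = {
            "region": list(self.region.as_tuple()),
            "lines": self.n_lines,
            "strips": self.n_strips,
        }
        if self.row_fractions is not None:
            d["row_fractions"] = list(self.row_fractions)
        if self.col_fractions is not None:
            d["col_fractions"] = list(self.col_fractions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(
            region=Rect(*d["region"]),
            n_lines=int(d["lines"]),
            n_strips=int(d["strips"]),
            row_fractions=tuple(d["row_fractions"]) if d.get("row_fractions") else None,
            col_fractions=tuple(d["col_fractions"]) if d.get("col_fractions") else None,
        )


@dataclass(frozen=True)
class Grid:
    """(2L-1) x S lattice of rectangles tiling the region.

    Even rows (0, 2, ...) are signal lines, odd rows are the background
    rectangles between them.
    """

    cells: tuple[tuple[Rect, ...], ...]  # rows x strips
    spec: GridSpec = field(repr=False)

    @property
    def n_rows(self) -> int:
        return len(self.cells)

    @property
    def n_strips(self) -> int:
        return len(self.cells[0])

    @property
    def n_lines(self) -> int:
        return (self.n_rows + 1) // 2

    @staticmethod
    def row_role(row: int) -> Role:
        return "line" if row % 2 == 0 else "background"

    @property
    def roles(self) -> tuple[Role, ...]:
        return tuple(self.row_role(i) for i in range(self.n_rows))

    def line_rows(self) -> list[int]:
        """Grid-row indices of the signal lines, top to bottom."""
        return list(range(0, self.n_rows, 2))

    def background_rows(self) -> list[int]:
        return list(range(1, self.n_rows, 2))


def _boundaries(start: int, stop: int, n: int,
                fractions: tuple[float, ...] | None) -> list[int]:
    """Split [start, stop) into n intervals; remainder goes to the last one."""
    extent = stop - start
    if fractions is not None:
        if len(fractions) != n - 1:
            raise ValueError(
                f"expected {n - 1} boundary fractions, got {len(fractions)}"
            )
        if not all(0.0 < f < 1.0 for f in fractions) or list(fractions) != sorted(
            set(fractions)
        ):
            raise ValueError("boundary fractions must be strictly increasing in (0,1)")
        cuts = [start + int(round(f * extent)) for f in fractions]
    else:
        cuts = [start + (extent // n) * i for i in range(1, n)]
    bounds = [start, *cuts, stop]
    if any(b1 <= b0 for b0, b1 in zip(bounds, bounds[1:])):
        raise GeometryError(
            f"cannot split extent {extent} into {n} non-empty intervals"
        )
    return bounds


def build_grid(spec: GridSpec) -> Grid:
    """Tile the region into the ``(2L-1) x S`` analysis grid.

    Columns get equal widths and rows equal heights (integer division,
    remainder pixels assigned to the last column/row) unless explicit
    boundary fractions are given in the spec.
    """
    region = spec.region
    n_rows = spec.n_rows
    if region.height < n_rows:
        raise GeometryError(
            f"region height {region.height} < required rows {n_rows}"
        )
    if region.width < spec.n_strips:
        raise GeometryError(
            f"region width {region.width} < strip count {spec.n_strips}"
        )
    row_b = _boundaries(region.row0, region.row1, n_rows, spec.row_fractions)
    col_b = _boundaries(region.col0, region.col1, spec.n_strips, spec.col_fractions)
    cells = tuple(
        tuple(
            Rect(row_b[i], col_b[j], row_b[i + 1], col_b[j + 1])
            for j in range(spec.n_strips)
        )
        for i in range(n_rows)
    )
    return Grid(cells=cells, spec=spec)


def cell_pixels(img: RasterImage, grid: Grid, row: int, col: int) -> np.ndarray:
    """Intensities of all pixels inside cell (row, col), flattened."""
    if not (0 <= row < grid.n_rows and 0 <= col < grid.n_strips):
        raise IndexError(f"cell ({row}, {col}) outside {grid.n_rows}x{grid.n_strips} grid")
    r = grid.cells[row][col]
    if r.row1 > img.height or r.col1 > img.width:
        raise GeometryError("grid region does not fit inside the image")
    return img.plane()[r.row0:r.row1, r.col0:r.col1].ravel()


def strip_pixels(img: RasterImage, grid: Grid, col: int,
                 roles: str = "all") -> np.ndarray:
    """Pooled intensities of one strip column, filtered by cell role."""
    if roles == "all":
        rows = range(grid.n_rows)
    elif roles == "line":
        rows = grid.line_rows()
    elif roles == "background":
        rows = grid.background_rows()
    else:
        raise ValueError(f"roles must be 'line', 'background' or 'all', got {roles!r}")
    parts = [cell_pixels(img, grid, i, col) for i in rows]
    if not parts:
        return np.empty(0, dtype=np.float64)
    return np.concatenate(parts)
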