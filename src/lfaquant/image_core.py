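"""Raster image handling for strip photographs.

Images are held as float arrays normalized to [0, 1] regardless of the
bit depth on disk, so that thresholds, offsets and band intensities all
live on a single scale.  Coordinates are 0-based and row-major with the
origin at the top-left; rectangles are half-open ``[row0, row1) x
[col0, col1)``.  Edits (rotate, flip, crop) are non-destructive: an
:class:`EditState` records the original image and the ordered list of
edits, and replaying the edits on the original reproduces the current
image bit-exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

logger = logging.getLogger("lfaquant")

#: RGB -> gray coefficient sets.  ``luminance`` preserves perceived
#: brightness (ITU-R BT.709 primaries); ``gray`` is the plain channel mean.
GRAYSCALE_WEIGHTS = {
    "luminance": (0.2126, 0.7152, 0.0722),
    "gray": (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0),
}
CHANNEL_INDEX = {"red": 0, "green": 1, "blue": 2}


class ImageFormatError(ValueError):
    """Unsupported image layout (channel count, dtype, file content)."""


class GeometryError(ValueError):
    """A rectangle or index that does not fit the image it is applied to."""


@dataclass(frozen=True)
class Rect:
    """Half-open pixel rectangle ``[row0, row1) x [col0, col1)``, 0-based."""

    row0: int
    col0: int
    row1: int
    col1: int

    def __post_init__(self) -> None:
        if not (0 <= self.row0 < self.row1 and 0 <= self.col0 < self.col1):
            raise GeometryError(
                f"invalid rectangle [{self.row0},{self.row1})x[{self.col0},{self.col1})"
            )

    @property
    def height(self) -> int:
        return self.row1 - self.row0

    @property
    def width(self) -> int:
        return self.col1 - self.col0

    @property
    def area(self) -> int:
        return self.height * self.width

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.row0, self.col0, self.row1, self.col1)


@dataclass(frozen=True)
class RasterImage:
    """Pixel array of shape ``H x W x C`` with values in [0, 1], C in {1, 3}."""

    pixels: np.ndarray
    source_path: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim == 2:
            px = px[:, :, np.newaxis]
        if px.ndim != 3 or px.shape[2] not in (1, 3):
            raise ImageFormatError(
                f"expected HxWxC array with C in {{1,3}}, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ImageFormatError(f"empty image of shape {px.shape}")
        if not np.isfinite(px).all():
            raise ImageFormatError("image contains non-finite pixel values")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ImageFormatError("pixel values must lie in [0, 1]")
        px = np.ascontiguousarray(px)
        px.flags.writeable = False
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def channels(self) -> int:
        return self.pixels.shape[2]

    def plane(self) -> np.ndarray:
        """The single channel as a 2-D array (single-channel images only)."""
        if self.channels != 1:
            raise ImageFormatError("plane() requires a single-channel image")
        return self.pixels[:, :, 0]

    def full_rect(self) -> Rect:
        return Rect(0, 0, self.height, self.width)


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------

_SUPPORTED_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}


def load_image(path: str | Path) -> RasterImage:
    """Read a PNG/TIFF/JPEG file and normalize its values to [0, 1].

    8-bit input is divided by 255, 16-bit by 65535; float input is assumed
    to already be on [0, 1] and is clipped.  An RGBA alpha channel is
    dropped with a log entry.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - reraise with the path named
        raise IOError(f"cannot read image file {path}: {exc}") from exc

    if raw.ndim == 3 and raw.shape[2] == 4:
        logger.info("dropping alpha channel of %s", path)
        raw = raw[:, :, :3]
    if raw.ndim == 3 and raw.shape[2] == 2:  # gray + alpha
        logger.info("dropping alpha channel of %s", path)
        raw = raw[:, :, :1]
    if raw.ndim == 3 and raw.shape[2] not in (1, 3):
        raise ImageFormatError(
            f"{path}: unsupported channel count {raw.shape[2]}"
        )
    if raw.ndim not in (2, 3):
        raise ImageFormatError(f"{path}: unsupported array rank {raw.ndim}")

    if raw.dtype == np.uint8:
        px = raw.astype(np.float64) / 255.0
    elif raw.dtype == np.uint16:
        px = raw.astype(np.float64) / 65535.0
    elif np.issubdtype(raw.dtype, np.integer):
        px = raw.astype(np.float64) / float(np.iinfo(raw.dtype).max)
    else:
        px = np.clip(raw.astype(np.float64), 0.0, 1.0)
    return RasterImage(px, source_path=str(path))


def save_image(img: RasterImage, path: str | Path, bit_depth: int = 8) -> None:
    """Write the image, quantizing to 8 or 16 bits.

    Lossless round-trip (to within one quantization step) is guaranteed
    for PNG and TIFF only; JPEG is lossy by nature.
    """
    path = Path(path)
    if path.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise ImageFormatError(f"unsupported output format: {path.suffix!r}")
    if bit_depth == 8:
        data = np.round(img.pixels * 255.0).astype(np.uint8)
    elif bit_depth == 16:
        if path.suffix.lower() in (".jpg", ".jpeg"):
            raise ImageFormatError("JPEG does not support 16-bit output")
        data = np.round(img.pixels * 65535.0).astype(np.uint16)
    else:
        raise ImageFormatError(f"bit_depth must be 8 or 16, got {bit_depth}")
    if data.shape[2] == 1:
        data = data[:, :, 0]
    iio.imwrite(path, data)


# ---------------------------------------------------------------------------
# Non-destructive edits
# ---------------------------------------------------------------------------

def rotate(img: RasterImage, degrees: float) -> RasterImage:
    """Rotate counter-clockwise by ``degrees``.

    Multiples of 90 are exact index permutations; any other angle uses
    bilinear interpolation onto the bounding canvas with out-of-image
    area filled with 0.
    """
    deg = float(degrees) % 360.0
    if deg == 0.0:
        return RasterImage(img.pixels, source_path=img.source_path)
    if deg % 90.0 == 0.0:
        k = int(deg // 90.0)
        return RasterImage(np.rot90(img.pixels, k=k, axes=(0, 1)),
                           source_path=img.source_path)
    out = ndimage.rotate(img.pixels, deg, axes=(1, 0), reshape=True,
                         order=1, mode="constant", cval=0.0, prefilter=False)
    return RasterImage(np.clip(out, 0.0, 1.0), source_path=img.source_path)


def flip(img: RasterImage, axis: str) -> RasterImage:
    """Mirror the image: ``horizontal`` reverses columns, ``vertical`` rows."""
    if axis == "horizontal":
        return RasterImage(img.pixels[:, ::-1, :], source_path=img.source_path)
    if axis == "vertical":
        return RasterImage(img.pixels[::-1, :, :], source_path=img.source_path)
    raise ValueError(f"axis must be 'horizontal' or 'vertical', got {axis!r}")


def crop(img: RasterImage, rect: Rect) -> RasterImage:
    """Extract the half-open rectangle ``rect``; it must lie inside the image."""
    if rect.row1 > img.height or rect.col1 > img.width:
        raise GeometryError(
            f"crop rect {rect.as_tuple()} exceeds image {img.height}x{img.width}"
        )
    return RasterImage(img.pixels[rect.row0:rect.row1, rect.col0:rect.col1, :],
                       source_path=img.source_path)


def to_grayscale(img: RasterImage, mode: str = "luminance") -> RasterImage:
    """Collapse RGB to one channel.

    ``luminance`` uses 0.2126 R + 0.7152 G + 0.0722 B, ``gray`` the plain
    mean (R + G + B)/3, and ``red``/``green``/``blue`` pick that channel
    verbatim.  A single-channel input is returned unchanged with a log note.
    """
    if img.channels == 1:
        logger.info("to_grayscale: image already single-channel, returned as is")
        return img
    if mode in GRAYSCALE_WEIGHTS:
        w = np.asarray(GRAYSCALE_WEIGHTS[mode])
        plane = img.pixels @ w
    elif mode in CHANNEL_INDEX:
        plane = img.pixels[:, :, CHANNEL_INDEX[mode]]
    else:
        raise ValueError(f"unknown grayscale mode {mode!r}")
    return RasterImage(np.clip(plane, 0.0, 1.0), source_path=img.source_path)


def invert(img: RasterImage) -> RasterImage:
    """Photographic negative: every pixel p becomes 1 - p."""
    return RasterImage(1.0 - img.pixels, source_path=img.source_path)


# ---------------------------------------------------------------------------
# Edit history
# ---------------------------------------------------------------------------

#: edit op encoding: ("rotate", degrees) | ("flip", axis) | ("crop", (r0,c0,r1,c1))
EditOp = tuple


def _apply_edit(img: RasterImage, op: EditOp) -> RasterImage:
    name = op[0]
    if name == "rotate":
        return rotate(img, op[1])
    if name == "flip":
        return flip(img, op[1])
    if name == "crop":
        return crop(img, Rect(*op[1]))
    raise ValueError(f"unknown edit operation {name!r}")


@dataclass
class EditState:
    """An image plus its ordered, replayable edit history."""

    original: RasterImage
    edits: list[EditOp] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._current = self.replay()

    @property
    def current(self) -> RasterImage:
        return self._current

    def apply(self, op_name: str, *args) -> RasterImage:
        """Append one edit and return the updated current image."""
        if op_name == "crop" and isinstance(args[0], Rect):
            args = (args[0].as_tuple(),)
        op: EditOp = (op_name, *args)
        new = _apply_edit(self._current, op)
        self.edits.append(op)
        self._current = new
        return new

    def replay(self) -> RasterImage:
        """Re-run every recorded edit on the original image."""
        img = self.original
        for op in self.edits:
            img = _apply_edit(img, op)
        return img

    def reset(self) -> RasterImage:
        """Discard all edits and restore the original image."""
        self.edits.clear()
        self._current = self.original
        return self.original

    def to_dict(self) -> dict:
        return {"edits": [list(op) for op in self.edits]}


def apply_edits(img: RasterImage, edits: Iterable[Sequence]) -> RasterImage:
    """Apply a list of edit-op encodings (as parsed from a config) in order."""
    out = img
    for op in edits:
        op = tuple(op)
        if op[0] == "crop" and not isinstance(op[1], (tuple, list)):
            op = ("crop", tuple(op[1:]))
        elif op[0] == "crop":
            op = ("crop", tuple(op[1]))
        out = _apply_edit(out, op)
    return out
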