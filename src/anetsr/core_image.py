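"""Image containers, TIFF I/O, bit-depth conversion and lossless tiling.

Images are 2D grids of nonnegative integers with an explicit bit depth
(8 or 16) and a physical pixel pitch in nanometres.  The pitch is kept as
an exact :class:`fractions.Fraction` so that repeated halving (e.g. 250 nm
-> 62.5 nm after two interpolation passes) stays exact; rounding to whole
nanometres happens only at display time.

Coordinates are 0-based, row-major, origin at the top-left corner.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "IntensityImage",
    "ImageStack",
    "TileGrid",
    "read_tiff",
    "write_tiff",
    "convert_16_to_8",
    "tile",
    "assemble",
]

_DTYPES = {8: np.uint8, 16: np.uint16}


def _as_fraction(value) -> Fraction:
    """Exact rational from int/float/Fraction (floats convert exactly)."""
    if isinstance(value, Fraction):
        return value
    return Fraction(value)


def display_nm(pitch: Fraction) -> int:
    """Round a pitch to whole nanometres, half away from zero (62.5 -> 63)."""
    d = decimal.Decimal(pitch.numerator) / decimal.Decimal(pitch.denominator)
    return int(d.quantize(decimal.Decimal(1), rounding=decimal.ROUND_HALF_UP))


@dataclass
class IntensityImage:
    """A single-channel nonnegative integer image.

    Parameters
    ----------
    pixels : ndarray
        2D integer array; values must fit in ``[0, 2**bit_depth - 1]``.
    bit_depth : int
        8 or 16.
    pitch_xy : Fraction or number
        Physical pixel interval in nm (exact rational internally).
    """

    pixels: np.ndarray
    bit_depth: int = 16
    pitch_xy: Fraction = Fraction(250)

    def __post_init__(self):
        if self.bit_depth not in _DTYPES:
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError(f"pixels must be 2D, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            raise TypeError(f"pixels must be integer-typed, got {arr.dtype}")
        if arr.size and (arr.min() < 0 or arr.max() > 2**self.bit_depth - 1):
            raise ValueError(
                f"pixel values out of range for {self.bit_depth}-bit image"
            )
        self.pixels = arr.astype(_DTYPES[self.bit_depth])
        self.pitch_xy = _as_fraction(self.pitch_xy)
        if self.pitch_xy <= 0:
            raise ValueError("pitch_xy must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def pitch_display_nm(self) -> int:
        return display_nm(self.pitch_xy)

    def astype_float(self) -> np.ndarray:
        return self.pixels.astype(np.float64)


@dataclass
class ImageStack:
    """An ordered z-stack of same-shaped :class:`IntensityImage` slices."""

    slices: list
    pitch_z: Fraction = Fraction(1000)

    def __post_init__(self):
        if not self.slices:
            raise ValueError("stack must contain at least one slice")
        first = self.slices[0]
        for s in self.slices:
            if s.shape != first.shape:
                raise ValueError("all slices must share the same shape")
            if s.bit_depth != first.bit_depth:
                raise ValueError("all slices must share the same bit depth")
            if s.pitch_xy != first.pitch_xy:
                raise ValueError("all slices must share the same pitch_xy")
        self.pitch_z = _as_fraction(self.pitch_z)
        if self.pitch_z <= 0:
            raise ValueError("pitch_z must be positive")

    def __len__(self) -> int:
        return len(self.slices)

    @property
    def bit_depth(self) -> int:
        return self.slices[0].bit_depth

    @property
    def pitch_xy(self) -> Fraction:
        return self.slices[0].pitch_xy

    def as_array(self) -> np.ndarray:
        """(z, y, x) array view of the stack."""
        return np.stack([s.pixels for s in self.slices])


@dataclass
class TileGrid:
    """Row-major grid of square, non-overlapping tiles of one image."""

    tiles: list
    rows: int
    cols: int
    tile_side: int

    def __post_init__(self):
        if len(self.tiles) != self.rows * self.cols:
            raise ValueError("len(tiles) must equal rows * cols")
        for t in self.tiles:
            if t.shape != (self.tile_side, self.tile_side):
                raise ValueError("all tiles must be square with side tile_side")


def read_tiff(path, pitch_xy=Fraction(250), pitch_z=Fraction(1000)):
    """Read a single-channel grayscale TIFF into an image or stack.

    Multi-page files yield an :class:`ImageStack`.  RGB and float TIFFs are
    rejected.  ``pitch_xy`` / ``pitch_z`` supply physical metadata that plain
    TIFF files do not carry.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(str(path)) as tf:
        pages = [p.asarray() for p in tf.pages]
    imgs = []
    for arr in pages:
        if arr.ndim != 2:
            raise ValueError(f"unsupported TIFF: expected single channel, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError(f"unsupported TIFF: non-integer dtype {arr.dtype}")
        if arr.dtype.itemsize == 1:
            depth = 8
        elif arr.dtype.itemsize == 2:
            depth = 16
        else:
            raise ValueError(f"unsupported TIFF bit depth: {arr.dtype}")
        imgs.append(IntensityImage(arr, bit_depth=depth, pitch_xy=pitch_xy))
    if len(imgs) == 1:
        return imgs[0]
    return ImageStack(imgs, pitch_z=pitch_z)


def write_tiff(path, img) -> None:
    """Write an :class:`IntensityImage` or :class:`ImageStack` losslessly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(img, ImageStack):
        tifffile.imwrite(str(path), img.as_array(), photometric="minisblack")
    elif isinstance(img, IntensityImage):
        tifffile.imwrite(str(path), img.pixels, photometric="minisblack")
    else:
        raise TypeError(f"cannot write object of type {type(img).__name__}")


def convert_16_to_8(img: IntensityImage, minmax: bool = False) -> IntensityImage:
    """Project a 16-bit image onto 8 bits.

    Default is fixed full-range scaling ``round(v * 255 / 65535)`` so that
    intensities stay comparable across images; ``minmax=True`` stretches the
    image's own min-max range instead.
    """
    if img.bit_depth != 16:
        raise ValueError("convert_16_to_8 requires a 16-bit input image")
    v = img.astype_float()
    if minmax:
        lo, hi = v.min(), v.max()
        scaled = np.zeros_like(v) if hi == lo else (v - lo) * 255.0 / (hi - lo)
    else:
        scaled = v * 255.0 / 65535.0
    out = np.floor(scaled + 0.5).astype(np.uint8)  # round half up
    return IntensityImage(out, bit_depth=8, pitch_xy=img.pitch_xy)


def tile(img: IntensityImage, tile_side: int) -> TileGrid:
    """Split an image into non-overlapping row-major square tiles."""
    h, w = img.shape
    if tile_side <= 0:
        raise ValueError("tile_side must be positive")
    if h % tile_side or w % tile_side:
        raise ValueError(
            f"image sides {h}x{w} not divisible by tile_side {tile_side}"
        )
    rows, cols = h // tile_side, w // tile_side
    tiles = []
    for r in range(rows):
        for c in range(cols):
            block = img.pixels[
                r * tile_side : (r + 1) * tile_side,
                c * tile_side : (c + 1) * tile_side,
            ]
            tiles.append(
                IntensityImage(block.copy(), bit_depth=img.bit_depth, pitch_xy=img.pitch_xy)
            )
    return TileGrid(tiles=tiles, rows=rows, cols=cols, tile_side=tile_side)


def assemble(grid: TileGrid) -> IntensityImage:
    """Reassemble a :class:`TileGrid` into the original image (exact inverse
    of :func:`tile`; tiles are disjoint so no blending is involved)."""
    first = grid.tiles[0]
    for t in grid.tiles:
        if t.shape != first.shape or t.bit_depth != first.bit_depth:
            raise ValueError("inconsistent tiles")
    s = grid.tile_side
    out = np.zeros((grid.rows * s, grid.cols * s), dtype=_DTYPES[first.bit_depth])
    for i, t in enumerate(grid.tiles):
        r, c = divmod(i, grid.cols)
        out[r * s : (r + 1) * s, c * s : (c + 1) * s] = t.pixels
    return IntensityImage(out, bit_depth=first.bit_depth, pitch_xy=first.pitch_xy)
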