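"""The 13 geometry features of a binary tongue mask.

The feature set combines extents (width w, length l), their ratio lw, the
smaller half distance z, the center distance cd and its ratio cdr, the
foreground area a, and three reference areas inscribed via z — a circle
(ca), a square (sa) and a triangle spanning the extreme points (ta) —
each with its ratio to a.

Conventions
-----------
* Coordinates are 0-based with y increasing downward (tongue tip at
  large y, root at small y).
* w and l are pixel extents, ``max − min + 1``, so that an N-pixel run
  has length N and a fully filled W×H rectangle has a = l·w.  Under this
  convention the rectangularity ratio a/(l·w) attains its maximum of 1
  exactly on filled rectangles.
* cd is reported as an absolute distance; the signed offset is available
  via ``center_distance(..., signed=True)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mask_io import BinaryMask

#: The 13 features in canonical order; feature i (1-based, canonical numbering)
#: is FEATURE_NAMES[i-1].
FEATURE_NAMES = (
    "w", "l", "lw", "z", "cd", "cdr", "a", "ca", "car", "sa", "sar", "ta", "tar",
)


@dataclass(frozen=True)
class ExtentBox:
    """Minimal axis-aligned bounding box of the foreground.

    ``y_cp`` is the vertical center ``(y_max + y_min)/2`` (may be a
    half-integer).  Every foreground pixel lies inside the box and at
    least one touches each of the four edges.
    """

    x_min: int
    x_max: int
    y_min: int
    y_max: int

    @property
    def y_cp(self) -> float:
        return (self.y_max + self.y_min) / 2.0


@dataclass(frozen=True)
class GeometryFeatures:
    """The 13 geometry feature values of one mask.

    w, l are in pixels; z, cd in pixels; a, ca, sa, ta in pixels²; the
    remaining five are dimensionless ratios.  a is an exact integer
    count.
    """

    w: float
    l: float
    lw: float
    z: float
    cd: float
    cdr: float
    a: int
    ca: float
    car: float
    sa: float
    sar: float
    ta: float
    tar: float

    def as_array(self) -> np.ndarray:
        """The features as a float vector in FEATURE_NAMES order."""
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)


def compute_extents(mask: BinaryMask) -> ExtentBox:
    """Minimal bounding box of the foreground pixels."""
    ys, xs = np.nonzero(mask.grid)
    return ExtentBox(
        x_min=int(xs.min()),
        x_max=int(xs.max()),
        y_min=int(ys.min()),
        y_max=int(ys.max()),
    )


def _column_bottom(mask: BinaryMask, col: int) -> int:
    """Largest y among foreground pixels in column ``col``."""
    ys = np.nonzero(mask.grid[:, col])[0]
    if ys.size == 0:
        raise ValueError(f"column {col} contains no foreground pixels")
    return int(ys.max())


def center_distance(mask: BinaryMask, ext: ExtentBox, signed: bool = False) -> float:
    """Vertical offset of the extreme-column bottom points from y_cp.

    The reference height is the mean of the lowest foreground y in the
    leftmost and rightmost occupied columns; the result is its distance
    to the bounding-box vertical center ``y_cp``.  By default the
    absolute value is returned; ``signed=True`` keeps the raw offset
    (positive = below center) as a diagnostic.
    """
    ref = (_column_bottom(mask, ext.x_max) + _column_bottom(mask, ext.x_min)) / 2.0
    off = ref - ext.y_cp
    return off if signed else abs(off)


def _row_median_x(mask: BinaryMask, row: int) -> int:
    """Lower median of foreground x in row ``row``."""
    xs = np.nonzero(mask.grid[row, :])[0]
    if xs.size == 0:
        raise ValueError(f"row {row} contains no foreground pixels")
    return int(xs[(xs.size - 1) // 2])


def triangle_area(mask: BinaryMask, ext: ExtentBox) -> float:
    """Shoelace area of the triangle spanning the mask's extreme points.

    Vertices: L = (x_min, bottom-most y in that column), R = (x_max,
    bottom-most y in that column), B = (median x in the bottom row,
    y_max).  Degenerate (collinear) configurations give 0.
    """
    lx, ly = ext.x_min, _column_bottom(mask, ext.x_min)
    rx, ry = ext.x_max, _column_bottom(mask, ext.x_max)
    bx, by = _row_median_x(mask, ext.y_max), ext.y_max
    return abs(
        lx * (ry - by) + rx * (by - ly) + bx * (ly - ry)
    ) / 2.0


def compute_features(mask: BinaryMask) -> GeometryFeatures:
    """Compute all 13 geometry features of a mask.

    The ratios satisfy ``lw·w = l``, ``car·a = ca``, ``sar·a = sa`` and
    ``tar·a = ta`` by construction; all values are finite for any valid
    mask, including single-pixel and single-row/column masks.
    """
    ext = compute_extents(mask)
    w = float(ext.x_max - ext.x_min + 1)
    l = float(ext.y_max - ext.y_min + 1)
    lw = l / w
    z = min(l, w) / 2.0
    cd = center_distance(mask, ext)
    cdr = cd / l
    a = int(mask.grid.sum())
    ca = math.pi * z * z
    sa = 4.0 * z * z
    ta = triangle_area(mask, ext)
    return GeometryFeatures(
        w=w, l=l, lw=lw, z=z, cd=cd, cdr=cdr, a=a,
        ca=ca, car=ca / a, sa=sa, sar=sa / a, ta=ta, tar=ta / a,
    )
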