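"""Reading and writing binary tongue masks and feature tables.

Masks come from an upstream segmentation step and are stored as 1-bit or
8-bit raster images (PNG/BMP).  Multi-channel inputs are collapsed by
standard luminance weights before thresholding.  Feature tables are plain
comma-delimited CSV with a fixed header.
"""

from __future__ import annotations

import csv
import os
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError


class MaskReadError(ValueError):
    """Raised when an image file cannot be read or decoded as a mask."""


class EmptyMaskError(ValueError):
    """Raised when a mask contains no foreground pixels."""


class BinaryMask:
    """A 2-D boolean grid of tongue foreground in image coordinates.

    ``grid[y, x]`` is True where the tongue is present.  Coordinates are
    0-based; x is the column index increasing rightward, y the row index
    increasing downward, so the tongue tip lies toward larger y and the
    root toward smaller y.

    At least one foreground pixel is required; this is enforced at
    construction.
    """

    __slots__ = ("grid",)

    def __init__(self, grid: np.ndarray) -> None:
        arr = np.asarray(grid)
        if arr.ndim != 2:
            raise ValueError(f"mask grid must be 2-D, got shape {arr.shape}")
        arr = arr.astype(bool)
        if not arr.any():
            raise EmptyMaskError("mask contains no foreground pixels")
        arr.setflags(write=False)
        self.grid = arr

    @property
    def height(self) -> int:
        return self.grid.shape[0]

    @property
    def width_px(self) -> int:
        return self.grid.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryMask):
            return NotImplemented
        return self.grid.shape == other.grid.shape and bool(
            np.array_equal(self.grid, other.grid)
        )

    def __hash__(self) -> int:  # immutable enough for set/dict use
        return hash((self.grid.shape, self.grid.tobytes()))

    def __repr__(self) -> str:
        return (
            f"BinaryMask({self.height}x{self.width_px}, "
            f"{int(self.grid.sum())} foreground px)"
        )


#: Column order of the 13 features in CSV output (canonical numbering).
CSV_FEATURE_COLUMNS = (
    "w", "l", "lw", "z", "cd", "cdr", "a", "ca", "car", "sa", "sar", "ta", "tar",
)


def read_mask(path: os.PathLike | str, threshold: int = 128) -> BinaryMask:
    """Read a raster image and threshold it into a BinaryMask.

    A pixel is foreground iff its intensity is >= ``threshold`` (default
    128), so the common {0, 255} encoding is split symmetrically.
    Multi-channel images are converted to single-channel luminance first.

    Raises
    ------
    MaskReadError
        If the file does not exist or cannot be decoded as an image.
    EmptyMaskError
        If no pixel reaches the threshold.
    """
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold must be in [0, 255], got {threshold}")
    try:
        with Image.open(path) as img:
            if img.mode == "1":
                arr = np.asarray(img, dtype=bool).astype(np.uint8) * 255
            elif img.mode == "L":
                arr = np.asarray(img, dtype=np.uint8)
            else:
                arr = np.asarray(img.convert("L"), dtype=np.uint8)
    except (FileNotFoundError, UnidentifiedImageError, OSError) as exc:
        raise MaskReadError(f"cannot read mask image {path!r}: {exc}") from exc
    return BinaryMask(arr >= threshold)


def write_mask(mask: BinaryMask, path: os.PathLike | str) -> None:
    """Write a mask as an 8-bit image (0 background, 255 foreground).

    PNG and BMP are lossless, so ``read_mask(write_mask(m))`` round-trips
    exactly with the default threshold.
    """
    img = Image.fromarray(mask.grid.astype(np.uint8) * 255, mode="L")
    img.save(path)


def write_features_csv(
    records: Sequence[Tuple[str, "GeometryFeatures", Optional[str]] | Tuple[str, "GeometryFeatures"]],
    path: os.PathLike | str,
) -> None:
    """Write (id, features[, shape label]) records to CSV.

    Header is ``id,w,l,lw,z,cd,cdr,a,ca,car,sa,sar,ta,tar`` with a final
    ``shape`` column iff any record carries a label.  Floats are written
    at full precision so read-back round-trips to equal values.
    """
    if len(records) == 0:
        raise ValueError("record list is empty")
    any_label = any(len(rec) > 2 and rec[2] is not None for rec in records)
    header = ["id", *CSV_FEATURE_COLUMNS] + (["shape"] if any_label else [])
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for rec in records:
            sample_id, feats = rec[0], rec[1]
            label = rec[2] if len(rec) > 2 else None
            # repr() is the shortest exact decimal form, so read-back
            # reproduces the binary value bit for bit
            row = [sample_id] + [
                str(int(feats.a)) if name == "a" else repr(float(getattr(feats, name)))
                for name in CSV_FEATURE_COLUMNS
            ]
            if any_label:
                row.append("" if label is None else str(label))
            writer.writerow(row)


def read_features_csv(path: os.PathLike | str) -> pd.DataFrame:
    """Read a feature CSV (mask_io dialect) into a DataFrame.

    Validates that the 13 feature columns are present and numeric.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("id", *CSV_FEATURE_COLUMNS) if c not in frame.columns]
    if missing:
        raise ValueError(f"feature CSV {path!r} is missing columns: {missing}")
    if len(frame) == 0:
        raise ValueError(f"feature CSV {path!r} has no rows")
    for col in CSV_FEATURE_COLUMNS:
        if not np.issubdtype(frame[col].dtype, np.number):
            raise ValueError(f"feature column {col!r} is not numeric")
    return frame
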