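"""Labeled-mask I/O and per-object feature extraction.

A *labeled mask* is a single-plane integer image in which 0 is background and
each positive value identifies one segmented object in that frame.  The
tracker is segmentation-independent: it consumes labeled masks from any
source.  This module reads and writes mask sequences as grayscale TIFF files
and reduces each frame to the per-object geometry table every downstream
stage works from.

Conventions (used consistently across the whole package): coordinates are
(row, col), 0-based; the centroid is the unweighted mean of a label's pixel
coordinates; region connectivity is 8-connected.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import tifffile
from skimage.measure import regionprops

__all__ = [
    "LabeledMask",
    "read_mask",
    "read_mask_sequence",
    "iter_mask_sequence",
    "write_tracked_masks",
    "extract_features",
]

#: Columns of a cell-feature table, indexed by label.
FEATURE_COLUMNS = (
    "area",
    "centroid_row",
    "centroid_col",
    "perimeter",
    "circularity",
    "aspect_ratio",
    "touches_border",
)


@dataclasses.dataclass
class LabeledMask:
    """One frame's integer-labeled segmentation image.

    ``pixels`` is a 2D non-negative integer array; 0 is background, each
    positive value is one object.  Labels need not be consecutive nor stable
    across frames.
    """

    pixels: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        pix = np.asarray(self.pixels)
        if pix.ndim != 2:
            raise ValueError(f"mask must be 2D, got shape {pix.shape}")
        if not np.issubdtype(pix.dtype, np.integer):
            raise TypeError(f"mask pixels must be integers, got dtype {pix.dtype}")
        if pix.size and pix.min() < 0:
            raise ValueError("mask labels must be non-negative")
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")
        self.pixels = pix

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def labels(self) -> np.ndarray:
        """Sorted array of distinct nonzero labels present in the frame."""
        lab = np.unique(self.pixels)
        return lab[lab > 0]

    def copy(self) -> "LabeledMask":
        return LabeledMask(self.pixels.copy(), self.frame_index)


def read_mask(path: str | Path, frame_index: int = 0) -> LabeledMask:
    """Read one single-plane integer TIFF as a :class:`LabeledMask`."""
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-plane 2D image, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise TypeError(f"{path}: mask pixels must be integer-valued, got dtype {arr.dtype}")
    return LabeledMask(arr.astype(np.int64, copy=False), frame_index)


def read_mask_sequence(paths: Sequence[str | Path]) -> list[LabeledMask]:
    """Read a time-ordered list of mask files.

    Frame indices are assigned 0..N-1 in list order and pixel values are
    preserved exactly.  All frames must share the same dimensions.
    """
    return list(iter_mask_sequence(paths))


def iter_mask_sequence(paths: Sequence[str | Path]) -> Iterator[LabeledMask]:
    """Lazily read a time-ordered mask sequence (one frame in memory at a time)."""
    if len(paths) == 0:
        raise ValueError("empty mask sequence")
    shape: tuple[int, int] | None = None
    for i, path in enumerate(paths):
        mask = read_mask(path, frame_index=i)
        if shape is None:
            shape = mask.shape
        elif mask.shape != shape:
            raise ValueError(
                f"{path}: frame {i} has shape {mask.shape}, expected {shape}"
            )
        yield mask


def _dtype_for(max_label: int) -> np.dtype:
    return np.dtype(np.uint16 if max_label <= np.iinfo(np.uint16).max else np.uint32)


def write_tracked_masks(
    masks: Iterable[LabeledMask], directory: str | Path, prefix: str = "tracked_"
) -> list[Path]:
    """Write masks as one integer TIFF per frame with zero-padded numbering.

    The pixel type widens to 32-bit when labels exceed the 16-bit range, so a
    write/read round trip reproduces pixel grids bit-exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for mask in masks:
        max_label = int(mask.pixels.max()) if mask.pixels.size else 0
        out = directory / f"{prefix}{mask.frame_index:06d}.tif"
        tifffile.imwrite(str(out), mask.pixels.astype(_dtype_for(max_label)))
        written.append(out)
    return written


def _aspect_ratio(prop) -> float:
    """Major/minor axis ratio of the moment-equivalent ellipse, floored at 1.

    Degenerate regions (single pixels, 1-px-wide lines) have a vanishing
    minor axis; the minor axis is floored at one pixel-width equivalent so
    the ratio stays finite.
    """
    major = prop.axis_major_length
    minor = prop.axis_minor_length
    # one pixel has axis length 0; a 1-px row of n has major ~ n. Floor the
    # minor axis at the moment length of a single pixel-wide strip.
    floor = 4.0 / np.sqrt(12.0)  # axis length of a 1-px-wide uniform strip
    minor = max(minor, floor)
    major = max(major, floor)
    return max(major / minor, 1.0)


def extract_features(mask: LabeledMask) -> pd.DataFrame:
    """Compute the per-object geometry table for one frame.

    Returns a DataFrame indexed by label with columns ``area`` (pixel
    count), ``centroid_row``/``centroid_col`` (mean pixel coordinates),
    ``perimeter`` (boundary length), ``circularity`` (4*pi*A/P^2, clipped to
    1.0 where discretisation pushes it above), ``aspect_ratio`` (>= 1) and
    ``touches_border``.  An empty mask yields an empty table.
    """
    pix = mask.pixels
    rows = []
    index = []
    nrows, ncols = pix.shape
    border_labels: set[int] = set()
    if pix.size:
        for edge in (pix[0, :], pix[-1, :], pix[:, 0], pix[:, -1]):
            border_labels.update(np.unique(edge).tolist())
    border_labels.discard(0)

    for prop in regionprops(pix):
        label = int(prop.label)
        area = float(prop.area)
        perim = float(prop.perimeter)
        if perim > 0:
            circularity = min(4.0 * np.pi * area / perim**2, 1.0)
        else:  # single pixel: perfectly compact by convention
            circularity = 1.0
        r, c = prop.centroid
        rows.append(
            (
                area,
                float(r),
                float(c),
                perim,
                circularity,
                _aspect_ratio(prop),
                label in border_labels,
            )
        )
        index.append(label)

    table = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS), index=index)
    table.index.name = "label"
    return table.sort_index()
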