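"""Preprocessing chain applied to raw SICM height maps before any metric.

The standard chain mirrors the usual SPM flattening sequence: scanline
mismatch correction (row-alignment by medians, or by medians of consecutive
row differences when the plain variant is unsuitable), levelling by
subtraction of the least-squares mean plane, and shifting the minimum to
zero so heights are apparent heights above the substrate.  All operations
preserve grid dimensions and pitches, exclude missing (NaN) pixels from the
statistics they compute and propagate them unchanged.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import (
    DegenerateGeometryError,
    ObjectMask,
    SegmentationError,
    Topography,
    _binary_structure,
)

__all__ = [
    "align_rows_median",
    "align_rows_median_diff",
    "subtract_mean_plane",
    "zero_floor",
    "preprocess",
    "segment_object",
    "STANDARD_CHAIN",
]

STANDARD_CHAIN = ("align_rows_median", "subtract_mean_plane", "zero_floor")


def _nan_aware(values: np.ndarray, func, axis=None):
    # all-NaN slices contribute offset 0 rather than a warning + NaN
    with np.errstate(all="ignore"):
        out = func(values, axis=axis)
    return np.nan_to_num(out, nan=0.0)


def align_rows_median(t: Topography) -> Topography:
    """Shift each row by its median so every output row has median 0.

    Within-row shape is unchanged; the correction removes per-line offsets
    caused by scanline mismatch.
    """
    offsets = _nan_aware(t.heights, np.nanmedian, axis=1)
    return t.with_heights(t.heights - offsets[:, None])


def align_rows_median_diff(t: Topography) -> Topography:
    """Remove scanline offsets using medians of consecutive row differences.

    Subtracts the cumulative median of (row_{r+1} - row_r) from each row, so
    the median difference between every consecutive row pair becomes zero
    while genuine within-row structure (e.g. a tilted plane) survives.  The
    first row is left in place; the chain's final zero-floor step fixes the
    global offset.
    """
    if t.n_rows < 2:
        raise DegenerateGeometryError("median-of-differences alignment needs >= 2 rows")
    diffs = t.heights[1:] - t.heights[:-1]
    step = _nan_aware(diffs, np.nanmedian, axis=1)
    offsets = np.concatenate([[0.0], np.cumsum(step)])
    return t.with_heights(t.heights - offsets[:, None])


def subtract_mean_plane(t: Topography) -> Topography:
    """Subtract the ordinary least-squares plane fitted to all valid pixels."""
    z = t.heights
    rows, cols = np.nonzero(~np.isnan(z))
    if rows.size < 3:
        raise DegenerateGeometryError("plane fit needs >= 3 non-missing pixels")
    x = cols * t.pitch_x
    y = rows * t.pitch_y
    design = np.column_stack([x, y, np.ones_like(x)])
    if np.linalg.matrix_rank(design) < 3:
        raise DegenerateGeometryError("pixels are collinear; mean plane is undefined")
    coeffs, *_ = np.linalg.lstsq(design, z[rows, cols], rcond=None)
    xx = np.arange(t.n_cols) * t.pitch_x
    yy = np.arange(t.n_rows) * t.pitch_y
    plane = coeffs[0] * xx[None, :] + coeffs[1] * yy[:, None] + coeffs[2]
    return t.with_heights(z - plane)


def zero_floor(t: Topography) -> Topography:
    """Shift heights so the minimum valid pixel sits at exactly zero."""
    return t.with_heights(t.heights - np.nanmin(t.heights))


_STEPS = {
    "align_rows_median": align_rows_median,
    "align_rows_median_diff": align_rows_median_diff,
    "subtract_mean_plane": subtract_mean_plane,
    "zero_floor": zero_floor,
}


def preprocess(t: Topography, chain=STANDARD_CHAIN) -> Topography:
    """Apply a named sequence of preprocessing steps in order."""
    for name in chain:
        try:
            step = _STEPS[name]
        except KeyError:
            raise ValueError(f"unknown preprocessing step {name!r}")
        t = step(t)
    return t


def segment_object(
    t: Topography,
    rel_threshold: float = 0.10,
    min_pixels: int = 16,
    connectivity: int = 8,
) -> ObjectMask:
    """Largest connected component above a relative height threshold.

    Operates on a zero-floored topography: pixels with
    ``z >= rel_threshold * z_max`` are candidate object pixels; the largest
    connected component (default 8-connectivity) with at least ``min_pixels``
    pixels is returned with interior holes filled.  Substrate roughness is a
    few nm against object heights of hundreds of nm, so the default 10%
    threshold is far from both.
    """
    if not 0 < rel_threshold < 1:
        raise ValueError("rel_threshold must lie strictly between 0 and 1")
    z = t.heights
    z_max = np.nanmax(z)
    if not z_max > 0:
        raise SegmentationError("no positive heights to segment")
    candidate = np.nan_to_num(z, nan=-np.inf) >= rel_threshold * z_max
    structure = _binary_structure(connectivity)
    labels, n_comp = ndimage.label(candidate, structure=structure)
    if n_comp == 0:
        raise SegmentationError("no pixels above threshold")
    sizes = ndimage.sum_labels(candidate, labels, index=np.arange(1, n_comp + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < min_pixels:
        raise SegmentationError(
            f"largest component has {int(sizes[best - 1])} px < min_pixels={min_pixels}"
        )
    component = labels == best
    filled = ndimage.binary_fill_holes(component, structure=_binary_structure(4))
    return ObjectMask(filled, connectivity=connectivity)
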