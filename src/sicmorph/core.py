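"""Core domain types for SICM topography scan pairs.

All lengths are carried internally in nanometres (heights, pixel pitches),
volumes in nm**3 and elapsed times in hours.  A topography grid follows the
acquisition layout of a hopping-mode SICM scan: rows are the slow scan axis
(y), columns the fast scan axis (x), and each line is recorded once in the
forward and once in the backward direction, giving two grids per measurement.
Missing pixels (e.g. aborted approaches) are represented as NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

FORWARD = "forward"
BACKWARD = "backward"
DIRECTIONS = (FORWARD, BACKWARD)

SPECIMENS = ("active_mito", "fixed_mito", "microsphere", "synthetic")
ISOLATIONS = ("cavitation", "mechanochemical", "none")


class TopographyError(ValueError):
    """Base class for domain validation errors."""


class MetadataError(TopographyError):
    """Required metadata (pitch, direction, units) missing or invalid."""


class ParseError(TopographyError):
    """A height-map file could not be parsed."""


class SegmentationError(TopographyError):
    """No object satisfying the segmentation contract was found."""


class DegenerateGeometryError(TopographyError):
    """Input grid too degenerate for the requested operation."""


def _as_height_array(heights) -> np.ndarray:
    arr = np.asarray(heights, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise TopographyError("heights must be a non-empty 2-D grid")
    finite_or_nan = np.isfinite(arr) | np.isnan(arr)
    if not finite_or_nan.all():
        raise TopographyError("non-missing heights must be finite")
    return arr


@dataclass(frozen=True)
class Topography:
    """One scan-direction height grid.

    Parameters
    ----------
    heights
        2-D array of apparent heights in nm; rows = slow axis (y),
        columns = fast axis (x).  NaN marks a missing pixel.
    pitch_x, pitch_y
        Pixel edge lengths Δx, Δy in nm (samples at pixel centres).
    direction
        ``"forward"`` or ``"backward"`` fast-axis scan direction.
    """

    heights: np.ndarray
    pitch_x: float
    pitch_y: float
    direction: str = FORWARD

    def __post_init__(self):
        object.__setattr__(self, "heights", _as_height_array(self.heights))
        if not (self.pitch_x > 0 and self.pitch_y > 0):
            raise TopographyError("pixel pitches must be positive")
        if not (math.isfinite(self.pitch_x) and math.isfinite(self.pitch_y)):
            raise TopographyError("pixel pitches must be finite")
        if self.direction not in DIRECTIONS:
            raise TopographyError(f"direction must be one of {DIRECTIONS}")

    @property
    def n_rows(self) -> int:
        return self.heights.shape[0]

    @property
    def n_cols(self) -> int:
        return self.heights.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    def x_coords(self) -> np.ndarray:
        """Physical x positions (nm) of the column centres."""
        return np.arange(self.n_cols) * self.pitch_x

    def y_coords(self) -> np.ndarray:
        """Physical y positions (nm) of the row centres."""
        return np.arange(self.n_rows) * self.pitch_y

    def with_heights(self, heights: np.ndarray) -> "Topography":
        """A copy of this topography with a new height grid (same geometry)."""
        return replace(self, heights=heights)

    def copy(self) -> "Topography":
        return replace(self, heights=self.heights.copy())


@dataclass(frozen=True)
class ScanPair:
    """Forward and backward scan of the same field of view."""

    forward: Topography
    backward: Topography

    def __post_init__(self):
        f, b = self.forward, self.backward
        if f.shape != b.shape:
            raise TopographyError("forward/backward grids must be congruent")
        if not (
            math.isclose(f.pitch_x, b.pitch_x) and math.isclose(f.pitch_y, b.pitch_y)
        ):
            raise TopographyError("forward/backward pitches must match")
        if f.direction != FORWARD or b.direction != BACKWARD:
            raise TopographyError("pair must hold a forward and a backward scan")

    @property
    def shape(self) -> tuple[int, int]:
        return self.forward.shape

    @property
    def pitch_x(self) -> float:
        return self.forward.pitch_x

    @property
    def pitch_y(self) -> float:
        return self.forward.pitch_y


@dataclass
class MeasurementRecord:
    """A scan pair plus the study metadata used by the analyses.

    ``t_prep`` is the time elapsed since sample preparation (thawing of the
    isolated mitochondria) in hours.  ``complete`` is False when the scan
    captured more than 90% but less than 100% of the object (drift or
    self-motion), in which case the edge-volume statistic is nominally
    greater than measured.
    """

    id: str
    pair: ScanPair
    t_prep: float
    specimen: str = "synthetic"
    isolation: str = "none"
    complete: bool = True

    def __post_init__(self):
        if not (math.isfinite(self.t_prep) and self.t_prep >= 0):
            raise TopographyError("t_prep must be finite and non-negative")
        if self.specimen not in SPECIMENS:
            raise TopographyError(f"specimen must be one of {SPECIMENS}")
        if self.isolation not in ISOLATIONS:
            raise TopographyError(f"isolation must be one of {ISOLATIONS}")


def _binary_structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)
    raise TopographyError("connectivity must be 4 or 8")


@dataclass(frozen=True)
class ObjectMask:
    """A single connected segmented object on a topography grid.

    Replaces the manual polygon outlining of the original workflow with an
    explicit, reproducible mask.  ``connectivity`` records the neighbourhood
    convention (4 or 8) under which the mask is one connected component.
    """

    mask: np.ndarray
    connectivity: int = 8

    def __post_init__(self):
        arr = np.asarray(self.mask, dtype=bool)
        if arr.ndim != 2 or arr.size == 0:
            raise TopographyError("mask must be a non-empty 2-D grid")
        if not arr.any():
            raise TopographyError("mask must contain at least one pixel")
        _, n_comp = ndimage.label(arr, structure=_binary_structure(self.connectivity))
        if n_comp != 1:
            raise TopographyError(
                f"mask must be a single connected component (found {n_comp})"
            )
        object.__setattr__(self, "mask", arr)

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def bbox(self) -> tuple[int, int, int, int]:
        """(row_min, row_max, col_min, col_max), inclusive."""
        rows, cols = np.nonzero(self.mask)
        return int(rows.min()), int(rows.max()), int(cols.min()), int(cols.max())

    def check_congruent(self, t: Topography) -> None:
        if self.mask.shape != t.shape:
            raise TopographyError("mask and topography grids are not congruent")
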