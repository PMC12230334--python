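"""Line-profile extraction and height-intermittency dropout detection.

Weakly immobilised, steeply sloped objects can transiently "tilt away" from
the approaching nanopipette, so line profiles along the fast scan axis drop
abruptly from object height to nearly substrate level and recover a few
pixels later.  A dropout event is a maximal run of columns whose height
falls below ``f_low * z_max`` while being flanked, on both sides within the
analysis window, by columns at or above ``f_high * z_max`` — i.e. a genuine
high → low → high excursion rather than the ordinary descent at the object
boundary.  Thresholds are relative to the object's maximum height, making
the detector invariant under uniform height rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ObjectMask, ScanPair, Topography, TopographyError

__all__ = [
    "LineProfile",
    "DropoutEvent",
    "IntermittencyParams",
    "IntermittencySummary",
    "line_profile",
    "detect_dropouts",
    "intermittency_summary",
    "events_to_frame",
]


@dataclass(frozen=True)
class LineProfile:
    """One row of a topography with physical fast-axis coordinates."""

    row: int
    x_nm: np.ndarray
    z_nm: np.ndarray
    direction: str


def line_profile(t: Topography, row: int) -> LineProfile:
    """Extract row ``row`` along the fast scanning direction (x-axis)."""
    if not 0 <= row < t.n_rows:
        raise IndexError(f"row {row} out of range for {t.n_rows} rows")
    return LineProfile(
        row=row,
        x_nm=t.x_coords(),
        z_nm=t.heights[row].copy(),
        direction=t.direction,
    )


@dataclass(frozen=True)
class DropoutEvent:
    """One height-intermittency excursion on a line profile."""

    start_col: int
    end_col: int  # inclusive
    min_z: float
    flank_z: float  # lower of the two nearest qualifying flank heights
    depth_fraction: float
    row: int = -1
    direction: str = ""


def detect_dropouts(
    p: LineProfile,
    object_cols: tuple[int, int],
    z_max: float,
    f_low: float = 0.2,
    f_high: float = 0.5,
) -> list[DropoutEvent]:
    """Dropout events on one profile, left to right.

    ``object_cols`` is the inclusive column interval to analyse (typically
    the object's extent in this row plus a margin, since events also occur
    a few hundred nm outside the apparent edge).  A run of columns with
    ``z < f_low * z_max`` qualifies only if a column with
    ``z >= f_high * z_max`` exists on each side of it inside the window.
    """
    if not 0 < f_low < f_high < 1:
        raise ValueError("need 0 < f_low < f_high < 1")
    lo, hi = int(object_cols[0]), int(object_cols[1])
    if lo > hi:
        raise ValueError("object_cols interval is empty")
    lo = max(lo, 0)
    hi = min(hi, len(p.z_nm) - 1)
    z = p.z_nm[lo : hi + 1]
    low = np.nan_to_num(z, nan=np.inf) < f_low * z_max
    high = np.nan_to_num(z, nan=-np.inf) >= f_high * z_max
    events: list[DropoutEvent] = []
    i = 0
    n = len(z)
    while i < n:
        if not low[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and low[j + 1]:
            j += 1
        left = np.nonzero(high[:i])[0]
        right = np.nonzero(high[j + 1 :])[0]
        if left.size and right.size:
            flank_left = float(z[left[-1]])
            flank_right = float(z[j + 1 + right[0]])
            flank = min(flank_left, flank_right)
            min_z = float(np.nanmin(z[i : j + 1]))
            events.append(
                DropoutEvent(
                    start_col=lo + i,
                    end_col=lo + j,
                    min_z=min_z,
                    flank_z=flank,
                    depth_fraction=(flank - min_z) / z_max,
                    row=p.row,
                    direction=p.direction,
                )
            )
        i = j + 1
    return events


@dataclass(frozen=True)
class IntermittencyParams:
    f_low: float = 0.2
    f_high: float = 0.5
    margin_nm: float = 500.0  # events occur up to ~500 nm beyond the edge


@dataclass
class IntermittencySummary:
    """Per-direction dropout statistics of one measurement."""

    events: list[DropoutEvent] = field(default_factory=list)
    n_events: dict = field(default_factory=dict)
    affected_fraction: dict = field(default_factory=dict)
    alternation_count: int = 0

    def to_dict(self) -> dict:
        return {
            "n_events_forward": self.n_events.get("forward", 0),
            "n_events_backward": self.n_events.get("backward", 0),
            "affected_fraction_forward": self.affected_fraction.get("forward", 0.0),
            "affected_fraction_backward": self.affected_fraction.get("backward", 0.0),
            "alternation_count": self.alternation_count,
        }


def intermittency_summary(
    pair: ScanPair,
    mask: ObjectMask,
    params: IntermittencyParams | None = None,
) -> IntermittencySummary:
    """Run the dropout detector over the object rows of both scan directions.

    Every row intersecting the mask is scanned, plus a band of
    ``margin_nm`` on either side (excursions occur up to a few hundred nm
    beyond the apparent edge).  Events are counted independently per
    direction (a forward event absent in the backward scan still counts
    once).  The alternation count is the total number of high → low → high
    transitions over all rows and both directions; the affected fraction is
    the share of in-mask pixels lying inside detected events, per direction.
    """
    params = params or IntermittencyParams()
    mask.check_congruent(pair.forward)
    margin_cols = int(round(params.margin_nm / pair.pitch_x))
    margin_rows = int(round(params.margin_nm / pair.pitch_y))
    rows_with_mask = np.nonzero(mask.mask.any(axis=1))[0]
    # events occur beyond the apparent edge, so widen the scanned band of
    # rows by the same margin as the column windows
    row_lo = max(int(rows_with_mask.min()) - margin_rows, 0)
    row_hi = min(int(rows_with_mask.max()) + margin_rows, mask.shape[0] - 1)
    _, _, bbox_c0, bbox_c1 = mask.bbox()
    mask_pixels = mask.pixel_count

    summary = IntermittencySummary()
    for topo in (pair.forward, pair.backward):
        z_max = float(np.nanmax(topo.heights[mask.mask]))
        direction_events: list[DropoutEvent] = []
        flagged = 0
        for row in range(row_lo, row_hi + 1):
            cols = np.nonzero(mask.mask[row])[0]
            if cols.size:
                window = (cols.min() - margin_cols, cols.max() + margin_cols)
            else:
                window = (bbox_c0 - margin_cols, bbox_c1 + margin_cols)
            profile = line_profile(topo, int(row))
            row_events = detect_dropouts(
                profile, window, z_max, f_low=params.f_low, f_high=params.f_high
            )
            direction_events.extend(row_events)
            for ev in row_events:
                in_mask = mask.mask[row, ev.start_col : ev.end_col + 1]
                flagged += int(in_mask.sum())
        summary.events.extend(direction_events)
        summary.n_events[topo.direction] = len(direction_events)
        summary.affected_fraction[topo.direction] = flagged / mask_pixels
    summary.alternation_count = sum(summary.n_events.values())
    return summary


def events_to_frame(events: list[DropoutEvent], measurement_id: str = "") -> pd.DataFrame:
    """Event table ready for CSV export."""
    rows = [
        {
            "id": measurement_id,
            "direction": ev.direction,
            "row": ev.row,
            "start_col": ev.start_col,
            "end_col": ev.end_col,
            "min_z_nm": ev.min_z,
            "depth_fraction": ev.depth_fraction,
        }
        for ev in events
    ]
    return pd.DataFrame(
        rows,
        columns=["id", "direction", "row", "start_col", "end_col", "min_z_nm", "depth_fraction"],
    )
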