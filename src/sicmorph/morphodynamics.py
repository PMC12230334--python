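"""Forward/backward difference statistics and their time trend.

A hopping-mode SICM measurement yields one forward and one backward scan of
every line.  For a static sample the two agree to within noise; a
metabolically active mitochondrion displaces its edges between the two
passes, leaving ± bands in the difference image (backward − forward).  The
total edge volume

    TEV = Δx Δy Σ_i |z_i^bwd − z_i^fwd|

integrates that disagreement over the frame (nm³).  On active mitochondria
TEV decreases roughly linearly with the time t_P elapsed since preparation,
and the zero crossing of the fitted line estimates when morphodynamic
activity ceases.  Submitochondrial particles — distinguished by an
equivalent-sphere diameter below ~1 µm — show no such trend and are excluded
from the fit by default, as are incomplete captures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import ScanPair, TopographyError

__all__ = [
    "GROUP_MITO",
    "GROUP_SUBMITO",
    "DifferenceImage",
    "TevPoint",
    "TrendFit",
    "MciTestResult",
    "difference_image",
    "total_edge_volume",
    "tev_trend",
    "split_by_equivalent_diameter",
    "mci_decrease_test",
]

GROUP_MITO = "mitochondrion"
GROUP_SUBMITO = "submito_particle"


class TrendError(TopographyError):
    """Not enough usable points for a trend fit."""


@dataclass(frozen=True)
class DifferenceImage:
    """Pixelwise backward − forward heights (nm); positive = backward higher."""

    heights: np.ndarray
    pitch_x: float
    pitch_y: float


def difference_image(pair: ScanPair) -> DifferenceImage:
    """Backward minus forward heights; missing pixels propagate as NaN."""
    return DifferenceImage(
        heights=pair.backward.heights - pair.forward.heights,
        pitch_x=pair.pitch_x,
        pitch_y=pair.pitch_y,
    )


def total_edge_volume(pair: ScanPair) -> float:
    """TEV = Δx Δy Σ |z_bwd − z_fwd| over all non-missing pixels (nm³)."""
    diff = pair.backward.heights - pair.forward.heights
    return float(pair.pitch_x * pair.pitch_y * np.nansum(np.abs(diff)))


@dataclass
class TevPoint:
    """One measurement's TEV with the metadata the trend fit needs."""

    id: str
    tev: float
    t_prep: float
    group: str = GROUP_MITO
    complete: bool = True

    def __post_init__(self):
        if self.tev < 0:
            raise TopographyError("TEV cannot be negative")


@dataclass(frozen=True)
class TrendFit:
    """Ordinary least-squares line TEV = intercept + slope · t_prep.

    ``t_zero = −intercept/slope`` (the extrapolated time at which TEV
    reaches zero) is reported only for a decreasing trend; ``p_slope`` is
    the two-sided p-value of the slope against zero.
    """

    slope: float
    intercept: float
    t_zero: float | None
    r_squared: float
    n_points: int
    p_slope: float
    stderr: float

    def to_dict(self) -> dict:
        return {
            "slope_nm3_per_h": self.slope,
            "intercept_nm3": self.intercept,
            "t_zero_h": self.t_zero,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "p_slope_two_sided": self.p_slope,
            "slope_stderr": self.stderr,
        }


def tev_trend(
    points: list[TevPoint],
    exclude_partial: bool = True,
    exclude_submito: bool = True,
) -> TrendFit:
    """Unweighted OLS fit of TEV against t_prep with the study's exclusions.

    Partial captures understate TEV and submitochondrial particles carry no
    edge-memory signal, so both are dropped by default before fitting.
    """
    kept = [
        p
        for p in points
        if (p.complete or not exclude_partial)
        and (p.group != GROUP_SUBMITO or not exclude_submito)
    ]
    t = np.array([p.t_prep for p in kept], dtype=float)
    v = np.array([p.tev for p in kept], dtype=float)
    if len(kept) < 3 or np.unique(t).size < 3:
        raise TrendError("trend fit needs >= 3 points with distinct t_prep")
    fit = stats.linregress(t, v)
    t_zero = None
    if fit.slope < 0:
        t_zero = -fit.intercept / fit.slope
    return TrendFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        t_zero=t_zero,
        r_squared=float(fit.rvalue**2),
        n_points=len(kept),
        p_slope=float(fit.pvalue),
        stderr=float(fit.stderr),
    )


def split_by_equivalent_diameter(d_sphere_equiv_nm, cutoff_nm: float = 1000.0):
    """Label objects below the equivalent-sphere-diameter cutoff as particles.

    The measured diameter distribution is bimodal (below 1.0 µm or above
    1.5 µm); the default 1000 nm cutoff separates submitochondrial particles
    from intact mitochondria.  The boundary itself counts as mitochondrion
    (half-open convention).  Accepts a scalar or a sequence.
    """
    arr = np.asarray(d_sphere_equiv_nm, dtype=float)
    labels = np.where(arr < cutoff_nm, GROUP_SUBMITO, GROUP_MITO)
    if arr.ndim == 0:
        return str(labels)
    return list(labels)


@dataclass(frozen=True)
class MciTestResult:
    t_statistic: float
    p_one_sided: float
    reject: bool
    n: int

    def to_dict(self) -> dict:
        return {
            "t_statistic": self.t_statistic,
            "p_one_sided": self.p_one_sided,
            "reject": self.reject,
            "n_pairs": self.n,
        }


def mci_decrease_test(first_last, alpha: float = 0.10) -> MciTestResult:
    """One-sided paired t-test for a decrease of MCI* between measurements.

    ``first_last`` holds (MCI*_first, MCI*_last) per repeatedly measured
    object; the test is a one-sample t-test on the differences last − first
    against zero with alternative < 0, rejected at the given significance
    level (default 10%, i.e. 90% confidence).
    """
    pairs = list(first_last)
    if len(pairs) < 2:
        raise TopographyError("MCI* decrease test needs >= 2 pairs")
    diffs = np.array([last - first for first, last in pairs], dtype=float)
    if np.std(diffs, ddof=1) == 0:
        # degenerate but well-defined limits: no spread in the differences
        if diffs[0] == 0:
            t_stat, p = 0.0, 0.5
        else:
            t_stat = -math.inf if diffs[0] < 0 else math.inf
            p = 0.0 if diffs[0] < 0 else 1.0
    else:
        res = stats.ttest_1samp(diffs, 0.0, alternative="less")
        t_stat, p = float(res.statistic), float(res.pvalue)
    return MciTestResult(t_statistic=t_stat, p_one_sided=p, reject=p < alpha, n=len(pairs))
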