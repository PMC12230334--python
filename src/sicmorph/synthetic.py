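"""Synthetic SICM scan-pair generator with ground truth.

Emulates the statistical structure the analyses assume, so every pipeline
stage can be validated against known truth:

* spherical, ellipsoidal or irregular (multi-lobed) cap-shaped objects,
  0.2–2.6 µm across and up to ~2.8 µm high, on a flat substrate.  Apparent
  heights follow the probe's top-down view: for a cap higher than its
  sphere radius the overhanging lower half appears as a vertical wall;
* shallow band-limited undulations of ~100 nm amplitude and lateral scale
  on the object surface;
* an *edge memory* displacement between forward and backward scans: the
  object boundary of the backward scan is shifted outward by a smooth,
  azimuthally asymmetric displacement field whose mean magnitude decays
  linearly with the time since preparation, δ(t_P) = δ0 · max(0, 1 − t_P/t_zero);
* stochastic height dropouts (transient tilting of the weakly immobilised
  object) starting just past steep fast-axis slopes and running a few
  pixels along the scan direction;
* i.i.d. Gaussian z-noise of ~1 nm.

All randomness flows from named integer seeds; regeneration is
bit-reproducible.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core import BACKWARD, FORWARD, MeasurementRecord, ObjectMask, ScanPair, Topography
from .io import write_manifest, write_topography
from . import shape as _shape

__all__ = [
    "SynthConfig",
    "make_cap",
    "make_irregular",
    "add_undulations",
    "apply_edge_memory",
    "apply_dropouts",
    "add_noise",
    "synthesize_pair",
    "simulate_study",
    "write_study",
    "cap_volume",
    "cap_surface_area",
]

_MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class SynthConfig:
    """Full parameterization of one synthetic measurement.

    Defaults mirror a typical metabolically active mitochondrion: a
    near-spherical cap ~1.9 µm across and ~1.8 µm high on a 128×128 grid
    framing it with ~35% margin, 100 nm peak-to-peak undulations, an
    edge-memory amplitude δ0 = 150 nm decaying to zero at t_zero = 18.8 h,
    sparse dropout runs at steep fast-axis slopes and 1 nm z-noise.
    """

    n_rows: int = 128
    n_cols: int = 128
    pitch_nm: float = 25.0
    shape: str = "spherical_cap"  # spherical_cap | ellipsoidal_cap | irregular
    cap_radius_nm: float = 950.0
    cap_height_nm: float = 1800.0
    ellipticity: float = 1.0
    n_lobes: int = 3
    lobe_radius_frac: float = 0.45
    lobe_offset_frac: float = 1.3
    undulation_amplitude_nm: float = 100.0  # peak-to-peak; RMS target = half
    undulation_corr_nm: float = 100.0
    delta0_nm: float = 150.0
    t_zero_h: float = 18.8
    anisotropy: float = 0.7
    anisotropy_phase: float = 0.0
    dropout_q: float = 0.01
    dropout_slope_threshold: float = 1.0  # nm/nm, i.e. 45 degrees
    dropout_max_run: int = 6
    noise_sigma_nm: float = 1.0
    t_prep_h: float = 2.0
    center_nm: tuple[float, float] | None = None  # (x, y); default frame centre
    seed: int = 0

    def __post_init__(self):
        if self.cap_height_nm > 2 * self.cap_radius_nm:
            raise ValueError("cap height cannot exceed the sphere diameter (h <= 2r)")
        for name in ("pitch_nm", "cap_radius_nm", "cap_height_nm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.dropout_q <= 1:
            raise ValueError("dropout_q must lie in [0, 1]")
        if self.noise_sigma_nm < 0:
            raise ValueError("noise_sigma_nm must be non-negative")


def cap_volume(r: float, h: float) -> float:
    """Closed-form volume under the apparent-height field of a cap (nm³).

    For h <= r this is the spherical-cap formula pi h^2 (3r - h) / 3; for
    h > r the visible shape is the upper hemisphere on a cylindrical shadow
    wall of height h - r.
    """
    hc = min(h, r)
    v = math.pi * hc**2 * (3 * r - hc) / 3.0
    if h > r:
        v += math.pi * r**2 * (h - r)
    return v


def cap_surface_area(r: float, h: float) -> float:
    """Closed-form visible (top + wall) surface area of a cap (nm²)."""
    hc = min(h, r)
    sa = 2 * math.pi * r * hc  # spherical zone
    if h > r:
        sa += 2 * math.pi * r * (h - r)  # vertical shadow wall
    return sa


def _grid_coords(n_rows, n_cols, pitch, center):
    if center is None:
        center = ((n_cols - 1) * pitch / 2.0, (n_rows - 1) * pitch / 2.0)
    cx, cy = center
    x = np.arange(n_cols) * pitch - cx
    y = np.arange(n_rows) * pitch - cy
    return np.meshgrid(x, y)


def _cap_field(xx, yy, r, h, ellipticity=1.0):
    rho = np.hypot(xx / ellipticity, yy)
    with np.errstate(invalid="ignore"):
        z = np.sqrt(np.clip(r**2 - rho**2, 0.0, None)) - (r - h)
    z[rho > r] = 0.0
    return np.clip(z, 0.0, None)


def make_cap(
    n_rows: int,
    n_cols: int,
    pitch_nm: float,
    radius_nm: float,
    height_nm: float,
    ellipticity: float = 1.0,
    center_nm: tuple[float, float] | None = None,
) -> Topography:
    """Ideal (noise-free) spherical or ellipsoidal cap on a flat substrate.

    ``z(ρ) = max(0, sqrt(r² − ρ²) − (r − h))`` with ρ the (optionally
    x-stretched) distance from the centre; for h > r the overhang is
    invisible from above and appears as a vertical wall at ρ = r.
    """
    if height_nm > 2 * radius_nm:
        raise ValueError("cap height cannot exceed the sphere diameter (h <= 2r)")
    xx, yy = _grid_coords(n_rows, n_cols, pitch_nm, center_nm)
    z = _cap_field(xx, yy, radius_nm, height_nm, ellipticity)
    return Topography(z, pitch_x=pitch_nm, pitch_y=pitch_nm, direction=FORWARD)


def make_irregular(
    n_rows: int,
    n_cols: int,
    pitch_nm: float,
    radius_nm: float,
    height_nm: float,
    n_lobes: int = 3,
    lobe_radius_frac: float = 0.45,
    lobe_offset_frac: float = 1.3,
    seed: int = 0,
    center_nm: tuple[float, float] | None = None,
) -> Topography:
    """Irregular object: pixelwise maximum of displaced overlapping caps.

    Lobe placement, size and height vary deterministically with the seed.
    A single-lobe request degenerates to :func:`make_cap` with a warning.
    """
    if n_lobes < 2:
        warnings.warn("n_lobes < 2: falling back to a plain cap", stacklevel=2)
        return make_cap(n_rows, n_cols, pitch_nm, radius_nm, height_nm, center_nm=center_nm)
    rng = np.random.default_rng(seed)
    xx, yy = _grid_coords(n_rows, n_cols, pitch_nm, center_nm)
    z = _cap_field(xx, yy, radius_nm, height_nm)
    # evenly spread lobes (random rotation + jitter) so the union outline is
    # genuinely lobed rather than accidentally re-circular
    k = n_lobes - 1
    angles = (
        rng.uniform(0, 2 * math.pi)
        + np.arange(k) * 2 * math.pi / k
        + rng.uniform(-0.3, 0.3, size=k)
    )
    for ang in angles:
        off = lobe_offset_frac * radius_nm * rng.uniform(0.85, 1.1)
        r_l = lobe_radius_frac * radius_nm * rng.uniform(0.8, 1.2)
        h_l = min(height_nm * rng.uniform(0.7, 1.0), 1.95 * r_l)
        z_l = _cap_field(xx - off * math.cos(ang), yy - off * math.sin(ang), r_l, h_l)
        z = np.maximum(z, z_l)
    return Topography(z, pitch_x=pitch_nm, pitch_y=pitch_nm, direction=FORWARD)


def add_undulations(
    t: Topography,
    amplitude_nm: float = 100.0,
    corr_length_nm: float = 100.0,
    seed: int = 0,
) -> Topography:
    """Add a band-limited random field to the object surface.

    ``amplitude_nm`` is interpreted as peak-to-peak, so the field is scaled
    to RMS = amplitude/2 with a Gaussian correlation length of
    ``corr_length_nm``.  Substrate pixels (ideal height 0) are untouched and
    low rim pixels are tapered so heights stay non-negative.
    """
    if amplitude_nm < 0:
        raise ValueError("amplitude must be non-negative")
    if amplitude_nm == 0:
        return t.copy()
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(t.shape)
    sigma_px = max(corr_length_nm / t.pitch_x, 1e-6)
    field = ndimage.gaussian_filter(white, sigma=sigma_px, mode="wrap")
    # centre before scaling: at long correlation lengths the realization's
    # own mean is comparable to its spread and would otherwise be amplified
    # into a large spurious offset
    field -= field.mean()
    field *= (amplitude_nm / 2.0) / field.std()
    weight = np.clip(t.heights / amplitude_nm, 0.0, 1.0)
    return t.with_heights(np.clip(t.heights + weight * field, 0.0, None))


def _boundary_radius_by_angle(z, pitch_x, pitch_y, n_bins=360):
    """Footprint boundary radius a(θ) around the footprint centroid (nm)."""
    rows, cols = np.nonzero(z > 0)
    if rows.size == 0:
        raise ValueError("empty footprint")
    cy = rows.mean() * pitch_y
    cx = cols.mean() * pitch_x
    px = cols * pitch_x - cx
    py = rows * pitch_y - cy
    theta = np.arctan2(py, px)
    rho = np.hypot(px, py)
    bins = ((theta + math.pi) / (2 * math.pi) * n_bins).astype(int) % n_bins
    a = np.zeros(n_bins)
    np.maximum.at(a, bins, rho)
    # fill empty bins and smooth circularly
    if (a == 0).any():
        good = np.nonzero(a > 0)[0]
        idx = np.arange(n_bins)
        a = np.interp(idx, good, a[good], period=n_bins)
    kernel = np.ones(5) / 5.0
    a = np.convolve(np.r_[a[-2:], a, a[:2]], kernel, mode="same")[2:-2]
    return (cx, cy), a


def apply_edge_memory(
    ideal: Topography,
    delta0_nm: float,
    t_prep_h: float,
    t_zero_h: float,
    anisotropy: float = 0.7,
    phase: float = 0.0,
    seed: int = 0,
) -> ScanPair:
    """Build a forward/backward pair with a decaying lateral edge displacement.

    The forward scan is the input; the backward scan displaces the footprint
    boundary outward by a smooth per-angle field δ(θ) of mean magnitude
    δ(t_P) = δ0 · max(0, 1 − t_P / t_zero), modulated asymmetrically
    (``1 + anisotropy · cos(θ − phase)`` plus seeded low-order harmonics),
    implemented as a per-angle radial stretch of the height field.  At
    t_P >= t_zero the two scans are identical.
    """
    if delta0_nm < 0 or t_zero_h <= 0:
        raise ValueError("need delta0 >= 0 and t_zero > 0")
    forward = ideal.with_heights(ideal.heights.copy())
    delta_mean = delta0_nm * max(0.0, 1.0 - t_prep_h / t_zero_h)
    if delta_mean == 0.0:
        backward = Topography(
            ideal.heights.copy(), ideal.pitch_x, ideal.pitch_y, direction=BACKWARD
        )
        return ScanPair(forward, backward)

    n_bins = 360
    (cx, cy), a_theta = _boundary_radius_by_angle(
        ideal.heights, ideal.pitch_x, ideal.pitch_y, n_bins
    )
    rng = np.random.default_rng(seed)
    theta_bins = np.linspace(-math.pi, math.pi, n_bins, endpoint=False)
    g = 1.0 + anisotropy * np.cos(theta_bins - phase)
    for k in (2, 3, 4):
        g += rng.normal(0.0, 0.10) * np.cos(k * theta_bins + rng.uniform(0, 2 * math.pi))
    g = np.clip(g, 0.05, None)
    g /= g.mean()
    delta_theta = delta_mean * g

    ny, nx = ideal.shape
    xx = np.arange(nx) * ideal.pitch_x - cx
    yy = np.arange(ny) * ideal.pitch_y - cy
    gx, gy = np.meshgrid(xx, yy)
    theta = np.arctan2(gy, gx)
    rho = np.hypot(gx, gy)
    bins = ((theta + math.pi) / (2 * math.pi) * n_bins) % n_bins
    a_px = np.interp(bins.ravel(), np.arange(n_bins), a_theta, period=n_bins)
    d_px = np.interp(bins.ravel(), np.arange(n_bins), delta_theta, period=n_bins)
    scale = (a_px / (a_px + d_px)).reshape(rho.shape)
    rho_src = rho * scale
    col_src = (rho_src * np.cos(theta) + cx) / ideal.pitch_x
    row_src = (rho_src * np.sin(theta) + cy) / ideal.pitch_y
    z_bwd = ndimage.map_coordinates(
        ideal.heights, [row_src, col_src], order=1, mode="constant", cval=0.0
    )
    backward = Topography(z_bwd, ideal.pitch_x, ideal.pitch_y, direction=BACKWARD)
    return ScanPair(forward, backward)


def _drop_one_direction(z, pitch_x, q, slope_threshold, max_run, rng, scan_sign):
    """Inject dropout runs into one scan grid; returns (grid, truth mask).

    A run is triggered, with probability q, at pixels whose climb along the
    scan direction exceeds the slope threshold; it starts at the following
    pixel and replaces up to ``max_run`` in-footprint pixels with substrate
    level.  ``scan_sign`` is +1 for forward (+x) and -1 for backward.
    """
    out = z.copy()
    truth = np.zeros(z.shape, dtype=bool)
    footprint = z > 0
    # climbs are only counted between two on-object pixels: tilting is a
    # lateral interaction along the flank, not the first vertical contact
    climb = np.full(z.shape, -np.inf)
    on_object = footprint[:, 1:] & footprint[:, :-1]
    if scan_sign > 0:
        climb[:, 1:] = np.where(on_object, (z[:, 1:] - z[:, :-1]) / pitch_x, -np.inf)
    else:
        climb[:, :-1] = np.where(on_object, (z[:, :-1] - z[:, 1:]) / pitch_x, -np.inf)
    draws = rng.random(z.shape)
    lengths = rng.integers(1, max_run + 1, size=z.shape)
    trig_rows, trig_cols = np.nonzero((climb > slope_threshold) & (draws < q))
    n_cols = z.shape[1]
    for r, c in zip(trig_rows, trig_cols):
        cc = c + scan_sign
        for _ in range(int(lengths[r, c])):
            if cc < 0 or cc >= n_cols or not footprint[r, cc]:
                break
            out[r, cc] = 0.0
            truth[r, cc] = True
            cc += scan_sign
    return out, truth


def apply_dropouts(
    pair: ScanPair,
    q: float = 0.01,
    slope_threshold: float = 1.0,
    max_run: int = 6,
    seed: int = 0,
) -> tuple[ScanPair, dict]:
    """Inject height-intermittency dropouts into both scans.

    Returns the modified pair and the ground-truth dropped-pixel masks
    ``{"forward": bool grid, "backward": bool grid}``.
    """
    if not 0 <= q <= 1:
        raise ValueError("q must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    z_f, truth_f = _drop_one_direction(
        pair.forward.heights, pair.pitch_x, q, slope_threshold, max_run, rng, +1
    )
    z_b, truth_b = _drop_one_direction(
        pair.backward.heights, pair.pitch_x, q, slope_threshold, max_run, rng, -1
    )
    new_pair = ScanPair(
        pair.forward.with_heights(z_f), pair.backward.with_heights(z_b)
    )
    return new_pair, {"forward": truth_f, "backward": truth_b}


def add_noise(t: Topography, sigma_nm: float = 1.0, seed: int = 0) -> Topography:
    """Add i.i.d. Gaussian z-noise (default 1 nm, the SICM z-resolution)."""
    if sigma_nm < 0:
        raise ValueError("sigma must be non-negative")
    if sigma_nm == 0:
        return t.copy()
    rng = np.random.default_rng(seed)
    return t.with_heights(t.heights + rng.normal(0.0, sigma_nm, size=t.shape))


def synthesize_pair(cfg: SynthConfig) -> tuple[ScanPair, dict]:
    """Generate one complete scan pair plus its ground-truth ledger entry."""
    rng = np.random.default_rng(cfg.seed)
    sub = rng.integers(0, _MAX_SEED, size=6)

    if cfg.shape == "spherical_cap":
        ideal = make_cap(
            cfg.n_rows, cfg.n_cols, cfg.pitch_nm, cfg.cap_radius_nm, cfg.cap_height_nm,
            center_nm=cfg.center_nm,
        )
    elif cfg.shape == "ellipsoidal_cap":
        ideal = make_cap(
            cfg.n_rows, cfg.n_cols, cfg.pitch_nm, cfg.cap_radius_nm, cfg.cap_height_nm,
            ellipticity=cfg.ellipticity, center_nm=cfg.center_nm,
        )
    elif cfg.shape == "irregular":
        ideal = make_irregular(
            cfg.n_rows, cfg.n_cols, cfg.pitch_nm, cfg.cap_radius_nm, cfg.cap_height_nm,
            n_lobes=cfg.n_lobes, lobe_radius_frac=cfg.lobe_radius_frac,
            lobe_offset_frac=cfg.lobe_offset_frac, seed=int(sub[0]),
            center_nm=cfg.center_nm,
        )
    else:
        raise ValueError(f"unknown shape {cfg.shape!r}")

    undulated = add_undulations(
        ideal, cfg.undulation_amplitude_nm, cfg.undulation_corr_nm, seed=int(sub[1])
    )
    pair = apply_edge_memory(
        undulated, cfg.delta0_nm, cfg.t_prep_h, cfg.t_zero_h,
        anisotropy=cfg.anisotropy, phase=cfg.anisotropy_phase, seed=int(sub[2]),
    )
    pair, dropout_truth = apply_dropouts(
        pair, q=cfg.dropout_q, slope_threshold=cfg.dropout_slope_threshold,
        max_run=cfg.dropout_max_run, seed=int(sub[3]),
    )
    forward = add_noise(pair.forward, cfg.noise_sigma_nm, seed=int(sub[4]))
    backward = add_noise(pair.backward, cfg.noise_sigma_nm, seed=int(sub[5]))
    pair = ScanPair(forward, backward)

    truth: dict = {
        "config": asdict(cfg),
        "delta_mean_nm": cfg.delta0_nm * max(0.0, 1.0 - cfg.t_prep_h / cfg.t_zero_h),
        "dropout_pixels_forward": int(dropout_truth["forward"].sum()),
        "dropout_pixels_backward": int(dropout_truth["backward"].sum()),
        "dropout_truth": dropout_truth,
        "ideal": ideal,
    }
    if cfg.shape == "spherical_cap":
        truth["ideal_volume_nm3"] = cap_volume(cfg.cap_radius_nm, cfg.cap_height_nm)
        truth["ideal_sa_nm2"] = cap_surface_area(cfg.cap_radius_nm, cfg.cap_height_nm)
        truth["ideal_method"] = "analytic"
    else:
        footprint = ideal.heights > 0
        if footprint.any():
            labeled, _ = ndimage.label(footprint)
            keep = labeled == np.argmax(np.bincount(labeled.ravel())[1:]) + 1
            mask = ObjectMask(keep)
            truth["ideal_volume_nm3"] = _shape.volume(ideal, mask)
            truth["ideal_sa_nm2"] = _shape.surface_area(ideal, mask)
            truth["ideal_method"] = "grid"
    return pair, truth


# ---------------------------------------------------------------------------
# Study-level simulation


def simulate_study(
    n_records: int = 30,
    master_seed: int = 0,
    delta0_nm: float = 150.0,
    t_zero_h: float = 18.8,
    tev_scatter: float = 0.10,
    submito_fraction: float = 0.2,
    partial_fraction: float = 0.1,
    irregular_fraction: float = 0.2,
    ellipsoidal_fraction: float = 0.2,
    grid: int = 128,
    specimen: str = "active_mito",
    t_prep_h=None,
    dropout_q: float = 0.01,
    noise_sigma_nm: float = 1.0,
    mito_d_nm: tuple[float, float] = (1650.0, 350.0),
    submito_d_nm: tuple[float, float] = (460.0, 150.0),
    height_ratio: tuple[float, float] = (1.7, 2.0),
) -> tuple[list[MeasurementRecord], dict]:
    """Generate a reproducible study of n measurement records plus its ledger.

    The size marginals follow the measured bimodal distribution: intact
    mitochondria with equivalent diameters above 1.5 µm (mean ~1.65 µm) and
    submitochondrial particles around 0.46 µm.  Heights are 0.85–1.0× the
    diameter (near-spherical caps).  Submitochondrial particles carry no
    edge-memory displacement (δ0 = 0); per-record δ0 of mitochondria is
    jittered log-normally with coefficient of variation ``tev_scatter``.
    A ``partial_fraction`` of records captures only >90% of the object
    (shifted off-frame) and is flagged ``complete=False``.
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    rng = np.random.default_rng(master_seed)
    if t_prep_h is None:
        t_sched = np.linspace(0.05, 0.90, n_records) * t_zero_h
        t_sched = np.clip(t_sched + rng.uniform(-0.02, 0.02, n_records) * t_zero_h, 0.0, None)
    else:
        t_sched = np.asarray(t_prep_h, dtype=float)
        if t_sched.size != n_records or not np.isfinite(t_sched).all() or (t_sched < 0).any():
            raise ValueError("invalid t_prep schedule")

    records: list[MeasurementRecord] = []
    ledger: dict = {"master_seed": master_seed, "records": []}
    for i in range(n_records):
        is_submito = rng.random() < submito_fraction
        if is_submito:
            d = float(np.clip(rng.normal(*submito_d_nm), 200.0, 950.0))
            isolation = "mechanochemical" if rng.random() < 0.75 else "cavitation"
        else:
            d = float(np.clip(rng.normal(*mito_d_nm), 1500.0, 2600.0))
            isolation = "cavitation"
        r = d / 2.0
        h = r * rng.uniform(*height_ratio)
        u = rng.random()
        if u < irregular_fraction:
            shape_kind = "irregular"
        elif u < irregular_fraction + ellipsoidal_fraction:
            shape_kind = "ellipsoidal_cap"
        else:
            shape_kind = "spherical_cap"
        ellipticity = float(rng.uniform(1.2, 1.6)) if shape_kind == "ellipsoidal_cap" else 1.0
        if shape_kind == "irregular":
            extent_x = 3.2 * r
        else:
            extent_x = 2.0 * r * ellipticity
        frame = 1.6 * extent_x
        pitch = frame / grid

        complete = rng.random() >= partial_fraction
        center = None
        if not complete:
            # shift so ~6% of the x-extent leaves the frame (>90% captured)
            center = (frame - 0.44 * extent_x, frame / 2.0)

        if is_submito or specimen == "fixed_mito":
            delta0_i = 0.0
        else:
            delta0_i = delta0_nm * float(np.exp(rng.normal(0.0, tev_scatter)))
        phase = float(rng.uniform(0, 2 * math.pi))
        seed_i = int(rng.integers(0, _MAX_SEED))

        cfg = SynthConfig(
            n_rows=grid,
            n_cols=grid,
            pitch_nm=pitch,
            shape=shape_kind,
            cap_radius_nm=r,
            cap_height_nm=h,
            ellipticity=ellipticity,
            delta0_nm=delta0_i,
            t_zero_h=t_zero_h,
            anisotropy_phase=phase,
            dropout_q=dropout_q,
            noise_sigma_nm=noise_sigma_nm,
            t_prep_h=float(t_sched[i]),
            center_nm=center,
            seed=seed_i,
        )
        pair, truth = synthesize_pair(cfg)
        rec = MeasurementRecord(
            id=f"syn{i:03d}",
            pair=pair,
            t_prep=float(t_sched[i]),
            specimen=specimen,
            isolation=isolation,
            complete=complete,
        )
        records.append(rec)
        entry = {
            "id": rec.id,
            "group_true": "submito_particle" if is_submito else "mitochondrion",
            "shape": shape_kind,
            "d_nm": d,
            "cap_radius_nm": r,
            "cap_height_nm": h,
            "pitch_nm": pitch,
            "t_prep_h": float(t_sched[i]),
            "delta0_nm": delta0_i,
            "delta_mean_nm": truth["delta_mean_nm"],
            "complete": complete,
            "seed": seed_i,
            "dropout_pixels_forward": truth["dropout_pixels_forward"],
            "dropout_pixels_backward": truth["dropout_pixels_backward"],
            "ideal_volume_nm3": truth.get("ideal_volume_nm3"),
            "ideal_sa_nm2": truth.get("ideal_sa_nm2"),
            "ideal_method": truth.get("ideal_method"),
        }
        ledger["records"].append(entry)
    return records, ledger


def write_study(
    records: list[MeasurementRecord],
    ledger: dict,
    outdir,
    dialect: str = "ascii_matrix",
) -> Path:
    """Serialize a study: height-map files, manifest CSV and ledger JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    suffix = {"ascii_matrix": ".asc", "float_tiff": ".tif", "csv": ".csv"}[dialect]
    rows = []
    for rec in records:
        fwd_name = f"{rec.id}_fwd{suffix}"
        bwd_name = f"{rec.id}_bwd{suffix}"
        meta = {
            "id": rec.id,
            "t_prep_h": rec.t_prep,
            "specimen": rec.specimen,
            "isolation": rec.isolation,
            "complete": rec.complete,
        }
        write_topography(rec.pair.forward, outdir / fwd_name, dialect, metadata=meta)
        write_topography(rec.pair.backward, outdir / bwd_name, dialect, metadata=meta)
        rows.append(
            {
                "id": rec.id,
                "forward": fwd_name,
                "backward": bwd_name,
                "t_prep_h": rec.t_prep,
                "specimen": rec.specimen,
                "isolation": rec.isolation,
                "complete": rec.complete,
            }
        )
    write_manifest(rows, outdir / "manifest.csv")
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(ledger, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return outdir
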