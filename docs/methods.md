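# Methods

This note records the models, conventions and numerical choices behind
`sicmorph`, and what the synthetic benchmark does and does not establish
about real SICM data.

## Data model and units

A topography is a grid of apparent heights sampled at pixel centres; rows
are the slow scan axis (y), columns the fast axis (x).  All lengths are
held in nanometres, volumes in nm³, elapsed times in hours; file metadata
declares units and is converted on read.  A measurement is a forward +
backward scan pair of the same field of view with congruent grids and
pitches.  Missing pixels are NaN; every statistic excludes them and
propagates them unchanged.

## Preprocessing

The standard chain for measured data is scanline alignment → mean-plane
subtraction → zero floor:

* **Row alignment (median).**  Each row is shifted by its median.  Valid
  only while the substrate holds the per-row majority; when an object spans
  more than half of a line the median lands on the object and the
  correction destroys it.  For that case the **median-of-differences**
  variant removes the cumulative median of consecutive row differences
  instead.  The first row is anchored and the global offset is fixed by the
  final zero-floor step.
* **Mean plane** is the ordinary least-squares plane over all non-missing
  pixels.  With a large object in frame the fit is object-biased (the
  levelled substrate acquires a shallow bowl); this is a known limitation
  of unmasked plane levelling, shared with common SPM software workflows.
* **Zero floor** shifts the minimum valid pixel to exactly 0, making
  heights apparent heights above the substrate.

The chain is exactly idempotent on data matching its model (per-row
offsets on a plane).  On noisy data the medians are nonlinear, so a second
application drifts the result at the noise scale (sub-nm); tests assert
both statements separately.  The order of row alignment versus plane
subtraction is not dictated by the upstream workflow description; the
order above is a configuration default, recorded in every report bundle.

Simulated studies are generated flat and zero-based, so the pipeline
default for simulated input is zero floor only — row-median alignment is
additionally invalid there because default objects fill more than half of
the central rows.

**Segmentation** replaces manual outlining: the largest connected
component (8-connectivity) above `rel_threshold × z_max` (default 0.10)
with at least 16 pixels, holes filled.  Substrate roughness is a few nm
against object heights of hundreds of nm, so the result is insensitive to
the threshold over a wide range; both parameters are configurable.

## Shape metrics

Perimeter and projected area come from a marching-squares iso-contour at
the segmentation level, not from pixel counting (pixel-edge perimeters are
biased high by up to 4/π).  Two numerical choices matter:

* Step-like edges (the vertical walls of tall caps) render as a staircase
  whose perimeter is inflated by up to ~6%; the polygon is therefore
  simplified (Douglas–Peucker) at a one-pixel tolerance before measuring.
  Verified against analytic circle, square and 4:1-ellipse perimeters
  (within 1–2%).
* Masks smaller than 4 pixels have no stable sub-pixel outline and raise a
  degenerate-polygon error.  Contours running off the image border are
  closed with a straight chord and flagged `border_clipped`.

Volume is Δx Δy Σ z over the mask.  Surface area triangulates each grid
cell along the fixed lower-left → upper-right diagonal; the alternative
diagonal changes SA by < 0.5% at default pitches.  Cells with at least one
vertex in the mask contribute, so steep side walls are counted; the
inaccessible bottom face never is.  For a discretized hemisphere
(r = 500 nm, 5 nm pitch) V and SA converge to the closed forms within 1%
and 1.5%.  A genuinely *vertical* curved wall, however, is rendered as a
staircase of facets whose area exceeds the true cylinder by a factor
between 1 and 4/π (≈ 1.16 empirically); MCI* of tall caps is accordingly
inflated by ~10%.  This bias is deterministic and shape-stable, which is
why MCI* is interpreted as a within-object trend (first vs last
measurement) rather than an absolute number — its decrease test is a
one-sided paired t-test on (last − first) differences at α = 0.10.

Diameters: `d_slow` (max extent along the slow axis) is the headline
"diameter" for irregular objects; for regular objects both `d_slow` and
the equal-area-circle diameter are reported, since either convention is
defensible.  `d_sphere_equiv = (6V/π)^{1/3}` feeds the group split:
objects below 1000 nm (half-open boundary) are labelled submitochondrial
particles, following the observed bimodality (modes near 0.46 µm and
1.65 µm).

## TEV and its time trend

TEV = Δx Δy Σ |z_bwd − z_fwd| over the full preprocessed frame, not only
the mask — edge bands extend partially outside the object footprint.  It
is symmetric in the two scans, scales with the pixel area and is additive
over disjoint pixel sets; tests cross-check it against an independent
per-pixel loop.  The trend fit is unweighted ordinary least squares of TEV
against t_P, with incomplete captures (TEV nominally understated) and
submitochondrial particles excluded by default (both toggles exposed);
t_zero = −intercept/slope is reported only for a negative slope.  Reports
print exact p-values, never significance stars, and apply no
multiple-testing correction.

## Intermittency detection

A dropout event on a line profile is a maximal run of columns below
`f_low × z_max` flanked on both sides, within the analysis window, by
columns at or above `f_high × z_max`.  Defaults f_low = 0.2, f_high = 0.5
map "nearly substrate height" to < 20% of the object height while
requiring genuinely high flanks; both are relative, so detection is
invariant under uniform height rescaling.  The window is the object's row
extent widened by 500 nm (events occur up to a few hundred nm beyond the
apparent edge), and the scanned row band is widened by the same margin —
the backward footprint can exceed the forward-derived mask when edge
memory is active.  Events are counted per scan direction.

## Synthetic generator

The generator emulates the statistical structure the analyses assume;
study-level defaults were set once from the observed marginals:

| parameter | default | rationale |
|---|---|---|
| grid | 128×128 | most common acquisition size |
| frame | 1.6 × object extent | objects fill ~60% of the frame |
| mito diameter | N(1650, 350) nm, ≥ 1500 nm | upper mode of the bimodal sizes |
| submito diameter | N(460, 150) nm, 200–950 nm | lower mode |
| height / radius | U(1.7, 2.0) | apparent heights ≈ diameters (near-spheres) |
| undulations | 100 nm peak-to-peak (RMS 50), corr. 100 nm | observed surface texture |
| δ0 | 150 nm | edge bands of one-to-a-few pixels |
| t_zero | 18.8 h | observed decay of the edge-memory trend |
| δ0 jitter | log-normal, CV 10% | per-record activity scatter |
| dropout trigger q | 0.01 per eligible pixel, runs ≤ 6 px | order-ten events per image |
| z-noise σ | 1 nm | SICM z-resolution |

Construction notes:

* **Caps.**  z(ρ) = max(0, √(r² − ρ²) − (r − h)) on ρ ≤ r.  For h > r the
  overhanging lower half is invisible from above and appears as a vertical
  wall at the equator — the physically consistent top-down view.  Closed
  forms for the visible volume and area of both regimes back the ground
  truth ledger.
* **Irregular objects** are pixelwise maxima of a main cap and lobes at
  evenly spread azimuths (random rotation + jitter, offset 1.3 r, radius
  0.45 r), chosen so the default 3-lobe object is irregular by
  construction (R ≈ 1.2–1.4 across seeds).
* **Undulations** are Gaussian-filtered white noise, centred (the
  realization mean would otherwise be amplified at long correlation
  lengths) and scaled to RMS = amplitude/2, applied only where the ideal
  height is positive and tapered at low rims so heights stay non-negative.
* **Edge memory** is a lateral boundary displacement, not a height change:
  difference images show ± bands localised at edges.  The backward scan
  resamples the forward field with a per-angle radial stretch moving the
  boundary outward by δ(θ) = δ(t_P) · g(θ), where g is a fixed asymmetric
  modulation (1 + 0.7 cos(θ − φ) plus seeded low-order harmonics,
  normalised to mean 1) — one side of the object displaces more than the
  other.  δ(t_P) = δ0 · max(0, 1 − t_P/t_zero) reproduces the linear trend
  and makes forward = backward beyond t_zero.
* **Dropouts** trigger with probability q at climbs steeper than 45°
  *between two on-object pixels* — tilting is modelled as a lateral
  interaction along the flank, not the first vertical contact — and
  replace up to `max_run` in-footprint pixels, starting one pixel past the
  trigger along the scan direction, with substrate level.  Ground-truth
  pixel masks are returned.
* All randomness flows from named integer seeds; identical master seeds
  give byte-identical serialized studies.

## What the benchmark shows — and does not

Problem sizes were chosen so the whole suite runs in well under a minute
of simulation time: parameter recovery uses 20 master seeds × 30 records
at 128×128; detector quality pools 10 seeds; convergence uses a 5 nm-pitch
hemisphere.  Under those conditions the package recovers a configured
t_zero = 18 h within 10% in ≥ 90% of seeds (homogeneous geometry, 10%
edge-memory jitter — with the full heterogeneous size mixture the scatter
is dominated by object-size variation, as in real data), flags injected
dropouts with precision and recall ≥ 0.9, and keeps R ≥ 0.98 and
MCI* ≥ 1/√2 − 0.03 for every segmented object of the default preset.

The generator does **not** emulate instrument drift, feedback dynamics,
pipette geometry or convolution, substrate waviness beyond a plane, or
biological shape change between repeated measurements; passing these tests
therefore validates the estimators and their implementation, not the
physical interpretation of any particular measured dataset.  Reproducing
the measured-data headline numbers (e.g. a fitted ~18.8 h zero crossing on
real mitochondria) requires the corresponding deposited raw data and is
outside the test suite.

## Degenerate inputs and tie-breaks

Single-row grids reject plane fitting and difference alignment; all-zero
grids reject segmentation; empty or multi-component masks are invalid by
construction.  Zero-variance samples reject Welch's test; zero-variance
paired differences short-circuit the MCI* test to its analytic limits
(t = 0, p = 0.5 at zero mean).  A zero trend slope leaves t_zero
undefined rather than infinite.  The classification boundary is inclusive
at exactly 15% (with a 1e-12 relative guard against representation error).
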