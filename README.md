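# sicmorph

Morphometry and morphodynamics of scanning ion conductance microscopy
(SICM) topography scan pairs.

Hopping-mode SICM maps the apparent height z(x, y) of a specimen with a
nanopipette, recording every line once in the forward and once in the
backward fast-axis direction.  For isolated, metabolically active
mitochondria — cap-like objects 0.2–2.6 µm across sitting on a flat
substrate — the two scans of one line systematically disagree at the object
edges, and that disagreement decays over the hours following sample
preparation.  `sicmorph` quantifies both the static shape and this
morphodynamic signal, and ships a synthetic scan-pair generator that
provides ground truth for every analysis stage.

## What it computes

**Projected shape.**  The object outline is a sub-pixel iso-contour of the
height field; its perimeter p_m is compared with the perimeter p of the
circle of equal area A:

    R = p_m / p = p_m / (2 √(π A))

R = 1 marks a circular projection; objects within 15% of 1 are classed
spherical/ellipsoidal, all others irregular.

**3-D shape.**  Volume is the integral of the apparent height,
V = Δx Δy Σ z_i; surface area SA is computed by triangulating the height
field (two spatial triangles per grid cell).  The modified mitochondrial
complexity index

    MCI* = SA^(3/2) / (6 √π V)

is 1 for a full sphere and 1/√2 ≈ 0.707 for a hemispherical top surface —
the practical floor, since the probe never sees the bottom face.

**Morphodynamics.**  The total edge volume of a forward/backward pair,

    TEV = Δx Δy Σ_i |z_i^bwd − z_i^fwd|,

integrates the scan disagreement over the frame (nm³).  On active
mitochondria TEV is dominated by a lateral edge displacement (the *edge
memory effect*) and decreases roughly linearly with the time t_P since
preparation; the zero crossing t_zero = −intercept/slope of the fitted
line estimates when morphodynamic activity ceases.  Objects with an
equivalent-sphere diameter below 1 µm (submitochondrial particles) carry
no edge-memory signal and are excluded from the fit, as are incomplete
captures.

**Height intermittency.**  Line profiles along the fast axis of weakly
immobilised, steep objects drop abruptly to near-substrate level and
recover a few pixels later ("tilting").  The detector flags maximal runs
below 20% of the object height flanked on both sides by columns above 50%.

**Synthetic data.**  `simulate_study` generates reproducible studies of
spherical / ellipsoidal / irregular caps with ~100 nm surface undulations,
a seeded edge-memory displacement δ(t_P) = δ0 · max(0, 1 − t_P/t_zero),
stochastic dropout runs at steep slopes, and 1 nm Gaussian z-noise —
together with a ground-truth ledger (true shapes, δ per record, dropout
pixels).

## Worked example

`examples/02_edge_memory_tev.py` simulates a 30-measurement study with the
edge memory decaying to zero at 18.8 h, computes TEV per scan pair and fits
the trend:

```
id      t_P[h]   TEV[nm^3]   group
syn000    0.95   2.394e+09  mitochondrion
syn001    1.83   1.093e+09  mitochondrion
syn002    1.77   1.245e+09  mitochondrion
...

slope      = -7.729e+07 nm^3/h
intercept  = 1.355e+09 nm^3
t_zero     = 17.5 h   (configured decay time: 18.8 h)
r^2        = 0.42  over n = 21 measurements
```

The fitted zero crossing recovers the configured decay time to within the
study's scatter (mixed object sizes, 10% edge-memory jitter, dropouts and
z-noise); 21 of 30 records enter the fit after excluding submitochondrial
particles and incomplete captures.  The other examples cover single-object
shape metrics (`01`), dropout detection against ground truth (`03`) and the
full report pipeline (`04`).

A thin CLI wraps the same library calls:

```sh
sicmorph simulate --n 30 --seed 1 --out study/
sicmorph report --manifest study/manifest.csv --out bundle/
```

## Layout

- `src/sicmorph/core.py` – domain types (Topography, ScanPair, masks)
- `src/sicmorph/io.py` – ascii/TIFF/CSV height maps, manifests
- `src/sicmorph/preprocess.py` – row alignment, plane levelling, zero floor, segmentation
- `src/sicmorph/shape.py` – contour, R, V, SA, MCI*, diameters
- `src/sicmorph/morphodynamics.py` – difference images, TEV, trend, grouping, MCI* decrease test
- `src/sicmorph/intermittency.py` – line profiles and dropout detection
- `src/sicmorph/synthetic.py` – generator and study simulation
- `src/sicmorph/pipeline.py`, `cli.py` – orchestration and command line
- `docs/methods.md` – model assumptions, parameter choices, limitations
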