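# Methods

This note documents the models, defaults and numerical conventions behind
`gelscreen`, and what the synthetic benchmarks do and do not demonstrate.

## Erosion kinetics model

Discs degrade by surface erosion acting on the radius only, with the
thickness held constant. This reflects the top-view imaging geometry of
the chip: under tangential perfusion the visible footprint of a disc
shrinks radially, and a top-down camera cannot observe thickness at all,
so the simulator deliberately matches what the measurement can see.

- Radius: `r(t) = max(0, r0 − k · C · t)` with enzyme concentration `C`
  (µg/mL) and erosion coefficient `k` (mm·h⁻¹ per µg/mL). Linearity in
  both time and concentration is the simplest model consistent with the
  endpoint-rate estimator's own linear-degradation assumption; the true
  rate-vs-concentration law is not known quantitatively, so `k` is an
  exposed parameter rather than a fitted constant.
- Default `k = 1/600 mm·h⁻¹ per µg/mL`, chosen so that a 2 mm disc at
  100 µg/mL completes at 12 h — the time scale observed for chip-perfused
  discs at that concentration.
- Mass: `m(t) = π r(t)² h0 · density_scale`. With `density_scale =
  100 µg/mm³` (a 10% w/v gel) the default disc weighs π·4·1·100 ≈ 1257 µg.
  Degraded-gel release is `m(0) − m(t)`, so gel mass is conserved exactly.
- Disintegration: an all-or-nothing collapse (radius → 0) mimicking the
  abrupt break-up of weakened discs at high enzyme levels. It is gated by
  an area-fraction threshold (`disintegrate_frac`, default 0.2) and fires
  with per-step probability `disintegrate_prob` (default 0 — off unless a
  condition enables it), drawn from a per-well seeded generator.

## Release model

Cumulative payload release combines passive diffusion and
degradation-coupled release:

```
cum(t) = load · [ f_b · (1 − exp(−t/τ)) + (1 − f_b) · (1 − r(t)²/r0²) ]
```

The first term is an early burst (fraction `f_b = 0.3`, time constant
`τ = 1 h`) reproducing the observation that a detectable burst appears at
the 1 h sample with or without enzyme; the second ties the remaining
payload to the eroded volume fraction, which for constant thickness equals
the eroded area fraction. The functional forms are modeling choices of
this package, not measured laws. Default `load = 942 µg` is 7.5% w/v PVA
times the 12.57 µL disc volume.

## Rendering

Frames are 8-bit RGB: neutral chip body (120,120,120), dye-tinted medium
inside wells (235,185,185 — red hue, saturation ≈ 0.21), strongly stained
disc (200,30,40 — saturation ≈ 0.85). A pixel belongs to a disc iff its
center lies within the circle (closed inequality); well centers sit at
half-integer coordinates so no pixel center coincides with a disc center.
This exact pixel-center-in-circle rule is shared by the renderer, the
segmentation benchmark and the brute-force test oracle. Additive Gaussian
sensor noise (default SD 5 intensity units) is clipped to [0,255];
Poisson-distributed debris specks (default rate 1/frame, ≤ 20 px) of
disc-colored pixels are grown by seeded random walks at non-well locations,
emulating fragments flowing through the channels. Default scale is
20 px/mm and one frame per minute over 20 h.

## Segmentation and tracking conventions

- The color gate works in HSV (hexcone conversion): hue within a
  wrap-around window (default [340°, 20°]) AND saturation ≥ 0.35 AND value
  ≥ 0.15. The saturation floor is what separates the disc from the tinted
  medium, which shares its hue; achromatic pixels (hue defined as 0°) are
  rejected by any positive saturation floor.
- Mask cleaning removes 8-connected regions smaller than `min_region_px`
  (default 5). It is a pure min-area filter — no morphology — so the
  cleaned mask is a subset of the thresholded pixels and the operation is
  idempotent. Note the coupling: a disc is declared "completely degraded"
  when its cleaned area reaches zero, so `min_region_px` is also the
  detection floor; at 20 px/mm, 5 px corresponds to a disc of radius
  ≈ 0.06 mm, which biases detected completion earlier by at most ~0.4 h at
  the 100 µg/mL erosion speed (within the 5% rate-recovery tolerance the
  benchmarks check).
- Connected components are 8-connected; labels follow raster-scan order of
  first encounter, making labelings deterministic and comparable.
- Regions are assigned to the well containing their centroid; fragments in
  one well are summed (the disc, not the fragment, is the unit of
  interest); regions with centroids in the channels are discarded as
  debris. A disc whose area returns above zero after reaching zero is
  logged as an anomaly and not marked complete.
- Traces are normalized to frame 0, which must have positive area for
  every tracked well.

## Rates and events

The endpoint pseudorate is `100/t_c` %/h for completing discs and
`100·(A(0)−A(T))/A(0)/T` otherwise, floored at zero; a least-squares-slope
variant (`pseudorate_regression`) is provided but is explicitly not the
canonical estimator. Disintegration flags fire when a single-frame drop
reaches `drop_frac` (default 0.3) of the initial area; the default is an
exposed choice, not a measured threshold.

## Assay conventions

The standard curve is a straight line fit by ordinary least squares — the
iodine–borate PVA assay is linear in its working range, so range
enforcement (an `extrapolated` flag outside the calibrated span, with a
1e-9-relative tolerance absorbing round-off at the endpoints) replaces
curve-shape complexity. Defaults slope 0.02 AU/(µg/mL), intercept 0.05,
standards 0–100 µg/mL. Two standards at distinct concentrations are the
accepted minimum (the fitted line then passes through both). Cumulative
mass assumes a closed recirculating reservoir (default 20 mL); the 50 µL
withdrawals are treated as negligible. Degraded gel in the eluate is
quantified with the same standard-curve machinery as a second analyte; the
assay chemistry itself is out of scope.

## Statistics

Pearson r with the t-transform p-value (n−2 df); one-way fixed-effects
ANOVA; Tukey HSD from the studentized-range distribution (Tukey–Kramer for
unequal group sizes); stars at 0.05/0.005. Degenerate designs are rejected
with explicit messages: fewer than three pairs or a zero-variance margin
for correlation; a group with fewer than two replicates, all observations
identical, or zero within-group variance in every group for ANOVA.
p-values in reports are rounded to 3 significant figures.

For the mass validation, visual area is paired with dry mass per well at
the mass-sampling times (nearest trace frame within 0.5 h). For the eluate
validation, the per-timepoint eluted-gel mass is converted to *remaining*
gel (initial mass minus eluted) before correlating with visual area: the
raw eluted quantity rises as the disc shrinks, so the remaining-gel
convention expresses the same information with a positive association.

## Replicate variability

Config-driven runs apply a multiplicative Gaussian jitter
(`erode_jitter_frac`, default 0.05) to each replicate's erosion
coefficient, representing disc-to-disc variability in casting and
crosslinking. Without it, replicates of a deterministic kinetics model are
identical and between/within-group statistics degenerate. The
`simulate_kinetics` function itself remains the exact closed-form model;
jitter enters only when wells are built from a config.

## Determinism and problem sizes

All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence` spawning — kinetics, rendering, standards,
eluates, masses and replicate jitter each get an independent child stream,
so a chained `run-all` is reproducible byte for byte (the machine-readable
summaries contain no timestamps). The test-suite and acceptance
benchmarks run the 8-well, 20 h experiment at a 15-min frame interval
(81 frames) rather than the 60 s study default; at 20 px/mm this changes
recovered rates by well under the tolerances checked, and keeps a full
synthetic run in the tens of seconds.

## What the synthetic benchmarks show — and don't

The simulator reproduces the features the pipeline must be robust to:
dye-tinted media sharing the disc's hue, sensor noise, flowing debris,
fragmenting discs, abrupt disintegration, and the burst-plus-coupled
release shape. It does not emulate uneven illumination, color drift,
shadows, reflections at the well walls, partial staining, disc swelling,
or out-of-well disc drift. Passing the benchmarks therefore demonstrates
correctness of the algorithms under controlled conditions — exact
segmentation of the rasterized geometry, rate recovery within 5%, release
recovery within 10% — not performance on real photographs, for which the
color gate and `min_region_px` should be tuned per rig. The near-unity
validation correlations on synthetic data follow partly by construction
(simulated mass is proportional to true area); they verify the
measurement chain, not the biological claim.
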