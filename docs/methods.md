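# Methods

`aggrescope` analyzes time-lapse microscopy of model marine-snow particles:
millimeter-scale hydrogel disks seeded with diatoms, facultatively
denitrifying bacteria and oxygen-sensitive nanoprobes, held in a millifluidic
device while seawater flows past at an imposed sinking speed. This note
describes the models and numerical choices behind each stage, what the
synthetic scene generator does and does not emulate, and the package's known
limitations.

## Depth translation

Time in the device is an analog of ocean depth: `depth(t) = w · t / 24` with
the sinking speed `w` in m d⁻¹ (default 4.8) and `t` in hours. The mapping is
strictly linear — no compaction, acceleration, or boundary-layer correction —
so 100 h corresponds to 20 m and 200 h to 40 m at the default speed. All
"depth profiles" produced by the package are time series relabeled through
this map.

## Particle geometry

The particle is detected once, in the first brightfield frame, and its
geometry reused for the whole stack (an optional per-frame re-detection is
deliberately absent: the hydrogel disk does not move). The chain is a
1st–99th percentile contrast stretch, Gaussian blur (σ = 20 px), Otsu
threshold, largest connected component, and hole fill. Two refinements
correct known biases of that chain:

- the raw Otsu cut is re-thresholded (3 passes) at the midpoint of the
  inside/outside median levels of the blurred image, because for a blurred
  symmetric step the midpoint level set sits exactly on the edge while Otsu
  drifts with the fore/background area ratio;
- the final boundary is re-localized on a lightly smoothed image (σ = 2 px)
  with the same midpoint rule, because heavy blur pulls the level set of a
  convex boundary inward by ≈ σ²/2R (≈ 1.9 px for σ = 20, R = 150 px).

With both refinements, a noiseless synthetic disk of radius 150 px is
recovered to ±0.5 px, and the estimate is stable under additive noise up to
5 % of the dynamic range.

`distance_to_edge` is the Euclidean distance transform anchored on the
*contour pixels* of the mask (mask pixels with a 4-connected background
neighbour are the zeros of the transform). A contour point therefore has
distance exactly 0 and the center of a disk has distance ≈ R. All radial
statistics use this distance-from-edge, not distance-from-center: oxidants
are resupplied from the boundary, so the edge is the physically meaningful
origin. Coordinates are 0-based `(row, col)`, origin top-left; the pixel size
(µm) is taken from the run configuration.

## Oxygen: sensor model, calibration, inversion

The nanoprobe is a quenching-type oxygen sensor: fluorescence is maximal
under anoxia and falls as oxygen rises, following two-parameter Stern–Volmer
kinetics

    F(C) = F0 / (1 + Ksv · C)

with `C` in µmol L⁻¹ and `Ksv` in (µmol L⁻¹)⁻¹. We use the two-point
Stern–Volmer form rather than linear interpolation between the endmembers:
interpolation is the degenerate `Ksv → 0` limit and misrepresents the
curvature of a quenching sensor; the choice is recorded in the calibration
metadata.

Each particle carries its own calibration: one endmember frame at full
anoxia (nitrogen-sparged, after chloramphenicol arrest) and one at
air-equilibration. Because the nanoparticles are never distributed perfectly
evenly, the particle is divided into `n_zones` equal-width annuli of
distance-from-edge (default 20; the zone count is a free parameter) and the
median endmember fluorescence is taken per zone, giving

    Ksv(zone) = (F_anoxic / F_air − 1) / C_sat.

`C_sat`, the air-equilibrated oxygen concentration, is supplied by the user
(generator default 210 µmol L⁻¹, a typical value for warm surface seawater;
no temperature/salinity solubility correction is applied — supplying the
right saturation is the caller's job). A zone where `F_anoxic ≤ F_air` has
no quenching contrast and is flagged invalid rather than interpolated;
conversion over an invalid zone yields NaN. Calibration frames are treated
as time-invariant (no photobleaching correction; none is modelled by the
generator either).

Per-pixel inversion uses the pixel's zone: `C = (F_anoxic/F − 1)/Ksv`,
clipped to `[0, C_sat]`; non-positive fluorescence pixels are masked and
counted in the log. Oxygen categories follow strict upper bounds — nanoxic
(< 1), suboxic (< 5), microoxic (< 10), hypoxic (< 40 µmol L⁻¹), otherwise
oxic — so exactly 40 µmol L⁻¹ is classified oxic and the category areas nest
by construction.

## Diatom exclusion and colony segmentation

Diatom chains are strongly elongated; hydrogel microcolonies are
near-circular. The elongation shape factor (ESF) of a pixel set is
`sqrt(λ_major/λ_minor)` of its second central moment matrix: 1 for a disk,
a/b for an a:b ellipse, ∞ (flagged) for collinear pixel sets. Objects with
ESF ≥ 2 (default; configurable) are masked as diatoms and their pixels
invalidated in the sensor and reporter channels before any statistic,
because chlorophyll autofluorescence bleeds into those channels.

Colony detection per frame is two-stage:

1. **Candidates** — Sobel gradient magnitude, Otsu threshold of the gradient,
   dilation (disk, radius 2 px), flood fill. This finds closed object
   outlines robustly but inflates every footprint by the dilation radius
   plus the Sobel support.
2. **Refinement** — an intensity Otsu binarization of the brightfield over
   the particle interior, intersected with the candidates. The intensity
   gate restores the imaged footprint (exactly, on noise-free synthetic
   scenes), while the candidate gate suppresses isolated intensity speckle.

Components smaller than 10 px² are dropped, and a 5 px edge-exclusion band
removes the particle's own rim from the object pass (the rim would otherwise
binarize as one giant "colony"); both parameters are logged. For every
retained colony the frame, time, label, pixel area, centroid,
distance-to-edge, and median oxygen over its pixels (with category) are
recorded.

## Backtracking

Microcolonies appear and expand in place; they do not translocate. Linking
therefore runs backward from the final frame — the most information-rich
anchor — matching each colony to at most one colony in the previous frame by
maximal pixel overlap. Matching is injective per frame pair and greedy in
descending overlap, with deterministic tie-breaks (larger area, then lower
label id). A colony with no overlap match may fall back to the nearest
unclaimed centroid within 20 µm; a track may bridge up to 2 missing frames
(segmentation dropouts). When two later colonies contend for one ancestor,
the larger overlap claims it and the loser's backtrack terminates, recorded
as a "split-orphan" in the QC output — tracks never share an ancestor. Both
thresholds and all QC counts are emitted alongside the track table.

## Growth phases and lag statistics

Facultative denitrifiers under falling oxygen show diauxic colony growth: an
aerobic exponential phase, an intermediate lag while the denitrification
machinery is synthesized, then a second (anaerobic) exponential phase.
Per track, log area vs time is fitted piecewise-linearly with up to 3
changepoints by dynamic-programming segmented least squares; the segment
count is chosen by BIC (`n ln(RSS/n) + p ln n`, `p = 2·segments +
changepoints`, RSS floored at `n·10⁻¹²` so noise-free segments do not
degenerate the log). Segment costs come from prefix sums, so the fit is
O(n²k).

The operational lag definition — the literature states the phenomenon but no
criterion — is: the maximal *interior* fitted segment whose |slope| is below
10 % of the first segment's rate μ₁. A trailing slow segment is stationary
phase, not lag. Zero-area observations are treated as missing, never
log(0). Tracks shorter than 12 observations are flagged and excluded from
lag statistics. Lag durations are reported in hours and depth-translated
meters, as mean ± std *and* median. Broken- vs intact-diatom lag
distributions are compared with Welch's t-test — a supporting routine
statistic, not a novel method.

## Exposure fractions and oxygen series

Per frame, the fraction of total colony area with pixel oxygen strictly
below each of {40, 10, 5, 1} µmol L⁻¹ is computed by pixel counting; the
fractions nest by construction. A frame with no colony pixels yields a
missing value, never zero. The particle-level oxygen series is the per-frame
mean of per-colony median oxygen, with per-replicate series retained when
several particles are analyzed together.

## Radial statistics

- **Biomass profile**: final-frame cumulative area, mean colony size and
  count per distance-from-edge bin; empty bins are missing, and binned
  totals conserve the overall area.
- **Colony density**: Gaussian KDE of colony distance-to-edge, reflected at
  distance 0 (otherwise the density is biased low exactly where the biology
  concentrates, at the edge) and renormalized numerically to integrate to 1
  over [0, R].
- **Expression profiles** (NarK/NirS-type reporters): the median intensity
  outside the particle is subtracted as background *without* clipping
  individual pixels — clipping rectifies sensor noise into a spurious
  signal floor across the whole disk, which measurably drags peak
  statistics inward. The per-bin statistic (10 µm bins) is the mean
  background-subtracted intensity at each distance, i.e. the radial
  sampling of the signal; using the raw per-bin *sum* instead would weight
  by annulus circumference and bias an interior peak by tens of µm on a
  1.5 mm disk (that variant remains available as `weighting="count"`).
  Bins not exceeding 2 standard errors of their in-bin scatter are zeroed
  (noise floor). Peak location is reported as the intensity-weighted mean,
  std and median distance; on real data mean and median can differ
  substantially when the profile is skewed, which is why both are kept.

## Quasi-steady oxygen field (generator)

The synthetic oxygen landscape solves `D ∇²C = q(x)` on the particle disk
with Dirichlet data `C = C_sat` outside and per-pixel colony consumption
`q`, by red–black successive over-relaxation with over-relaxation factor
`2/(1 + sin(π/N))`. SOR is used within the prescribed relaxation family
because plain Jacobi/Gauss–Seidel needs O(N²) sweeps on an N-grid and is an
order of magnitude too slow at 256². The field is clipped at zero every
sweep, so consumption shuts off at anoxia (an obstacle-problem
approximation). Convergence is declared when the largest per-sweep update
falls below `tol × C_sat` (default 10⁻⁶); exceeding the sweep budget raises
an explicit error, never a silent return. A quasi-steady solve per frame is
justified because colony-scale diffusive equilibration (< 1 s) is orders of
magnitude faster than the 1 h frame interval; each frame warm-starts from
the previous solution.

The solver is validated against the closed-form uniform-consumption disk
solution `C(r) = C_sat − q(R² − r²)/(4D)`, using the effective radius
`sqrt(A/π) + 0.5 px`: the Dirichlet data live on the first exterior node
layer, so the continuum boundary sits half a grid spacing beyond the last
interior node. Agreement at the center and half-radius is ≈ 4×10⁻⁴ relative
on a 256² grid.

## What the generator emulates, and what it does not

Defaults are the study conditions: particle radius 1.5 mm, 10 µm pixels,
1 h frames for ≥ 13 days (312 frames), sinking 4.8 m d⁻¹, O₂ diffusivity
1.9×10⁻⁹ m² s⁻¹, diauxic growth (μ₁ = 0.05 h⁻¹, μ₂ = 0.04 h⁻¹), static
3:1 ellipse diatoms, additive Gaussian sensor noise of 1 % of F0, and a 5 %
linear radial heterogeneity in nanoparticle density (which the zoned
calibration must absorb). Bulk chemistry series anchor the initial DOC
efflux at 28.0 (broken diatoms) vs 14 (intact) mg L⁻¹ C, with a faster
decay and an early nitrite leak in the broken scenario and a flatter efflux
with a mid-depth nitrite peak in the intact one. Colony growth-law lag
populations draw lag durations from Normal(48 h, 20.5 h) — 9.6 ± 4.1 m once
depth-translated — for the broken scenario and Normal(63.5 h, 25 h) —
12.7 ± 5.0 m — for the intact one.

Deliberately not emulated: 3-D particle geometry (the experimental disks are
sandwiched between impermeable plates, so 2-D is faithful); flow
hydrodynamics and boundary-layer thinning around the particle;
carbon-explicit metabolism (consumption strength is a fixed per-colony
parameter, not coupled to substrate); diatom physiology (diatoms are static
bright ellipses, a carbon source and optical nuisance, not tracked
objects); colony merging, irregular colony shapes, illumination drift and
photobleaching. Passing the round-trip suites therefore demonstrates the
*pipeline's* correctness on scenes obeying these assumptions — it does not
certify performance on real stacks with merging colonies, drifting focus or
non-radial sensor heterogeneity. The skew that makes measured expression
peak means and medians differ (204 vs 360 µm in the nitrate-reduction
channel of real particles) is reproduced structurally by reporting both
statistics, not numerically by the symmetric synthetic rings.

## Problem sizes in the shipped checks

The test suite and the reproduction script run at desk scale by choice:
round-trip scenes use a 1 mm particle (260² px) over 10 hourly frames with
5 colonies and 6 diatoms; solver validation uses a 256² grid; lag recovery
uses 200 synthetic tracks per scenario; expression-peak recovery uses 20
noise realizations on a full-size 1.5 mm disk. These sizes keep every check
well-conditioned (hundreds of thousands of pixels, hundreds of tracks)
while the full pipeline completes in well under an hour on one core.

## Known limitations

- The changepoint fit assumes piecewise log-linear growth; smooth ramps
  between phases blur the inferred lag boundaries by 1–2 frames.
- Calibration zones are radial annuli; azimuthal nanoparticle heterogeneity
  within a zone is not corrected and appears as inversion error.
- The tracker's split-orphan policy discards the shorter branch of a true
  colony division rather than building a lineage tree.
- The solver's zero-clip is an approximation to the free-boundary
  (obstacle) problem; fully anoxic cores are handled correctly, but the
  anoxic/oxic interface is resolved only to one pixel.
- `classify_oxygen` and the exposure fractions use strict `<` bounds
  exactly as defined; values sitting exactly on a bound go to the higher
  category.
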