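# aggrescope

Microscale image analysis of bacterial colonies and oxygen microenvironments
in sinking marine-snow particles.

Sinking organic particles host dense microbial activity, and because oxygen
must diffuse in from the boundary while colonies consume it locally, anoxic
microsites can arise inside a particle — even within microns of its edge and
in fully oxygenated bulk seawater — permitting anaerobic metabolisms such as
denitrification far outside the ocean's classical oxygen-deficient zones.
`aggrescope` is a pipeline for the laboratory version of this system:
millimeter-scale hydrogel disks seeded with diatoms, facultatively
denitrifying bacteria and oxygen-sensitive nanoprobes, imaged hourly for
~two weeks while seawater flows past at an imposed sinking speed. It is
aimed at microbial ecologists and biogeochemists who need calibrated,
per-colony oxygen and growth trajectories from such time-lapse stacks — and
a ground-truthed synthetic microscope to validate every stage without real
data.

## What it computes

- **Particle geometry** — edge detection (Gaussian blur σ = 20 px + refined
  global threshold) and a per-pixel distance-to-edge transform, the origin
  of all radial statistics.
- **Oxygen** — per-particle, radially zoned two-endmember calibration of a
  quenching nanosensor, `F = F0/(1 + Ksv·C)`, inverted per pixel via
  `C = (F_anoxic/F − 1)/Ksv`; oxygen categories at strict bounds
  nanoxic < 1 < suboxic < 5 < microoxic < 10 < hypoxic < 40 µmol L⁻¹ < oxic.
- **Colonies** — diatom exclusion by elongation shape factor
  (ESF = √(λ_major/λ_minor); 1 for disks, ≥ 2 masks diatom chains), then
  edge-filter → Otsu → dilate → flood-fill segmentation with an intensity
  refinement, and backward-in-time linking of colonies into tracks with
  explicit split handling.
- **Dynamics** — linear time→depth translation (`depth = w·t/24`, default
  w = 4.8 m d⁻¹), diauxic growth-phase decomposition of log-area by
  BIC-penalized piecewise-linear changepoint fitting (exponential → lag →
  second exponential → stationary), lag-duration statistics in hours and
  meters, and oxygen-exposure area fractions per threshold.
- **Spatial statistics** — radial biomass profiles, edge-reflected colony
  density estimates, gene-expression (e.g. NarK/NirS reporter) radial
  densities with peak localization, and depth-translated bulk chemistry
  (DOC, nitrate, nitrite) profiles with Welch-test condition comparisons.
- **Synthetic scenes** — a generator producing brightfield + nanosensor
  stacks with known colony labels, a quasi-steady reaction–diffusion oxygen
  field (`D∇²C = q` solved by successive over-relaxation), calibration
  endmember frames, and bulk chemistry series for "broken" vs "intact"
  diatom scenarios.

The full model description, parameter defaults and numerical choices are in
[docs/methods.md](docs/methods.md).

## Worked example

```python
import numpy as np
import aggrescope as ag

# ground-truthed synthetic particle: 1 mm radius, 10 hourly frames
config = ag.SceneConfig(
    particle_radius_um=1000, pixel_size_um=10, n_frames=10,
    n_colonies=5, n_diatoms=6, noise_sd=0.0, rng_seed=3,
    growth_law=ag.DiauxicGrowthParams(mu1=0.05, lag_start_h=6,
                                      lag_duration_h=0, mu2=0.04,
                                      area0_um2=3000),
)
stack, cal, truth = ag.render_frames(config)

geom = ag.detect_particle(stack.brightfield[0], pixel_size_um=10)
model = ag.fit_calibration(cal.anoxic, cal.air, geom,
                           o2_saturation_umol_L=config.o2_saturation_umol_L)
diatoms = ag.mask_diatoms(stack.brightfield[0], geom)

labels, obs = [], []
for i, t in enumerate(stack.times_h):
    o2 = ag.fluorescence_to_oxygen(stack.sensor[i], model, geom)
    lab, o = ag.segment_colonies(stack.brightfield[i], geom, diatoms, o2,
                                 frame_index=i, time_h=float(t))
    labels.append(lab); obs.append(o)
tracks, qc = ag.backtrack(np.stack(labels), obs, pixel_size_um=10)

print(f"particle radius  : {geom.equivalent_radius_um:.0f} um")
print(f"Ksv recovered    : {model.ksv.mean():.4f} per umol/L (true 0.0100)")
print(f"colonies tracked : {len(tracks)} over {config.n_frames} frames")
last = tracks[0].observations[-1]
print(f"track 0 at t={last.time_h:.0f} h: area {last.area_um2:.0f} um^2, "
      f"median O2 {last.median_o2_umol_L:.0f} umol/L ({last.o2_category}), "
      f"{last.distance_to_edge_um:.0f} um from the edge")
```

prints

```
particle radius  : 1015 um
Ksv recovered    : 0.0100 per umol/L (true 0.0100)
colonies tracked : 5 over 10 frames
track 0 at t=9 h: area 4400 um^2, median O2 133 umol/L (oxic), 424 um from the edge
```

The detected radius is the generator's 1000 µm disk plus its 2-px bright
rim as seen through the edge detector; the quenching constant comes back at
the generator's true value because both calibration endmembers share the
same nanoparticle heterogeneity; and each tracked colony carries its area,
local median oxygen with category, and distance to the particle edge at
every time point. On this noise-free scene segmentation recovers the
ground-truth colony count and pixel areas exactly, and the recovered oxygen
field agrees with the generator's to well under 2 µmol L⁻¹ RMSE.

The same pipeline is available from the shell:

```sh
aggrescope simulate --config scene.yaml --out scene/
aggrescope geometry --in scene/ --out geom.json
aggrescope calibrate --anoxic scene/calibration_anoxic.tif \
    --air scene/calibration_air.tif --mask geom.mask.tif \
    --pixel-size 10 --saturation 210 --out cal.json
aggrescope segment --in scene/ --mask geom.mask.tif --calibration cal.json --out seg/
aggrescope track --obs seg/observations.csv --labels seg/colony_labels.tif \
    --pixel-size 10 --out tracks.csv
aggrescope dynamics --tracks tracks.csv --speed 4.8 --out phases.csv
aggrescope profile --tracks tracks.csv --mask geom.mask.tif --pixel-size 10 --out profiles/
```

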