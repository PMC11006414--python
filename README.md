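# nestflux

Tools for studying how termite construction is organized by its physical
substrate. Early nest building by *Coptotermes gestroi* on a humid clay
disk shows a striking asymmetry: pellets are collected wherever the
animals happen to be, but deposited at specific places — the tips of
topographic cues and the rim of the clay disk. Those places share one
physical property: they are local maxima of the evaporation flux, which
in the diffusive regime near the surface is proportional to the surface
mean curvature. `nestflux` implements the three computations needed to
study this mechanism quantitatively, plus synthetic-data generators so
the whole chain is testable without experimental footage:

- **`scene_geometry`** — parametric arenas (clay disk, pillar and wall
  cues, pellet band), height maps, voxel occupancy masks, and import of
  surface-scan meshes (STL/PLY/OBJ) as height fields.
- **`growth_model`** — a phase-field model of curvature-driven
  construction: an order parameter f (1 = clay, 0 = air) evolves by
  `df/dt = f(1-f)[-d lap f - lap lap f]`, so convex clay accretes,
  concave clay erodes, and a curvature-diffusion term sets a cutoff
  scale selected by the single parameter `d` (calibrated to the 3 mm cue
  scale). Initially solid voxels are frozen: dried structures are never
  re-worked.
- **`humidity_solver`** — the steady diffusive humidity field
  `lap h = 0` over a scene (100% at the wet clay surface, 70% ambient at
  the top, no-flux walls), humidity-gradient maps |grad h| in mm^-1,
  surface evaporation flux with a staircase-corrected estimator,
  tip-amplification ratios, the boundary-layer estimate
  `|grad h|0 = delta_h / delta = 0.15 mm^-1`, and the flux–curvature
  rank correlation (the Maxwell droplet law, flux ∝ 1/R, is the built-in
  oracle).
- **`image_pipeline`** — timelapse change detection: background
  subtraction, rolling-median suppression of moving animals, 800 s
  activity windows, connected-component pellet events (10–400 px),
  collection/deposition/occupancy maps on a 0.75 mm grid, conditionals
  P(D|O), P(C|O), radial profiles and cut cross-sections.
- **`synthetic_timelapse`** — ground-truth generator: renders arena
  frames with walking termite blobs, pellet collections and
  stimulus-weighted depositions (curvature or humidity-gradient
  stimulus), trajectory tables and a full event log.
- **`profiles` / `reproduce` / `cli`** — the comparison layer (profile
  overlays along the cut through the pillars, end-to-end target
  computations, a `nestflux` command-line front end).

## Worked example

Amplification of the evaporation flux at the pillar tips, and the
growth-model deposition profile, from scratch:

```python
from nestflux import reproduce as rp

amp = rp.pillar_tip_amplification(spacing=0.2)
print(amp["amplification"], amp["tip_max_mm^-1"], amp["reference_median_mm^-1"])
# 8.345  0.1128  0.0135

growth = rp.growth_deposition_peak(spacing=0.3)
print(growth["d"], growth["peak_radius_mm"])
# 17.54596337971441  4.75
```

The first numbers say: solving the humidity field over the two-pillar
scene (18 mm cube, 0.2 mm voxels), the strongest surface gradient sits
at the pillar tips at ~0.11 mm^-1, about 8.3 times the ~0.014 mm^-1 over
the flat disk — evaporation is focused where deposition is observed (at
0.15 mm resolution the ratio is 9.3, approaching the ~10x working
figure). The second: with `d` calibrated so the model expresses a ~3 mm
feature scale, integrating the growth equation to dimensionless t = 9
adds material whose radial histogram along the cut through both pillars
peaks at R = 4.75 mm — the pillar tips (centres at R = 4 mm).

Synthetic end-to-end closure:

```python
res = rp.pipeline_recovery(seed=1)
print(res["recovery_fraction"])   # 1.0
```

i.e. every pellet event planted in a rendered timelapse is recovered by
the image pipeline within one 0.75 mm cell.

The same computations are available from the shell:

```bash
nestflux scene --spec spec.yaml --spacing 0.15 --out scene.h5
nestflux humidity --scene scene.h5 --out h.h5
nestflux growth --scene scene.h5 --d auto --t-end 9 --out run.h5
nestflux synth --stimulus humidity --alpha 4 --seed 7 --out sim/
nestflux reproduce --config config.yaml --out report.json
```

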