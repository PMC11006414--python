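# Methods

`nestflux` models the early construction behaviour of *Coptotermes
gestroi* workers on a humid clay disk decorated with topographic cues
(two pillars or a short wall), and the physics that organizes it:
substrate evaporation, which in the diffusive regime is proportional to
surface curvature. The package has three computational pillars — a
curvature-driven phase-field growth model, a steady diffusive humidity
solver, and a timelapse change-detection pipeline — plus generators for
synthetic scenes and synthetic recordings so that every stage can be
validated against known ground truth.

All lengths are millimetres; the coordinate origin is the arena centre,
x–y in the Petri plane, z up. Voxel indices map to cell centres.

## Scene geometry

A scene is parametrized (`SceneSpec`) by the arena (Petri) radius
42.5 mm, clay-disk radius 25 mm, cue dimensions (pillars 6 mm high,
3 mm across, 8 mm apart centre-to-centre; wall 6 mm high, 12 mm long,
3 mm thick) and the annular pellet band (7.5–17.5 mm, pellets 0.75 mm).
Two values the experimental description does not pin down are defaults
here:

- **disk thickness 1.5 mm** — 2.8 g of wet clay spread over a 5 cm disk
  gives an order-1 mm layer; configurable.
- **transition smoothing** — the disk rim is hand-feathered onto the
  Petri floor: Gaussian smoothing over `edge_smoothing` = 1.0 mm. The
  molded cues are crisper than the rim, so their edges get a separate
  `cue_edge_smoothing` = 0.5 mm; a single 1 mm kernel would blunt a 3 mm
  pillar top by about a third of its height, which the molded clay
  pieces do not show. Kernels use sigma = width/2.

Height maps are sampled on node-registered grids (default 0.15 mm,
coarsenable for the PDE solvers) and voxelized by the centre-below-
surface rule. Surface-scan meshes (STL/PLY/OBJ) are imported by
rasterizing the triangle soup into an upper-envelope height map — a
containment test on vertex positions only, hence independent of face
orientation — and voxelized through the same path; non-manifold or
degenerate meshes are rejected.

## Curvature-driven growth model

The nest wall is an order parameter f on a 3D grid (f = 1 clay, 0 air;
building surface = the 0.5 level set, ties toward solid). The update is

    df/dt = f (1 - f) [ -d K - lap K ],     K = lap f,

where K approximates |grad f| div(n) near the interface. The first term
makes convex clay accrete (and concave clay erode — the digging
prediction); the second damps curvature variations below a cutoff,
standing in for the finite pellet size and the smoothing the builders
apply. The signs are pinned behaviourally: a solid sphere grows, a
spherical cavity deepens, a flat interface is stationary, and short-
wavelength corrugations decay while long ones grow. Voxels with
f > 0.85 at t = 0 are frozen (dried structures are never re-worked).
Time is the model's dimensionless unit; no mapping to wall-clock
building time is attempted.

Numerics: explicit Euler with the biharmonic-dominated stability bound
dt <= dx^4 / (8 (d dx^2 + 4)) (validated by the boundedness suite),
7-point Laplacians with zero-flux ghost cells on all domain faces, and
clipping to [0, 1]. The inner loop is a compiled (numba) kernel; runs
are bitwise deterministic.

**Pattern-scale calibration.** `d` selects the emergent feature scale.
Sharp-interface theory predicts a fastest-growing wavelength
2 pi sqrt(2/d), but at affordable resolution the diffuse interface
(width ~1 mm) renormalizes the dispersion relation appreciably, and for
d beyond roughly 30 (at 0.3 mm spacing) the 1D interface profile itself
destabilizes. The calibration therefore *measures* rather than assumes:
`perturbation_growth_rate` displaces a relaxed flat interface by a
single small cosine corrugation and measures its growth rate; the
emergent wavelength is the fastest-growing probe wavelength, and
`calibrate_d` picks, among candidates 0.5/1/2 times the theory estimate,
the one whose measured wavelength is nearest the 3 mm cue scale. The
procedure is deterministic and monotone in d over the stable range. (A
noisy-interface variant with a spectral-peak readout was tried first and
discarded: with the weak, broad-band growth rates of the diffuse-
interface regime, single-realization spectral peaks land on domain-scale
modes.) The pillars-scene deposition peak is insensitive to d across
8.8–35, because the pillar tips dominate the curvature field regardless.

Deposition extraction follows the shape-difference recipe: added voxels
are those solid at the end but not at t = 0; each added voxel within
half a cue thickness of the vertical cut plane through the pillar
centres is mapped to its nearest t = 0 surface voxel (k-d tree), and the
histogram of the horizontal radii of those surface voxels, normalized by
its maximum, is the simulated deposition profile. Peaks are read off
after a 3-bin boxcar.

## Diffusive humidity solver

In the viscous boundary layer, vapour transport is diffusive and the
stationary relative-humidity field solves lap h = 0. The reference
domain is an 18 mm cube whose bottom is the scene surface: Dirichlet
h = 100% on every air face adjacent to wet clay (the whole surface, not
only z = 0), Dirichlet h = 70% at the top plate, zero-flux lateral
walls; dry floor (bare Petri outside the disk) is reflecting. Relative
and absolute humidity are proportional at constant temperature, so
|grad h| is quoted in mm^-1 on the fraction scale (0.1 mm^-1 = 10% per
mm). A closed-form anchor: a 30% drop across the ~2 mm boundary layer
gives |grad h|0 = 0.15 mm^-1.

Discretization: 7-point finite differences on the air voxels with
Dirichlet values imposed on voxel *faces* (coefficient-2 ghosts half a
step away), which keeps the system symmetric positive definite and puts
the numerical surface exactly at the staircase geometry; conjugate
gradients to relative residual 1e-8 from a linear initial profile.
Arbitrary per-face boundary conditions are supported; the Maxwell sphere
oracle imposes the analytic far field h_top + (h_s - h_top) R/r on all
box faces to emulate an infinite domain. Discrete flux conservation
(surface outflow = top-plate outflow with no-flux laterals) holds to the
solver residual by construction.

**Surface flux.** The raw one-sided face difference is exact on flat
axis-aligned surfaces but ~35% low on curved staircase surfaces, because
it samples a decaying near-field a finite distance out. The default
estimator therefore (i) locates the surface sub-voxel as the
0.5-crossing of a Gaussian-smoothed solid indicator along the outward
normal, corrected for the sigma^2 kappa / 2 level-set shrinkage of
Gaussian smoothing, and (ii) samples the mean gradient toward that point
at 2 and 4 voxels and extrapolates harmonically (1/m is linear in
distance for 1/r fields, so the extrapolation is exact for the fields
around convex features and reduces to the one-sided difference on flat
ones). All numerical constants were fixed against the analytic
sphere/slab oracles only. Accuracy on voxelized spheres: mean flux
within 4% of (h_s - h_top)/R with ~4% scatter, fitted radius exponent
-1.000; flat slabs are exact. Values within ~2 voxels of the lateral
domain boundary are less reliable (the indicator normal degrades there);
measurement regions keep away from the walls.

**Region statistics.** Tip amplification = max surface |grad h| within
2 mm of the cue's highest surface point(s), divided by the median over
the flat disk 8–15 mm from centre (clipped to the domain). Wall top-edge
statistics are read along the crest line (per-x maximum near the top of
the wall): the t3 number is the max within 1 mm of the two lateral ends,
the t4 number the median over the middle half, and the corner-vs-edge
comparison uses the median corner value over the median mid-edge value
so that like statistics are compared. At 0.15 mm spacing the pillars
scene gives an amplification of ~9.3 (tip max ~0.128 mm^-1 over a flat
reference of ~0.014 mm^-1), the wall scene tip maxima ~0.110 mm^-1, a
top-edge plateau of ~0.073 mm^-1 and corners ~40% above the mid-edge.
The plateau value sits ~25% below the reference simulation's ~0.10; the
idealized rectangular-cross-section wall (vs scanned hand-molded clay,
whose rounded flanks enlarge the crest's solid angle exposure) is the
suspected cause, and the value is grid-converged, so we report it as is
rather than sharpening the geometry to chase the number.

The flux–curvature link is quantified by the Spearman rank correlation
between per-surface-voxel evaporation flux and the local mean curvature
of the smoothed solid indicator (exact-divergence operator): 1 for
pooled spheres by construction, positive on cue scenes, undefined (and
flagged) on a flat slab. The disk-on-dry-plane configuration reproduces
the coffee-ring prediction: edge-ring flux exceeds the disk-centre flux
(threshold 1.5x in the test; measured ~1.8x band mean, ~4x peak).

## Timelapse image pipeline

Input: top-view frames at 20 s cadence plus a tracker-style trajectory
table (frame, id, x, y in pixels). Processing follows the
change-detection recipe: subsample to 80 s (one search–collection–
deposition cycle), convert to greyscale (luminance weights), subtract
the animal-free reference, rolling median over 10 consecutive frames
(trailing, valid mode — moving animals vanish, displaced pellets
persist), then integrate in non-overlapping blocks of 10 (800 s
windows); the number of windows is floor((n - 9)/10). Collections are
dark traces, depositions bright traces (segmented after inversion).
Binarization at k·MAD (k = 3) of the change image unless an explicit
threshold is given; connected components with area in the closed range
[10, 400] px are kept (half the smallest pellet up to a cluster of
resting animals). One extra gate beyond the classic chain: a pixel only
counts if its trace holds at least half the threshold in *every* median
frame of its window ("static gate"). Pellet traces are static once laid
down; residuals of animals that linger long enough to leak through the
rolling median are not, and without the gate they produce a handful of
false bright components on animal-only control sequences. Events that
occur mid-window are simply picked up from the following window onward.

Heatmaps are binned at 0.75 mm (one average pellet) — component areas in
mass mode, one count per centroid in count mode. Because pellets are
almost always displaced only once, traces persist in the change images
and the **last window already contains every past event**: the
cumulative maps P(C), P(D) are the last-window grids (summing windows
would multi-count persistent traces). Occupancy P(O) bins trajectory
points per window on the same grid and *is* summed across windows
(positions are transient); out-of-frame points are dropped and counted.
Maps are normalized by their mean (so P > 1 marks high-frequency cells),
conditionals are cellwise ratios P(D|O) = P(D)/P(O) masked where
occupancy is below a validity threshold, radial densities are
per-unit-area annulus averages normalized to sum 1, and cross-sections
along a cut are max-normalized.

## Synthetic timelapse generator

The generator renders what the pipeline expects to see: a brown clay
disk (greyscale 110) on a darker floor (70), ~340 grey pellets
(contrast +60, diameter 0.75 mm) in the band — the count corresponds to
the 0.12 g of pellets provided in the experiments — and 50 worker + 5
soldier blobs (4 x 1.5 mm ellipses, intensity 200) doing a reflected
random walk (worker step 3 mm per 20 s frame ~ 0.15 mm/s average speed;
soldiers slower). Gaussian pixel noise (sd 2) is added per frame at
0.15 mm/px, matching a pellet area of ~20 px so the [10, 400] px filter
behaves as in the reference pipeline. Collections delete a uniformly
random pellet (building material is picked where it lies); depositions
add a pellet at a site drawn proportionally to stimulus^alpha over the
disk, where the stimulus is either the 2D surface mean curvature of the
scene or the humidity-gradient magnitude sampled at the first air voxel
above the surface. Only the humidity source expresses the evaporation
ring at the disk edge — the generator's encoding of the discriminating
prediction that the rim attracts deposition despite weak curvature.
Planted pellets keep >= 1 mm separation (random sequential adsorption is
feasible at that density), deposition sites keep 2 mm from each other by
default so traces stay resolvable; when many events are aimed at a small
target (e.g. pillar tips) this separation, not the stimulus, can shape
the placement — discrimination analyses use pellet-scale (1 mm)
separation and few events. Everything is driven by one seed;
renders are bitwise reproducible.

What the generator does *not* emulate: perspective and lens distortion,
illumination drift, pellet-size variability, genuinely stationary
animals (a truly motionless bright blob is indistinguishable from a
deposition trace for any background-subtraction scheme; soldiers walk
slowly instead), digging, and any feedback of deposits onto the stimulus
field (single pass). Pipeline tests passing on this data therefore
validate the bookkeeping and the detection logic under the stated noise
model, not performance on real footage.

## Reference problem sizes

The headline computations (also recomputed by `scripts/acceptance.py`)
run at: humidity solves on the 18 mm cube at 0.15 mm spacing (~1.6 M air
voxels, CG converges in seconds–tens of seconds); the growth run on a
20 x 20 x 16 mm pillars box at 0.3 mm spacing integrated to t = 9
(~50 k explicit steps, about a minute compiled); synthetic recovery on
three 800 s windows at 0.15 mm/px. Halving the humidity spacing moves
the tip statistics by a few percent (the values quoted above are the
0.15 mm ones); the growth peak location is stable between 0.35 and
0.25 mm.

## Known limitations

- The growth model is phenomenological: no wall-clock time scale, no
  discrete pellets, no coupling to the humidity field.
- The humidity solver omits convection, temperature coupling and
  in-substrate capillary transport; "wet" is a binary per-voxel label.
- Surface-flux values carry a residual ~4% low bias on strongly curved
  staircase surfaces and are unreliable within ~2 voxels of the lateral
  domain walls.
- The idealized wall/pillar cross-sections are stand-ins for surface
  scans; absolute gradient levels on the cue tops are sensitive to the
  actual molded shapes at the 20–30% level.
- The image pipeline assumes aligned frames and a calibrated pixel
  pitch; registration is out of scope.
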