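"""Ground-truth synthetic timelapse generator.

Renders top-view timelapse sequences of a building arena — brown clay
disk, grey pellets in an annular band, moving elongated termite-shaped
blobs — together with the tracker-style trajectory table and a log of
every planted pellet event, so the full image pipeline can be validated
end to end against known ground truth.

Collections remove a pellet at a uniformly random band location (builders
pick pellets where pellets are); depositions add a pellet at a location
sampled proportionally to a configurable stimulus field raised to a power
``alpha`` — either the surface curvature of the scene or the simulated
humidity-gradient magnitude.  The two stimuli coincide on topographic
cues but only the humidity field expresses the evaporation ring at the
edge of the clay disk, which is the discriminating prediction the
generator lets one probe.

Image convention: row 0 is the top of the frame, x = column, y = row
(y down, as delivered by trackers); arena coordinates are mm, y up,
origin at the centre.  Helpers convert between the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .scene_geometry import SceneSpec, HeightMap, build_height_map, voxelize
from .image_pipeline import TimelapseSequence


@dataclass
class BehaviorParams:
    """Synthetic builder-group behaviour.

    Defaults emulate the reference group size (50 workers, 5 soldiers; the
    soldiers walk more slowly but are not rendered fully inactive) and an
    overall activity of a few hundred pellet events per day, scaled in
    tests by passing explicit rates.  Rates are events per second;
    ``alpha`` is the stimulus exponent for deposition site choice
    (``alpha = 0`` = uniform over the disk); ``event_window`` is the
    fraction of the recording within which events are planted.
    """

    n_workers: int = 50
    n_soldiers: int = 5
    collection_rate: float = 0.006
    deposition_rate: float = 0.006
    alpha: float = 4.0
    noise_sd: float = 2.0
    seed: int = 0
    worker_step_mm: float = 3.0
    soldier_step_mm: float = 2.0
    n_pellets: int = 340
    pellet_contrast: float = 60.0
    termite_intensity: float = 200.0
    disk_intensity: float = 110.0
    floor_intensity: float = 70.0
    min_separation_mm: float = 1.0
    min_event_separation_mm: float = 2.0
    event_window: tuple[float, float] = (0.1, 0.6)

    def __post_init__(self) -> None:
        if self.collection_rate < 0 or self.deposition_rate < 0:
            raise ValueError("event rates must be non-negative")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")


@dataclass
class EventLog:
    """Planted ground-truth events."""

    events: list = field(default_factory=list)  # dict records

    def add(self, kind: str, time_s: float, x_mm: float, y_mm: float,
            pellet_radius_px: float, contrast: float) -> None:
        self.events.append(dict(kind=kind, time_s=time_s, x_mm=x_mm,
                                y_mm=y_mm, pellet_radius_px=pellet_radius_px,
                                contrast=contrast))

    def to_dataframe(self) -> pd.DataFrame:
        cols = ["kind", "time_s", "x_mm", "y_mm", "pellet_radius_px", "contrast"]
        return pd.DataFrame(self.events, columns=cols)

    def of_kind(self, kind: str) -> pd.DataFrame:
        df = self.to_dataframe()
        return df[df["kind"] == kind].reset_index(drop=True)


@dataclass
class StimulusField:
    """2D stimulus map over the arena (mm grid, node-registered)."""

    values: np.ndarray
    spacing: float
    origin: tuple[float, float] = (0.0, 0.0)

    def sample(self, x_mm: np.ndarray, y_mm: np.ndarray) -> np.ndarray:
        """Nearest-node lookup at arbitrary arena coordinates."""
        i = np.clip(np.round((np.asarray(x_mm) - self.origin[0]) / self.spacing)
                    .astype(int), 0, self.values.shape[0] - 1)
        j = np.clip(np.round((np.asarray(y_mm) - self.origin[1]) / self.spacing)
                    .astype(int), 0, self.values.shape[1] - 1)
        return self.values[i, j]


def surface_curvature_2d(hm: HeightMap) -> np.ndarray:
    """Mean curvature of the graph z = eta(x, y), positive where the
    surface is convex (bumps, tips, ridges)."""
    gx, gy = np.gradient(hm.elevation, hm.spacing)
    norm = np.sqrt(1.0 + gx ** 2 + gy ** 2)
    div_x = np.gradient(gx / norm, hm.spacing)[0]
    div_y = np.gradient(gy / norm, hm.spacing)[1]
    return -(div_x + div_y)


def stimulus_field(scene: SceneSpec, source: str, spacing: float = 0.5,
                   domain_height: float = 18.0, hm: HeightMap | None = None,
                   humidity=None) -> StimulusField:
    """Surface-projected deposition stimulus over the arena.

    ``source="curvature"``: positive part of the surface mean curvature —
    near zero on the flat disk (only weakly expressing its smoothed edge),
    maximal on cue tips.  ``source="humidity_gradient"``: |grad h| of the
    steady diffusive humidity field sampled at the first air voxel above
    the surface — this one additionally expresses the evaporation ring at
    the disk edge (the dry Petri floor does not evaporate).

    Precomputed inputs can be passed (``hm``, or a solved
    ``HumidityField`` as ``humidity``) to skip recomputation.
    """
    if hm is None:
        hm = build_height_map(scene, spacing)
    if source == "curvature":
        vals = np.clip(surface_curvature_2d(hm), 0.0, None)
        return StimulusField(vals, hm.spacing, hm.origin)
    if source == "humidity_gradient":
        from . import humidity_solver as hs

        if humidity is None:
            mask = voxelize(hm, hm.spacing)
            humidity = hs.solve_laplace(mask, domain_height=domain_height)
        gm = hs.gradient_map(humidity)
        ksurf = np.clip(humidity.solid.sum(axis=2), 0, gm.mag.shape[2] - 1)
        vals = np.take_along_axis(gm.mag, ksurf[:, :, None], axis=2)[:, :, 0]
        return StimulusField(np.nan_to_num(vals), humidity.spacing, humidity.origin)
    raise ValueError("source must be 'curvature' or 'humidity_gradient'")


# ---------------------------------------------------------------------------
# Coordinate transforms
# ---------------------------------------------------------------------------

def mm_to_px(x_mm, y_mm, half_extent: float, pitch: float):
    """Arena mm (y up, centred) -> image px (col, row; y down)."""
    col = (np.asarray(x_mm) + half_extent) / pitch - 0.5
    row = (half_extent - np.asarray(y_mm)) / pitch - 0.5
    return col, row


def px_to_mm(col, row, half_extent: float, pitch: float):
    x = (np.asarray(col) + 0.5) * pitch - half_extent
    y = half_extent - (np.asarray(row) + 0.5) * pitch
    return x, y


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _disc_offsets(radius_px: float) -> tuple[np.ndarray, np.ndarray]:
    r = int(np.ceil(radius_px))
    di, dj = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1), indexing="ij")
    m = di ** 2 + dj ** 2 <= radius_px ** 2
    return di[m], dj[m]


def _paint_disc(img: np.ndarray, row: float, col: float,
                offsets, value: float) -> None:
    di, dj = offsets
    ii = np.round(row).astype(int) + di
    jj = np.round(col).astype(int) + dj
    ok = (ii >= 0) & (ii < img.shape[0]) & (jj >= 0) & (jj < img.shape[1])
    img[ii[ok], jj[ok]] = value


def _paint_ellipse(img: np.ndarray, row: float, col: float, theta: float,
                   a_px: float, b_px: float, value: float) -> None:
    r = int(np.ceil(a_px)) + 1
    i0 = int(np.round(row))
    j0 = int(np.round(col))
    ii = np.arange(max(i0 - r, 0), min(i0 + r + 1, img.shape[0]))
    jj = np.arange(max(j0 - r, 0), min(j0 + r + 1, img.shape[1]))
    if ii.size == 0 or jj.size == 0:
        return
    di = ii[:, None] - row
    dj = jj[None, :] - col
    c, s = np.cos(theta), np.sin(theta)
    u = c * dj + s * di
    v = -s * dj + c * di
    m = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
    sub = img[ii[0]:ii[-1] + 1, jj[0]:jj[-1] + 1]
    sub[m] = value


def _sample_separated(rng, propose, n: int, min_sep: float,
                      existing: np.ndarray | None = None,
                      existing_sep: float | None = None,
                      max_tries: int = 500) -> np.ndarray:
    """Draw n points from ``propose(rng)``, pairwise at least ``min_sep``
    apart and at least ``existing_sep`` from the ``existing`` points."""
    if existing_sep is None:
        existing_sep = min_sep
    pts: list[np.ndarray] = []
    anchor = np.asarray(existing) if existing is not None and len(existing) else None
    for _ in range(n):
        for _try in range(max_tries):
            p = propose(rng)
            if anchor is not None and \
                    np.min(np.hypot(*(anchor - p).T)) < existing_sep:
                continue
            if pts and np.min(np.hypot(*(np.array(pts) - p).T)) < min_sep:
                continue
            pts.append(p)
            break
        else:
            raise RuntimeError(
                "could not place points with the requested separation; "
                "lower the density or the separation")
    return np.array(pts) if pts else np.empty((0, 2))


def _stimulus_sampler(stim: StimulusField | None, alpha: float,
                      scene: SceneSpec):
    """Return propose(rng) drawing deposition sites ~ stimulus^alpha on
    the disk (uniform when stim is None or alpha == 0)."""
    if stim is None or alpha == 0:
        def propose(rng):
            while True:
                p = rng.uniform(-scene.disk_radius, scene.disk_radius, 2)
                if np.hypot(*p) <= scene.disk_radius - 1.0:
                    return p
        return propose
    nx, ny = stim.values.shape
    x = stim.origin[0] + stim.spacing * np.arange(nx)
    y = stim.origin[1] + stim.spacing * np.arange(ny)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    on_disk = np.hypot(xx, yy) <= scene.disk_radius - 1.0
    w = np.where(on_disk, np.clip(stim.values, 0.0, None) ** alpha, 0.0).ravel()
    if w.sum() <= 0:
        raise ValueError("stimulus field is zero over the disk")
    w = w / w.sum()
    flat_x, flat_y = xx.ravel(), yy.ravel()

    def propose(rng):
        k = rng.choice(w.size, p=w)
        jitter = rng.uniform(-stim.spacing / 2, stim.spacing / 2, 2)
        return np.array([flat_x[k] + jitter[0], flat_y[k] + jitter[1]])
    return propose


def render_sequence(scene: SceneSpec, params: BehaviorParams,
                    duration: float, cadence: float = 20.0,
                    pixel_pitch: float = 0.15,
                    stimulus: StimulusField | None = None,
                    half_extent: float | None = None
                    ) -> tuple[TimelapseSequence, pd.DataFrame, EventLog]:
    """Render a synthetic building timelapse.

    Returns the frame sequence (uint8 greyscale, one frame per
    ``cadence`` seconds plus the animal-free reference), the trajectory
    table (columns frame, id, x, y in px, tracker convention) and the
    ground-truth :class:`EventLog` (positions in arena mm).
    Deterministic for a fixed ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    if half_extent is None:
        half_extent = scene.arena_radius
    npx = int(round(2 * half_extent / pixel_pitch))
    n_frames = int(np.floor(duration / cadence)) + 1
    times = cadence * np.arange(n_frames)

    # --- static background -------------------------------------------------
    cols, rows = np.meshgrid(np.arange(npx), np.arange(npx), indexing="xy")
    xg, yg = px_to_mm(cols, rows, half_extent, pixel_pitch)
    rr = np.hypot(xg, yg)
    background = np.where(rr <= scene.disk_radius,
                          params.disk_intensity, params.floor_intensity)

    # --- initial pellets in the band ---------------------------------------
    inner, outer = scene.pellet_band

    def propose_band(r):
        while True:
            p = r.uniform(-outer, outer, 2)
            if inner <= np.hypot(*p) <= outer:
                return p
    pellets = _sample_separated(rng, propose_band, params.n_pellets,
                                params.min_separation_mm)
    pellet_alive = np.ones(len(pellets), dtype=bool)
    pellet_radius_px = (scene.pellet_diameter / 2) / pixel_pitch
    disc = _disc_offsets(pellet_radius_px)
    pellet_value = params.disk_intensity + params.pellet_contrast

    # --- planted events -----------------------------------------------------
    log = EventLog()
    w0, w1 = params.event_window
    t0, t1 = w0 * duration, w1 * duration
    n_coll = int(round(params.collection_rate * duration))
    n_dep = int(round(params.deposition_rate * duration))

    coll_times = np.sort(rng.uniform(t0, t1, n_coll))
    # greedily choose pellets to collect, pairwise well separated
    coll_idx: list[int] = []
    order = rng.permutation(len(pellets))
    for idx in order:
        if len(coll_idx) == n_coll:
            break
        if all(np.hypot(*(pellets[idx] - pellets[k])) >=
               params.min_event_separation_mm for k in coll_idx):
            coll_idx.append(idx)
    if len(coll_idx) < n_coll:
        raise RuntimeError("not enough separable pellets for the requested "
                           "collection events")
    dep_times = np.sort(rng.uniform(t0, t1, n_dep))
    propose_dep = _stimulus_sampler(stimulus, params.alpha, scene)
    dep_sites = _sample_separated(rng, propose_dep, n_dep,
                                  params.min_event_separation_mm,
                                  existing=pellets,
                                  existing_sep=params.min_separation_mm)

    for t, idx in zip(coll_times, coll_idx):
        log.add("collection", float(t), float(pellets[idx][0]),
                float(pellets[idx][1]), pellet_radius_px, params.pellet_contrast)
    for t, p in zip(dep_times, dep_sites):
        log.add("deposition", float(t), float(p[0]), float(p[1]),
                pellet_radius_px, params.pellet_contrast)

    # --- termite walkers ----------------------------------------------------
    n_t = params.n_workers + params.n_soldiers
    steps = np.full(n_t, params.worker_step_mm)
    steps[params.n_workers:] = params.soldier_step_mm
    body_a = 2.0 / pixel_pitch   # semi-major (4 mm long body)
    body_b = 0.75 / pixel_pitch  # semi-minor (1.5 mm wide)
    rmax = scene.arena_radius - 2.0
    pos = np.empty((n_t, 2))
    for i in range(n_t):
        while True:
            p = rng.uniform(-rmax, rmax, 2)
            if np.hypot(*p) <= rmax:
                pos[i] = p
                break
    headings = rng.uniform(0, 2 * np.pi, n_t)

    # --- render -------------------------------------------------------------
    def paint_pellets(img, alive, deposits):
        for k in np.flatnonzero(alive):
            c, r = mm_to_px(pellets[k, 0], pellets[k, 1], half_extent, pixel_pitch)
            _paint_disc(img, r, c, disc, pellet_value)
        for p in deposits:
            c, r = mm_to_px(p[0], p[1], half_extent, pixel_pitch)
            _paint_disc(img, r, c, disc, pellet_value)

    ref = background.copy()
    paint_pellets(ref, pellet_alive, [])
    ref_img = np.clip(ref + rng.normal(0, params.noise_sd, ref.shape),
                      0, 255).astype(np.uint8)

    frames = np.empty((n_frames, npx, npx), dtype=np.uint8)
    traj_rows = []
    ci = 0
    di = 0
    deposits_done: list[np.ndarray] = []
    for fi, t in enumerate(times):
        while ci < n_coll and coll_times[ci] <= t:
            pellet_alive[coll_idx[ci]] = False
            ci += 1
        while di < n_dep and dep_times[di] <= t:
            deposits_done.append(dep_sites[di])
            di += 1
        img = background.copy()
        paint_pellets(img, pellet_alive, deposits_done)
        # advance and draw termites
        if fi > 0:
            delta = rng.normal(0, 1, (n_t, 2)) * steps[:, None]
            newpos = pos + delta
            radii = np.hypot(newpos[:, 0], newpos[:, 1])
            out = radii > rmax
            newpos[out] *= ((2 * rmax - radii[out]) / radii[out])[:, None]
            headings = np.arctan2(newpos[:, 1] - pos[:, 1],
                                  newpos[:, 0] - pos[:, 0])
            pos = newpos
        for i in range(n_t):
            c, r = mm_to_px(pos[i, 0], pos[i, 1], half_extent, pixel_pitch)
            _paint_ellipse(img, r, c, -headings[i], body_a, body_b,
                           params.termite_intensity)
            traj_rows.append((fi, i, float(c), float(r)))
        img = img + rng.normal(0, params.noise_sd, img.shape)
        frames[fi] = np.clip(img, 0, 255).astype(np.uint8)

    seq = TimelapseSequence(frames, times, pixel_pitch, ref_img)
    traj = pd.DataFrame(traj_rows, columns=["frame", "id", "x", "y"])
    return seq, traj, log


def save_outputs(seq: TimelapseSequence, traj: pd.DataFrame, log: EventLog,
                 outdir) -> None:
    """Write frames (PNG), trajectories and event log (CSV) to a directory."""
    from pathlib import Path
    import imageio.v3 as iio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out / "reference.png", seq.reference)
    for i, frame in enumerate(seq.frames):
        iio.imwrite(out / f"frame_{i:05d}.png", frame)
    traj.to_csv(out / "trajectories.csv", index=False)
    log.to_dataframe().to_csv(out / "events.csv", index=False)
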