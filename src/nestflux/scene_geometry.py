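"""Parametric arena geometry and voxelization.

Experimental arenas are a thin disk of humid clay centred in a Petri dish,
optionally decorated with topographic cues (two pillars or a short wall)
and sprinkled with loose clay pellets in an annular band.  This module
builds height-map descriptions of such scenes, voxelizes them into 3D
occupancy masks for the growth and humidity solvers, and imports surface
scans (meshes) through the same height-map representation.

Coordinate convention: origin at the arena centre, x-y in the Petri plane,
z up, all lengths in millimetres.  Grid indices map to cell centres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage


_CUE_TYPES = ("pillars", "wall", "none")


@dataclass(frozen=True)
class SceneSpec:
    """Parametric description of an experimental arena.

    Defaults follow the reference setup: a 50 mm clay disk in an
    85 mm Petri dish, pillar cues 6 mm high and 8 mm apart, wall cues
    6 mm high and 12 mm long, both 3 mm thick, and a 10 mm-wide pellet
    band halfway between the disk centre and its edge.
    """

    arena_radius: float = 42.5
    disk_radius: float = 25.0
    disk_thickness: float = 1.5
    cue_type: str = "pillars"
    pillar_height: float = 6.0
    pillar_spacing: float = 8.0
    pillar_diameter: float = 3.0
    wall_height: float = 6.0
    wall_length: float = 12.0
    wall_thickness: float = 3.0
    pellet_band: tuple[float, float] = (7.5, 17.5)
    pellet_diameter: float = 0.75
    edge_smoothing: float = 1.0
    cue_edge_smoothing: float = 0.5

    def __post_init__(self) -> None:
        lengths = (
            self.arena_radius, self.disk_radius, self.disk_thickness,
            self.pillar_height, self.pillar_spacing, self.pillar_diameter,
            self.wall_height, self.wall_length, self.wall_thickness,
            self.pellet_diameter,
        )
        if any(v <= 0 for v in lengths):
            raise ValueError("all scene lengths must be positive")
        if self.edge_smoothing < 0 or self.cue_edge_smoothing < 0:
            raise ValueError("smoothing widths must be non-negative")
        if self.cue_type not in _CUE_TYPES:
            raise ValueError(f"cue_type must be one of {_CUE_TYPES}")
        if self.disk_radius >= self.arena_radius:
            raise ValueError("disk must fit inside the arena")
        inner, outer = self.pellet_band
        if not (0 <= inner < outer <= self.disk_radius):
            raise ValueError("pellet band must lie inside the disk")
        # cue footprint containment
        if self.cue_type == "pillars":
            extent = self.pillar_spacing / 2 + self.pillar_diameter / 2
        elif self.cue_type == "wall":
            extent = float(np.hypot(self.wall_length / 2, self.wall_thickness / 2))
        else:
            extent = 0.0
        if extent > self.disk_radius:
            raise ValueError("cue footprint extends outside the clay disk")

    @property
    def cue_height(self) -> float:
        if self.cue_type == "pillars":
            return self.pillar_height
        if self.cue_type == "wall":
            return self.wall_height
        return 0.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        d = dict(d)
        if "pellet_band" in d:
            d["pellet_band"] = tuple(d["pellet_band"])
        return cls(**d)


@dataclass
class HeightMap:
    """Single-valued elevation field z = eta(x, y) on a regular grid.

    ``elevation[i, j]`` is the surface height (mm) at
    ``x = x0 + i * spacing``, ``y = y0 + j * spacing`` with the physical
    origin at the arena centre.
    """

    elevation: np.ndarray
    spacing: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.elevation = np.asarray(self.elevation, dtype=float)
        if self.elevation.ndim != 2:
            raise ValueError("elevation must be 2D")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevation.shape

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical x and y coordinates of grid nodes (1D arrays)."""
        nx, ny = self.elevation.shape
        x = self.origin[0] + self.spacing * np.arange(nx)
        y = self.origin[1] + self.spacing * np.arange(ny)
        return x, y

    def crop(self, half_extent: float, center: tuple[float, float] = (0.0, 0.0)) -> "HeightMap":
        """Extract the square window |x-cx|, |y-cy| <= half_extent."""
        x, y = self.coords()
        ix = np.flatnonzero(np.abs(x - center[0]) <= half_extent + 1e-9)
        iy = np.flatnonzero(np.abs(y - center[1]) <= half_extent + 1e-9)
        if ix.size == 0 or iy.size == 0:
            raise ValueError("crop window does not intersect the grid")
        sub = self.elevation[ix[0]:ix[-1] + 1, iy[0]:iy[-1] + 1]
        return HeightMap(sub.copy(), self.spacing, (float(x[ix[0]]), float(y[iy[0]])))


@dataclass
class SolidMask:
    """3D boolean occupancy of clay on a regular grid.

    ``solid[i, j, k]`` is True when the voxel centred at
    ``origin + spacing * (i, j, k + 0.5)`` lies inside the material.
    The horizontal origin is at node positions (consistent with
    :class:`HeightMap`); the vertical origin is the arena floor z = 0,
    with voxel centres at ``(k + 0.5) * dz``.
    """

    solid: np.ndarray
    spacing: float
    dz: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.solid = np.asarray(self.solid, dtype=bool)
        if self.solid.ndim != 3:
            raise ValueError("solid mask must be 3D")
        if self.spacing <= 0 or self.dz <= 0:
            raise ValueError("grid spacings must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.solid.shape

    @property
    def isotropic(self) -> bool:
        return abs(self.spacing - self.dz) < 1e-12

    def coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        nx, ny, nz = self.solid.shape
        x = self.origin[0] + self.spacing * np.arange(nx)
        y = self.origin[1] + self.spacing * np.arange(ny)
        z = self.dz * (np.arange(nz) + 0.5)
        return x, y, z

    def volume(self) -> float:
        """Total solid volume in mm^3."""
        return float(self.solid.sum()) * self.spacing ** 2 * self.dz

    def column_heights(self) -> np.ndarray:
        """Height (mm) of the top of the solid column at each (x, y)."""
        return self.solid.sum(axis=2) * self.dz


def build_height_map(spec: SceneSpec, spacing: float,
                     half_extent: float | None = None) -> HeightMap:
    """Render a scene description into an elevation grid.

    The elevation is ``disk_thickness`` over the clay disk, raised by the
    cue height over the cue footprint and zero outside the disk (the bare
    Petri floor is the datum).  Transitions are softened with Gaussian
    kernels of sigma = width / 2, so a transition is spread over roughly
    the stated width: ``edge_smoothing`` for the disk rim (hand-smoothed
    to meet the Petri floor) and the smaller ``cue_edge_smoothing`` for
    the molded pillar and wall edges, which are crisper than the rim.

    Parameters
    ----------
    spec : scene description.
    spacing : grid step in mm; must resolve a pellet (<= pellet_diameter).
    half_extent : half-width of the (square) rendered window, default the
        arena radius.
    """
    if spacing > spec.pellet_diameter:
        raise ValueError(
            f"spacing {spacing} mm too coarse: must be <= pellet diameter "
            f"({spec.pellet_diameter} mm)")
    if half_extent is None:
        half_extent = spec.arena_radius
    n = int(np.floor(2 * half_extent / spacing)) + 1
    x = -half_extent + spacing * np.arange(n)
    xx, yy = np.meshgrid(x, x, indexing="ij")
    rr = np.hypot(xx, yy)

    disk = np.where(rr <= spec.disk_radius, spec.disk_thickness, 0.0)
    if spec.edge_smoothing > 0:
        disk = ndimage.gaussian_filter(
            disk, spec.edge_smoothing / 2.0 / spacing, mode="nearest")

    cue = np.zeros_like(disk)
    if spec.cue_type == "pillars":
        half = spec.pillar_spacing / 2
        for cx in (-half, half):
            footprint = np.hypot(xx - cx, yy) <= spec.pillar_diameter / 2
            cue = np.where(footprint, spec.pillar_height, cue)
    elif spec.cue_type == "wall":
        footprint = (np.abs(xx) <= spec.wall_length / 2) & \
                    (np.abs(yy) <= spec.wall_thickness / 2)
        cue = np.where(footprint, spec.wall_height, cue)
    if spec.cue_edge_smoothing > 0 and spec.cue_type != "none":
        cue = ndimage.gaussian_filter(
            cue, spec.cue_edge_smoothing / 2.0 / spacing, mode="nearest")
    return HeightMap(disk + cue, spacing, (float(x[0]), float(x[0])))


def voxelize(hm: HeightMap, dz: float) -> SolidMask:
    """Sample a height map onto a 3D occupancy grid.

    A voxel is solid iff its centre lies below the surface:
    ``(k + 0.5) * dz < elevation``.
    """
    if dz <= 0:
        raise ValueError("dz must be positive")
    top = float(hm.elevation.max())
    nz = max(int(np.ceil(top / dz)), 1)
    zc = dz * (np.arange(nz) + 0.5)
    solid = hm.elevation[:, :, None] > zc[None, None, :]
    return SolidMask(solid, hm.spacing, dz, hm.origin)


def with_headroom(mask: SolidMask, total_height: float) -> SolidMask:
    """Pad a mask with air above so the domain reaches ``total_height`` mm."""
    nz_target = int(np.ceil(total_height / mask.dz))
    nx, ny, nz = mask.shape
    if nz_target <= nz:
        return mask
    solid = np.zeros((nx, ny, nz_target), dtype=bool)
    solid[:, :, :nz] = mask.solid
    return SolidMask(solid, mask.spacing, mask.dz, mask.origin)


# ---------------------------------------------------------------------------
# Mesh import / export ("3D scan" stand-in)
# ---------------------------------------------------------------------------

def height_map_to_mesh(hm: HeightMap):
    """Triangulate a height map into a trimesh surface (for export)."""
    import trimesh

    nx, ny = hm.shape
    x, y = hm.coords()
    xx, yy = np.meshgrid(x, y, indexing="ij")
    verts = np.column_stack([xx.ravel(), yy.ravel(), hm.elevation.ravel()])
    idx = np.arange(nx * ny).reshape(nx, ny)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[1:, 1:].ravel()
    d = idx[:-1, 1:].ravel()
    faces = np.concatenate([np.column_stack([a, b, c]),
                            np.column_stack([a, c, d])])
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


def _rasterize_max_z(vertices: np.ndarray, faces: np.ndarray,
                     x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Upper envelope of a triangle soup sampled at grid nodes.

    For each grid node the maximum z over all triangles whose horizontal
    projection covers it; -inf where no triangle covers the node.  Works
    for open, non-oriented and non-watertight meshes because only vertex
    positions are used (containment is a 2D point-in-triangle test).
    """
    nx, ny = x.size, y.size
    zmax = np.full((nx, ny), -np.inf)
    dx = x[1] - x[0] if nx > 1 else 1.0
    dy = y[1] - y[0] if ny > 1 else 1.0
    tri = vertices[faces]  # (m, 3, 3)
    for p0, p1, p2 in tri:
        i0 = max(int(np.ceil((min(p0[0], p1[0], p2[0]) - x[0]) / dx)), 0)
        i1 = min(int(np.floor((max(p0[0], p1[0], p2[0]) - x[0]) / dx)), nx - 1)
        j0 = max(int(np.ceil((min(p0[1], p1[1], p2[1]) - y[0]) / dy)), 0)
        j1 = min(int(np.floor((max(p0[1], p1[1], p2[1]) - y[0]) / dy)), ny - 1)
        if i1 < i0 or j1 < j0:
            continue
        gx, gy = np.meshgrid(x[i0:i1 + 1], y[j0:j1 + 1], indexing="ij")
        v0 = p1[:2] - p0[:2]
        v1 = p2[:2] - p0[:2]
        det = v0[0] * v1[1] - v0[1] * v1[0]
        if abs(det) < 1e-14:
            continue  # degenerate (vertical or zero-area) triangle
        px = gx - p0[0]
        py = gy - p0[1]
        u = (px * v1[1] - py * v1[0]) / det
        v = (py * v0[0] - px * v0[1]) / det
        inside = (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9)
        if not inside.any():
            continue
        z = p0[2] + u * (p1[2] - p0[2]) + v * (p2[2] - p0[2])
        block = zmax[i0:i1 + 1, j0:j1 + 1]
        np.maximum(block, np.where(inside, z, -np.inf), out=block)
    return zmax


def load_scan_mesh(path, spacing: float = 0.15, dz: float | None = None,
                   half_extent: float | None = None) -> SolidMask:
    """Voxelize a surface-scan mesh (STL/PLY/OBJ) into a solid mask.

    The mesh is interpreted as a scan of an upward-facing surface: it is
    closed against the floor plane z = 0 by taking, per grid column, the
    highest mesh intersection, which makes the result independent of face
    orientation (flipped normals give the same mask).

    Raises ``ValueError`` for unreadable, empty, degenerate or
    non-manifold meshes.
    """
    import trimesh

    try:
        mesh = trimesh.load(str(path), force="mesh")
    except Exception as exc:  # unreadable file
        raise ValueError(f"cannot read mesh {path!r}: {exc}") from exc
    if mesh is None or not hasattr(mesh, "faces") or len(mesh.faces) == 0:
        raise ValueError(f"mesh {path!r} is empty or degenerate")
    verts = np.asarray(mesh.vertices, float)
    faces = np.asarray(mesh.faces, int)
    if not np.isfinite(verts).all():
        raise ValueError(f"mesh {path!r} has non-finite vertices")
    # an edge shared by more than two faces means the closed-against-floor
    # surface cannot be watertight
    edges = np.sort(faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    if (counts > 2).any():
        raise ValueError(f"mesh {path!r} is non-manifold (edge shared by >2 faces)")

    if dz is None:
        dz = spacing
    if half_extent is None:
        half_extent = float(np.abs(verts[:, :2]).max())
    n = int(np.floor(2 * half_extent / spacing)) + 1
    x = -half_extent + spacing * np.arange(n)
    zmax = _rasterize_max_z(verts, faces, x, x)
    if not np.isfinite(zmax).any():
        raise ValueError(f"mesh {path!r} does not cover the sampling grid")
    elev = np.where(np.isfinite(zmax), np.maximum(zmax, 0.0), 0.0)
    hm = HeightMap(elev, spacing, (float(x[0]), float(x[0])))
    return voxelize(hm, dz)


# ---------------------------------------------------------------------------
# HDF5 persistence
# ---------------------------------------------------------------------------

def save_mask(mask: SolidMask, path, spec: SceneSpec | None = None) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("solid", data=mask.solid, compression="gzip")
        meta = {"spacing": mask.spacing, "dz": mask.dz, "origin": list(mask.origin)}
        if spec is not None:
            meta["scene_spec"] = spec.to_dict()
        d.attrs["meta"] = json.dumps(meta)


def load_mask(path) -> SolidMask:
    import h5py

    with h5py.File(path, "r") as f:
        d = f["solid"]
        meta = json.loads(d.attrs["meta"])
        return SolidMask(d[...], meta["spacing"], meta["dz"],
                         tuple(meta["origin"]))


def save_height_map(hm: HeightMap, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("elevation", data=hm.elevation, compression="gzip")
        d.attrs["meta"] = json.dumps({"spacing": hm.spacing, "origin": list(hm.origin)})


def load_height_map(path) -> HeightMap:
    import h5py

    with h5py.File(path, "r") as f:
        d = f["elevation"]
        meta = json.loads(d.attrs["meta"])
        return HeightMap(d[...], meta["spacing"], tuple(meta["origin"]))
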