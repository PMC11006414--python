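"""Steady-state diffusive humidity field over a scene.

Close to an evaporating substrate, water-vapour transport is purely
diffusive, so the stationary relative-humidity field h obeys the Laplace
equation ``lap(h) = 0``.  This module solves that boundary-value problem
on the voxel grid of a scene: Dirichlet ``h = h_surface`` (100%) on the
wet clay surface, Dirichlet ``h = h_top`` (70%, the ambient value) at the
top of the domain, and zero-flux lateral walls.  From the solution it
derives the humidity-gradient magnitude ``|grad h|`` (in mm^-1 on the
relative-humidity-fraction scale: 0.1 mm^-1 means 10% variation over
1 mm), the evaporation flux off the surface (the outward normal
derivative, up to the constant vapour diffusivity), tip-amplification
ratios and the flux-curvature rank correlation.

Relative humidity is proportional to absolute humidity at constant
temperature, so gradients of either are interchangeable up to a constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import cg

from .scene_geometry import SolidMask

_FACES = ("x-", "x+", "y-", "y+", "z-", "z+")


@dataclass
class BoundaryLayerParams:
    """Diffusive boundary layer over the clay disk.

    ``delta`` is the boundary-layer thickness in mm; ``delta_h`` the
    humidity drop across it in % (surface to room).
    """

    delta: float = 2.0
    delta_h: float = 30.0

    def __post_init__(self) -> None:
        if self.delta <= 0 or self.delta_h < 0:
            raise ValueError("delta must be > 0 and delta_h >= 0")


def boundary_layer_gradient(p: BoundaryLayerParams) -> float:
    """Flat-region humidity gradient estimate delta_h / delta, in mm^-1
    on the fraction scale (30% over 2 mm -> 0.15 mm^-1)."""
    return (p.delta_h / 100.0) / p.delta


@dataclass
class HumidityField:
    """Solved relative-humidity field (%, NaN inside solid)."""

    h: np.ndarray
    solid: np.ndarray
    spacing: float
    h_surface: float
    h_top: float
    wet: np.ndarray
    face_bc: dict
    residual: float
    origin: tuple[float, float] = (0.0, 0.0)

    @property
    def air(self) -> np.ndarray:
        return ~self.solid


@dataclass
class GradientMap:
    """|grad h| per air voxel (mm^-1, fraction scale; NaN inside solid)."""

    mag: np.ndarray
    components: tuple[np.ndarray, np.ndarray, np.ndarray]
    spacing: float
    surface_adjacent: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)


@dataclass
class SurfaceFlux:
    """Evaporation flux per wet surface voxel (mm^-1 scale, NaN elsewhere)."""

    values: np.ndarray
    mask: np.ndarray
    spacing: float


def _face_bc_value(face_bc: dict, face: str, coords=None):
    """Resolve a face boundary condition to ('neumann',) / ('dirichlet', arr)."""
    bc = face_bc.get(face, ("neumann",))
    if bc[0] == "neumann":
        return None
    if bc[0] == "dirichlet":
        return bc[1]
    if bc[0] == "dirichlet_fn":
        return bc[1](*coords)
    raise ValueError(f"unknown boundary condition {bc!r} on face {face}")


def _check_connectivity(air: np.ndarray) -> None:
    lbl, n = ndimage.label(air, structure=ndimage.generate_binary_structure(3, 1))
    top_labels = set(np.unique(lbl[:, :, -1])) - {0}
    all_labels = set(range(1, n + 1))
    if not top_labels:
        raise ValueError("no air voxels reach the top of the domain")
    orphan = all_labels - top_labels
    if orphan:
        raise ValueError(
            f"{len(orphan)} air region(s) are sealed off from the top boundary; "
            "the humidity problem is disconnected")


def solve_laplace(mask: SolidMask, domain_height: float = 18.0,
                  h_surface: float = 100.0, h_top: float = 70.0,
                  wet: np.ndarray | None = None,
                  face_bc: dict | None = None,
                  tol: float = 1e-8, maxiter: int = 20000) -> HumidityField:
    """Solve ``lap(h) = 0`` on the air voxels above a solid scene.

    The domain is the mask's horizontal footprint extruded to
    ``domain_height`` mm; air above the mask's top layer is added as
    needed.  Default boundary conditions follow the reference simulation:
    Dirichlet ``h_surface`` on every air-voxel face adjacent to wet solid
    (the whole scanned surface, not only z=0), Dirichlet ``h_top`` on the
    top plate, zero-flux on the lateral walls and on dry floor.

    ``wet`` marks which solid voxels evaporate (default: all).
    ``face_bc`` overrides the domain-face conditions; each face in
    {"x-","x+","y-","y+","z-","z+"} maps to ``("neumann",)``,
    ``("dirichlet", value)`` or ``("dirichlet_fn", fn(x, y, z))`` with the
    ghost-cell coordinates in mm (used e.g. to impose an analytic
    far-field on a sphere problem).

    Dirichlet values are imposed on the bounding faces themselves (half a
    grid step from the adjacent voxel centres), which keeps the system
    symmetric positive definite and puts the numerical surface at the
    staircase geometry; it is solved by conjugate gradients to relative
    residual ``tol``.
    """
    if not mask.isotropic:
        raise ValueError("humidity solver requires isotropic voxels")
    h = mask.spacing
    nz_dom = int(round(domain_height / h))
    nx, ny, nz0 = mask.shape
    if nz_dom < nz0:
        raise ValueError("domain_height lower than the scene itself")
    solid = np.zeros((nx, ny, nz_dom), dtype=bool)
    solid[:, :, :nz0] = mask.solid
    if wet is None:
        wet = solid.copy()
    else:
        w = np.zeros_like(solid)
        w[:, :, :nz0] = wet
        wet = w & solid
    if face_bc is None:
        face_bc = {"z+": ("dirichlet", h_top)}
    air = ~solid
    _check_connectivity(air)

    n_air = int(air.sum())
    index = -np.ones(solid.shape, dtype=np.int64)
    index[air] = np.arange(n_air)
    diag = np.zeros(n_air)
    rhs = np.zeros(n_air)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []

    x0 = mask.origin[0] + h * np.arange(nx)
    y0 = mask.origin[1] + h * np.arange(ny)
    z0 = h * (np.arange(nz_dom) + 0.5)
    shape = solid.shape

    def interior(axis: int, sign: int):
        """Couple air voxels to their in-domain neighbours along one direction."""
        cur = [slice(None)] * 3
        nb = [slice(None)] * 3
        if sign > 0:
            cur[axis] = slice(0, shape[axis] - 1)
            nb[axis] = slice(1, shape[axis])
        else:
            cur[axis] = slice(1, shape[axis])
            nb[axis] = slice(0, shape[axis] - 1)
        cur, nb = tuple(cur), tuple(nb)
        ic = index[cur]
        a_cur = air[cur]
        a_nb = air[nb]
        m_air = a_cur & a_nb
        rows.append(ic[m_air])
        cols.append(index[nb][m_air])
        np.add.at(diag, ic[m_air], 1.0)
        # wet solid neighbour: Dirichlet imposed at the shared face
        # (half a grid step away), hence the factor 2
        m_wet = a_cur & ~a_nb & wet[nb]
        np.add.at(diag, ic[m_wet], 2.0)
        np.add.at(rhs, ic[m_wet], 2.0 * h_surface)
        # dry solid neighbour: reflecting, no contribution

    def face(axis: int, sign: int, name: str):
        sl = [slice(None)] * 3
        sl[axis] = -1 if sign > 0 else 0
        sl = tuple(sl)
        ids = index[sl]
        m = air[sl]
        if not m.any():
            return
        # Dirichlet values are imposed on the domain face itself, half a
        # grid step from the boundary voxel centres
        grids = np.meshgrid(x0, y0, z0, indexing="ij")
        gx, gy, gz = (g[sl] for g in grids)
        offset = h * sign / 2.0
        if axis == 0:
            gx = gx + offset
        elif axis == 1:
            gy = gy + offset
        else:
            gz = gz + offset
        val = _face_bc_value(face_bc, name, coords=(gx, gy, gz))
        if val is None:
            return
        val = np.broadcast_to(np.asarray(val, float), ids.shape)
        np.add.at(diag, ids[m], 2.0)
        np.add.at(rhs, ids[m], 2.0 * val[m])

    for axis, sign, name in ((0, -1, "x-"), (0, 1, "x+"), (1, -1, "y-"),
                             (1, 1, "y+"), (2, -1, "z-"), (2, 1, "z+")):
        interior(axis, sign)
        face(axis, sign, name)

    r = np.concatenate(rows)
    c = np.concatenate(cols)
    A = sparse.coo_matrix(
        (np.concatenate([diag, -np.ones(r.size)]),
         (np.concatenate([np.arange(n_air), r]),
          np.concatenate([np.arange(n_air), c]))),
        shape=(n_air, n_air)).tocsr()

    # linear-in-z initial guess between the two Dirichlet plates
    zc = np.broadcast_to(z0[None, None, :], shape)[air]
    ztop = domain_height
    guess = h_surface + (h_top - h_surface) * np.clip(zc / ztop, 0, 1)
    sol, info = cg(A, rhs, x0=guess, rtol=tol, atol=0.0, maxiter=maxiter)
    res = float(np.linalg.norm(A @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300))
    if info != 0:
        raise RuntimeError(
            f"Laplace solve did not converge (info={info}, residual={res:.2e})")

    hfield = np.full(shape, np.nan)
    hfield[air] = sol
    ext_mask = SolidMask(solid, h, h, mask.origin)
    return HumidityField(hfield, solid, h, h_surface, h_top, wet, face_bc,
                         res, mask.origin)


# ---------------------------------------------------------------------------
# Derived fields
# ---------------------------------------------------------------------------

def _neighbor_values(hf: HumidityField, axis: int, sign: int):
    """Per-air-voxel neighbour humidity along one direction.

    Returns ``(values, dist, defined)``: air neighbours carry their field
    value at distance 1 (in grid steps), Dirichlet faces (wet solid, top
    plate) carry the imposed value at distance 0.5; reflecting sides
    (dry solid, Neumann faces) are flagged undefined so the caller can
    fall back to a one-sided difference.
    """
    shape = hf.h.shape
    vals = np.full(shape, np.nan)
    dist = np.ones(shape)
    defined = np.zeros(shape, dtype=bool)
    cur = [slice(None)] * 3
    nb = [slice(None)] * 3
    if sign > 0:
        cur[axis] = slice(0, shape[axis] - 1)
        nb[axis] = slice(1, shape[axis])
        face_name = "xyz"[axis] + "+"
        face_sl = [slice(None)] * 3
        face_sl[axis] = -1
    else:
        cur[axis] = slice(1, shape[axis])
        nb[axis] = slice(0, shape[axis] - 1)
        face_name = "xyz"[axis] + "-"
        face_sl = [slice(None)] * 3
        face_sl[axis] = 0
    cur, nb, face_sl = tuple(cur), tuple(nb), tuple(face_sl)

    nb_air = ~hf.solid[nb]
    v = vals[cur]
    d = defined[cur]
    dd = dist[cur]
    v[nb_air] = hf.h[nb][nb_air]
    d[nb_air] = True
    nb_wet = hf.solid[nb] & hf.wet[nb]
    v[nb_wet] = hf.h_surface
    dd[nb_wet] = 0.5
    d[nb_wet] = True
    vals[cur] = v
    defined[cur] = d
    dist[cur] = dd

    h = hf.spacing
    nx, ny, nz = shape
    xg = hf.origin[0] + h * np.arange(nx)
    yg = hf.origin[1] + h * np.arange(ny)
    zg = h * (np.arange(nz) + 0.5)
    grids = np.meshgrid(xg, yg, zg, indexing="ij")
    gx, gy, gz = (g[face_sl].copy() for g in grids)
    if axis == 0:
        gx += h * sign / 2.0
    elif axis == 1:
        gy += h * sign / 2.0
    else:
        gz += h * sign / 2.0
    bc_val = _face_bc_value(hf.face_bc, face_name, coords=(gx, gy, gz))
    if bc_val is not None:
        vals[face_sl] = np.broadcast_to(np.asarray(bc_val, float), vals[face_sl].shape)
        dist[face_sl] = 0.5
        defined[face_sl] = True
    return vals, dist, defined


def gradient_map(hf: HumidityField) -> GradientMap:
    """Humidity-gradient magnitude per air voxel, in mm^-1 (fraction scale).

    Centred differences in the air interior; one-sided next to reflecting
    (dry-solid or Neumann) sides; Dirichlet values (wet surface, top
    plate) enter at their face positions, half a grid step away.
    """
    h = hf.spacing
    comps = []
    air = ~hf.solid
    for axis in range(3):
        vp, sp, dp = _neighbor_values(hf, axis, +1)
        vm, sm, dm = _neighbor_values(hf, axis, -1)
        g = np.zeros(hf.h.shape)
        both = dp & dm
        g[both] = (vp[both] - vm[both]) / ((sp[both] + sm[both]) * h)
        only_p = dp & ~dm
        g[only_p] = (vp[only_p] - hf.h[only_p]) / (sp[only_p] * h)
        only_m = dm & ~dp
        g[only_m] = (hf.h[only_m] - vm[only_m]) / (sm[only_m] * h)
        g[~air] = np.nan
        comps.append(g)
    mag = np.sqrt(comps[0] ** 2 + comps[1] ** 2 + comps[2] ** 2) / 100.0
    surf_adj = air & (ndimage.binary_dilation(
        hf.solid, structure=ndimage.generate_binary_structure(3, 1)) & air)
    return GradientMap(mag, tuple(comps), h, surf_adj, hf.origin)


def _face_flux(hf: HumidityField) -> tuple[np.ndarray, np.ndarray]:
    """Raw staircase flux per wet surface voxel: mean over exposed faces
    of (h_s - h_air)/(dx/2), matching the face-Dirichlet discretization."""
    h = hf.spacing
    air = ~hf.solid
    total = np.zeros(hf.h.shape)
    nfaces = np.zeros(hf.h.shape, dtype=int)
    shape = hf.h.shape
    for axis in range(3):
        for sign in (+1, -1):
            cur = [slice(None)] * 3
            nb = [slice(None)] * 3
            if sign > 0:
                cur[axis] = slice(0, shape[axis] - 1)
                nb[axis] = slice(1, shape[axis])
            else:
                cur[axis] = slice(1, shape[axis])
                nb[axis] = slice(0, shape[axis] - 1)
            cur, nb = tuple(cur), tuple(nb)
            m = hf.wet[cur] & air[nb]
            t = total[cur]
            n = nfaces[cur]
            t[m] += (hf.h_surface - hf.h[nb][m]) / (h / 2.0)
            n[m] += 1
            total[cur] = t
            nfaces[cur] = n
    mask = nfaces > 0
    values = np.full(shape, np.nan)
    values[mask] = total[mask] / nfaces[mask] / 100.0
    return values, mask


def surface_flux(hf: HumidityField, method: str = "extrapolated") -> SurfaceFlux:
    """Evaporation flux per wet surface voxel (mm^-1 scale).

    ``method="face"`` is the raw staircase estimate — the mean over the
    voxel's air-exposed faces of ``(h_surface - h_air)/dx``; it is exact
    on axis-aligned flat surfaces but biased low on curved ones, because
    the samples sit a finite distance into a decaying near-surface field.

    ``method="extrapolated"`` (default) removes that bias: the surface is
    located per voxel at the 0.5-crossing of a smoothed solid indicator
    along the outward normal, the mean gradient toward that point is
    sampled at two distances, and the surface value is recovered by
    harmonic extrapolation (exact for the 1/r fields that surround convex
    features; on flat staircase-aligned surfaces it reduces to the
    one-sided difference).
    """
    values, mask = _face_flux(hf)
    if method == "face":
        return SurfaceFlux(values, mask, hf.spacing)
    if method != "extrapolated":
        raise ValueError(f"unknown surface-flux method {method!r}")

    h = hf.spacing
    # outward normal from the smoothed indicator (points air-ward)
    sigma_ind = 1.2
    # replicate laterally (consistent with the no-flux walls), zero-pad
    # vertically so thin floors keep a one-sided indicator profile
    ind = ndimage.gaussian_filter(hf.solid.astype(float), sigma_ind,
                                  mode=["nearest", "nearest", "constant"])
    grads = np.gradient(-ind)
    idx = np.argwhere(mask)
    n = np.stack([g[tuple(idx.T)] for g in grads], axis=1)
    norm = np.linalg.norm(n, axis=1)
    ok = norm > 1e-12
    n[ok] /= norm[ok, None]
    c = idx.astype(float)

    # local mean curvature (voxel^-1, positive convex solid) of the
    # smoothed indicator, for the level-set shrinkage correction below
    gnorm = np.sqrt(sum(g * g for g in grads)) + 1e-12
    div = np.zeros_like(ind)
    for ax, g in enumerate(grads):
        div += np.gradient(g / gnorm)[ax]
    kappa = div[tuple(idx.T)]

    # sub-voxel surface location: 0.5-crossing of the indicator along
    # the normal ray from the voxel centre
    ts = np.linspace(-1.0, 2.5, 15)
    ivals = np.stack([
        ndimage.map_coordinates(ind, (c + t * n).T, order=1, mode="nearest")
        for t in ts])
    s0 = np.full(len(c), 0.5)
    above = ivals >= 0.5
    for k in range(len(c)):
        cross = np.flatnonzero(~above[:, k])
        if cross.size and cross[0] > 0:
            i2 = cross[0]
            i1 = i2 - 1
            v1, v2 = ivals[i1, k], ivals[i2, k]
            s0[k] = ts[i1] + (v1 - 0.5) / max(v1 - v2, 1e-12) * (ts[i2] - ts[i1])
    # Gaussian smoothing contracts level sets of curved surfaces by
    # sigma^2 kappa / 2 (mean-curvature shrinkage); undo it
    s0 = s0 + np.clip(0.5 * sigma_ind ** 2 * kappa, -0.5, 0.5)

    # fill solid with the Dirichlet value so interpolation near the
    # surface is well defined
    filled = np.where(hf.solid, hf.h_surface, hf.h)
    filled = np.nan_to_num(filled, nan=hf.h_surface)

    base = c + s0[:, None] * n
    out = values.copy()
    d1, d2 = 2.0, 4.0                           # sample distances in voxels
    h1 = ndimage.map_coordinates(filled, (base + d1 * n).T, order=1,
                                 mode="nearest")
    h2 = ndimage.map_coordinates(filled, (base + d2 * n).T, order=1,
                                 mode="nearest")
    m1 = (hf.h_surface - h1) / (d1 * h)
    m2 = (hf.h_surface - h2) / (d2 * h)
    # mean gradients over [0, d] scale as g* R/(R+d) near a convex
    # feature, so 1/m is linear in d: extrapolate to the surface
    with np.errstate(divide="ignore", invalid="ignore"):
        g = 1.0 / (2.0 / m1 - 1.0 / m2)
    good = ok & np.isfinite(g) & (m1 > 0) & (g > 0)
    ii = tuple(idx[good].T)
    out[ii] = g[good] / 100.0
    return SurfaceFlux(out, mask, h)


def flux_balance(hf: HumidityField) -> tuple[float, float]:
    """(flux through the top plate, flux off the wet surface), in %*mm.

    With no-flux lateral walls the two must agree; the discretization
    conserves them exactly up to the linear-solver residual.
    """
    h = hf.spacing
    bc = hf.face_bc.get("z+", ("neumann",))
    if bc[0] != "dirichlet":
        raise ValueError("flux balance requires a Dirichlet top plate")
    top = hf.h[:, :, -1]
    air_top = ~hf.solid[:, :, -1]
    top_flux = float(np.sum((top[air_top] - bc[1]) / (h / 2.0)) * h * h)
    sf = surface_flux(hf)
    # undo the per-voxel face averaging: sum over faces directly
    air = ~hf.solid
    total = 0.0
    shape = hf.h.shape
    for axis in range(3):
        for sign in (+1, -1):
            cur = [slice(None)] * 3
            nb = [slice(None)] * 3
            if sign > 0:
                cur[axis] = slice(0, shape[axis] - 1)
                nb[axis] = slice(1, shape[axis])
            else:
                cur[axis] = slice(1, shape[axis])
                nb[axis] = slice(0, shape[axis] - 1)
            cur, nb = tuple(cur), tuple(nb)
            m = hf.wet[cur] & air[nb]
            total += float(np.sum((hf.h_surface - hf.h[nb][m]) / (h / 2.0)) * h * h)
    return top_flux, total


# ---------------------------------------------------------------------------
# Region statistics
# ---------------------------------------------------------------------------

def tip_region(mask: SolidMask, shape_3d: tuple[int, int, int],
               radius: float = 2.0) -> np.ndarray:
    """Geometric neighbourhood (3D bool) within ``radius`` mm of the
    cue's highest surface point(s); intersect with a surface mask
    (``SurfaceFlux.mask`` or ``GradientMap.surface_adjacent``) to obtain
    the tip measurement region."""
    heights = mask.column_heights()
    top = heights.max()
    tips_ij = np.argwhere(heights >= top - mask.dz / 2)
    h = mask.spacing
    nx, ny, nz = shape_3d
    xg = mask.origin[0] + h * np.arange(nx)
    yg = mask.origin[1] + h * np.arange(ny)
    zg = h * (np.arange(nz) + 0.5)
    region = np.zeros(shape_3d, dtype=bool)
    for i, j in tips_ij:
        tx, ty, tz = xg[i], yg[j], heights[i, j]
        dist2 = ((xg[:, None, None] - tx) ** 2
                 + (yg[None, :, None] - ty) ** 2
                 + (zg[None, None, :] - tz) ** 2)
        region |= dist2 <= radius ** 2
    return region


def flat_reference_region(mask: SolidMask, shape_3d: tuple[int, int, int],
                          r_inner: float = 8.0, r_outer: float = 15.0) -> np.ndarray:
    """Radial band (3D bool) ``r_inner``-``r_outer`` mm from the arena
    centre, for the flat-disk reference statistic (intersect with a
    surface mask as for :func:`tip_region`)."""
    h = mask.spacing
    nx, ny, nz = shape_3d
    xg = mask.origin[0] + h * np.arange(nx)
    yg = mask.origin[1] + h * np.arange(ny)
    rr = np.hypot(xg[:, None], yg[None, :])
    band = (rr >= r_inner) & (rr <= r_outer)
    return np.broadcast_to(band[:, :, None], shape_3d).copy()


def amplification(values: np.ndarray, tip_mask: np.ndarray,
                  reference_mask: np.ndarray) -> float:
    """max of ``values`` over the tip region divided by the median over
    the reference region (NaN entries ignored)."""
    if not tip_mask.any() or not reference_mask.any():
        raise ValueError("tip and reference regions must be nonempty")
    if (tip_mask & reference_mask).any():
        raise ValueError("tip and reference regions must be disjoint")
    tip_max = float(np.nanmax(values[tip_mask]))
    ref_med = float(np.nanmedian(values[reference_mask]))
    return tip_max / ref_med


def flux_curvature_correlation(flux: SurfaceFlux, mask: SolidMask,
                               smoothing_sigma: float | None = None) -> float:
    """Spearman rank correlation between per-surface-voxel evaporation
    flux and the local mean curvature of the surface.

    Curvature comes from the exact-divergence operator evaluated on a
    Gaussian-smoothed indicator of the solid (positive = convex solid).
    Returns NaN with a warning when either input is constant.
    """
    from scipy.stats import spearmanr
    from .growth_model import PhaseField, mean_curvature

    nz0 = mask.shape[2]
    pts = np.argwhere(flux.mask[:, :, :nz0])
    if len(pts) < 100:
        raise ValueError("need at least 100 surface voxels")
    sigma = smoothing_sigma if smoothing_sigma is not None else 1.5 * mask.spacing
    ind = ndimage.gaussian_filter(
        np.pad(mask.solid.astype(float), 2, mode="edge"), sigma / mask.spacing)
    pf = PhaseField(ind, np.zeros_like(ind, dtype=bool), mask.spacing)
    curv = mean_curvature(pf)[2:-2, 2:-2, 2:-2]
    fvals = flux.values[tuple(pts.T)]
    cvals = curv[tuple(pts.T)]
    if np.ptp(fvals) < 1e-15 or np.ptp(cvals) < 1e-15:
        warnings.warn("flux or curvature constant over the surface; "
                      "correlation undefined", RuntimeWarning)
        return float("nan")
    rho, _ = spearmanr(fvals, cvals)
    return float(rho)
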