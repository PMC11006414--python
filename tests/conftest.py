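"""Shared fixtures: small scenes, coarse PDE solves, synthetic renders.

Heavier artefacts are session-scoped so each expensive solve or render
happens once per run.
"""

from __future__ import annotations

import numpy as np
import pytest

from nestflux import scene_geometry as sg
from nestflux import humidity_solver as hs
from nestflux import growth_model as gr


@pytest.fixture(scope="session")
def pillars_spec():
    return sg.SceneSpec(cue_type="pillars")


@pytest.fixture(scope="session")
def wall_spec():
    return sg.SceneSpec(cue_type="wall")


@pytest.fixture(scope="session")
def flat_spec():
    return sg.SceneSpec(cue_type="none")


@pytest.fixture(scope="session")
def pillars_mask_coarse(pillars_spec):
    """Pillars scene cropped to the 18 mm simulation window, 0.3 mm voxels."""
    hm = sg.build_height_map(pillars_spec, 0.3, half_extent=9.0)
    return sg.voxelize(hm, 0.3)


@pytest.fixture(scope="session")
def wall_mask_coarse(wall_spec):
    hm = sg.build_height_map(wall_spec, 0.3, half_extent=9.0)
    return sg.voxelize(hm, 0.3)


@pytest.fixture(scope="session")
def pillars_humidity(pillars_mask_coarse):
    return hs.solve_laplace(pillars_mask_coarse, domain_height=18.0)


@pytest.fixture(scope="session")
def wall_humidity(wall_mask_coarse):
    return hs.solve_laplace(wall_mask_coarse, domain_height=18.0)


def make_sphere_mask(R: float, dx: float, box_factor: float = 4.0) -> sg.SolidMask:
    L = box_factor * R
    n = int(round(L / dx))
    x = (np.arange(n) - n / 2 + 0.5) * dx
    X, Y = np.meshgrid(x, x, indexing="ij")
    z = dx * (np.arange(n) + 0.5)
    zc = L / 2
    solid = (X[:, :, None] ** 2 + Y[:, :, None] ** 2
             + (z[None, None, :] - zc) ** 2) <= R * R
    return sg.SolidMask(solid, dx, dx, (float(x[0]), float(x[0])))


def solve_sphere(R: float, dx: float, box_factor: float = 4.0,
                 h_surface: float = 100.0, h_top: float = 70.0):
    """Sphere in a box with the analytic Maxwell far field imposed on all
    domain faces (emulating an infinite domain with h -> h_top)."""
    mask = make_sphere_mask(R, dx, box_factor)
    L = box_factor * R
    zc = L / 2

    def far(gx, gy, gz):
        r = np.sqrt(gx ** 2 + gy ** 2 + (gz - zc) ** 2)
        return h_top + (h_surface - h_top) * R / r

    bc = {f: ("dirichlet_fn", far) for f in ("x-", "x+", "y-", "y+", "z-", "z+")}
    hf = hs.solve_laplace(mask, domain_height=L, face_bc=bc)
    return mask, hf


@pytest.fixture(scope="session")
def sphere_R3():
    """R = 3 mm sphere at 0.2 mm with analytic far field."""
    return solve_sphere(3.0, 0.2)


def make_slab_field(d: float, spacing: float = 0.3, nx: int = 12,
                    nz: int = 50) -> gr.PhaseField:
    """Flat slab initialized with the relaxed (stationary) 1D profile."""
    prof = gr.steady_interface_profile(d, spacing, nz)
    f = np.broadcast_to(prof, (nx, nx, nz)).copy()
    return gr.PhaseField(f, np.zeros((nx, nx, nz), bool), spacing)


def sphere_phase_field(R: float = 3.0, dx: float = 0.3, n: int = 40,
                       sigma_cells: float = 1.5) -> gr.PhaseField:
    mask = make_sphere_mask(R, dx, box_factor=n * dx / R)
    params = gr.GrowthParams(smoothing_sigma=sigma_cells * dx)
    pf = gr.initialize_field(mask, params)
    pf.frozen[:] = False
    return pf
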