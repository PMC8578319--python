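"""Shared fixtures.  The expensive finite-element solutions are computed once
per session at the production resolution and reused across test modules."""

import numpy as np
import pytest

from ventmech import synthetic, meshing, fem, directions, markers


PRODUCTION_H = 0.35
PRODUCTION_H_FAR = 2.6


@pytest.fixture(scope="session")
def default_spec():
    return synthetic.SubjectSpec()


@pytest.fixture(scope="session")
def default_geometry(default_spec):
    return synthetic.make_geometry(default_spec)


@pytest.fixture(scope="session")
def default_mesh(default_geometry):
    mesh, bset = meshing.mesh_geometry(default_geometry, PRODUCTION_H, h_far=PRODUCTION_H_FAR)
    return mesh, bset


@pytest.fixture(scope="session")
def default_wall(default_mesh):
    mesh, bset = default_mesh
    return meshing.order_wall(mesh, bset)


@pytest.fixture(scope="session")
def default_solution(default_mesh):
    mesh, bset = default_mesh
    disp = fem.solve_quasistatic(mesh, bset)
    state = fem.kinematics(disp, mesh)
    return disp, state


@pytest.fixture(scope="session")
def default_frames(default_mesh, default_wall):
    mesh, bset = default_mesh
    T = directions.solve_laplace(mesh, bset)
    return directions.wall_frames(T, mesh, default_wall)


@pytest.fixture(scope="session")
def default_profile(default_mesh, default_wall, default_solution, default_frames):
    mesh, _ = default_mesh
    _, state = default_solution
    return markers.project_wall_stretches(state, default_frames, default_wall, mesh)


@pytest.fixture(scope="session")
def annulus_mesh():
    """Homogeneous thick-walled annulus (a=10, b=20 mm), fine enough for the
    closed-form elasticity comparisons."""
    t = np.linspace(0, 2 * np.pi, 256, endpoint=False)
    rings = [np.c_[10 * np.cos(t), 10 * np.sin(t)], np.c_[20 * np.cos(t), 20 * np.sin(t)]]
    mesh = meshing.triangulate_rings(rings, ["white_matter"], h_wall=0.5, h_far=1.0)
    bset = meshing.extract_boundary_sets(mesh)
    return mesh, bset
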