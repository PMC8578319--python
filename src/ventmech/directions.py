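"""Reference wall direction fields from a Laplacian diffusion problem.

A harmonic scalar field T (reported in degrees C by convention) is solved
on the white- and gray-matter triangles with Dirichlet values 1.0 on the
ventricular wall, 0.2 on the gray/white interface, and 0.0 on the
gray-matter/CSF interface.  The steepest-descent direction of T at each
wall node is the reference wall normal n0 (oriented outward from the
cavity, into the tissue); rotating n0 by +90 deg gives the reference wall
tangent t0, aligned with counter-clockwise traversal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .meshing import Mesh2D, BoundarySets, WallPath

__all__ = ["DirectionField", "solve_laplace", "wall_frames"]

ROT_PLUS = np.array([[0.0, -1.0], [1.0, 0.0]])


@dataclass
class DirectionField:
    """Orthonormal (n0, t0) frames on the ordered wall nodes, plus the
    harmonic field T on all mesh nodes (NaN outside white/gray matter)."""

    n0: np.ndarray   # (n, 2) unit, outward-from-cavity
    t0: np.ndarray   # (n, 2) unit, n0 rotated +90 deg
    T: np.ndarray    # (N,) nodal scalar


def solve_laplace(mesh: Mesh2D, bset: BoundarySets) -> np.ndarray:
    """Solve the piecewise Laplace problem; returns nodal T (NaN off-domain).

    The subarachnoid CSF region carries no equation; the three Dirichlet
    sets fully separate the white-matter and gray-matter subproblems.
    """
    wall_nodes = np.unique(bset.ventricular_wall_edges)
    gmwm_nodes = np.unique(bset.gm_wm_interface_edges)
    gmcsf_nodes = np.unique(bset.gm_csf_interface_edges)
    for name, nodes in (
        ("ventricular_wall", wall_nodes),
        ("gm_wm_interface", gmwm_nodes),
        ("gm_csf_interface", gmcsf_nodes),
    ):
        if len(nodes) == 0:
            raise ValueError(f"empty boundary set: {name}")

    sel = np.isin(mesh.region, ["white_matter", "gray_matter"])
    tris = mesh.triangles[sel]
    p = mesh.nodes[tris]
    d1 = p[:, 1] - p[:, 0]
    d2 = p[:, 2] - p[:, 0]
    det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    area = 0.5 * det
    g = np.empty((len(tris), 3, 2))
    g[:, 1, 0] = d2[:, 1] / det
    g[:, 1, 1] = -d2[:, 0] / det
    g[:, 2, 0] = -d1[:, 1] / det
    g[:, 2, 1] = d1[:, 0] / det
    g[:, 0] = -g[:, 1] - g[:, 2]

    Ke = np.einsum("e,eiJ,ejJ->eij", area, g, g)
    rows = np.repeat(tris, 3, axis=1).ravel()
    cols = np.tile(tris, (1, 3)).ravel()
    n = mesh.n_nodes
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()

    T = np.full(n, np.nan)
    dirichlet = np.zeros(n, bool)
    for nodes, value in ((wall_nodes, 1.0), (gmwm_nodes, 0.2), ((gmcsf_nodes), 0.0)):
        T[nodes] = value
        dirichlet[nodes] = True

    domain = np.zeros(n, bool)
    domain[np.unique(tris)] = True
    free = domain & ~dirichlet
    Td = np.where(dirichlet, T, 0.0)
    rhs = -K @ Td
    fidx = np.nonzero(free)[0]
    Kff = K[np.ix_(fidx, fidx)].tocsc()
    T[fidx] = spla.spsolve(Kff, rhs[fidx])
    return T


def wall_frames(T: np.ndarray, mesh: Mesh2D, wall: WallPath) -> DirectionField:
    """Recover (n0, t0) on the wall by area-weighted nodal gradient averaging.

    Degenerate gradients (norm < 1e-12) fall back to the discrete wall-edge
    geometric frame; orientation is fixed to point outward from the cavity.
    """
    sel = np.isin(mesh.region, ["white_matter", "gray_matter"])
    tris = mesh.triangles[sel]
    p = mesh.nodes[tris]
    d1 = p[:, 1] - p[:, 0]
    d2 = p[:, 2] - p[:, 0]
    det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    area = 0.5 * det
    g = np.empty((len(tris), 3, 2))
    g[:, 1, 0] = d2[:, 1] / det
    g[:, 1, 1] = -d2[:, 0] / det
    g[:, 2, 0] = -d1[:, 1] / det
    g[:, 2, 1] = d1[:, 0] / det
    g[:, 0] = -g[:, 1] - g[:, 2]
    gradT = np.einsum("en,enJ->eJ", T[tris], g)      # per-element, constant

    num = np.zeros((mesh.n_nodes, 2))
    den = np.zeros(mesh.n_nodes)
    for i in range(3):
        np.add.at(num, tris[:, i], area[:, None] * gradT)
        np.add.at(den, tris[:, i], area)

    idx = wall.node_indices
    grad = num[idx] / np.maximum(den[idx], 1e-300)[:, None]

    # geometric frame of the CCW wall loop: tangent along traversal,
    # outward normal = tangent rotated -90 deg
    nxt = np.roll(wall.coords, -1, axis=0)
    prv = np.roll(wall.coords, 1, axis=0)
    tang = nxt - prv
    tang /= np.linalg.norm(tang, axis=1)[:, None]
    geo_n = tang @ ROT_PLUS  # rotate -90: (x,y) @ [[0,-1],[1,0]] = (y,-x)

    n0 = np.empty_like(grad)
    norms = np.linalg.norm(grad, axis=1)
    good = norms > 1e-12
    n0[good] = -grad[good] / norms[good, None]        # T decreases into tissue
    n0[~good] = geo_n[~good]
    # safeguard: enforce outward-from-cavity orientation
    flip = np.sum(n0 * geo_n, axis=1) < 0
    n0[flip] = -n0[flip]
    t0 = n0 @ ROT_PLUS.T                              # rotate +90
    return DirectionField(n0=n0, t0=t0, T=T)
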