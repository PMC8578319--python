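"""Quasistatic plane-strain hyperelastic finite elements.

Constitutive model: a one-term Ogden energy in squared isochoric principal
stretches (the alpha = 2 member, an isochoric neo-Hookean) plus a
logarithmic volumetric penalty,

    Psi = mu/2 [lam1b^2 + lam2b^2 + lam3b^2 - 3] + kappa/4 [J^2 - 1 - 2 ln J],

with per-region shear modulus mu and bulk modulus kappa.  Gray matter
defaults to (0.34, 3.3) kPa, white matter to (0.68, 6.6) kPa (2x stiffness
ratio, Poisson ratio 0.45); the subarachnoid CSF layer is an ultrasoft
compressible surrogate with the same energy form, its (mu, kappa) converted
from E = 0.1 kPa, nu = 0.3.

Loads are follower (deformed-normal) pressures: the ventricular pressure
p_LV on the cavity wall, and the subarachnoid pressure p_SAS applied as a
one-sided traction on the outer gray-matter surface, pressing the brain
inward, while the meshed CSF layer stays attached and transmits the
reaction to the skull.  (Treating the interface as a pressurized fluid film
with both faces loaded and detached leaves the brain without kinematic
support — a floating body with near-singular rigid modes — so the one-sided
form is used.)  The skull is a zero-displacement constraint on the outer
periphery.  Plane strain fixes the out-of-plane stretch at 1.

Solved with full Newton iteration (analytic consistent tangent, including
the nonsymmetric follower-load stiffness), backtracking line search, and
uniform load incrementation as a fallback.  Entirely deterministic.

Units: lengths mm, pressures Pa, moduli supplied in kPa and converted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .meshing import Mesh2D, BoundarySets

__all__ = [
    "MaterialParams",
    "LoadCase",
    "DisplacementField",
    "DeformationState",
    "ogden_energy",
    "stress_and_tangent",
    "solve_quasistatic",
    "kinematics",
]

KPA_TO_PA = 1000.0


def _csf_moduli(E_kpa=0.1, nu=0.3):
    mu = E_kpa / (2 * (1 + nu))
    kappa = E_kpa / (3 * (1 - 2 * nu))
    return mu, kappa


@dataclass(frozen=True)
class MaterialParams:
    """Per-region (shear, bulk) moduli in kPa."""

    gray_matter: tuple[float, float] = (0.34, 3.3)
    white_matter: tuple[float, float] = (0.68, 6.6)
    csf: tuple[float, float] = _csf_moduli()

    def for_region(self, label: str) -> tuple[float, float]:
        try:
            mu, kappa = getattr(self, label)
        except AttributeError:
            raise KeyError(f"no material parameters for region {label!r}") from None
        if mu <= 0 or kappa <= 0:
            raise ValueError(f"moduli must be positive for region {label!r}")
        return mu, kappa


@dataclass(frozen=True)
class LoadCase:
    """Pressure loading (Pa) with multipliers for sensitivity sweeps.

    ``pressure_scale`` multiplies both pressures; ``stiffness_scale``
    multiplies the white-matter moduli.
    """

    p_lv: float = 20.0
    p_sas: float = 1.0
    pressure_scale: float = 1.0
    stiffness_scale: float = 1.0


@dataclass
class DisplacementField:
    """Converged nodal displacements (mm); ``residual_history`` lists the
    Newton residual norms per iteration of the final load step."""

    u: np.ndarray
    residual_history: list[float] = field(default_factory=list)


@dataclass
class DeformationState:
    """Per-element finite-strain kinematics under plane strain (F33 = 1)."""

    F: np.ndarray        # (M, 3, 3)
    J: np.ndarray        # (M,)
    C: np.ndarray        # (M, 3, 3)
    Cbar: np.ndarray     # (M, 3, 3)
    I1_bar: np.ndarray   # (M,)
    I2_bar: np.ndarray   # (M,)
    principal_stretches_bar: np.ndarray  # (M, 3), descending
    E: np.ndarray        # (M, 3, 3) Green-Lagrange
    mps: np.ndarray      # (M,) max principal Green-Lagrange strain


# --------------------------------------------------------------------------
# constitutive point functions (3x3 deformation gradients)

def _as33(F):
    F = np.asarray(F, float)
    if F.shape == (2, 2):
        G = np.eye(3)
        G[:2, :2] = F
        return G
    return F


def ogden_energy(F, mu: float, kappa: float) -> float:
    """Strain energy density for a deformation gradient (kPa in -> kPa out)."""
    F = _as33(F)
    J = np.linalg.det(F)
    if J <= 0:
        raise ValueError(f"element inversion: det F = {J:.3e} <= 0")
    C = F.T @ F
    I1b = J ** (-2.0 / 3.0) * np.trace(C)
    return mu / 2.0 * (I1b - 3.0) + kappa / 4.0 * (J**2 - 1.0 - 2.0 * np.log(J))


def stress_and_tangent(F, mu: float, kappa: float):
    """First Piola-Kirchhoff stress P = dPsi/dF and tangent A = dP/dF.

    Works on 3x3 gradients; returns (P (3,3), A (3,3,3,3)).
    """
    F = _as33(F)
    J = np.linalg.det(F)
    if J <= 0:
        raise ValueError(f"element inversion: det F = {J:.3e} <= 0")
    G = np.linalg.inv(F).T
    I1 = np.trace(F.T @ F)
    Jm23 = J ** (-2.0 / 3.0)
    a = mu * Jm23
    b = -mu / 3.0 * Jm23 * I1 + kappa / 2.0 * (J**2 - 1.0)
    P = a * F + b * G

    da = -(2.0 / 3.0) * a * G                       # d a / dF
    db = (2.0 * mu / 9.0) * Jm23 * I1 * G - (2.0 * mu / 3.0) * Jm23 * F + kappa * J**2 * G
    I = np.eye(3)
    A = (
        np.einsum("iJ,kL->iJkL", F, da)
        + a * np.einsum("ik,JL->iJkL", I, I)
        + np.einsum("iJ,kL->iJkL", G, db)
        - b * np.einsum("iL,kJ->iJkL", G, G)
    )
    return P, A


# --------------------------------------------------------------------------
# vectorized element routines (2x2 in-plane blocks, plane strain)

def _batch_PA(F2, mu, kappa):
    """Vectorized in-plane P and tangent for (M,2,2) gradients.

    Out-of-plane stretch fixed at 1: J = det F2, I1 = |F2|^2 + 1.
    """
    J = F2[:, 0, 0] * F2[:, 1, 1] - F2[:, 0, 1] * F2[:, 1, 0]
    if np.any(J <= 0):
        bad = int(np.argmax(J <= 0))
        raise FloatingPointError(f"element inversion at element {bad}: J = {J[bad]:.3e}")
    inv = np.empty_like(F2)
    inv[:, 0, 0] = F2[:, 1, 1]
    inv[:, 0, 1] = -F2[:, 0, 1]
    inv[:, 1, 0] = -F2[:, 1, 0]
    inv[:, 1, 1] = F2[:, 0, 0]
    inv /= J[:, None, None]
    G = np.swapaxes(inv, 1, 2)                     # F^{-T}
    I1 = np.einsum("eij,eij->e", F2, F2) + 1.0
    Jm23 = J ** (-2.0 / 3.0)
    a = mu * Jm23
    b = -mu / 3.0 * Jm23 * I1 + kappa / 2.0 * (J**2 - 1.0)
    P = a[:, None, None] * F2 + b[:, None, None] * G

    da = -(2.0 / 3.0) * a[:, None, None] * G
    db = (
        (2.0 * mu / 9.0) * Jm23 * I1
    )[:, None, None] * G - ((2.0 * mu / 3.0) * Jm23)[:, None, None] * F2 + (
        kappa * J**2
    )[:, None, None] * G
    I2 = np.eye(2)
    A = (
        np.einsum("eiJ,ekL->eiJkL", F2, da)
        + a[:, None, None, None, None] * np.einsum("ik,JL->iJkL", I2, I2)[None]
        + np.einsum("eiJ,ekL->eiJkL", G, db)
        - b[:, None, None, None, None] * np.einsum("eiL,ekJ->eiJkL", G, G)
    )
    return P, A


def _batch_energy(F2, mu, kappa):
    J = F2[:, 0, 0] * F2[:, 1, 1] - F2[:, 0, 1] * F2[:, 1, 0]
    if np.any(J <= 0):
        raise FloatingPointError("element inversion")
    I1 = np.einsum("eij,eij->e", F2, F2) + 1.0
    return mu / 2.0 * (J ** (-2.0 / 3.0) * I1 - 3.0) + kappa / 4.0 * (J**2 - 1 - 2 * np.log(J))


class _Assembler:
    """Precomputed shape-function gradients + vectorized assembly."""

    def __init__(self, nodes, tris, mu, kappa):
        self.nodes = nodes
        self.tris = tris
        self.mu = mu
        self.kappa = kappa
        p = nodes[tris]
        d1 = p[:, 1] - p[:, 0]
        d2 = p[:, 2] - p[:, 0]
        det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
        if np.any(det <= 0):
            raise ValueError("mesh contains non-positively-oriented triangles")
        self.area = 0.5 * det
        # gradients of the three hat functions: (M, 3 nodes, 2)
        g = np.empty((len(tris), 3, 2))
        g[:, 1, 0] = d2[:, 1] / det
        g[:, 1, 1] = -d2[:, 0] / det
        g[:, 2, 0] = -d1[:, 1] / det
        g[:, 2, 1] = d1[:, 0] / det
        g[:, 0] = -g[:, 1] - g[:, 2]
        self.grad = g
        self.ndof = 2 * len(nodes)
        # sparse pattern indices for K
        e = len(tris)
        rows = np.empty((e, 6, 6), int)
        cols = np.empty((e, 6, 6), int)
        dof = (2 * tris[:, :, None] + np.array([0, 1])[None, None]).reshape(e, 6)
        rows[:] = dof[:, :, None]
        cols[:] = dof[:, None, :]
        self._rows = rows.ravel()
        self._cols = cols.ravel()

    def deformation(self, u):
        ue = u.reshape(-1, 2)[self.tris]               # (M, 3, 2)
        F2 = np.einsum("eni,enJ->eiJ", ue, self.grad)  # grad u
        F2[:, 0, 0] += 1.0
        F2[:, 1, 1] += 1.0
        return F2

    def internal_force(self, u):
        F2 = self.deformation(u)
        P, A = _batch_PA(F2, self.mu, self.kappa)
        fe = np.einsum("e,eaJ,enJ->ena", self.area, P, self.grad)
        f = np.zeros(self.ndof)
        np.add.at(f, 2 * self.tris, fe[:, :, 0])
        np.add.at(f, 2 * self.tris + 1, fe[:, :, 1])
        Ke = np.einsum("e,enJ,eaJbL,emL->enamb", self.area, self.grad, A, self.grad)
        K = sp.coo_matrix(
            (Ke.reshape(len(self.tris), 6, 6).ravel(), (self._rows, self._cols)),
            shape=(self.ndof, self.ndof),
        ).tocsc()
        return f, K

    def internal_force_only(self, u):
        F2 = self.deformation(u)
        J = F2[:, 0, 0] * F2[:, 1, 1] - F2[:, 0, 1] * F2[:, 1, 0]
        if np.any(J <= 0):
            raise FloatingPointError("element inversion")
        P, _ = _batch_PA(F2, self.mu, self.kappa)
        fe = np.einsum("e,eaJ,enJ->ena", self.area, P, self.grad)
        f = np.zeros(self.ndof)
        np.add.at(f, 2 * self.tris, fe[:, :, 0])
        np.add.at(f, 2 * self.tris + 1, fe[:, :, 1])
        return f

    def total_energy(self, u):
        F2 = self.deformation(u)
        return float(np.sum(self.area * _batch_energy(F2, self.mu, self.kappa)))


ROT_MINUS = np.array([[0.0, 1.0], [-1.0, 0.0]])   # rotate -90 deg: outward of a CCW loop
ROT_PLUS = np.array([[0.0, -1.0], [1.0, 0.0]])    # rotate +90 deg: inward of a CCW loop


@dataclass
class PressureLoad:
    """Follower pressure on oriented edges.

    ``edges`` are (E, 2) node pairs walked with the loaded body on the side
    given by ``rot`` (ROT_MINUS pushes to the right of the walking
    direction, i.e. outward for a CCW loop around a pressurized cavity).
    """

    edges: np.ndarray
    pressure: float      # Pa
    rot: np.ndarray


def _external_force(loads: list[PressureLoad], x, ndof):
    f = np.zeros(ndof)
    for ld in loads:
        if ld.pressure == 0 or len(ld.edges) == 0:
            continue
        a, b = ld.edges[:, 0], ld.edges[:, 1]
        d = x[b] - x[a]
        t = 0.5 * ld.pressure * d @ ld.rot.T
        np.add.at(f, 2 * a, t[:, 0])
        np.add.at(f, 2 * a + 1, t[:, 1])
        np.add.at(f, 2 * b, t[:, 0])
        np.add.at(f, 2 * b + 1, t[:, 1])
    return f


def _external_stiffness(loads: list[PressureLoad], ndof):
    rows, cols, vals = [], [], []
    for ld in loads:
        if ld.pressure == 0 or len(ld.edges) == 0:
            continue
        W = 0.5 * ld.pressure * ld.rot
        for a, b in ld.edges:
            for i in range(2):
                for j in range(2):
                    if W[i, j] == 0:
                        continue
                    for node in (a, b):
                        rows.append(2 * node + i)
                        cols.append(2 * b + j)
                        vals.append(W[i, j])
                        rows.append(2 * node + i)
                        cols.append(2 * a + j)
                        vals.append(-W[i, j])
    if not rows:
        return sp.csc_matrix((ndof, ndof))
    return sp.coo_matrix((vals, (rows, cols)), shape=(ndof, ndof)).tocsc()


class NewtonError(RuntimeError):
    def __init__(self, msg, history):
        super().__init__(msg)
        self.history = history


def _newton(assembler, loads, fixed_dofs, tol_rel=1e-9, max_iter=30, n_steps=1):
    ndof = assembler.ndof
    free = np.setdiff1d(np.arange(ndof), fixed_dofs)
    u = np.zeros(ndof)
    history = []
    nodes = assembler.nodes
    for step in range(1, n_steps + 1):
        frac = step / n_steps
        step_loads = [PressureLoad(l.edges, frac * l.pressure, l.rot) for l in loads]
        fext_ref = _external_force(step_loads, nodes, ndof)
        scale = max(np.linalg.norm(fext_ref), 1e-30)
        history = []
        for it in range(max_iter):
            x = nodes + u.reshape(-1, 2)
            fext = _external_force(step_loads, x, ndof)
            fint, K = assembler.internal_force(u)
            r = fint - fext
            rn = np.linalg.norm(r[free])
            history.append(rn)
            if rn <= tol_rel * scale:
                break
            K = K - _external_stiffness(step_loads, ndof)
            Kff = K[np.ix_(free, free)]
            du = spla.spsolve(Kff.tocsc(), -r[free])
            # backtracking line search on the residual norm
            alpha = 1.0
            for _ in range(10):
                u_try = u.copy()
                u_try[free] += alpha * du
                try:
                    x = nodes + u_try.reshape(-1, 2)
                    r_try = assembler.internal_force_only(u_try) - _external_force(
                        step_loads, x, ndof
                    )
                    if np.linalg.norm(r_try[free]) < (1.0 - 1e-4 * alpha) * rn or alpha < 1e-3:
                        break
                except FloatingPointError:
                    pass
                alpha *= 0.5
            else:
                raise NewtonError("line search failed", history)
            u = u_try
        else:
            raise NewtonError(
                f"Newton did not converge in {max_iter} iterations "
                f"(last residual {history[-1]:.3e})",
                history,
            )
    return u, history


# --------------------------------------------------------------------------
# public solve

def solve_quasistatic(
    mesh: Mesh2D,
    bset: BoundarySets,
    materials: MaterialParams = MaterialParams(),
    loads: LoadCase = LoadCase(),
    tol_rel: float = 1e-9,
    max_iter: int = 30,
) -> DisplacementField:
    """Solve the pressurized equilibrium problem.

    Ventricular pressure acts as a follower load on the cavity wall;
    subarachnoid pressure as a one-sided follower traction on the outer
    gray-matter surface; skull nodes are fixed.  Falls back to up to 10
    uniform load increments if the full-step Newton iteration fails.
    """
    if len(bset.skull_nodes) == 0:
        raise ValueError("skull node set is empty; the problem would be unconstrained")

    p_lv = loads.p_lv * loads.pressure_scale
    p_sas = loads.p_sas * loads.pressure_scale
    nodes, tris = mesh.nodes, mesh.triangles

    mu = np.empty(len(tris))
    kappa = np.empty(len(tris))
    for lab in np.unique(mesh.region):
        m, k = materials.for_region(lab)
        if lab == "white_matter":
            m, k = m * loads.stiffness_scale, k * loads.stiffness_scale
        sel = mesh.region == lab
        mu[sel] = m * KPA_TO_PA
        kappa[sel] = k * KPA_TO_PA

    asm = _Assembler(nodes, tris, mu, kappa)

    pl: list[PressureLoad] = []
    if p_lv != 0 and len(bset.ventricular_wall_edges):
        pl.append(PressureLoad(bset.ventricular_wall_edges, p_lv, ROT_MINUS))
    if p_sas != 0 and len(bset.gm_csf_interface_edges):
        # subarachnoid pressure on the outer gray-matter surface: one-sided
        # follower traction pushing the brain inward (the CSF layer stays
        # attached and transmits the reaction to the fixed skull)
        pl.append(PressureLoad(bset.gm_csf_interface_edges, p_sas, ROT_PLUS))

    fixed = np.concatenate([2 * bset.skull_nodes, 2 * bset.skull_nodes + 1])

    if not pl:
        return DisplacementField(u=np.zeros_like(mesh.nodes), residual_history=[0.0])

    try:
        u, history = _newton(asm, pl, fixed, tol_rel=tol_rel, max_iter=max_iter)
    except NewtonError:
        u, history = _newton(asm, pl, fixed, tol_rel=tol_rel, max_iter=max_iter, n_steps=10)

    return DisplacementField(u=u.reshape(-1, 2).copy(), residual_history=history)


def kinematics(fieldd: DisplacementField, mesh: Mesh2D) -> DeformationState:
    """Per-element finite-strain measures from a converged displacement."""
    ue = fieldd.u[mesh.triangles]
    p = mesh.nodes[mesh.triangles]
    d1 = p[:, 1] - p[:, 0]
    d2 = p[:, 2] - p[:, 0]
    det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    g = np.empty((len(mesh.triangles), 3, 2))
    g[:, 1, 0] = d2[:, 1] / det
    g[:, 1, 1] = -d2[:, 0] / det
    g[:, 2, 0] = -d1[:, 1] / det
    g[:, 2, 1] = d1[:, 0] / det
    g[:, 0] = -g[:, 1] - g[:, 2]
    F2 = np.einsum("eni,enJ->eiJ", ue, g)
    F2[:, 0, 0] += 1.0
    F2[:, 1, 1] += 1.0

    m = len(F2)
    F = np.tile(np.eye(3), (m, 1, 1))
    F[:, :2, :2] = F2
    J = F2[:, 0, 0] * F2[:, 1, 1] - F2[:, 0, 1] * F2[:, 1, 0]
    if np.any(J <= 0):
        bad = int(np.argmax(J <= 0))
        raise ValueError(f"element inversion at element {bad}: J = {J[bad]:.3e}")
    C = np.einsum("eki,ekj->eij", F, F)
    Cbar = C * (J ** (-2.0 / 3.0))[:, None, None]
    I1b = np.trace(Cbar, axis1=1, axis2=2)
    tr2 = np.trace(np.einsum("eij,ejk->eik", Cbar, Cbar), axis1=1, axis2=2)
    I2b = 0.5 * (I1b**2 - tr2)
    eig = np.linalg.eigvalsh(Cbar)[:, ::-1]
    stretches = np.sqrt(eig)
    E = 0.5 * (C - np.eye(3)[None])
    mps = np.linalg.eigvalsh(E)[:, -1]
    return DeformationState(
        F=F, J=J, C=C, Cbar=Cbar, I1_bar=I1b, I2_bar=I2b,
        principal_stretches_bar=stretches, E=E, mps=mps,
    )
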