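"""Wall-level mechanomarkers: ependymal stretches, horn radii, wall fraction.

From a converged deformation state, the right Cauchy-Green tensor C is
averaged onto the ventricular-wall nodes (white-matter side) and projected
onto the reference wall frames,

    lambda_t = sqrt(t0 . C t0)   (cell tension, tangential)
    lambda_c = sqrt(n0 . C n0)   (cell compression, normal),

giving the wall profile of ependymal cell tension and compression.  The
four horn peaks are the four highest arclength-separated local maxima of
lambda_t.  Each horn's radius is the circumradius of the circle through the
peak point and the two flanking points where the *excess* tension
(lambda_t - 1) has dropped to 10% of the peak excess; the same 10%-excess
convention defines the wall fraction under elevated stretch.  (A 10% rule
on raw stretch would be meaningless for a quantity bounded near 1, so the
excess reading is used throughout and flagged in reports.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .meshing import Mesh2D, WallPath
from .directions import DirectionField
from .fem import DeformationState

__all__ = [
    "WallProfile",
    "HornMetrics",
    "project_wall_stretches",
    "detect_horn_peaks",
    "horn_circle_fit",
    "wall_fraction_elevated",
    "horn_metrics",
    "circumcircle",
]


@dataclass
class WallProfile:
    """Ordered wall-node stretches with the traversal geometry."""

    arclength: np.ndarray    # (n,) mm
    lambda_t: np.ndarray     # (n,)
    lambda_c: np.ndarray     # (n,)
    coords: np.ndarray       # (n, 2) reference coordinates
    n0: np.ndarray
    t0: np.ndarray
    total_length: float
    mps: np.ndarray | None = None   # per-element MPS over the whole mesh

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "arclength_mm": self.arclength,
                "lambda_t": self.lambda_t,
                "lambda_c": self.lambda_c,
                "x_mm": self.coords[:, 0],
                "y_mm": self.coords[:, 1],
                "n0_x": self.n0[:, 0],
                "n0_y": self.n0[:, 1],
                "t0_x": self.t0[:, 0],
                "t0_y": self.t0[:, 1],
            }
        )


@dataclass
class HornMetrics:
    """Per-horn geometry/loading summary plus the subject-level wall fraction.

    The 10% thresholds use the excess-stretch convention (lambda_t - 1).
    """

    radii: list[float]                  # fitted circle radius per horn, mm
    peak_lambda_t: list[float]
    peak_arclength: list[float]
    arc_endpoints: list[tuple[float, float]]   # (left, right) arclength of 10% drop
    wall_fraction_elevated: float
    convention: str = "excess-stretch 10% rule: thresholds on (lambda_t - 1)"


def project_wall_stretches(
    state: DeformationState,
    frames: DirectionField,
    wall: WallPath,
    mesh: Mesh2D,
) -> WallProfile:
    """Average C onto wall nodes (white-matter elements only) and project."""
    wm = mesh.region == "white_matter"
    tris = mesh.triangles[wm]
    C2 = state.C[wm][:, :2, :2]
    p = mesh.nodes[tris]
    d1 = p[:, 1] - p[:, 0]
    d2 = p[:, 2] - p[:, 0]
    area = 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])

    num = np.zeros((mesh.n_nodes, 2, 2))
    den = np.zeros(mesh.n_nodes)
    for i in range(3):
        np.add.at(num, tris[:, i], area[:, None, None] * C2)
        np.add.at(den, tris[:, i], area)
    idx = wall.node_indices
    Cw = num[idx] / np.maximum(den[idx], 1e-300)[:, None, None]

    lt = np.sqrt(np.einsum("ni,nij,nj->n", frames.t0, Cw, frames.t0))
    lc = np.sqrt(np.einsum("ni,nij,nj->n", frames.n0, Cw, frames.n0))
    return WallProfile(
        arclength=wall.arclength,
        lambda_t=lt,
        lambda_c=lc,
        coords=wall.coords,
        n0=frames.n0,
        t0=frames.t0,
        total_length=wall.total_length,
        mps=state.mps,
    )


def detect_horn_peaks(profile: WallProfile, min_separation_frac: float = 0.05) -> np.ndarray:
    """Indices of the four horn peaks of lambda_t, in traversal order.

    Peaks are strict local maxima on the closed profile; the four largest
    values separated by at least ``min_separation_frac`` of the wall length
    are kept.  Ties break toward smaller arclength.  Raises if fewer than
    four separated maxima exist (degenerate geometry or load).
    """
    lt = profile.lambda_t
    left = np.roll(lt, 1)
    right = np.roll(lt, -1)
    is_max = (lt > left) & (lt >= right)
    cand = np.nonzero(is_max)[0]
    if len(cand) == 0:
        raise ValueError("no local maxima in the tension profile (zero load?)")
    # sort by value descending, then arclength ascending for determinism
    order = cand[np.lexsort((profile.arclength[cand], -lt[cand]))]
    L = profile.total_length
    min_sep = min_separation_frac * L
    picked: list[int] = []
    for i in order:
        si = profile.arclength[i]
        ok = all(
            min(abs(si - profile.arclength[j]), L - abs(si - profile.arclength[j])) >= min_sep
            for j in picked
        )
        if ok:
            picked.append(int(i))
        if len(picked) == 4:
            break
    if len(picked) < 4:
        raise ValueError(
            f"only {len(picked)} separated tension maxima found; expected 4 horn peaks"
        )
    return np.array(sorted(picked))


def refined_peak_arclength(profile: WallProfile, peak: int, level: float = 0.7) -> float:
    """Sub-node peak location: excess-weighted centroid of the contiguous
    wall section around ``peak`` where excess tension stays above ``level``
    times the peak excess.  Robust against adjacent nodes swapping the
    argmax on a flat-topped peak."""
    ex = profile.lambda_t - 1.0
    thr = level * ex[peak]
    n = len(ex)
    idx = [peak]
    for direction in (-1, +1):
        i = peak
        while True:
            j = (i + direction) % n
            if j == peak or ex[j] < thr:
                break
            idx.append(j)
            i = j
    idx = np.array(idx)
    L = profile.total_length
    # unwrap arclengths around the peak
    s = profile.arclength[idx]
    s0 = profile.arclength[peak]
    ds = (s - s0 + L / 2) % L - L / 2
    w = ex[idx] - thr
    return float((s0 + np.sum(w * ds) / max(np.sum(w), 1e-300)) % L)


def circumcircle(p1, p2, p3):
    """Center and radius of the circle through three points."""
    ax, ay = p1
    bx, by = p2
    cx, cy = p3
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-12 * max(1.0, abs(ax) + abs(bx) + abs(cx)) ** 2:
        raise ValueError("collinear points: circumcircle radius is infinite")
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay) + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx) + (cx**2 + cy**2) * (bx - ax)) / d
    center = np.array([ux, uy])
    return center, float(np.linalg.norm(np.asarray(p1) - center))


def _interp_point(profile: WallProfile, s: float) -> np.ndarray:
    """Wall coordinate at arclength s (periodic linear interpolation)."""
    L = profile.total_length
    s = s % L
    sa = profile.arclength
    k = int(np.searchsorted(sa, s, side="right") - 1)
    k = max(k, 0)
    s0 = sa[k]
    k1 = (k + 1) % len(sa)
    ds = (sa[k1] - s0) % L
    if ds == 0:
        return profile.coords[k]
    f = ((s - s0) % L) / ds
    return (1 - f) * profile.coords[k] + f * profile.coords[k1]


def _crossing(profile: WallProfile, peak: int, threshold: float, direction: int):
    """Arclength where excess tension first falls to ``threshold`` walking
    from the peak in ``direction`` (+1/-1); linear interpolation between
    nodes.  Raises if no crossing exists before returning to the peak."""
    n = len(profile.lambda_t)
    ex = profile.lambda_t - 1.0
    L = profile.total_length
    i = peak
    for _ in range(n - 1):
        j = (i + direction) % n
        if ex[j] <= threshold:
            e0, e1 = ex[i], ex[j]
            f = (e0 - threshold) / max(e0 - e1, 1e-300)
            s0, s1 = profile.arclength[i], profile.arclength[j]
            ds = (s1 - s0) % L if direction > 0 else -((s0 - s1) % L)
            return (s0 + f * ds) % L
        i = j
    raise ValueError("tension never drops to the 10% level along the wall")


def horn_circle_fit(profile: WallProfile, peak: int, drop_frac: float = 0.10):
    """Radius (mm) of the circle through the tension peak and its two
    10%-of-peak-excess flank crossings."""
    ex_peak = profile.lambda_t[peak] - 1.0
    if ex_peak <= 0:
        raise ValueError("peak has no excess tension; cannot fit a horn circle")
    thr = drop_frac * ex_peak
    s_left = _crossing(profile, peak, thr, -1)
    s_right = _crossing(profile, peak, thr, +1)
    p_left = _interp_point(profile, s_left)
    p_right = _interp_point(profile, s_right)
    p_peak = profile.coords[peak]
    _, r = circumcircle(p_peak, p_left, p_right)
    return r, (float(s_left), float(s_right))


def wall_fraction_elevated(profile: WallProfile, drop_frac: float = 0.10) -> float:
    """Fraction of the wall where excess tension exceeds 10% of the global
    peak excess, measured by linear interpolation along the closed loop."""
    ex = profile.lambda_t - 1.0
    peak = float(np.max(ex))
    if peak <= 0:
        return 0.0
    thr = drop_frac * peak
    s = profile.arclength
    L = profile.total_length
    above = ex > thr
    total = 0.0
    n = len(ex)
    for i in range(n):
        j = (i + 1) % n
        ds = (s[j] - s[i]) % L
        e0, e1 = ex[i], ex[j]
        if above[i] and above[j]:
            total += ds
        elif above[i] != above[j]:
            f = (e0 - thr) / (e0 - e1)
            total += f * ds if above[i] else (1 - f) * ds
    return total / L


def horn_metrics(profile: WallProfile, drop_frac: float = 0.10) -> HornMetrics:
    """Detect the four horns and assemble their radius/peak/extent summary."""
    peaks = detect_horn_peaks(profile)
    radii, arcs = [], []
    for pk in peaks:
        r, endpoints = horn_circle_fit(profile, int(pk), drop_frac)
        radii.append(r)
        arcs.append(endpoints)
    return HornMetrics(
        radii=radii,
        peak_lambda_t=[float(profile.lambda_t[p]) for p in peaks],
        peak_arclength=[refined_peak_arclength(profile, int(p)) for p in peaks],
        arc_endpoints=arcs,
        wall_fraction_elevated=wall_fraction_elevated(profile, drop_frac),
    )
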