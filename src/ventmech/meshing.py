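"""Graded triangular meshing of nested-ring geometries and wall extraction.

The mesher triangulates the annular bands between a sequence of nested
closed boundary rings (innermost ring = the unmeshed ventricular cavity).
It works in three deterministic stages:

1. each ring is resampled at a locally prescribed edge length (fine at the
   ventricular wall, coarse toward the skull);
2. interior points are placed by greedy Poisson-disk-style thinning of a
   fine hexagonal lattice against the local size field, keeping clear of
   the boundary rings;
3. an (unconstrained) Delaunay triangulation of boundary + interior points
   is classified by region, lightly Laplacian-smoothed, and finally checked
   for conformity: every consecutive boundary-ring segment must appear as a
   mesh edge, and no triangle may straddle an interface.

Coordinates are 2D Cartesian mm with y increasing anterior; closed loops
are oriented counter-clockwise in this frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .synthetic import LabeledGeometry

__all__ = [
    "Mesh2D",
    "BoundarySets",
    "WallPath",
    "mesh_geometry",
    "triangulate_rings",
    "order_wall",
    "structured_rectangle_mesh",
    "detect_polygon_tips",
    "write_msh",
    "write_vtk",
]


@dataclass
class Mesh2D:
    """Conforming triangulation with per-triangle region tags.

    ``ring_nodes[i]`` lists, in closed-loop order, the node indices lying on
    input ring ``i`` (innermost first); ``ring_labels`` names the region in
    the band outside each ring.
    """

    nodes: np.ndarray           # (N, 2) mm
    triangles: np.ndarray       # (M, 3) int, positively oriented
    region: np.ndarray          # (M,) str region label per triangle
    ring_nodes: list[np.ndarray]
    ring_labels: list[str]      # len == len(ring_nodes) - 1 if inner hole else len(ring_nodes)
    has_hole: bool
    target_edge_length: float

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def triangle_areas(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        return 0.5 * ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                      - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))

    def min_angle_deg(self) -> float:
        p = self.nodes[self.triangles]
        angles = []
        for i in range(3):
            a = p[:, (i + 1) % 3] - p[:, i]
            b = p[:, (i + 2) % 3] - p[:, i]
            cosang = np.sum(a * b, 1) / (np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1))
            angles.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
        return float(np.min(angles))

    def edge_triangle_map(self) -> dict[tuple[int, int], list[int]]:
        emap: dict[tuple[int, int], list[int]] = {}
        for t, tri in enumerate(self.triangles):
            for i in range(3):
                key = tuple(sorted((int(tri[i]), int(tri[(i + 1) % 3]))))
                emap.setdefault(key, []).append(t)
        return emap


@dataclass
class BoundarySets:
    """Named boundary/interface edge sets (node-index pairs, loop-ordered)."""

    ventricular_wall_edges: np.ndarray      # (E, 2), CCW around the cavity
    gm_wm_interface_edges: np.ndarray
    gm_csf_interface_edges: np.ndarray      # CCW around the gray-matter outer boundary
    skull_nodes: np.ndarray                 # outer periphery


@dataclass
class WallPath:
    """Ordered closed loop of ventricular-wall nodes.

    Starts at the node nearest the midpoint between the two posterior horn
    tips and runs counter-clockwise; ``arclength`` is cumulative along the
    reference coordinates, with ``total_length`` closing the loop.
    """

    node_indices: np.ndarray   # (n,)
    coords: np.ndarray         # (n, 2)
    arclength: np.ndarray      # (n,)
    total_length: float


# --------------------------------------------------------------------------
# helpers

def _polygon_area(xy: np.ndarray) -> float:
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _ensure_ccw(xy: np.ndarray) -> np.ndarray:
    return xy if _polygon_area(xy) > 0 else xy[::-1]


def _resample_closed(xy: np.ndarray, hfun, corner_angle_deg: float = 25.0) -> np.ndarray:
    """Resample a closed polyline at locally varying spacing ``hfun(point)``.

    Sharp corners (turn angle above ``corner_angle_deg``) are preserved as
    sample points so the resampled loop neither cuts corners nor loses
    arclength there.
    """
    xy = np.asarray(xy, float)
    prev = np.roll(xy, 1, axis=0)
    nxt = np.roll(xy, -1, axis=0)
    v1 = xy - prev
    v2 = nxt - xy
    turn = np.abs(
        np.arctan2(v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0], np.sum(v1 * v2, axis=1))
    )
    corners = np.nonzero(turn > np.radians(corner_angle_deg))[0]
    if len(corners) >= 2:
        pieces = []
        for k in range(len(corners)):
            i0, i1 = corners[k], corners[(k + 1) % len(corners)]
            if i1 > i0:
                seg = xy[i0 : i1 + 1]
            else:
                seg = np.vstack([xy[i0:], xy[: i1 + 1]])
            pieces.append(_resample_open(seg, hfun))
        return np.vstack(pieces)
    seg = np.diff(np.vstack([xy, xy[:1]]), axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    total = s[-1]

    def point_at(si):
        si = si % total
        k = np.searchsorted(s, si, side="right") - 1
        k = min(k, len(xy) - 1)
        f = (si - s[k]) / max(seglen[k], 1e-300)
        return xy[k] + f * seg[k]

    # march with local step, then rescale so the loop closes exactly
    steps = []
    si = 0.0
    while si < total:
        h = float(hfun(point_at(si)))
        steps.append(h)
        si += h
    if len(steps) < 8:  # never undersample a closed loop
        steps = [total / 8.0] * 8
    # redistribute: walk again with steps scaled to close the loop
    scale = total / sum(steps)
    out = []
    si = 0.0
    for h in steps:
        out.append(point_at(si))
        si += h * scale
    pts = np.array(out)
    # drop accidental duplicates
    keep = np.ones(len(pts), bool)
    d = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
    keep[d < 1e-9] = False
    return pts[keep]


def _resample_open(xy: np.ndarray, hfun) -> np.ndarray:
    """Resample an open polyline keeping both endpoints; excludes the last
    point (the next piece supplies it)."""
    xy = np.asarray(xy, float)
    seg = np.diff(xy, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    total = s[-1]
    h_here = float(hfun(xy[len(xy) // 2]))
    n = max(int(round(total / h_here)), 1)
    targets = total * np.arange(n) / n
    out = np.empty((n, 2))
    for k, si in enumerate(targets):
        j = min(np.searchsorted(s, si, side="right") - 1, len(seglen) - 1)
        f = (si - s[j]) / max(seglen[j], 1e-300)
        out[k] = xy[j] + f * seg[j]
    return out


def _hex_lattice(bounds, spacing) -> np.ndarray:
    minx, miny, maxx, maxy = bounds
    dy = spacing * np.sqrt(3) / 2
    rows = int(np.ceil((maxy - miny) / dy)) + 1
    cols = int(np.ceil((maxx - minx) / spacing)) + 2
    pts = []
    for r in range(rows):
        x0 = minx + (0.5 * spacing if r % 2 else 0.0)
        xs = x0 + np.arange(cols) * spacing
        ys = np.full(cols, miny + r * dy)
        pts.append(np.c_[xs, ys])
    return np.vstack(pts)


def _greedy_thin(candidates: np.ndarray, h_of: np.ndarray, factor: float = 0.72) -> np.ndarray:
    """Keep a subset of candidates so kept points are >= factor*h apart.

    Candidates are processed fine-to-coarse; a spatial hash keeps this O(n).
    Fully deterministic.
    """
    order = np.argsort(h_of, kind="stable")
    cell = max(float(np.max(h_of)) * factor, 1e-9)
    grid: dict[tuple[int, int], list[int]] = {}
    kept: list[int] = []
    pts = candidates
    for idx in order:
        p = pts[idx]
        r = factor * h_of[idx]
        ci, cj = int(np.floor(p[0] / cell)), int(np.floor(p[1] / cell))
        ok = True
        reach = int(np.ceil(r / cell))
        for di in range(-reach, reach + 1):
            for dj in range(-reach, reach + 1):
                for k in grid.get((ci + di, cj + dj), ()):
                    if (p[0] - pts[k, 0]) ** 2 + (p[1] - pts[k, 1]) ** 2 < r * r:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            grid.setdefault((ci, cj), []).append(idx)
            kept.append(idx)
    return pts[np.array(kept, dtype=int)]


def _point_in_rings(pts: np.ndarray, rings: list[np.ndarray]):
    """Boolean matrix inside[i, k]: point i strictly inside ring k."""
    import shapely
    from shapely.geometry import Polygon

    out = np.zeros((len(pts), len(rings)), bool)
    for k, ring in enumerate(rings):
        poly = Polygon(ring)
        out[:, k] = shapely.contains_xy(poly, pts[:, 0], pts[:, 1])
    return out


# --------------------------------------------------------------------------
# core mesher

def triangulate_rings(
    rings: list[np.ndarray],
    region_labels: list[str],
    h_wall: float,
    h_far: float | None = None,
    grade_length: float = 18.0,
    has_hole: bool = True,
    smooth_iters: int = 3,
    min_angle_deg: float = 20.0,
) -> Mesh2D:
    """Triangulate the bands between nested closed rings.

    ``rings`` are closed polylines innermost-first (no repeated end point).
    With ``has_hole`` the innermost ring bounds an unmeshed cavity and
    ``region_labels[i]`` names the band between rings i and i+1.  The local
    target edge length grades linearly from ``h_wall`` at the innermost ring
    to ``h_far`` over ``grade_length`` mm.
    """
    if h_far is None:
        h_far = h_wall
    rings = [_ensure_ccw(np.asarray(r, float)) for r in rings]
    n_regions = len(rings) - 1 if has_hole else len(rings)
    if len(region_labels) != n_regions:
        raise ValueError(f"expected {n_regions} region labels, got {len(region_labels)}")

    wall_tree = cKDTree(rings[0])

    def hloc(p):
        p = np.atleast_2d(p)
        d, _ = wall_tree.query(p)
        return np.clip(h_wall + (h_far - h_wall) * d / grade_length, h_wall, h_far)

    sampled = [_resample_closed(r, lambda p: float(hloc(p)[0])) for r in rings]
    boundary_pts = np.vstack(sampled)

    # interior candidate lattice, thinned against the size field
    outer = sampled[-1]
    bounds = (outer[:, 0].min(), outer[:, 1].min(), outer[:, 0].max(), outer[:, 1].max())
    cand = _hex_lattice(bounds, 0.95 * h_wall)
    inside = _point_in_rings(cand, [sampled[-1]] + ([sampled[0]] if has_hole else []))
    keep = inside[:, 0]
    if has_hole:
        keep &= ~inside[:, 1]
    cand = cand[keep]
    h_cand = hloc(cand)
    btree = cKDTree(boundary_pts)
    dist_b, _ = btree.query(cand)
    cand = cand[dist_b > 0.75 * h_cand]
    h_cand = hloc(cand)
    interior = _greedy_thin(cand, np.asarray(h_cand, float))

    def classify(tris, pts_now):
        cent = pts_now[tris].mean(axis=1)
        inside = _point_in_rings(cent, sampled)
        # containment count from innermost: region index = number of rings NOT containing,
        # counted inward.  With nested CCW rings innermost-first:
        depth = inside.sum(axis=1)  # in how many rings
        # depth == len(rings): inside innermost ring -> cavity (if hole)
        region_idx = len(sampled) - depth  # 0 => inside all rings
        return region_idx

    def build(pts_now):
        tri = Delaunay(pts_now)
        tris = tri.simplices
        region_idx = classify(tris, pts_now)
        if has_hole:
            keep = (region_idx >= 1) & (region_idx <= n_regions)
            labels_for = lambda ridx: region_labels[ridx - 1]
        else:
            keep = (region_idx >= 0) & (region_idx <= n_regions - 1)
            labels_for = lambda ridx: region_labels[ridx]
        tris = tris[keep]
        region_idx = region_idx[keep]
        # enforce positive orientation
        p = pts_now[tris]
        area2 = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
            p[:, 2, 0] - p[:, 0, 0]
        ) * (p[:, 1, 1] - p[:, 0, 1])
        flip = area2 < 0
        tris[flip] = tris[flip][:, ::-1]
        labels = np.array([labels_for(r) for r in region_idx])
        return tris, labels

    def missing_segments(tris, pts_now, offsets):
        """Per ring, consecutive sample pairs that are not mesh edges."""
        edges = set()
        for i in range(3):
            a = tris[:, i]
            b = tris[:, (i + 1) % 3]
            lo = np.minimum(a, b)
            hi = np.maximum(a, b)
            edges.update(zip(lo.tolist(), hi.tolist()))
        out = []
        for k, s in enumerate(sampled):
            off = offsets[k]
            nk = len(s)
            for i in range(nk):
                a = off + i
                b = off + (i + 1) % nk
                if (min(a, b), max(a, b)) not in edges:
                    out.append((k, i))
        return out

    def assemble_points():
        boundary_pts = np.vstack(sampled)
        offsets = np.concatenate([[0], np.cumsum([len(s) for s in sampled])])[:-1]
        return np.vstack([boundary_pts, interior]), len(boundary_pts), offsets

    # refine boundary sampling until every ring segment is a Delaunay edge
    pts, n_boundary, offsets = assemble_points()
    for _ in range(12):
        tris, labels = build(pts)
        miss = missing_segments(tris, pts, offsets)
        if not miss:
            break
        for k, i in sorted(miss, key=lambda t: (t[0], -t[1])):
            s = sampled[k]
            mid = 0.5 * (s[i] + s[(i + 1) % len(s)])
            sampled[k] = np.insert(s, i + 1, mid, axis=0)
        pts, n_boundary, offsets = assemble_points()
    else:
        raise ValueError(
            "non-conforming triangulation persists after boundary refinement"
        )

    # Laplacian smoothing of interior nodes on the kept triangulation
    for _ in range(smooth_iters):
        nbr_sum = np.zeros_like(pts)
        nbr_cnt = np.zeros(len(pts))
        for i in range(3):
            a = tris[:, i]
            b = tris[:, (i + 1) % 3]
            np.add.at(nbr_sum, a, pts[b])
            np.add.at(nbr_cnt, a, 1)
            np.add.at(nbr_sum, b, pts[a])
            np.add.at(nbr_cnt, b, 1)
        movable = np.zeros(len(pts), bool)
        movable[n_boundary:] = nbr_cnt[n_boundary:] > 0
        target = pts.copy()
        target[movable] = nbr_sum[movable] / nbr_cnt[movable, None]
        new_pts = pts + 0.8 * (target - pts)
        # reject moves that invert any triangle
        p = new_pts[tris]
        area2 = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
            p[:, 2, 0] - p[:, 0, 0]
        ) * (p[:, 1, 1] - p[:, 0, 1])
        bad = area2 <= 1e-12
        if np.any(bad):
            bad_nodes = np.unique(tris[bad])
            new_pts[bad_nodes] = pts[bad_nodes]
        new_tris, new_labels = build(new_pts)
        if missing_segments(new_tris, new_pts, offsets):
            break  # keep the last conforming state
        pts, tris, labels = new_pts, new_tris, new_labels

    # prune unused nodes (e.g. lattice points swallowed by dropped triangles)
    used = np.zeros(len(pts), bool)
    used[: n_boundary] = True
    used[np.unique(tris)] = True
    remap = -np.ones(len(pts), int)
    remap[used] = np.arange(used.sum())
    pts = pts[used]
    tris = remap[tris]

    ring_nodes = []
    off = 0
    for s in sampled:
        ring_nodes.append(remap[np.arange(off, off + len(s))])
        off += len(s)

    mesh = Mesh2D(
        nodes=pts,
        triangles=tris,
        region=labels,
        ring_nodes=ring_nodes,
        ring_labels=list(region_labels),
        has_hole=has_hole,
        target_edge_length=h_wall,
    )

    _check_conformity(mesh)
    worst = mesh.min_angle_deg()
    if worst < min_angle_deg:
        raise ValueError(
            f"mesh quality below floor: min interior angle {worst:.2f} deg < {min_angle_deg} deg"
        )
    return mesh


def _check_conformity(mesh: Mesh2D) -> None:
    """Every consecutive ring segment must be a mesh edge, and interface
    edges must separate exactly the expected region pair."""
    emap = mesh.edge_triangle_map()
    for k, loop in enumerate(mesh.ring_nodes):
        missing = 0
        for i in range(len(loop)):
            a, b = int(loop[i]), int(loop[(i + 1) % len(loop)])
            if tuple(sorted((a, b))) not in emap:
                missing += 1
        if missing:
            raise ValueError(
                f"non-conforming triangulation: {missing} segments of ring {k} "
                "are not mesh edges (increase boundary density)"
            )


def mesh_geometry(
    geometry: LabeledGeometry,
    target_edge_length: float = 0.55,
    h_far: float | None = None,
    **kwargs,
) -> tuple[Mesh2D, BoundarySets]:
    """Triangulate a labelled slice geometry.

    ``target_edge_length`` applies at the ventricular wall; ``h_far``
    (default ~4.7x coarser) applies far from it.  Returns the mesh and its
    named boundary sets.  The cavity is left unmeshed.
    """
    geometry.validate()
    if h_far is None:
        h_far = 4.7 * target_edge_length
    rings = geometry.ordered_rings()
    mesh = triangulate_rings(
        rings,
        ["white_matter", "gray_matter", "csf"],
        h_wall=target_edge_length,
        h_far=h_far,
        has_hole=True,
        **kwargs,
    )
    bset = extract_boundary_sets(mesh)
    return mesh, bset


def extract_boundary_sets(mesh: Mesh2D) -> BoundarySets:
    def loop_edges(loop):
        return np.c_[loop, np.roll(loop, -1)]

    if not mesh.has_hole:
        raise ValueError("boundary sets are defined for cavity-holed meshes")
    wall = loop_edges(mesh.ring_nodes[0])
    labels = list(mesh.ring_labels)
    gm_wm = np.empty((0, 2), int)
    gm_csf = np.empty((0, 2), int)
    for k in range(1, len(mesh.ring_nodes)):
        inner = labels[k - 1]
        outer = labels[k] if k < len(labels) else None
        if inner == "white_matter" and outer == "gray_matter":
            gm_wm = loop_edges(mesh.ring_nodes[k])
        if inner == "gray_matter":  # outer boundary of gray matter
            gm_csf = loop_edges(mesh.ring_nodes[k])
    skull = mesh.ring_nodes[-1]
    return BoundarySets(
        ventricular_wall_edges=wall,
        gm_wm_interface_edges=gm_wm,
        gm_csf_interface_edges=gm_csf,
        skull_nodes=skull,
    )


# --------------------------------------------------------------------------
# wall ordering

def detect_polygon_tips(xy: np.ndarray, n_tips: int = 4, window: float = 4.0):
    """Locate high-curvature tip apices on a closed polygon.

    Returns (n_tips, 2) apex coordinates, or None when the curvature has no
    distinct peaks (e.g. a circle).  The curvature measure is the integral
    of the signed turn angle over a sliding arclength window of ``window``
    mm, divided by the window: sustained tip arcs dominate over isolated
    corner spikes from concave wall features.
    """
    xy = _ensure_ccw(np.asarray(xy, float))
    n = len(xy)
    prev = np.roll(xy, 1, axis=0)
    nxt = np.roll(xy, -1, axis=0)
    v1 = xy - prev
    v2 = nxt - xy
    ang = np.arctan2(
        v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0],
        np.sum(v1 * v2, axis=1),
    )
    seglen = np.linalg.norm(v2, axis=1)
    s_v = np.concatenate([[0.0], np.cumsum(seglen)])[:-1]
    total_len = s_v[-1] + seglen[-1]
    w = min(window, 0.2 * total_len)
    # circular sliding-window sum of turn angles
    s3 = np.concatenate([s_v - total_len, s_v, s_v + total_len])
    a3 = np.concatenate([ang, ang, ang])
    ca = np.concatenate([[0.0], np.cumsum(a3)])
    lo = np.searchsorted(s3, s_v - w / 2.0, side="left")
    hi = np.searchsorted(s3, s_v + w / 2.0, side="right")
    lo_i = lo
    hi_i = hi
    curv = (ca[hi_i] - ca[lo_i]) / w
    if curv.max() <= 0 or curv.max() < 1.5 * max(np.median(np.abs(curv)), 1e-12):
        return None
    # greedy peak picking with angular separation
    order = np.argsort(-curv, kind="stable")
    # minimum separation: 5% of the perimeter
    seglen = np.linalg.norm(np.diff(np.vstack([xy, xy[:1]]), axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seglen)])[:-1]
    total = s[-1] + seglen[-1]
    min_sep = 0.05 * total
    picked = []
    for idx in order:
        if curv[idx] <= 0:
            break
        ok = all(
            min(abs(s[idx] - s[j]), total - abs(s[idx] - s[j])) >= min_sep for j in picked
        )
        if ok:
            picked.append(idx)
        if len(picked) == n_tips:
            break
    if len(picked) < n_tips:
        return None
    return xy[np.array(sorted(picked))]


def order_wall(mesh: Mesh2D, bset: BoundarySets) -> WallPath:
    """Order the ventricular-wall loop counter-clockwise starting at the
    midpoint between the two posterior horn tips.

    Falls back to the lowest-y wall node as the start when no horn tips can
    be detected (e.g. a circular cavity).  Orientation and start are purely
    geometric: independent of node storage order.
    """
    loops = _edges_to_loops(bset.ventricular_wall_edges)
    if len(loops) != 1:
        raise ValueError(f"ventricular wall must be a single closed loop, found {len(loops)}")
    loop = loops[0]
    xy = mesh.nodes[loop]
    if _polygon_area(xy) < 0:
        loop = loop[::-1]
        xy = xy[::-1]

    tips = detect_polygon_tips(xy)
    if tips is not None:
        # start on the wall section between the two posterior horns: the
        # posterior-side wall node on the vertical through the tips' midpoint
        posterior = tips[np.argsort(tips[:, 1])[:2]]
        x_mid = posterior[:, 0].mean()
        centroid_y = xy[:, 1].mean()
        cand = np.nonzero(xy[:, 1] < centroid_y)[0]
        if len(cand) == 0:
            cand = np.arange(len(xy))
        score = np.abs(xy[cand, 0] - x_mid) + 1e-9 * xy[cand, 1]
        start = int(cand[np.argmin(score)])
    else:
        start = int(np.argmin(xy[:, 1]))
    loop = np.roll(loop, -start)
    xy = mesh.nodes[loop]
    seg = np.linalg.norm(np.diff(np.vstack([xy, xy[:1]]), axis=0), axis=1)
    arclength = np.concatenate([[0.0], np.cumsum(seg)])[:-1]
    return WallPath(
        node_indices=loop,
        coords=xy,
        arclength=arclength,
        total_length=float(seg.sum()),
    )


def _edges_to_loops(edges: np.ndarray) -> list[np.ndarray]:
    nxt = {}
    for a, b in edges:
        nxt[int(a)] = int(b)
    loops = []
    seen = set()
    for a in nxt:
        if a in seen:
            continue
        loop = [a]
        seen.add(a)
        cur = nxt[a]
        while cur != a:
            loop.append(cur)
            seen.add(cur)
            cur = nxt.get(cur)
            if cur is None:
                raise ValueError("open wall edge chain: boundary is not closed")
        loops.append(np.array(loop, int))
    return loops


# --------------------------------------------------------------------------
# structured helpers and mesh I/O

def structured_rectangle_mesh(width, height, nx, ny, split_x=None):
    """Structured right-triangle mesh of [0,w]x[0,h]; two region tags split
    at ``split_x`` (default midline).  Used for patch tests."""
    if split_x is None:
        split_x = width / 2.0
    xs = np.linspace(0, width, nx + 1)
    ys = np.linspace(0, height, ny + 1)
    X, Y = np.meshgrid(xs, ys)
    nodes = np.c_[X.ravel(), Y.ravel()]
    tris = []
    for j in range(ny):
        for i in range(nx):
            n0 = j * (nx + 1) + i
            n1 = n0 + 1
            n2 = n0 + (nx + 1)
            n3 = n2 + 1
            tris.append([n0, n1, n3])
            tris.append([n0, n3, n2])
    tris = np.array(tris, int)
    cent = nodes[tris].mean(axis=1)
    region = np.where(cent[:, 0] < split_x, "left", "right")
    # boundary loops (outer ring CCW)
    bottom = [i for i in range(nx + 1)]
    right = [jj * (nx + 1) + nx for jj in range(ny + 1)]
    top = [ny * (nx + 1) + i for i in range(nx, -1, -1)]
    left = [jj * (nx + 1) for jj in range(ny, -1, -1)]
    ring = np.array(bottom + right[1:] + top[1:] + left[1:-1], int)
    return Mesh2D(
        nodes=nodes,
        triangles=tris,
        region=region,
        ring_nodes=[ring],
        ring_labels=["left", "right"],
        has_hole=False,
        target_edge_length=width / nx,
    )


def write_msh(mesh: Mesh2D, path) -> None:
    """Write Gmsh .msh v2.2 (ASCII) with region names as physical groups."""
    labels = sorted(set(mesh.region))
    phys = {lab: i + 1 for i, lab in enumerate(labels)}
    with open(path, "w") as f:
        f.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        f.write("$PhysicalNames\n%d\n" % len(labels))
        for lab, i in phys.items():
            f.write(f'2 {i} "{lab}"\n')
        f.write("$EndPhysicalNames\n$Nodes\n%d\n" % mesh.n_nodes)
        for i, (x, y) in enumerate(mesh.nodes, 1):
            f.write(f"{i} {x:.10g} {y:.10g} 0\n")
        f.write("$EndNodes\n$Elements\n%d\n" % len(mesh.triangles))
        for e, (tri, lab) in enumerate(zip(mesh.triangles, mesh.region), 1):
            p = phys[lab]
            f.write(f"{e} 2 2 {p} {p} {tri[0]+1} {tri[1]+1} {tri[2]+1}\n")
        f.write("$EndElements\n")


def write_vtk(mesh: Mesh2D, path, point_data=None, cell_data=None) -> None:
    """Write legacy ASCII VTK with optional per-node / per-cell fields."""
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nventmech fields\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_nodes} double\n")
        for x, y in mesh.nodes:
            f.write(f"{x:.10g} {y:.10g} 0\n")
        m = len(mesh.triangles)
        f.write(f"CELLS {m} {4 * m}\n")
        for tri in mesh.triangles:
            f.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")
        f.write(f"CELL_TYPES {m}\n")
        f.write("5\n" * m)
        if point_data:
            f.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 1:
                    f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    f.writelines(f"{v:.10g}\n" for v in arr)
                else:
                    f.write(f"VECTORS {name} double\n")
                    f.writelines(f"{v[0]:.10g} {v[1]:.10g} 0\n" for v in arr)
        if cell_data:
            f.write(f"CELL_DATA {m}\n")
            for name, arr in cell_data.items():
                arr = np.asarray(arr, float)
                f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                f.writelines(f"{v:.10g}\n" for v in arr)
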