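"""Parametric synthetic subjects: ventricle geometry, FLAIR-like images, and
the embedded eight-subject reference table.

A synthetic subject is a single axial slice through the lateral ventricles,
idealised as one connected "butterfly" cavity: two wing-shaped lobes joined
across the midline by a thin septal channel.  The four outer tips of the
wings are exact circular arcs whose radii model the anterior and posterior
horn radii -- the geometric quantity the downstream mechanomarker analysis
estimates back from the simulated stretch field.  The cavity is surrounded
by a white-matter annulus, a gray-matter rim (elliptical outer cortex), and
an outer subarachnoid CSF layer bounded by the skull.

The FLAIR surrogate is a 2D intensity image on the same slice: uniform
brain-tissue background with Gaussian noise, dark CSF, bright planted
white-matter lesions, plus one bright septum-like component lying inside
ventricular CSF to exercise the CSF-adjacency pruning rule of the lesion
segmentation.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon, box
from shapely.ops import unary_union

__all__ = [
    "SubjectSpec",
    "LabeledGeometry",
    "SyntheticFlair",
    "make_geometry",
    "make_flair",
    "table1_fixture",
    "default_lesion_centers",
    "LABELS",
]

# integer raster labels
LABELS = {"background": 0, "csf": 1, "gray_matter": 2, "white_matter": 3, "cavity": 4}

REGION_ORDER = ("cavity", "white_matter", "gray_matter", "csf")


@dataclass(frozen=True)
class SubjectSpec:
    """Geometric parameters of one synthetic subject (all lengths in mm).

    ``horn_radius_anterior`` / ``horn_radius_posterior`` set the circular-arc
    radii of the upper (anterior, +y) and lower (posterior, -y) horn tips.
    ``ventricle_halfwidth`` / ``ventricle_halfheight`` set the lateral and
    anterior-posterior extent of the cavity; ``septum_gap`` is the height of
    the thin channel joining the two wings across the midline.  ``seed``
    affects image noise only, never geometry.
    """

    horn_radius_anterior: float = 2.0
    horn_radius_posterior: float = 2.5
    ventricle_halfwidth: float = 26.0
    ventricle_halfheight: float = 21.0
    wing_width: float = 10.0
    cortex_semiaxes: tuple[float, float] = (62.0, 50.0)
    gm_thickness: float = 3.0
    csf_thickness: float = 4.0
    septum_gap: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        lengths = {
            "horn_radius_anterior": self.horn_radius_anterior,
            "horn_radius_posterior": self.horn_radius_posterior,
            "ventricle_halfwidth": self.ventricle_halfwidth,
            "ventricle_halfheight": self.ventricle_halfheight,
            "gm_thickness": self.gm_thickness,
            "csf_thickness": self.csf_thickness,
            "septum_gap": self.septum_gap,
        }
        for name, value in lengths.items():
            if not value > 0:
                raise ValueError(f"SubjectSpec.{name} must be > 0, got {value}")
        a, b = self.cortex_semiaxes
        if not (a > 0 and b > 0):
            raise ValueError(f"cortex_semiaxes must be positive, got {self.cortex_semiaxes}")
        for name in ("horn_radius_anterior", "horn_radius_posterior"):
            if getattr(self, name) >= self.ventricle_halfwidth:
                raise ValueError(f"{name} must be smaller than ventricle_halfwidth")
        # the cavity must fit inside the white-matter annulus with some margin
        wm_a, wm_b = a - self.gm_thickness, b - self.gm_thickness
        if self.ventricle_halfwidth + 2.0 >= wm_a or self.ventricle_halfheight + 2.0 >= wm_b:
            raise ValueError(
                "infeasible spec: cavity extent leaves no white-matter annulus inside the "
                f"cortex ellipse (cavity {self.ventricle_halfwidth}x{self.ventricle_halfheight} mm "
                f"vs white-matter ellipse {wm_a:.1f}x{wm_b:.1f} mm)"
            )
        if self.septum_gap >= self.ventricle_halfheight:
            raise ValueError("infeasible spec: septum_gap must be below ventricle_halfheight")


@dataclass
class LabeledGeometry:
    """Nested region boundaries of one axial slice.

    ``region_polygons`` maps region label to that region's *outer* closed
    boundary polygon; regions are the annular bands between successive
    boundaries (cavity interior is fluid, not tissue).  ``horn_tips`` holds
    the four tip apex points (anterior pair first) when the geometry was
    generated parametrically.
    """

    region_polygons: dict[str, Polygon]
    provenance: object = "external"
    horn_tips: np.ndarray | None = None  # (4, 2): ant-left, ant-right, post-left, post-right

    def ordered_rings(self) -> list[np.ndarray]:
        """Boundary rings innermost-first as (k, 2) coordinate arrays (open)."""
        rings = []
        for name in REGION_ORDER:
            poly = self.region_polygons[name]
            xy = np.asarray(poly.exterior.coords)[:-1]
            rings.append(xy)
        return rings

    def validate(self) -> None:
        prev = None
        for name in REGION_ORDER:
            poly = self.region_polygons[name]
            if not poly.is_valid or not poly.is_simple:
                raise ValueError(f"region boundary {name!r} is not a simple valid polygon")
            if prev is not None and not poly.contains(prev):
                raise ValueError(f"region boundaries not nested: {name!r} does not contain its inner boundary")
            prev = poly

    def to_geojson(self) -> str:
        features = []
        for name in REGION_ORDER:
            poly = self.region_polygons[name]
            features.append(
                {
                    "type": "Feature",
                    "properties": {"region": name},
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [[list(c) for c in poly.exterior.coords]],
                    },
                }
            )
        return json.dumps({"type": "FeatureCollection", "features": features})

    @classmethod
    def from_geojson(cls, text: str) -> "LabeledGeometry":
        data = json.loads(text)
        polys = {}
        for feat in data["features"]:
            name = feat["properties"]["region"]
            polys[name] = Polygon(feat["geometry"]["coordinates"][0])
        return cls(region_polygons=polys, provenance="external")


@dataclass
class SyntheticFlair:
    """FLAIR-like 2D image bundle: intensity, integer labels, ground truth."""

    intensity: np.ndarray
    label_image: np.ndarray
    truth_lesion_mask: np.ndarray
    pixel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self):
        if not (self.intensity.shape == self.label_image.shape == self.truth_lesion_mask.shape):
            raise ValueError("intensity, label and truth images must share shape")

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """World (mm) coordinates of pixel centers as meshgrids (X, Y)."""
        ny, nx = self.intensity.shape
        xs = self.origin[0] + (np.arange(nx) + 0.5) * self.pixel_size
        ys = self.origin[1] + (np.arange(ny) + 0.5) * self.pixel_size
        return np.meshgrid(xs, ys)


def _circle(center, radius, quad_segs=32) -> Polygon:
    return Point(center).buffer(radius, quad_segs=quad_segs)


def _tip_centers(spec: SubjectSpec, side: int):
    w, h = spec.ventricle_halfwidth, spec.ventricle_halfheight
    tip_a = (side * 0.42 * w, h - spec.horn_radius_anterior)
    tip_p = (side * 0.58 * w, -(h - spec.horn_radius_posterior))
    return tip_a, tip_p


def _arc_points(center, radius, p0, p1, side_point=None, max_seg=0.1):
    """Sample the circular arc from p0 to p1 about ``center``.

    Of the two candidate arcs, picks the one whose midpoint is closer to
    ``side_point`` (default: the minor arc).  Points include p0, exclude p1.
    """
    center = np.asarray(center, float)
    a0 = np.arctan2(*(np.asarray(p0) - center)[::-1])
    a1 = np.arctan2(*(np.asarray(p1) - center)[::-1])
    sweep_ccw = (a1 - a0) % (2 * np.pi)
    candidates = [sweep_ccw, sweep_ccw - 2 * np.pi]  # ccw and cw traversals
    if side_point is None:
        pick = min(candidates, key=abs)
    else:
        sp = np.asarray(side_point, float)

        def middist(sweep):
            am = a0 + sweep / 2.0
            pm = center + radius * np.array([np.cos(am), np.sin(am)])
            return np.linalg.norm(pm - sp)

        pick = min(candidates, key=middist)
    nseg = max(int(np.ceil(abs(pick) * radius / max_seg)), 32)
    ang = a0 + pick * np.arange(nseg) / nseg
    return center[None] + radius * np.c_[np.cos(ang), np.sin(ang)]


def _tangent_line_normal(C1, r1, C2, r2, direction):
    """Unit normal m of the external tangent line of two circles with
    m . C_i = c - r_i, picked so m points along ``direction``."""
    C1, C2 = np.asarray(C1, float), np.asarray(C2, float)
    w = C2 - C1
    L = np.linalg.norm(w)
    what = w / L
    perp_ = np.array([-what[1], what[0]])
    alpha = (r1 - r2) / L
    beta = np.sqrt(max(1.0 - alpha**2, 0.0))
    for sb in (+1.0, -1.0):
        m = alpha * what + sb * beta * perp_
        if np.dot(m, direction) > 0:
            return m
    raise ValueError("no tangent line normal in the requested direction")


def _circle_circle(c1, r1, c2, r2):
    """Both intersection points of two circles."""
    c1, c2 = np.asarray(c1, float), np.asarray(c2, float)
    d = np.linalg.norm(c2 - c1)
    if d > r1 + r2 or d < abs(r1 - r2) or d == 0:
        raise ValueError("circles do not intersect")
    a = (r1**2 - r2**2 + d**2) / (2 * d)
    h2 = r1**2 - a**2
    h = np.sqrt(max(h2, 0.0))
    mid = c1 + a * (c2 - c1) / d
    perp = np.array([-(c2 - c1)[1], (c2 - c1)[0]]) / d
    return mid + h * perp, mid - h * perp


def _wing(spec: SubjectSpec, side: int) -> Polygon:
    """One ventricle wing with exact circular horn-tip arcs.

    The lateral wall is a smooth tangent chain: tip arc -> concave base
    notch -> long shallow concave arc -> base notch -> tip arc; the medial
    wall is the straight tangent between the tip circles.  The concave
    base notches mimic the structures indenting the real ventricular wall
    (caudate head at the anterior horn, calcar avis at the posterior
    horn): each horn is a protrusion set off from the wall, so the
    pressure-driven tension concentration decays within the horn itself
    instead of bleeding down the wall.
    """
    tip_a, tip_p = _tip_centers(spec, side)
    r_a, r_p = spec.horn_radius_anterior, spec.horn_radius_posterior
    A, P = np.asarray(tip_a, float), np.asarray(tip_p, float)
    w = P - A
    L = np.linalg.norm(w)
    what = w / L
    perp = np.array([-what[1], what[0]])
    if perp[0] * side < 0:
        perp = -perp  # lateral: away from the midline

    m_lat = _tangent_line_normal(A, r_a, P, r_p, perp)
    m_med = _tangent_line_normal(A, r_a, P, r_p, -perp)

    # lateral shallow arc: dips d_mid into the cavity at the wall midpoint
    TA_lat = A + r_a * m_lat
    TP_lat = P + r_p * m_lat
    M = 0.5 * (TA_lat + TP_lat)
    d_mid = 0.55 * min(r_a, r_p)
    chord = np.linalg.norm(TP_lat - TA_lat)
    R = max(chord**2 / (8.0 * d_mid) + 2.0 * max(r_a, r_p), 60.0)
    B = M + (R - d_mid) * m_lat

    # base notches: tangent to the tip circle and internally to the big arc
    def notch(center, r_tip, toward):
        rho = 1.8 * r_tip
        p1, p2 = _circle_circle(center, r_tip + rho, B, R - rho)
        # of the two tangent positions take the one toward the wall midpoint
        c = p1 if np.dot(p1 - center, toward) > np.dot(p2 - center, toward) else p2
        return c, rho

    NA, rho_a = notch(A, r_a, what)
    NP, rho_p = notch(P, r_p, -what)

    # tangency points along the lateral chain
    t1 = A + r_a * (NA - A) / np.linalg.norm(NA - A)
    t2 = B + R * (NA - B) / np.linalg.norm(NA - B)
    t3 = B + R * (NP - B) / np.linalg.norm(NP - B)
    t4 = P + r_p * (NP - P) / np.linalg.norm(NP - P)

    # medial wall: a single gently convex arc bulging toward the midline so
    # the wing body is wider than the horn protrusions; the tip circles are
    # internally tangent to it, so the whole boundary is tangent-continuous
    w_extra = max(spec.wing_width + d_mid - (r_a + r_p), 0.0)
    medial_arc = None
    if w_extra > 0.3:
        c_med = np.dot(m_med, A) + r_a          # medial tangent line offset
        chord_m = np.linalg.norm((P + r_p * m_med) - (A + r_a * m_med))
        R_med = chord_m**2 / (8.0 * w_extra) + 0.5 * w_extra + max(r_a, r_p)
        # center on the lateral side: |O - A| = R_med - r_a, |O - P| = R_med - r_p
        o1, o2 = _circle_circle(A, R_med - r_a, P, R_med - r_p)
        O = o1 if np.dot(o1, m_med) < np.dot(o2, m_med) else o2
        s1 = P + r_p * (P - O) / np.linalg.norm(P - O)   # internal tangencies
        s2 = A + r_a * (A - O) / np.linalg.norm(A - O)
        medial_arc = (O, R_med, s1, s2)

    apex_A = A - 0.5 * L * what
    apex_P = P + 0.5 * L * what
    if medial_arc is None:
        med_A = A + r_a * m_med
        med_P = P + r_p * m_med
    else:
        med_A, med_P = medial_arc[3], medial_arc[2]
    pts = []
    pts.append(_arc_points(A, r_a, med_A, t1, side_point=apex_A))
    pts.append(_arc_points(NA, rho_a, t1, t2))
    pts.append(_arc_points(B, R, t2, t3, max_seg=0.3))
    pts.append(_arc_points(NP, rho_p, t3, t4))
    pts.append(_arc_points(P, r_p, t4, med_P, side_point=apex_P))
    if medial_arc is None:
        pts.append(np.asarray(med_P)[None])
    else:
        O, R_med, s1, s2 = medial_arc
        mid_med = 0.5 * (A + P) + (0.5 * (r_a + r_p) + w_extra) * m_med
        pts.append(_arc_points(O, R_med, s1, s2, side_point=mid_med, max_seg=0.3))
    boundary = np.vstack(pts)
    poly = Polygon(boundary)
    if not poly.is_valid:
        poly = poly.buffer(0)
    if poly.geom_type != "Polygon" or poly.area <= 0:
        raise ValueError("infeasible spec: wing construction degenerated")

    # sharpen the horn bases: small concave cuts grazing the tip circles on
    # both sides, pinning the base of each horn protrusion
    if medial_arc is None:
        med_dir_A = med_dir_P = m_med
    else:
        med_dir_A = (med_A - A) / r_a   # tip->medial-arc tangency directions
        med_dir_P = (med_P - P) / r_p
    for T, r_tip, u_away, med_dir in (
        (A, r_a, what, med_dir_A),
        (P, r_p, -what, med_dir_P),
    ):
        for m_side in (m_lat, med_dir):
            rho = 1.6 * r_tip
            q = T + r_tip * m_side
            c = q + 1.6 * r_tip * u_away + (rho - 0.5 * r_tip) * m_side
            trial = poly.difference(_circle(c, rho))
            if (
                trial.geom_type == "Polygon"
                and not list(trial.interiors)
                and trial.area > 0.6 * poly.area
            ):
                poly = trial
    return poly


def make_geometry(spec: SubjectSpec) -> LabeledGeometry:
    """Build the labelled slice geometry for a subject spec.

    Deterministic and independent of ``spec.seed``.  The cavity is the union
    of two mirror wings and a septal channel; the surrounding boundaries are
    ellipses offset per the spec thicknesses.
    """
    spec.validate()
    w, h = spec.ventricle_halfwidth, spec.ventricle_halfheight
    # septal channel ends at the wing centerline so it never pokes through
    # the straight lateral wall
    (xa, ya), (xp, yp) = _tip_centers(spec, +1)
    x_mid = xa + (xp - xa) * ya / (ya - yp)
    channel = box(-x_mid, -spec.septum_gap / 2.0, x_mid, spec.septum_gap / 2.0)
    cavity = unary_union([_wing(spec, +1), _wing(spec, -1), channel])
    if cavity.geom_type != "Polygon":
        raise ValueError("infeasible spec: cavity is not a single connected polygon")
    cavity = shapely.geometry.polygon.orient(cavity, sign=1.0)

    a, b = spec.cortex_semiaxes
    def ellipse(sa, sb, n=256):
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        return Polygon(np.c_[sa * np.cos(t), sb * np.sin(t)])

    wm = ellipse(a - spec.gm_thickness, b - spec.gm_thickness)
    gm = ellipse(a, b)
    csf = ellipse(a + spec.csf_thickness, b + spec.csf_thickness)
    if not wm.contains(cavity):
        raise ValueError("infeasible spec: cavity intersects the white-matter outer boundary")

    tips = np.array(
        [
            [-0.42 * w, h],   # anterior-left
            [+0.42 * w, h],   # anterior-right
            [-0.58 * w, -h],  # posterior-left
            [+0.58 * w, -h],  # posterior-right
        ]
    )
    geom = LabeledGeometry(
        region_polygons={"cavity": cavity, "white_matter": wm, "gray_matter": gm, "csf": csf},
        provenance=spec,
        horn_tips=tips,
    )
    geom.validate()
    return geom


def default_lesion_centers(geometry: LabeledGeometry, offset: float = 1.5) -> np.ndarray:
    """Lesion centers planted just outside each horn tip, inside white matter.

    Mimics the clinical observation of periventricular caps at the horns.
    """
    if geometry.horn_tips is None:
        raise ValueError("geometry has no horn tip metadata")
    cavity = geometry.region_polygons["cavity"]
    wm = geometry.region_polygons["white_matter"]
    centers = []
    for tip in geometry.horn_tips:
        n = tip / np.linalg.norm(tip)
        c = tip + offset * n
        # pull back if the offset overshoots white matter
        for _ in range(20):
            p = Point(c)
            if wm.contains(p) and not cavity.contains(p):
                break
            c = c - 0.3 * n
        centers.append(c)
    return np.array(centers)


def make_flair(
    geometry: LabeledGeometry,
    lesion_centers,
    lesion_radius: float = 2.2,
    contrast: float = 1.0,
    noise_sd: float = 5.0,
    seed: int = 0,
    pixel_size: float = 0.7,
    background: float = 100.0,
    csf_intensity: float = 30.0,
) -> SyntheticFlair:
    """Rasterize a FLAIR-like image with planted lesions.

    Background tissue (white and gray matter) sits at ``background`` with
    additive Gaussian noise; CSF (subarachnoid and intraventricular) is dark;
    lesion pixels are at ``background * (1 + contrast)``.  One extra bright
    component is placed inside the septal channel, fully surrounded by
    ventricular CSF, as a septum/choroid-plexus surrogate that the
    segmentation's CSF-adjacency rule must remove.
    """
    if contrast is None or contrast < 0:
        raise ValueError(f"contrast must be >= 0, got {contrast}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    csf_poly = geometry.region_polygons["csf"]
    minx, miny, maxx, maxy = csf_poly.bounds
    pad = 2 * pixel_size
    origin = np.array([minx - pad, miny - pad])
    nx = int(np.ceil((maxx - minx + 2 * pad) / pixel_size))
    ny = int(np.ceil((maxy - miny + 2 * pad) / pixel_size))
    xs = origin[0] + (np.arange(nx) + 0.5) * pixel_size
    ys = origin[1] + (np.arange(ny) + 0.5) * pixel_size
    X, Y = np.meshgrid(xs, ys)

    flat_x, flat_y = X.ravel(), Y.ravel()
    label = np.zeros(X.shape, dtype=np.int16).ravel()
    for name, lab in (("csf", 1), ("gray_matter", 2), ("white_matter", 3), ("cavity", 4)):
        inside = shapely.contains_xy(geometry.region_polygons[name], flat_x, flat_y)
        label[inside] = lab
    label = label.reshape(X.shape)

    intensity = np.zeros(X.shape)
    intensity[label == LABELS["csf"]] = csf_intensity
    intensity[label == LABELS["cavity"]] = csf_intensity
    intensity[label == LABELS["gray_matter"]] = background
    intensity[label == LABELS["white_matter"]] = background

    lesion_value = background * (1.0 + contrast)
    truth = np.zeros(X.shape, dtype=bool)
    wm_mask = label == LABELS["white_matter"]
    for c in np.atleast_2d(np.asarray(lesion_centers, dtype=float)):
        disk = (X - c[0]) ** 2 + (Y - c[1]) ** 2 <= lesion_radius**2
        if not np.any(disk & wm_mask):
            raise ValueError(f"lesion center {c} does not cover any white-matter pixel")
        truth |= disk & wm_mask
    intensity[truth] = lesion_value

    # septum surrogate: a bright bar inside the channel, surrounded by cavity CSF
    cav = label == LABELS["cavity"]
    interior = cav.copy()
    interior[1:, :] &= cav[:-1, :]
    interior[:-1, :] &= cav[1:, :]
    interior[:, 1:] &= cav[:, :-1]
    interior[:, :-1] &= cav[:, 1:]
    bar = interior & (np.abs(X) <= max(1.0, 1.5 * pixel_size))
    if np.any(bar):
        intensity[bar] = lesion_value

    rng = np.random.default_rng(seed)
    noisy = label != LABELS["background"]
    intensity = intensity + noise_sd * rng.standard_normal(X.shape) * noisy

    return SyntheticFlair(
        intensity=intensity,
        label_image=label,
        truth_lesion_mask=truth,
        pixel_size=pixel_size,
        origin=origin,
    )


# --------------------------------------------------------------------------
# embedded eight-subject reference table

_TABLE1_CSV = """id,age,vCSF,vLV,vWMH,FS
F20,65.1,421.0,30.2,1.1,0
F40,68.5,473.0,34.2,5.2,1
F60,75.3,519.0,40.1,4.0,1
F80,77.6,579.0,74.1,20.7,3
M20,68.5,451.0,33.4,6.2,1
M40,81.1,493.0,35.3,7.8,2
M60,79.9,519.0,56.9,7.0,1
M80,71.4,581.0,61.4,16.4,3
"""


def table1_fixture() -> pd.DataFrame:
    """The eight-subject reference table (age in years, volumes in cm^3,
    Fazekas score 0-3), with a derived ``sex`` column from the subject id."""
    df = pd.read_csv(io.StringIO(_TABLE1_CSV))
    df["sex"] = df["id"].str[0]
    return df


def nifti_image(arr: np.ndarray, pixel_size: float):
    """Wrap a 2D array as a (nx, ny, 1) NIfTI image with mm pixel size."""
    import nibabel as nib

    affine = np.diag([pixel_size, pixel_size, 1.0, 1.0])
    return nib.Nifti1Image(np.asarray(arr)[..., None].astype(np.float32), affine)
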