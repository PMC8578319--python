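"""End-to-end orchestration: synthesize -> mesh -> solve -> directions ->
markers -> segment -> statistics, plus the pressure/stiffness sensitivity
sweeps and the unit helpers.

All stages are deterministic given the run configuration (the seed enters
only through image noise); a run manifest with content hashes makes
nondeterminism regressions detectable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial import cKDTree

from . import synthetic, meshing, fem, directions, markers, segmentation, stats

__all__ = [
    "RunConfig",
    "SubjectResult",
    "SweepReport",
    "run_subject",
    "sensitivity_sweep",
    "pa_to_mmhg",
    "wall_lesion_flags",
]

MMHG_PER_PA = 1.0 / 133.322

DEFAULT_PRESSURE_SCALES = (0.5, 1.0, 5.0, 10.0)
DEFAULT_STIFFNESS_SCALES = (0.25, 0.5, 1.0, 2.0, 4.0)


def pa_to_mmhg(p_pa: float) -> float:
    """Convert pressure from Pa to mmHg (1 mmHg = 133.322 Pa)."""
    return p_pa * MMHG_PER_PA


@dataclass
class RunConfig:
    """One flat, serializable configuration; units are explicit in names."""

    # geometry
    horn_radius_anterior_mm: float = 2.0
    horn_radius_posterior_mm: float = 2.5
    ventricle_halfwidth_mm: float = 26.0
    ventricle_halfheight_mm: float = 21.0
    wing_width_mm: float = 10.0
    cortex_semiaxis_x_mm: float = 62.0
    cortex_semiaxis_y_mm: float = 50.0
    gm_thickness_mm: float = 3.0
    csf_thickness_mm: float = 4.0
    septum_gap_mm: float = 3.0
    # mesh
    wall_edge_length_mm: float = 0.35
    far_edge_length_mm: float = 2.6
    # materials (kPa) and loads (Pa)
    mu_gray_kpa: float = 0.34
    kappa_gray_kpa: float = 3.3
    mu_white_kpa: float = 0.68
    kappa_white_kpa: float = 6.6
    pressure_lv_pa: float = 20.0
    pressure_sas_pa: float = 1.0
    pressure_scale: float = 1.0
    stiffness_scale: float = 1.0
    # image + segmentation
    pixel_size_mm: float = 0.7
    lesion_radius_mm: float = 3.0
    lesion_contrast: float = 1.0
    noise_sd: float = 5.0
    segmentation_k: float = 2.5
    connectivity: int = 4
    # stats
    n_wall_samples: int = 30
    seed: int = 0

    def subject_spec(self) -> synthetic.SubjectSpec:
        return synthetic.SubjectSpec(
            horn_radius_anterior=self.horn_radius_anterior_mm,
            horn_radius_posterior=self.horn_radius_posterior_mm,
            ventricle_halfwidth=self.ventricle_halfwidth_mm,
            ventricle_halfheight=self.ventricle_halfheight_mm,
            wing_width=self.wing_width_mm,
            cortex_semiaxes=(self.cortex_semiaxis_x_mm, self.cortex_semiaxis_y_mm),
            gm_thickness=self.gm_thickness_mm,
            csf_thickness=self.csf_thickness_mm,
            septum_gap=self.septum_gap_mm,
            seed=self.seed,
        )

    def materials(self) -> fem.MaterialParams:
        return fem.MaterialParams(
            gray_matter=(self.mu_gray_kpa, self.kappa_gray_kpa),
            white_matter=(self.mu_white_kpa, self.kappa_white_kpa),
        )

    def load_case(self) -> fem.LoadCase:
        return fem.LoadCase(
            p_lv=self.pressure_lv_pa,
            p_sas=self.pressure_sas_pa,
            pressure_scale=self.pressure_scale,
            stiffness_scale=self.stiffness_scale,
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class SubjectResult:
    """Everything one subject run produces, in memory."""

    config: RunConfig
    geometry: synthetic.LabeledGeometry
    mesh: meshing.Mesh2D
    bset: meshing.BoundarySets
    wall: meshing.WallPath
    displacement: fem.DisplacementField
    state: fem.DeformationState
    frames: directions.DirectionField
    profile: markers.WallProfile
    horn_metrics: markers.HornMetrics | None
    flair: synthetic.SyntheticFlair
    segmentation: segmentation.SegmentationResult
    wall_test: stats.WallSampleTest | None
    manifest: dict = field(default_factory=dict)


def wall_lesion_flags(
    wall: meshing.WallPath,
    mask: np.ndarray,
    pixel_size: float,
    origin,
    reach_px: float = 1.5,
) -> np.ndarray:
    """True for wall nodes lying within ``reach_px`` pixels of a lesion
    pixel center (the node "abuts" a lesion component)."""
    ys, xs = np.nonzero(mask)
    if len(xs) == 0:
        return np.zeros(len(wall.node_indices), bool)
    centers = np.c_[
        origin[0] + (xs + 0.5) * pixel_size,
        origin[1] + (ys + 0.5) * pixel_size,
    ]
    tree = cKDTree(centers)
    d, _ = tree.query(wall.coords)
    return d <= reach_px * pixel_size


def run_subject(config: RunConfig, outdir=None) -> SubjectResult:
    """Run the full pipeline for one synthetic subject.

    With ``outdir`` set, writes the mesh (.msh), field file (.vtk), wall
    profile (CSV), horn metrics (JSON), images (NIfTI) and a manifest.
    A zero-load run reports a unit-stretch profile and no horn metrics.
    """
    spec = config.subject_spec()
    geometry = synthetic.make_geometry(spec)
    mesh, bset = meshing.mesh_geometry(
        geometry, config.wall_edge_length_mm, h_far=config.far_edge_length_mm
    )
    wall = meshing.order_wall(mesh, bset)
    disp = fem.solve_quasistatic(mesh, bset, config.materials(), config.load_case())
    state = fem.kinematics(disp, mesh)
    T = directions.solve_laplace(mesh, bset)
    frames = directions.wall_frames(T, mesh, wall)
    profile = markers.project_wall_stretches(state, frames, wall, mesh)
    try:
        hm = markers.horn_metrics(profile)
    except ValueError:
        hm = None  # e.g. zero load: lambda_t = 1 everywhere

    centers = synthetic.default_lesion_centers(geometry)
    flair = synthetic.make_flair(
        geometry,
        centers,
        lesion_radius=config.lesion_radius_mm,
        contrast=config.lesion_contrast,
        noise_sd=config.noise_sd,
        seed=config.seed,
        pixel_size=config.pixel_size_mm,
    )
    seg = segmentation.segment(
        flair.intensity,
        flair.label_image,
        k=config.segmentation_k,
        connectivity=config.connectivity,
    )

    flags = wall_lesion_flags(wall, seg.mask, flair.pixel_size, flair.origin)
    values, sample_flags = stats.sample_wall_points(profile, flags, config.n_wall_samples)
    if 2 <= sample_flags.sum() <= len(sample_flags) - 2:
        wall_test = stats.welch_ttest(values[sample_flags], values[~sample_flags])
    else:
        wall_test = None

    result = SubjectResult(
        config=config, geometry=geometry, mesh=mesh, bset=bset, wall=wall,
        displacement=disp, state=state, frames=frames, profile=profile,
        horn_metrics=hm, flair=flair, segmentation=seg, wall_test=wall_test,
    )
    result.manifest = _manifest(result)
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _manifest(result: SubjectResult) -> dict:
    def h(arr):
        return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]

    import scipy

    from . import __version__

    return {
        "config_hash": result.config.config_hash(),
        "versions": {
            "ventmech": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
        },
        "mesh_nodes": h(result.mesh.nodes),
        "mesh_triangles": h(result.mesh.triangles),
        "displacement": h(np.round(result.displacement.u, 12)),
        "lambda_t": h(np.round(result.profile.lambda_t, 12)),
        "segmentation": h(result.segmentation.mask),
    }


def _write_outputs(result: SubjectResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    meshing.write_msh(result.mesh, outdir / "mesh.msh")
    Tn = np.nan_to_num(result.frames.T, nan=0.0)
    meshing.write_vtk(
        result.mesh,
        outdir / "fields.vtk",
        point_data={"displacement": result.displacement.u, "temperature": Tn},
        cell_data={"J": result.state.J, "I1_bar": result.state.I1_bar, "MPS": result.state.mps},
    )
    df = result.profile.to_dataframe()
    df.to_csv(outdir / "wall_profile.csv", index=False)
    (outdir / "geometry.geojson").write_text(result.geometry.to_geojson())
    if result.horn_metrics is not None:
        hm = result.horn_metrics
        (outdir / "horn_metrics.json").write_text(
            json.dumps(
                {
                    "radii_mm": hm.radii,
                    "peak_lambda_t": hm.peak_lambda_t,
                    "peak_arclength_mm": hm.peak_arclength,
                    "arc_endpoints_mm": hm.arc_endpoints,
                    "wall_fraction_elevated": hm.wall_fraction_elevated,
                    "convention": hm.convention,
                },
                indent=2,
            )
        )
    synthetic.nifti_image(result.flair.intensity, result.flair.pixel_size).to_filename(
        str(outdir / "flair.nii")
    )
    synthetic.nifti_image(result.flair.label_image, result.flair.pixel_size).to_filename(
        str(outdir / "labels.nii")
    )
    synthetic.nifti_image(result.segmentation.mask, result.flair.pixel_size).to_filename(
        str(outdir / "wmh_mask.nii")
    )
    result.segmentation.audit_dataframe().to_csv(outdir / "components.csv", index=False)
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2))


@dataclass
class SweepReport:
    """Sensitivity sweep results, one row per scale value."""

    parameter: str                   # "pressure_scale" or "stiffness_scale"
    scales: list[float]
    peak_lambda_t: list[float]
    min_lambda_c: list[float]
    wall_fraction_elevated: list[float]
    peak_arclengths: list[list[float]]
    failures: dict = field(default_factory=dict)

    def peak_location_shift(self) -> float:
        """Largest pairwise shift (mm) of matched peak locations across the
        sweep, a check that peak locations are stationary."""
        locs = [np.sort(p) for p in self.peak_arclengths if p]
        if len(locs) < 2:
            return 0.0
        ref = locs[0]
        return float(max(np.max(np.abs(np.sort(l) - ref)) for l in locs[1:]))


def _solve_markers(mesh, bset, wall, frames_cache, materials, loads):
    disp = fem.solve_quasistatic(mesh, bset, materials, loads)
    state = fem.kinematics(disp, mesh)
    profile = markers.project_wall_stretches(state, frames_cache, wall, mesh)
    hm = markers.horn_metrics(profile)
    return profile, hm


def sensitivity_sweep(
    config: RunConfig,
    pressure_scales=DEFAULT_PRESSURE_SCALES,
    stiffness_scales=DEFAULT_STIFFNESS_SCALES,
) -> dict[str, SweepReport]:
    """Pressure and white-matter-stiffness sweeps on one subject.

    The mesh, wall ordering and direction fields are computed once (they
    are reference-configuration quantities); one solve per grid point.
    Per-point failures are recorded and the sweep continues.
    """
    spec = config.subject_spec()
    geometry = synthetic.make_geometry(spec)
    mesh, bset = meshing.mesh_geometry(
        geometry, config.wall_edge_length_mm, h_far=config.far_edge_length_mm
    )
    wall = meshing.order_wall(mesh, bset)
    T = directions.solve_laplace(mesh, bset)
    frames = directions.wall_frames(T, mesh, wall)
    materials = config.materials()

    reports = {}
    for name, scales in (
        ("pressure_scale", pressure_scales),
        ("stiffness_scale", stiffness_scales),
    ):
        rep = SweepReport(parameter=name, scales=list(scales), peak_lambda_t=[],
                          min_lambda_c=[], wall_fraction_elevated=[], peak_arclengths=[])
        for s in scales:
            loads = fem.LoadCase(
                p_lv=config.pressure_lv_pa,
                p_sas=config.pressure_sas_pa,
                pressure_scale=s if name == "pressure_scale" else config.pressure_scale,
                stiffness_scale=s if name == "stiffness_scale" else config.stiffness_scale,
            )
            try:
                profile, hm = _solve_markers(mesh, bset, wall, frames, materials, loads)
            except Exception as exc:  # record and continue
                rep.failures[s] = str(exc)
                rep.peak_lambda_t.append(float("nan"))
                rep.min_lambda_c.append(float("nan"))
                rep.wall_fraction_elevated.append(float("nan"))
                rep.peak_arclengths.append([])
                continue
            rep.peak_lambda_t.append(max(hm.peak_lambda_t))
            rep.min_lambda_c.append(float(np.min(profile.lambda_c)))
            rep.wall_fraction_elevated.append(hm.wall_fraction_elevated)
            rep.peak_arclengths.append(hm.peak_arclength)
        reports[name] = rep
    return reports


def radius_sweep(
    base_config: RunConfig,
    radii_mm,
) -> dict:
    """Solve a family of subjects differing only in horn radius (both
    anterior and posterior set to the same value); returns the per-subject
    mean fitted horn radius, peak tension, and elevated wall fraction."""
    out = {"radius_set_mm": [], "radius_fitted_mm": [], "peak_lambda_t": [],
           "wall_fraction_elevated": [], "horn_radii_mm": [], "horn_peak_lambda_t": []}
    for r in radii_mm:
        cfg = dataclasses.replace(
            base_config, horn_radius_anterior_mm=r, horn_radius_posterior_mm=r
        )
        spec = cfg.subject_spec()
        geometry = synthetic.make_geometry(spec)
        mesh, bset = meshing.mesh_geometry(
            geometry, cfg.wall_edge_length_mm, h_far=cfg.far_edge_length_mm
        )
        wall = meshing.order_wall(mesh, bset)
        T = directions.solve_laplace(mesh, bset)
        frames = directions.wall_frames(T, mesh, wall)
        profile, hm = _solve_markers(mesh, bset, wall, frames, cfg.materials(), cfg.load_case())
        out["radius_set_mm"].append(float(r))
        out["radius_fitted_mm"].append(float(np.mean(hm.radii)))
        out["peak_lambda_t"].append(float(max(hm.peak_lambda_t)))
        out["wall_fraction_elevated"].append(float(hm.wall_fraction_elevated))
        out["horn_radii_mm"].extend(float(v) for v in hm.radii)
        out["horn_peak_lambda_t"].extend(float(v) for v in hm.peak_lambda_t)
    return out
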