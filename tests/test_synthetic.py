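"""Synthetic subject generation: geometry, FLAIR surrogate, subject table."""

import numpy as np
import pytest

from ventmech import synthetic, meshing, segmentation
from ventmech.markers import circumcircle


class TestGeometry:
    def test_mirror_symmetry_for_symmetric_spec(self):
        spec = synthetic.SubjectSpec(horn_radius_anterior=2.0, horn_radius_posterior=2.0)
        geom = synthetic.make_geometry(spec)
        cav = geom.region_polygons["cavity"]
        xy = np.asarray(cav.exterior.coords)
        mirrored = np.c_[-xy[:, 0], xy[:, 1]]
        from shapely.geometry import Polygon

        assert cav.symmetric_difference(Polygon(mirrored)).area < 1e-6 * cav.area

    @pytest.mark.parametrize("r", [1.5, 2.0, 3.0])
    def test_tip_arc_recovers_prescribed_radius(self, r):
        """Fitting a circle through three points of the anterior tip arc must
        recover the prescribed radius (the arc is circular by construction)."""
        spec = synthetic.SubjectSpec(horn_radius_anterior=r)
        geom = synthetic.make_geometry(spec)
        xy = np.asarray(geom.region_polygons["cavity"].exterior.coords)[:-1]
        tip = geom.horn_tips[1]  # anterior-right apex
        center = tip - np.array([0.0, r])  # arc center by construction
        near = xy[np.linalg.norm(xy - tip, axis=1) < 0.8 * r]
        on_arc = near[np.abs(np.linalg.norm(near - center, axis=1) - r) < 1e-9]
        assert len(on_arc) >= 8  # a substantial exposed cap
        ang = np.arctan2(on_arc[:, 1] - center[1], on_arc[:, 0] - center[0])
        on_arc = on_arc[np.argsort(ang)]
        _, rad = circumcircle(on_arc[0], on_arc[len(on_arc) // 2], on_arc[-1])
        assert rad == pytest.approx(r, rel=0.02)

    def test_geometry_independent_of_seed(self):
        g1 = synthetic.make_geometry(synthetic.SubjectSpec(seed=1))
        g2 = synthetic.make_geometry(synthetic.SubjectSpec(seed=99))
        for name in ("cavity", "white_matter", "gray_matter", "csf"):
            a = np.asarray(g1.region_polygons[name].exterior.coords)
            b = np.asarray(g2.region_polygons[name].exterior.coords)
            np.testing.assert_array_equal(a, b)

    def test_nesting_and_validity(self, default_geometry):
        default_geometry.validate()  # raises on violation

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(horn_radius_anterior=-1.0),
            dict(horn_radius_anterior=30.0),  # >= halfwidth
            dict(csf_thickness=0.0),
            dict(ventricle_halfwidth=62.0),  # no annulus left
        ],
    )
    def test_infeasible_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            synthetic.make_geometry(synthetic.SubjectSpec(**kwargs))

    @pytest.mark.parametrize("r", [1.2, 2.0, 2.8, 3.6])
    def test_curvature_maxima_at_the_four_tips(self, r):
        """The cavity boundary's sustained-curvature maxima sit at the four
        horn-tip arcs for any valid spec."""
        spec = synthetic.SubjectSpec(horn_radius_anterior=r, horn_radius_posterior=r)
        geom = synthetic.make_geometry(spec)
        xy = np.asarray(geom.region_polygons["cavity"].exterior.coords)[:-1]
        tips = meshing.detect_polygon_tips(xy)
        assert tips is not None and len(tips) == 4
        for true_tip in geom.horn_tips:
            d = np.min(np.linalg.norm(tips - true_tip, axis=1))
            assert d < 1.0 * r + 0.6  # apex found on the tip arc

    def test_geojson_roundtrip(self, default_geometry):
        text = default_geometry.to_geojson()
        back = synthetic.LabeledGeometry.from_geojson(text)
        for name in ("cavity", "white_matter"):
            assert back.region_polygons[name].equals_exact(
                default_geometry.region_polygons[name], 1e-9
            )


class TestFlair:
    def test_deterministic_under_fixed_seed(self, default_geometry):
        centers = synthetic.default_lesion_centers(default_geometry)
        f1 = synthetic.make_flair(default_geometry, centers, seed=7)
        f2 = synthetic.make_flair(default_geometry, centers, seed=7)
        np.testing.assert_array_equal(f1.intensity, f2.intensity)
        f3 = synthetic.make_flair(default_geometry, centers, seed=8)
        assert not np.array_equal(f1.intensity, f3.intensity)

    def test_noiseless_high_contrast_segmentation_recovers_truth(self, default_geometry):
        centers = synthetic.default_lesion_centers(default_geometry)
        fl = synthetic.make_flair(default_geometry, centers, contrast=1.0, noise_sd=0.0)
        res = segmentation.segment(fl.intensity, fl.label_image)
        np.testing.assert_array_equal(res.mask, fl.truth_lesion_mask)

    def test_zero_contrast_yields_no_detectable_lesions(self, default_geometry):
        centers = synthetic.default_lesion_centers(default_geometry)
        fl = synthetic.make_flair(default_geometry, centers, contrast=0.0, noise_sd=5.0, seed=3)
        res = segmentation.segment(fl.intensity, fl.label_image)
        truth = fl.truth_lesion_mask
        recovered = (res.mask & truth).sum() / max(truth.sum(), 1)
        assert recovered < 0.05

    def test_truth_lesions_inside_white_matter(self, default_geometry):
        centers = synthetic.default_lesion_centers(default_geometry)
        fl = synthetic.make_flair(default_geometry, centers)
        assert np.all(fl.label_image[fl.truth_lesion_mask] == synthetic.LABELS["white_matter"])

    def test_septum_surrogate_is_majority_csf_bounded(self, default_geometry):
        """The planted septum-like component must trip the >50% CSF-boundary
        pruning rule."""
        centers = synthetic.default_lesion_centers(default_geometry)
        fl = synthetic.make_flair(default_geometry, centers, noise_sd=0.0)
        res = segmentation.segment(fl.intensity, fl.label_image)
        removed = [c for c in res.components if c.removed]
        assert len(removed) >= 1
        assert all(c.csf_fraction > 0.5 for c in removed)

    def test_negative_contrast_rejected(self, default_geometry):
        centers = synthetic.default_lesion_centers(default_geometry)
        with pytest.raises(ValueError):
            synthetic.make_flair(default_geometry, centers, contrast=-0.5)


class TestSubjectTable:
    def test_row_count_and_reference_rows(self):
        df = synthetic.table1_fixture()
        assert len(df) == 8
        f80 = df.set_index("id").loc["F80"]
        assert (f80.age, f80.vCSF, f80.vLV, f80.vWMH, f80.FS) == (77.6, 579.0, 74.1, 20.7, 3)
        assert df.set_index("id").loc["F20", "vWMH"] == 1.1
        assert df.set_index("id").loc["F20", "FS"] == 0
        assert df.set_index("id").loc["M80", "vLV"] == 61.4
        assert df.set_index("id").loc["M80", "FS"] == 3

    def test_sex_derived_from_id(self):
        df = synthetic.table1_fixture()
        assert (df["sex"] == df["id"].str[0]).all()
        assert set(df["sex"]) == {"F", "M"}
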