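import numpy as np
import pytest
import trimesh

from mandiblemetrics.geometry import DegenerateGeometryError, dihedral_angle, signed_distance
from mandiblemetrics.reconstruction import (
    BorderPlanes,
    MandibleLandmarks,
    aggregate_reconstruction,
    compare_measures,
    find_condyle_lateral,
    find_gonion,
    find_pogonion,
    fit_border_planes,
    measure_mandible,
)
from mandiblemetrics.reference_frame import SkullLandmarks, build_frame
from tests.conftest import random_rigid


@pytest.fixture(scope="module")
def frame(planned):
    return build_frame(SkullLandmarks.from_dict(planned.landmarks))


class TestCondyleAndPogonion:
    def test_condyle_lateral_at_sphere_pole(self, planned, frame):
        for side, key, sgn in (("left", "L", -1), ("right", "R", 1)):
            p = find_condyle_lateral(planned.mandible, side, frame,
                                     planned.rois[f"condyle_{key}"])
            expected = planned.condyle_centers[key] + sgn * np.array(
                [planned.spec.condyle_radius, 0, 0])
            assert np.allclose(p, expected, atol=1e-9)

    def test_empty_roi_rejected(self, planned, frame):
        with pytest.raises(DegenerateGeometryError):
            find_condyle_lateral(planned.mandible, "left", frame, np.array([], int))

    def test_pogonion_is_chin_apex(self, planned, frame):
        p = find_pogonion(planned.mandible, frame)
        assert np.allclose(p, planned.mandible.vertices[planned.chin_apex_index])

    def test_equivariance_under_rigid_transform(self, planned, rng):
        T = random_rigid(rng)
        moved = planned.mandible.transformed(T)
        frame_t = build_frame(SkullLandmarks.from_dict(
            {k: T.apply(v) for k, v in planned.landmarks.items()}))
        p0 = find_pogonion(planned.mandible,
                           build_frame(SkullLandmarks.from_dict(planned.landmarks)))
        p1 = find_pogonion(moved, frame_t)
        assert np.allclose(p1, T.apply(p0), atol=1e-9)


class TestBorderPlanes:
    def test_exact_bands_fit_with_zero_rms(self, planned):
        for side in ("L", "R"):
            borders = fit_border_planes(
                planned.mandible,
                planned.rois[f"posterior_border_{side}"],
                planned.rois[f"inferior_border_{side}"])
            assert borders.rms_posterior < 1e-9
            assert borders.rms_inferior < 1e-9
            n_post_true = planned.border_planes[(side, "posterior")][1]
            assert np.allclose(borders.posterior.normal, n_post_true, atol=1e-9)

    def test_outward_orientation(self, planned):
        centroid = planned.mandible.vertices.mean(axis=0)
        borders = fit_border_planes(planned.mandible,
                                    planned.rois["posterior_border_R"],
                                    planned.rois["inferior_border_R"])
        assert signed_distance(borders.posterior, centroid) < 0
        assert signed_distance(borders.inferior, centroid) < 0

    def test_two_vertex_roi_rejected(self, planned):
        with pytest.raises(DegenerateGeometryError):
            fit_border_planes(planned.mandible, np.array([0, 1]),
                              planned.rois["inferior_border_R"])

    def test_noisy_band_beyond_tolerance_rejected(self, planned, rng):
        mesh = planned.mandible.copy()
        roi = planned.rois["posterior_border_R"]
        mesh.vertices[roi] += rng.normal(0, 4.0, size=(len(roi), 3))
        with pytest.raises(DegenerateGeometryError, match="posterior"):
            fit_border_planes(mesh, roi, planned.rois["inferior_border_R"])


class TestGonion:
    def test_phantom_corner_recovered(self, planned, frame):
        for side, name in (("left", "L"), ("right", "R")):
            borders = fit_border_planes(
                planned.mandible,
                planned.rois[f"posterior_border_{name}"],
                planned.rois[f"inferior_border_{name}"])
            g = find_gonion(planned.mandible, borders, frame, side=side)
            corner = planned.mandible.vertices[planned.corner_indices[name]]
            d = (planned.border_planes[(name, "posterior")][1]
                 + planned.border_planes[(name, "inferior")][1])
            d /= np.linalg.norm(d)
            # must land on the corner edge, at its tie-broken representative
            dists = np.linalg.norm(corner - g, axis=1)
            assert dists.min() < 1e-9
            assert g @ d == pytest.approx(float((corner @ d).max()), abs=1e-9)

    def test_matches_exhaustive_intersection_scan(self, planned, frame):
        from mandiblemetrics.reconstruction import _bisecting_plane

        borders = fit_border_planes(planned.mandible,
                                    planned.rois["posterior_border_R"],
                                    planned.rois["inferior_border_R"])
        g = find_gonion(planned.mandible, borders, frame, side="right")
        bis, d = _bisecting_plane(borders)
        tm = planned.mandible.to_trimesh()
        segments = trimesh.intersections.mesh_plane(
            tm, plane_normal=bis.normal, plane_origin=bis.point)
        pts = np.asarray(segments).reshape(-1, 3)
        verts = planned.mandible.vertices
        on_plane = np.abs((verts - bis.point) @ bis.normal) < 1e-9
        pts = np.vstack([pts, verts[on_plane]])
        pts = pts[(pts[:, 0] > 0)]
        assert g @ d == pytest.approx(float((pts @ d).max()), abs=1e-9)

    def test_parallel_border_planes_rejected(self, planned):
        from mandiblemetrics.geometry import Plane
        borders = BorderPlanes(
            posterior=Plane((0, 0, 0), (0, 0, 1)),
            inferior=Plane((0, 0, -5), (0, 0, 1)),
            rms_posterior=0.0, rms_inferior=0.0)
        with pytest.raises(DegenerateGeometryError):
            find_gonion(planned.mandible, borders)

    def test_sharp_wedge_extremal_on_edge(self):
        # right-angle wedge: floor z in [0, -...]: solid z >= 0, x <= 5;
        # the bisector must pick the corner edge x = 5, z = 0
        from mandiblemetrics.mesh_io import TriangleMesh
        from mandiblemetrics.geometry import Plane
        xs = np.linspace(0, 5, 6)
        ys = np.linspace(-3, 3, 7)
        zs = np.linspace(0, 5, 6)
        floor = [(x, y, 0.0) for y in ys for x in xs]
        wall = [(5.0, y, z) for y in ys for z in zs[1:]]
        verts = np.array(floor + wall)
        faces = []
        nx = len(xs)
        for j in range(len(ys) - 1):
            for i in range(nx - 1):
                a = j * nx + i
                faces.append((a, a + 1, a + nx))
                faces.append((a + 1, a + nx + 1, a + nx))
        off = len(floor)
        nz = len(zs) - 1
        for j in range(len(ys) - 1):
            for k in range(nz - 1):
                a = off + j * nz + k
                faces.append((a, a + 1, a + nz))
                faces.append((a + 1, a + nz + 1, a + nz))
        mesh = TriangleMesh(verts, np.array(faces), "wedge")
        borders = BorderPlanes(
            posterior=Plane((5.0, 0.0, 2.0), (1.0, 0.0, 0.0)),
            inferior=Plane((2.0, 0.0, 0.0), (0.0, 0.0, -1.0)),
            rms_posterior=0.0, rms_inferior=0.0)
        g = find_gonion(mesh, borders)
        assert g[0] == pytest.approx(5.0, abs=1e-9)
        assert g[2] == pytest.approx(0.0, abs=1e-9)


class TestMeasures:
    frame_canonical = build_frame(SkullLandmarks(
        porion_L=np.array([-60.0, 0.0, 0.0]), porion_R=np.array([60.0, 0.0, 0.0]),
        orbitale_R=np.array([40.0, 80.0, 0.0]), nasion=np.array([0.0, 90.0, 5.0]),
        basion=np.array([0.0, 0.0, -5.0])))

    def borders(self, gonial=120.0):
        from mandiblemetrics.geometry import Plane
        from tests.conftest import rotation_matrix
        n_inf = np.array([0.0, 0.0, -1.0])
        n_post = rotation_matrix((1, 0, 0), 180.0 - gonial) @ n_inf
        return BorderPlanes(posterior=Plane((0, -45, -20), n_post),
                            inferior=Plane((0, -45, -35), n_inf),
                            rms_posterior=0.0, rms_inferior=0.0)

    def landmarks(self):
        return MandibleLandmarks(
            condyle_lateral_L=np.array([-50.0, -40.0, 30.0]),
            condyle_lateral_R=np.array([50.0, -40.0, 30.0]),
            gonion_L=np.array([-45.0, -45.0, -20.0]),
            gonion_R=np.array([45.0, -45.0, -20.0]),
            pogonion=np.array([0.0, 60.0, -25.0]))

    def test_closed_form_values(self):
        m = measure_mandible(self.landmarks(), self.borders(), self.borders(),
                             self.frame_canonical, "right")
        assert m.ICD == pytest.approx(100.0)
        assert m.IGD == pytest.approx(90.0)
        assert round(m.APD, 2) == 114.13  # sqrt(100^2 + 55^2)
        # axial angle left: arcsin(45 / |(45, 105, -5)|)
        expected_axial_L = np.degrees(np.arcsin(45 / np.linalg.norm([45, 105, -5])))
        assert m.axial_angle_nonop == pytest.approx(expected_axial_L)
        assert round(expected_axial_L, 2) == 23.18
        assert m.gonial_angle_op == pytest.approx(120.0)

    def test_operated_side_swap_moves_columns_only(self):
        m_r = measure_mandible(self.landmarks(), self.borders(110.0), self.borders(130.0),
                               self.frame_canonical, "right")
        m_l = measure_mandible(self.landmarks(), self.borders(110.0), self.borders(130.0),
                               self.frame_canonical, "left")
        assert m_r.ICD == m_l.ICD and m_r.IGD == m_l.IGD and m_r.APD == m_l.APD
        assert m_r.gonial_angle_op == m_l.gonial_angle_nonop
        assert m_r.coronal_angle_op == m_l.coronal_angle_nonop

    def test_coincident_condyles_rejected(self):
        lm = self.landmarks()
        lm.condyle_lateral_L = lm.condyle_lateral_R.copy()
        with pytest.raises(DegenerateGeometryError):
            measure_mandible(lm, self.borders(), self.borders(),
                             self.frame_canonical, "right")

    def test_side_validation(self):
        lm = self.landmarks()
        lm.gonion_L = np.array([45.0, -45.0, -20.0])  # wrong side
        with pytest.raises(DegenerateGeometryError):
            lm.validate_sides(self.frame_canonical)


class TestCompareAndAggregate:
    def test_identity_and_symmetry(self):
        frame = TestMeasures.frame_canonical
        tm = TestMeasures()
        m1 = measure_mandible(tm.landmarks(), tm.borders(), tm.borders(), frame, "right")
        d0 = compare_measures(m1, m1)
        assert all(v == 0.0 for v in d0.values())
        m2 = measure_mandible(tm.landmarks(), tm.borders(118.0), tm.borders(), frame, "right")
        assert compare_measures(m1, m2) == compare_measures(m2, m1)

    def test_simple_difference(self):
        tm = TestMeasures()
        frame = TestMeasures.frame_canonical
        m1 = measure_mandible(tm.landmarks(), tm.borders(), tm.borders(), frame, "right")
        lm = tm.landmarks()
        lm.condyle_lateral_R = lm.condyle_lateral_R + np.array([-1.5, 0, 0])
        m2 = measure_mandible(lm, tm.borders(), tm.borders(), frame, "right")
        assert compare_measures(m1, m2)["ICD"] == pytest.approx(1.5)

    def test_aggregate_mad_and_groups(self):
        diffs = [{k: v for k in (
            "ICD", "IGD", "APD", "gonial_angle_op", "gonial_angle_nonop",
            "axial_angle_op", "axial_angle_nonop", "coronal_angle_op",
            "coronal_angle_nonop")} for v in (1.0, 3.0)]
        table = aggregate_reconstruction(diffs, ["conventional", "conventional"])
        row = table.set_index("measurement").loc["ICD"]
        assert row["all_mad"] == pytest.approx(2.0)
        assert row["all_sd"] == pytest.approx(np.sqrt(2), abs=5e-3)
        assert np.isnan(row["p_conventional_vs_psi"])  # PSI group empty

    def test_group_p_value_present_when_both_groups(self):
        names = ("ICD", "IGD", "APD", "gonial_angle_op", "gonial_angle_nonop",
                 "axial_angle_op", "axial_angle_nonop", "coronal_angle_op",
                 "coronal_angle_nonop")
        rng = np.random.default_rng(1)
        diffs = [{k: abs(rng.normal()) for k in names} for _ in range(10)]
        plates = ["conventional"] * 5 + ["PSI"] * 5
        table = aggregate_reconstruction(diffs, plates)
        p = table.set_index("measurement").loc["ICD", "p_conventional_vs_psi"]
        assert 0.0 <= p <= 1.0

    def test_half_normal_mad_recovery(self):
        # per-case ICD error drawn |N(0, 2^2)|: recovered mean within 3
        # standard errors of the half-normal mean 2 sqrt(2/pi)
        rng = np.random.default_rng(11)
        names = ("ICD", "IGD", "APD", "gonial_angle_op", "gonial_angle_nonop",
                 "axial_angle_op", "axial_angle_nonop", "coronal_angle_op",
                 "coronal_angle_nonop")
        vals = np.abs(rng.normal(0, 2.0, size=200))
        diffs = [{k: (v if k == "ICD" else 0.0) for k in names} for v in vals]
        table = aggregate_reconstruction(diffs, ["conventional"] * 200)
        mad = table.set_index("measurement").loc["ICD", "all_mad"]
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(mad - 2.0 * np.sqrt(2 / np.pi)) < 3 * se
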