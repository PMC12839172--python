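import numpy as np
import pytest

from mandiblemetrics.geometry import PlanarPatch
from mandiblemetrics.mesh_io import TriangleMesh
from mandiblemetrics.phantom import ErrorModel
from mandiblemetrics.phantom_truth import sample_draw
from mandiblemetrics.reference_frame import SkullLandmarks, build_frame
from mandiblemetrics.resection import (
    KEY_POINT_ROLES,
    ResectionPatchPair,
    aggregate_resection,
    boundary_vertex_indices,
    extract_key_points,
    plane_deviation,
)
from tests.conftest import random_rigid, rotation_matrix

CANONICAL_FRAME = build_frame(SkullLandmarks(
    porion_L=np.array([-60.0, 0.0, 0.0]), porion_R=np.array([60.0, 0.0, 0.0]),
    orbitale_R=np.array([40.0, 80.0, 0.0]), nasion=np.array([0.0, 90.0, 5.0]),
    basion=np.array([0.0, 0.0, -5.0]),
))


def rectangle_patch(x0=30.0, half_w=5.0, half_h=15.0, flip_x=False):
    """Rectangular patch in the plane y = 0, spanning x0 +- half_w and z
    in +-half_h, subdivided so it has interior structure."""
    xs = np.linspace(x0 - half_w, x0 + half_w, 5)
    zs = np.linspace(-half_h, half_h, 7)
    verts, faces = [], []
    for z in zs:
        for x in xs:
            verts.append((-x if flip_x else x, 0.0, z))
    nx = len(xs)
    for j in range(len(zs) - 1):
        for i in range(nx - 1):
            a = j * nx + i
            faces.append((a, a + 1, a + nx))
            faces.append((a + 1, a + nx + 1, a + nx))
    return TriangleMesh(np.array(verts), np.array(faces), "rect")


class TestKeyPoints:
    def test_rectangle_roles(self):
        patch = PlanarPatch.from_mesh(rectangle_patch())
        kp = extract_key_points(patch, CANONICAL_FRAME)
        assert np.allclose(kp.centroid, (30, 0, 0))
        assert kp.superior[2] == pytest.approx(15.0)
        assert kp.inferior[2] == pytest.approx(-15.0)
        assert kp.buccal[0] == pytest.approx(35.0)   # farther from midsagittal
        assert kp.lingual[0] == pytest.approx(25.0)

    def test_left_side_buccal_flips(self):
        patch = PlanarPatch.from_mesh(rectangle_patch(flip_x=True))
        kp = extract_key_points(patch, CANONICAL_FRAME)
        assert kp.buccal[0] == pytest.approx(-35.0)
        assert kp.lingual[0] == pytest.approx(-25.0)

    def test_degenerate_orientation_rejected(self):
        # a cut plane perpendicular to the superior axis has no in-plane
        # "up" direction
        verts = np.array([(0, 0, 0), (10, 0, 0), (10, 10, 0), (0, 10, 0)], float)
        faces = np.array([(0, 1, 2), (0, 2, 3)])
        patch = PlanarPatch.from_mesh(TriangleMesh(verts, faces, "flat"))
        from mandiblemetrics.geometry import DegenerateGeometryError
        with pytest.raises(DegenerateGeometryError):
            extract_key_points(patch, CANONICAL_FRAME)

    def test_outline_points_match_brute_force_scan(self, planned):
        for info in planned.patches.values():
            patch = PlanarPatch.from_mesh(info.mesh)
            kp = extract_key_points(patch, CANONICAL_FRAME)
            ring_idx = boundary_vertex_indices(info.mesh)
            ring = info.mesh.vertices[ring_idx]
            n = patch.fitted_plane.normal
            u = CANONICAL_FRAME.axis_superior - np.dot(
                CANONICAL_FRAME.axis_superior, n) * n
            u /= np.linalg.norm(u)
            w = np.cross(n, u)
            assert np.allclose(kp.superior, ring[np.argmax(ring @ u)])
            assert np.allclose(kp.inferior, ring[np.argmax(ring @ -u)])
            extremes = {tuple(ring[np.argmax(ring @ w)]),
                        tuple(ring[np.argmax(ring @ -w)])}
            assert {tuple(kp.buccal), tuple(kp.lingual)} == extremes


class TestPlaneDeviation:
    tumor = np.array([20.0, 10.0, -20.0])

    def pair(self, achieved_mesh, planned_mesh=None):
        return ResectionPatchPair(
            planned=PlanarPatch.from_mesh(planned_mesh or rectangle_patch()),
            achieved=PlanarPatch.from_mesh(achieved_mesh),
            label="anterior", case_id="t",
        )

    def test_identity_gives_exact_zeros(self):
        dev = plane_deviation(self.pair(rectangle_patch()), CANONICAL_FRAME, self.tumor)
        for role in KEY_POINT_ROLES:
            assert dev.distance(role) == pytest.approx(0.0, abs=1e-12)
        assert dev.angle == pytest.approx(0.0, abs=1e-9)
        assert dev.shift_direction == "on_plane"

    def test_translation_by_1_2_2_gives_three_mm_everywhere(self):
        moved = rectangle_patch()
        moved.vertices = moved.vertices + np.array([1.0, 2.0, 2.0])
        dev = plane_deviation(self.pair(moved), CANONICAL_FRAME, self.tumor)
        for role in KEY_POINT_ROLES:
            assert dev.distance(role) == pytest.approx(3.0, abs=1e-9)
        assert dev.angle == pytest.approx(0.0, abs=1e-6)

    def test_in_plane_rotation_about_centroid(self):
        moved = rectangle_patch()
        c = np.array([30.0, 0.0, 0.0])
        R = rotation_matrix((0, 0, 1), 10.0)  # in-plane axis through centroid
        moved.vertices = (moved.vertices - c) @ R.T + c
        dev = plane_deviation(self.pair(moved), CANONICAL_FRAME, self.tumor)
        assert dev.d_centroid == pytest.approx(0.0, abs=1e-9)
        assert dev.angle == pytest.approx(10.0, abs=1e-9)
        # outline chord length: |p' - p| = 2 sin(5 deg) * r for points that
        # stay extremal; the corner-region points move by exactly this chord
        kp = extract_key_points(PlanarPatch.from_mesh(rectangle_patch()),
                                CANONICAL_FRAME)
        for role in ("superior", "inferior"):
            p = kp.as_dict()[role]
            chord = np.linalg.norm(((p - c) @ R.T + c) - p)
            assert dev.distance(role) == pytest.approx(chord, abs=1e-9)

    def test_toward_tumor_sign(self):
        moved = rectangle_patch()
        moved.vertices = moved.vertices + np.array([0.0, 2.0, 0.0])  # towards y+
        dev = plane_deviation(self.pair(moved), CANONICAL_FRAME, self.tumor)
        assert dev.shift_direction == "toward_tumor"
        moved2 = rectangle_patch()
        moved2.vertices = moved2.vertices + np.array([0.0, -2.0, 0.0])
        dev2 = plane_deviation(self.pair(moved2), CANONICAL_FRAME, self.tumor)
        assert dev2.shift_direction == "away_from_tumor"

    def test_common_rigid_transform_invariance(self, planned, rng):
        # uses the phantom's elliptical patch: its extremal boundary
        # vertices are unique, so the metrics are exactly equivariant
        info = planned.patches["anterior"]
        achieved = info.mesh.copy()
        achieved.vertices = achieved.vertices + np.array([0.5, 1.5, -1.0])
        pair0 = ResectionPatchPair(
            planned=PlanarPatch.from_mesh(info.mesh),
            achieved=PlanarPatch.from_mesh(achieved),
            label="anterior", case_id="t")
        frame0 = build_frame(SkullLandmarks.from_dict(planned.landmarks))
        base = plane_deviation(pair0, frame0, planned.tumor_centroid)
        for _ in range(5):
            T = random_rigid(rng)
            pair_t = ResectionPatchPair(
                planned=PlanarPatch.from_mesh(info.mesh.transformed(T)),
                achieved=PlanarPatch.from_mesh(achieved.transformed(T)),
                label="anterior", case_id="t")
            frame_t = build_frame(SkullLandmarks.from_dict(
                {k: T.apply(v) for k, v in planned.landmarks.items()}))
            dev_t = plane_deviation(pair_t, frame_t, T.apply(planned.tumor_centroid))
            for role in KEY_POINT_ROLES:
                assert dev_t.distance(role) == pytest.approx(
                    base.distance(role), abs=1e-9)
            # arccos of a near-unit dot bottoms out around 1e-6 degrees
            assert dev_t.angle == pytest.approx(base.angle, abs=1e-5)


class TestAggregate:
    def make_dev(self, case_id, label, d, toward=True):
        from mandiblemetrics.resection import PlaneDeviation
        off = d if toward else -d
        return PlaneDeviation(
            label=label, case_id=case_id,
            d_centroid=d, d_superior=d, d_inferior=d, d_buccal=d, d_lingual=d,
            angle=d, signed_centroid_offset=off, shift_direction=(
                "toward_tumor" if toward else "away_from_tumor"),
            point_offsets={r: off for r in KEY_POINT_ROLES},
        )

    def test_mean_and_sample_sd(self):
        devs = [self.make_dev("a", "anterior", 1.0), self.make_dev("b", "anterior", 3.0)]
        table = aggregate_resection(devs).set_index("measurement")
        assert table.loc["centroid", "all_mean"] == pytest.approx(2.0)
        assert table.loc["centroid", "all_sd"] == pytest.approx(np.sqrt(2), abs=5e-3)

    def test_all_toward_tumor_is_100_percent(self):
        devs = [self.make_dev(c, "anterior", 1.0 + i) for i, c in enumerate("abc")]
        table = aggregate_resection(devs).set_index("measurement")
        assert table.loc["centroid", "toward_tumor_pct"] == pytest.approx(100.0)

    def test_explicit_exclusion_is_echoed(self):
        devs = [self.make_dev("a", "anterior", 1.0), self.make_dev("b", "anterior", 9.0)]
        table = aggregate_resection(devs, exclude=[("b", "anterior")])
        assert table.set_index("measurement").loc["centroid", "all_mean"] == pytest.approx(1.0)
        assert table.attrs["excluded"] == [("b", "anterior")]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate_resection([])

    def test_monte_carlo_centroid_mean_matches_maxwell(self, planned):
        # centroid deviation |t| with t ~ N(0, sigma^2 I3) has mean
        # sigma * sqrt(8 / pi); recover it from the generator's analytic
        # ground truth over 200 draws within 3 standard errors
        from mandiblemetrics.phantom_truth import case_ground_truth

        sigma = 1.3
        model = ErrorModel(plane_translation_sd=sigma, plane_rotation_sd=0.0,
                           global_rotation_max=0.0, global_translation_max=0.0)
        rng = np.random.default_rng(77)
        vals = []
        for _ in range(200):
            gt = case_ground_truth(planned, sample_draw(planned, model, rng))
            for dev in gt.plane_deviations.values():
                vals.append(dev["d_centroid"])
        vals = np.asarray(vals)
        analytic_mean = sigma * np.sqrt(8 / np.pi)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - analytic_mean) < 3 * se
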