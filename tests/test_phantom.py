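import numpy as np
import pytest

from mandiblemetrics.geometry import dihedral_angle
from mandiblemetrics.phantom import ErrorModel, PhantomSpec, generate_phantom, randomized_spec
from mandiblemetrics.phantom_truth import (
    apply_error,
    case_ground_truth,
    sample_draw,
    simulate_cohort,
)
from mandiblemetrics.reconstruction import fit_border_planes


ZERO = ErrorModel(plane_translation_sd=0, plane_rotation_sd=0,
                  global_rotation_max=0, global_translation_max=0)


class TestGeneration:
    def test_condyle_lateral_ground_truth_positions(self, planned):
        spec = planned.spec
        for key, sgn in (("L", -1), ("R", 1)):
            pole = planned.mandible.vertices[planned.sphere_indices[key][0]]
            assert pole[0] == pytest.approx(
                sgn * (spec.arch_half_width + spec.condyle_radius))

    def test_border_bands_exactly_planar(self, planned):
        v = planned.mandible.vertices
        for side in ("L", "R"):
            for kind in ("posterior", "inferior"):
                p0, n = planned.border_planes[(side, kind)]
                roi = planned.rois[f"{kind}_border_{side}"]
                assert np.abs((v[roi] - p0) @ n).max() < 1e-9

    def test_gonial_angle_recovered_from_fitted_planes(self, planned):
        for side in ("L", "R"):
            borders = fit_border_planes(
                planned.mandible,
                planned.rois[f"posterior_border_{side}"],
                planned.rois[f"inferior_border_{side}"])
            angle = dihedral_angle(borders.posterior, borders.inferior)
            assert angle == pytest.approx(planned.spec.target_gonial_angle, abs=0.01)

    def test_generation_is_bit_identical(self, coarse_spec):
        a = generate_phantom(coarse_spec)
        b = generate_phantom(coarse_spec)
        assert np.array_equal(a.mandible.vertices, b.mandible.vertices)
        assert np.array_equal(a.mandible.faces, b.mandible.faces)

    def test_segments_partition_vertices(self, planned):
        idx = np.concatenate(list(planned.segments.values()))
        assert len(idx) == len(np.unique(idx)) == planned.mandible.n_vertices

    def test_randomized_specs_keep_guarantees(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            spec = randomized_spec(rng, edge=2.5)
            b = generate_phantom(spec)
            for side in ("L", "R"):
                borders = fit_border_planes(
                    b.mandible, b.rois[f"posterior_border_{side}"],
                    b.rois[f"inferior_border_{side}"])
                angle = dihedral_angle(borders.posterior, borders.inferior)
                assert angle == pytest.approx(spec.target_gonial_angle, abs=0.01)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(target_gonial_angle=80.0)
        with pytest.raises(ValueError):
            PhantomSpec(condyle_radius=-1.0)


class TestApplyError:
    def test_zero_model_changes_nothing(self, planned):
        case = apply_error(planned, ZERO, seed=0)
        assert np.allclose(case.postop_meshes["postop_mandible"].vertices,
                           planned.mandible.vertices)
        gt = case.ground_truth
        for dev in gt.plane_deviations.values():
            assert dev["d_centroid"] == 0.0 and dev["angle"] == 0.0
            assert dev["shift_direction"] == "on_plane"
        assert all(v == 0.0 for v in gt.measure_difference.values())

    def test_fixed_plane_translation_ground_truth(self, planned):
        # force translation (0, 0, 2) on both patches, nothing else
        model = ErrorModel(plane_translation_sd=1.0, plane_rotation_sd=0,
                           global_rotation_max=0, global_translation_max=0)
        case = apply_error(planned, model, seed=1)
        for label, pd in case.draw.patches.items():
            pd.translation[:] = (0.0, 0.0, 2.0)
        gt = case_ground_truth(planned, case.draw)
        for dev in gt.plane_deviations.values():
            assert dev["d_centroid"] == pytest.approx(2.0, abs=1e-12)
            assert dev["angle"] == pytest.approx(0.0, abs=1e-9)

    def test_same_seed_reproduces_case(self, planned):
        model = ErrorModel(segment_shift_sd=1.0, vertex_noise_sd=0.1)
        a = apply_error(planned, model, seed=42)
        b = apply_error(planned, model, seed=42)
        assert np.array_equal(a.postop_meshes["postop_mandible"].vertices,
                              b.postop_meshes["postop_mandible"].vertices)
        assert a.ground_truth.measure_difference == b.ground_truth.measure_difference

    def test_rotation_only_patch_angle(self, planned):
        model = ErrorModel(plane_translation_sd=0.0, plane_rotation_sd=5.0,
                           global_rotation_max=0, global_translation_max=0)
        rng = np.random.default_rng(7)
        draw = sample_draw(planned, model, rng)
        gt = case_ground_truth(planned, draw)
        for label, dev in gt.plane_deviations.items():
            assert dev["angle"] == pytest.approx(
                abs(draw.patches[label].angle_deg), abs=1e-9)
            assert dev["d_centroid"] == pytest.approx(0.0, abs=1e-12)


class TestCohort:
    def test_zero_error_cohort_all_zero(self, planned):
        cohort = simulate_cohort(5, model=ZERO, seed=0, planned=planned)
        table = cohort.ground_truth_table()
        num = table.select_dtypes("number")
        assert np.allclose(num.to_numpy(dtype=float), 0.0)

    def test_cohort_determinism(self, planned):
        a = simulate_cohort(4, model=ErrorModel(), seed=9, planned=planned)
        b = simulate_cohort(4, model=ErrorModel(), seed=9, planned=planned)
        assert a.ground_truth_table().equals(b.ground_truth_table())

    def test_plate_mix(self, planned):
        cohort = simulate_cohort(10, model=ErrorModel(), plate_mix=0.3,
                                 seed=1, planned=planned)
        plates = [c.plate_type for c in cohort.cases]
        assert plates.count("PSI") == 3

    def test_group_difference_power_at_known_effect_size(self, planned):
        """Two plate groups with 4x different plane-error scales: the
        Mann-Whitney comparison of centroid deviations detects the
        difference at p < 0.05 in at least 90% of 100 replicate
        cohorts of 15 + 15 cases."""
        from mandiblemetrics.stats import mann_whitney_u

        big = ErrorModel(plane_translation_sd=2.0, plane_rotation_sd=0,
                         global_rotation_max=0, global_translation_max=0)
        small = ErrorModel(plane_translation_sd=0.5, plane_rotation_sd=0,
                           global_rotation_max=0, global_translation_max=0)
        hits = 0
        for rep in range(100):
            cohort = simulate_cohort(30, model=big, psi_model=small,
                                     plate_mix=0.5, seed=1000 + rep,
                                     planned=planned)
            t = cohort.ground_truth_table()
            x = t[t.plate_type == "conventional"]["anterior_d_centroid"]
            y = t[t.plate_type == "PSI"]["anterior_d_centroid"]
            if mann_whitney_u(x, y).p_value < 0.05:
                hits += 1
        assert hits >= 90

    def test_distinct_group_error_models_separate(self, planned):
        # the PSI group gets a smaller error scale: its ground-truth
        # centroid deviations should be stochastically smaller
        big = ErrorModel(plane_translation_sd=2.0, plane_rotation_sd=0,
                         global_rotation_max=0, global_translation_max=0)
        small = ErrorModel(plane_translation_sd=0.5, plane_rotation_sd=0,
                           global_rotation_max=0, global_translation_max=0)
        cohort = simulate_cohort(40, model=big, psi_model=small, plate_mix=0.5,
                                 seed=2, planned=planned)
        t = cohort.ground_truth_table()
        psi = t[t.plate_type == "PSI"]["anterior_d_centroid"].mean()
        conv = t[t.plate_type == "conventional"]["anterior_d_centroid"].mean()
        assert psi < conv
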