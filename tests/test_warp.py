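import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from bcaccum.gamma import GammaCriteria
from bcaccum.grids import VoxelGrid
from bcaccum.warp import (
    QAGates,
    accumulate,
    pelvic_roi,
    qa_check,
    rigid_align,
    warp_dose,
)


@pytest.fixture()
def landmarks(rng):
    return rng.uniform(20, 200, size=(5, 3))


class TestRigidAlign:
    def test_identity(self, landmarks):
        t = rigid_align(landmarks, landmarks)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t.translation, 0, atol=1e-9)
        assert t.residual_rms_mm < 1e-9

    def test_pure_translation_recovered(self, landmarks):
        shifted = landmarks + np.array([5.0, 0.0, 0.0])
        t = rigid_align(shifted, landmarks)
        np.testing.assert_allclose(t.translation, [-5.0, 0.0, 0.0], atol=1e-6)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-9)

    def test_random_rigid_motion_inverted(self, landmarks, rng):
        """Generate-and-invert oracle: apply a known rigid motion, recover it."""
        rot = Rotation.from_euler("xyz", rng.uniform(-30, 30, 3), degrees=True)
        trans = rng.uniform(-20, 20, 3)
        moved = landmarks @ rot.as_matrix().T + trans
        t = rigid_align(moved, landmarks)
        np.testing.assert_allclose(t.apply(moved), landmarks, atol=1e-6)
        np.testing.assert_allclose(t.rotation @ rot.as_matrix(), np.eye(3), atol=1e-9)

    def test_composition_with_inverse_is_identity(self, landmarks, rng):
        moved = landmarks + rng.normal(0, 3, landmarks.shape)
        t = rigid_align(moved, landmarks)
        comp_r = t.rotation @ t.inverse().rotation
        np.testing.assert_allclose(comp_r, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t.apply(t.inverse().apply(landmarks)), landmarks,
                                   atol=1e-9)

    def test_collinear_landmarks_rejected(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            rigid_align(pts, pts + [0.0, 1.0, 0.0])


class TestWarpDose:
    def test_zero_dvf_is_identity(self, rng):
        dose = VoxelGrid(rng.uniform(0, 2, (12, 12, 12)))
        out, n_out = warp_dose(dose, np.zeros(dose.shape + (3,)))
        np.testing.assert_array_equal(out.data, dose.data)
        assert n_out == 0

    def test_uniform_dose_invariant_under_smooth_in_grid_dvf(self):
        dose = VoxelGrid(np.full((16, 16, 16), 2.0), spacing=(4, 4, 4))
        x = np.linspace(0, np.pi, 16)
        bump = 3.0 * np.sin(x)[:, None, None] * np.sin(x)[None, :, None] * np.sin(x)[None, None, :]
        dvf = np.zeros(dose.shape + (3,))
        dvf[..., 0] = bump
        out, _ = warp_dose(dose, dvf)
        np.testing.assert_allclose(out.data, 2.0, atol=1e-12)

    def test_integer_voxel_translation_matches_shift_oracle(self, rng):
        dose = VoxelGrid(rng.uniform(0, 2, (10, 10, 10)), spacing=(4, 4, 4))
        dvf = np.zeros(dose.shape + (3,))
        dvf[..., 2] = 8.0  # exactly two voxels along z
        out, _ = warp_dose(dose, dvf)
        np.testing.assert_allclose(out.data[:, :, :8], dose.data[:, :, 2:], atol=1e-12)
        assert np.all(out.data[:, :, 8:] == 0)  # sampled outside -> 0

    def test_inverse_round_trip_within_interpolation_tolerance(self, spec, planning_dose, fraction_plus30):
        dvf = fraction_plus30.true_dvf
        fwd, _ = warp_dose(planning_dose.grid, dvf)
        back, _ = warp_dose(fwd, -dvf)
        rms = np.sqrt(np.mean((back.data - planning_dose.data) ** 2))
        assert rms < 0.02 * planning_dose.data.max()

    def test_geometry_mismatch_rejected(self):
        dose = VoxelGrid(np.zeros((8, 8, 8)))
        with pytest.raises(ValueError):
            warp_dose(dose, np.zeros((8, 8, 9, 3)))


class TestQACheck:
    def test_ground_truth_dvf_passes(self, spec, planning, planning_dose, fraction_plus30):
        _, labels = planning
        fa = fraction_plus30
        warped, _ = warp_dose(planning_dose.grid, fa.true_dvf)
        roi = pelvic_roi(labels["body"], labels["ptv"], spec.spacing)
        qa = qa_check(fa.true_dvf, spec.landmarks_mm, fa.landmarks_mm,
                      warped, planning_dose.grid, QAGates(), roi_mask=roi)
        assert qa.tre_mean_mm < 0.5
        assert qa.gamma_pass_pct > 90.0
        assert qa.passed

    def test_5mm_landmark_perturbation_fails_tre_gate(self, spec, planning, planning_dose, fraction_plus30):
        _, labels = planning
        fa = fraction_plus30
        bad = fa.true_dvf + np.array([5.0, 0.0, 0.0])
        warped, _ = warp_dose(planning_dose.grid, bad)
        roi = pelvic_roi(labels["body"], labels["ptv"], spec.spacing)
        qa = qa_check(bad, spec.landmarks_mm, fa.landmarks_mm,
                      warped, planning_dose.grid, QAGates(), roi_mask=roi)
        assert qa.tre_mean_mm == pytest.approx(5.0, abs=0.2)
        assert not qa.passed and qa.excluded

    def test_dose_scale_error_decided_by_measured_gamma(self, spec, planning, planning_dose):
        """A 4% dose-scale error passes or fails strictly according to the
        measured gamma rate against the 90% gate."""
        _, labels = planning
        roi = pelvic_roi(labels["body"], labels["ptv"], spec.spacing)
        scaled = planning_dose.grid.copy_with(planning_dose.data * 1.04)
        gates = QAGates(gamma_criteria=GammaCriteria(dose_pct=2.0, dta_mm=2.0))
        qa = qa_check(np.zeros(labels.shape + (3,)), spec.landmarks_mm,
                      spec.landmarks_mm, scaled, planning_dose.grid, gates,
                      roi_mask=roi)
        assert qa.passed == (qa.gamma_pass_pct >= 90.0)
        assert qa.tre_mean_mm == 0.0

    def test_retry_hook_invoked_then_excluded(self, spec, planning, planning_dose, fraction_plus30):
        fa = fraction_plus30
        bad = fa.true_dvf + np.array([6.0, 0.0, 0.0])
        warped, _ = warp_dose(planning_dose.grid, bad)
        calls = []

        def hook(dvf, wd, attempt):
            calls.append(attempt)
            return dvf, wd  # no improvement

        _, labels = planning
        roi = pelvic_roi(labels["body"], labels["ptv"], spec.spacing)
        qa = qa_check(bad, spec.landmarks_mm, fa.landmarks_mm, warped,
                      planning_dose.grid, QAGates(max_retries=2), roi_mask=roi,
                      retry_hook=hook)
        assert calls == [0, 1]
        assert qa.retries == 2 and qa.excluded


class TestAccumulate:
    def test_25_uniform_fractions_sum_to_50(self):
        frac = VoxelGrid(np.full((8, 8, 8), 2.0))
        acc = accumulate([frac] * 25)
        np.testing.assert_allclose(acc.dose.data, 50.0)
        assert acc.n_fractions == 25

    def test_single_fraction_unchanged(self, rng):
        frac = VoxelGrid(rng.uniform(0, 2, (8, 8, 8)))
        acc = accumulate([frac])
        np.testing.assert_array_equal(acc.dose.data, frac.data)

    def test_matches_per_voxel_loop_oracle(self, rng):
        fracs = [VoxelGrid(rng.uniform(0, 2, (5, 5, 5))) for _ in range(7)]
        acc = accumulate(fracs)
        expected = np.zeros((5, 5, 5))
        for f in fracs:
            for idx in np.ndindex(5, 5, 5):
                expected[idx] += f.data[idx]
        np.testing.assert_allclose(acc.dose.data, expected, atol=1e-12)

    def test_linearity(self, rng):
        a = [VoxelGrid(rng.uniform(0, 2, (6, 6, 6))) for _ in range(3)]
        b = [VoxelGrid(rng.uniform(0, 2, (6, 6, 6))) for _ in range(4)]
        lhs = accumulate(a).dose.data + accumulate(b).dose.data
        rhs = accumulate(a + b).dose.data
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError):
            accumulate([VoxelGrid(np.zeros((4, 4, 4)), spacing=(2, 2, 2)),
                        VoxelGrid(np.zeros((4, 4, 4)), spacing=(3, 3, 3))])
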