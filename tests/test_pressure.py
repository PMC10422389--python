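"""Force/CoP computation, stance detection, registration, segmentation."""

import numpy as np
import pytest
from scipy.spatial import Delaunay

import footkinetics as fk
from footkinetics.errors import NoStanceError, ValidationError
from footkinetics.pressure import (
    RigidTransform2D,
    detect_stance,
    frame_force_cop,
    register_cop,
    register_insole,
    segment_cells,
    segmented_forces,
    sequence_forces,
    stance_threshold,
)
from footkinetics.kinematics import joint_center


def _geom(n_rows, n_cols, pitch=0.01, origin=(0.0, 0.0)):
    return fk.GridGeometry(n_rows=n_rows, n_cols=n_cols, pitch_x=pitch,
                           pitch_y=pitch, origin=origin)


class TestFrameForce:
    def test_single_cell(self):
        geom = _geom(1, 1, origin=(0.05, 0.10))
        ff = frame_force_cop(np.array([[100.0]]), geom)
        assert np.isclose(ff.f_normal, 10.0)  # 100 kPa over 1 cm^2
        np.testing.assert_allclose(ff.cop, [0.05, 0.10])

    def test_symmetric_cells(self):
        geom = _geom(3, 1, origin=(0.0, 0.0))
        frame = np.array([[50.0], [0.0], [50.0]])  # y = 0 and y = 0.02
        ff = frame_force_cop(frame, geom)
        assert np.isclose(ff.cop[1], 0.01)

    def test_weighted_mean(self):
        geom = _geom(2, 1, origin=(0.0, 0.0))
        ff = frame_force_cop(np.array([[100.0], [300.0]]), geom)
        assert np.isclose(ff.f_normal, 40.0)
        assert np.isclose(ff.cop[1], 0.0075)

    def test_all_zero_frame_flagged(self):
        ff = frame_force_cop(np.zeros((3, 3)), _geom(3, 3))
        assert ff.f_normal == 0.0
        assert not ff.defined
        assert np.isnan(ff.cop).all()

    def test_cop_in_convex_hull_of_active_cells(self, rng):
        geom = _geom(8, 8)
        centers = geom.cell_centers().reshape(-1, 2)
        for _ in range(50):
            frame = np.where(rng.random((8, 8)) < 0.3, rng.uniform(10, 500, (8, 8)), 0.0)
            if (frame > 0).sum() < 4:
                continue
            ff = frame_force_cop(frame, geom)
            pts = centers[(frame > 0).ravel()]
            if np.linalg.matrix_rank(pts - pts[0]) < 2:
                continue
            assert Delaunay(pts).find_simplex(ff.cop) >= 0


class TestStance:
    def test_stated_example(self):
        assert detect_stance(np.array([0, 0, 50, 80, 60, 0.0]), 10.0, 2) == (2, 4)

    def test_all_zero_raises(self):
        with pytest.raises(NoStanceError):
            detect_stance(np.zeros(20), 10.0, 3)

    def test_longest_run_wins(self):
        f = np.array([0, 20, 20, 0, 30, 30, 30, 30, 0.0])
        assert detect_stance(f, 10.0, 2) == (4, 7)

    def test_synthetic_onset_within_two_frames(self, noiseless_trial):
        trial, gt = noiseless_trial
        total, _ = sequence_forces(trial.platform)
        onset, offset = detect_stance(total, stance_threshold(trial.meta.body_mass))
        assert abs(onset - gt.contact[0]) <= 2
        assert abs(offset - gt.contact[1]) <= 2


class TestRegistration:
    def test_identity_when_cops_match_and_angle_zero(self):
        tr = register_cop(np.array([0.1, 0.2]), np.array([0.1, 0.2]), 0.0)
        assert tr.theta == 0.0
        np.testing.assert_allclose(tr.t, 0.0, atol=1e-15)

    def test_transform_apply_inverse_identity(self, rng):
        for _ in range(20):
            tr = RigidTransform2D(rng.uniform(-3, 3), rng.normal(size=2))
            pts = rng.normal(size=(7, 2))
            np.testing.assert_allclose(tr.inverse().apply(tr.apply(pts)), pts,
                                       atol=1e-12)

    def test_exact_recovery_on_continuous_cops(self):
        model = fk.default_model(noise_sd=0.0, theta=np.deg2rad(10.0),
                                 heel_pos=(0.03, -0.12))
        gt = fk.ground_truth(model)
        tr = register_cop(gt.total_cop_foot[10], gt.total_cop_global[10], model.theta)
        assert abs(tr.theta - model.theta) < 1e-9
        np.testing.assert_allclose(tr.t, model.heel_pos, atol=1e-9)

    def test_grid_recovery_within_one_pitch(self):
        model = fk.default_model(noise_sd=0.0, theta=np.deg2rad(10.0),
                                 heel_pos=(0.03, -0.12))
        trial, gt = fk.simulate_trial(model)
        total, _ = sequence_forces(trial.platform)
        onset, _ = detect_stance(total, stance_threshold(model.body_mass))
        tr = register_insole(trial.insole, trial.platform, trial.markers, onset)
        assert abs(tr.theta - model.theta) < 1e-9  # markers are noiseless
        assert np.linalg.norm(tr.t - np.asarray(model.heel_pos)) <= model.insole_pitch
        # post-registration CoP trajectories agree within one insole pitch RMS
        # over the loaded part of stance (near-zero-force edge frames sit at
        # the sensing floor, where a CoP comparison is meaningless)
        f_p, cop_p = sequence_forces(trial.platform)
        f_i, cop_i_loc = sequence_forces(trial.insole)
        loaded = (f_p > 0.05 * f_p.max()) & (f_i > 0.05 * f_i.max())
        cop_i = tr.apply(cop_i_loc[loaded])
        d = np.linalg.norm(cop_i - cop_p[loaded], axis=1)
        assert np.sqrt(np.mean(d**2)) <= model.insole_pitch


class TestSegmentation:
    JC = {"ankle": 0.05, "MT": 0.15, "MP": 0.22}
    AXIS = np.array([0.0, 1.0])

    def _geom_1d(self, ys):
        # a 1-column grid whose rows sit at the given y coordinates
        pitch = ys[1] - ys[0]
        return fk.GridGeometry(n_rows=len(ys), n_cols=1, pitch_x=0.01,
                               pitch_y=pitch, origin=(0.0, ys[0]))

    def test_between_mt_and_mp_is_forefoot(self):
        geom = self._geom_1d([0.18, 0.19])
        masks = segment_cells(np.array([[100.0], [0.0]]), geom, self.JC, self.AXIS)
        assert masks["forefoot"][0, 0]
        assert not masks["hindfoot"][0, 0] and not masks["hallux"][0, 0]

    def test_boundary_cell_goes_distal(self):
        geom = self._geom_1d([0.15, 0.16])
        masks = segment_cells(np.array([[100.0], [0.0]]), geom, self.JC, self.AXIS)
        assert masks["forefoot"][0, 0]

    def test_beyond_mp_is_hallux(self):
        geom = self._geom_1d([0.25, 0.26])
        masks = segment_cells(np.array([[100.0], [0.0]]), geom, self.JC, self.AXIS)
        assert masks["hallux"][0, 0]

    def test_unordered_joint_coords_rejected(self):
        geom = self._geom_1d([0.1, 0.2])
        with pytest.raises(ValidationError):
            segment_cells(np.ones((2, 1)), geom,
                          {"ankle": 0.3, "MT": 0.2, "MP": 0.1}, self.AXIS)

    def test_masks_partition_active_cells(self, rng):
        geom = _geom(10, 10)
        frame = np.where(rng.random((10, 10)) < 0.5, rng.uniform(5, 300, (10, 10)), 0.0)
        masks = segment_cells(frame, geom, {"ankle": 0.01, "MT": 0.04, "MP": 0.07},
                              self.AXIS)
        combined = masks["hindfoot"] | masks["forefoot"] | masks["hallux"]
        np.testing.assert_array_equal(combined, frame > 0)
        assert not (masks["hindfoot"] & masks["forefoot"]).any()
        assert not (masks["forefoot"] & masks["hallux"]).any()


class TestSegmentedForces:
    def test_heel_only_pressure_loads_only_ankle(self, noiseless_model):
        import dataclasses

        from footkinetics.synthetic import LoadSchedule, simulate_trial

        # keep every blob but the heel switched off: all load stays posterior
        model = dataclasses.replace(
            noiseless_model,
            schedule=LoadSchedule(heel_off=(98.0, 99.0), met_on=(98.5, 99.5),
                                  met_off=(99.6, 100.0), hallux_on=(98.5, 99.5)),
        )
        trial, gt = simulate_trial(model)
        on, off = gt.stance
        jc = {j: joint_center(trial.markers, j) for j in ("ankle", "MT", "MP")}
        seg = segmented_forces(trial.platform, jc, (on, off - 3),
                               markers=trial.markers)
        assert np.allclose(seg["MT"].f_normal[:-5], 0.0)
        assert np.allclose(seg["MP"].f_normal[:-5], 0.0)
        assert seg["ankle"].f_normal.max() > 100.0

    def test_nesting_and_conservation(self, noiseless_trial):
        trial, gt = noiseless_trial
        on, off = gt.stance
        jc = {j: joint_center(trial.markers, j) for j in ("ankle", "MT", "MP")}
        seg = segmented_forces(trial.platform, jc, (on, off), markers=trial.markers)
        assert np.all(seg["MP"].f_normal <= seg["MT"].f_normal + 1e-9)
        assert np.all(seg["MT"].f_normal <= seg["ankle"].f_normal + 1e-9)
        total, _ = sequence_forces(trial.platform)
        np.testing.assert_allclose(seg["ankle"].f_normal, total[on : off + 1],
                                   rtol=1e-12)

    def test_segmented_forces_match_ground_truth(self, noiseless_trial):
        trial, gt = noiseless_trial
        on, off = gt.stance
        jc = {j: joint_center(trial.markers, j) for j in ("ankle", "MT", "MP")}
        seg = segmented_forces(trial.platform, jc, (on, off), markers=trial.markers)
        for joint in ("ankle", "MT", "MP"):
            ref = gt.seg_force[joint]
            rms = np.sqrt(np.mean((seg[joint].f_normal - ref) ** 2))
            assert rms <= 0.05 * ref.max()

    def test_finer_grid_does_not_increase_error(self, noiseless_model, fine_grid_trial):
        import dataclasses

        def seg_rms(model, trial, gt):
            on, off = gt.stance
            jc = {j: joint_center(trial.markers, j) for j in ("ankle", "MT", "MP")}
            seg = segmented_forces(trial.platform, jc, (on, off),
                                   markers=trial.markers)
            return {
                j: np.sqrt(np.mean((seg[j].f_normal - gt.seg_force[j]) ** 2))
                for j in ("ankle", "MT", "MP")
            }

        coarse_trial, coarse_gt = fk.simulate_trial(noiseless_model)
        fine_model, fine_trial, fine_gt = fine_grid_trial
        coarse = seg_rms(noiseless_model, coarse_trial, coarse_gt)
        fine = seg_rms(fine_model, fine_trial, fine_gt)
        for joint in ("ankle", "MT", "MP"):
            assert fine[joint] <= coarse[joint] + 1e-9
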