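"""The synthetic trial generator and its continuous-field ground truth."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import spearmanr

import footkinetics as fk
from footkinetics.errors import ValidationError
from footkinetics.synthetic import Blob, LoadSchedule, ground_truth


class TestModelValidation:
    def test_joint_fraction_ordering_enforced(self):
        with pytest.raises(ValidationError):
            fk.default_model(mt_frac=0.8, mp_frac=0.5)

    def test_nonpositive_bias_rejected(self):
        with pytest.raises(ValidationError):
            fk.default_model(insole_bias=0.0)

    def test_weights_nonnegative_and_normalized(self):
        s = np.linspace(0, 100, 501)
        w = LoadSchedule().weights(s)
        assert np.all(w >= 0)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, rtol=1e-12)


class TestSimulateTrial:
    def test_fixed_seed_bitwise_deterministic(self):
        model = fk.default_model(seed=42, noise_sd=5.0)
        t1, _ = fk.simulate_trial(model, with_ground_truth=False)
        t2, _ = fk.simulate_trial(model, with_ground_truth=False)
        np.testing.assert_array_equal(t1.platform.frames, t2.platform.frames)
        np.testing.assert_array_equal(t1.insole.frames, t2.insole.frames)
        np.testing.assert_array_equal(t1.markers.positions, t2.markers.positions)

    def test_load_posterior_to_mt_gives_zero_distal_force(self, noiseless_model):
        # hold all load on the (truncated) heel blob until 30 % stance: the
        # blob's support ends posterior to the MT line, so distal forces
        # vanish exactly on that interval
        model = dataclasses.replace(
            noiseless_model,
            schedule=LoadSchedule(heel_off=(35.0, 60.0), met_on=(30.0, 45.0),
                                  met_off=(80.0, 100.0), hallux_on=(65.0, 90.0)),
        )
        gt = ground_truth(model)
        s = model.stance_percent()
        early = s < 30.0
        assert np.all(gt.seg_force["MT"][early] == 0.0)
        assert np.all(gt.seg_force["MP"][early] == 0.0)
        assert gt.seg_force["ankle"][early].max() > 0

    def test_platform_peak_force_within_two_percent_of_profile(self, noiseless_trial):
        trial, gt = noiseless_trial
        sampled = (trial.platform.frames.sum(axis=(1, 2))
                   * trial.platform.geometry.cell_area * 1000.0)
        assert sampled.max() == pytest.approx(gt.peak_force, rel=0.02)

    def test_both_grids_sample_one_field(self, noiseless_trial):
        # total force seen by the two devices agrees up to discretization
        trial, gt = noiseless_trial
        on, off = gt.stance
        fp = (trial.platform.frames.sum(axis=(1, 2))
              * trial.platform.geometry.cell_area * 1000.0)
        fi = (trial.insole.frames.sum(axis=(1, 2))
              * trial.insole.geometry.cell_area * 1000.0)
        assert fp[on:off + 1].max() == pytest.approx(fi[on:off + 1].max(), rel=0.02)

    def test_cop_progresses_heel_to_toe(self, noiseless_trial):
        trial, gt = noiseless_trial
        y = gt.total_cop_foot[:, 1]
        assert y[0] < 0.06  # starts near the heel
        assert y[-1] > y[0] + 0.1  # ends > 10 cm anterior
        assert np.all(np.diff(y) >= -1e-9)  # monotone progression


class TestGroundTruth:
    def test_quadrature_refinement_converges(self, noiseless_model):
        g1 = ground_truth(noiseless_model, quad_step=0.001)
        g2 = ground_truth(noiseless_model, quad_step=0.0005)
        a1 = g1.moment_curves["ankle"].dfpf
        a2 = g2.moment_curves["ankle"].dfpf
        assert np.abs(a1 - a2).max() <= 0.001 * np.abs(a2).max()

    def test_doubling_grf_doubles_moments(self, noiseless_model):
        prof = noiseless_model.profile
        doubled = dataclasses.replace(
            noiseless_model,
            profile=dataclasses.replace(prof, peak1=2 * prof.peak1,
                                        peak2=2 * prof.peak2,
                                        valley=2 * prof.valley),
        )
        g1 = ground_truth(noiseless_model)
        g2 = ground_truth(doubled)
        for joint in ("ankle", "MT", "MP"):
            np.testing.assert_allclose(g2.moment_curves[joint].dfpf,
                                       2 * g1.moment_curves[joint].dfpf,
                                       rtol=1e-9, atol=1e-12)

    def test_laterally_centered_load_gives_no_frontal_moment(self):
        # all blobs on the foot axis and joint centers on the axis: the CoP
        # never deviates laterally, so the global frontal moment vanishes
        model = fk.default_model(
            noise_sd=0.0, theta=0.0, heel_pos=(0.0, -0.13),
            blobs=(Blob(0.0, 0.14, 0.058), Blob(0.0, 0.70, 0.058),
                   Blob(0.0, 0.90, 0.042)),
        )
        gt = ground_truth(model)
        for joint in ("ankle", "MT", "MP"):
            cop_x = gt.seg_cop_global[joint][:, 0]
            f = gt.seg_force[joint]
            # 1 mm quadrature leaves a few microns of grid asymmetry
            assert np.nanmax(np.abs(cop_x[f > 0])) < 1e-5


class TestDevicePair:
    def test_unbiased_pair_agrees_within_discretization(self, noiseless_model):
        tp, ti = fk.make_device_pair(noiseless_model, insole_bias=1.0)
        a = fk.process_trial(tp, "platform").moments["ankle"].dfpf.max()
        b = fk.process_trial(ti, "insole").moments["ankle"].dfpf.max()
        assert abs(a - b) / a <= 0.03

    def test_bias_translates_to_peak_difference(self, noiseless_model):
        tp, ti = fk.make_device_pair(noiseless_model, insole_bias=0.9)
        a = fk.process_trial(tp, "platform").moments["ankle"].dfpf.max()
        b = fk.process_trial(ti, "insole").moments["ankle"].dfpf.max()
        assert 100.0 * (a - b) / a == pytest.approx(10.0, abs=1.5)

    def test_unit_bias_identical_insole_streams(self, noiseless_model):
        tp, ti = fk.make_device_pair(noiseless_model, insole_bias=1.0)
        np.testing.assert_array_equal(tp.insole.frames, ti.insole.frames)


class TestNoiseRobustness:
    def test_recovery_error_grows_with_noise(self):
        # pooled over seeds: Spearman correlation between noise level and
        # ankle peak-moment recovery error is positive
        levels = [0.0, 10.0, 30.0, 80.0]
        xs, ys = [], []
        for seed in range(20):
            gt_peak = None
            for sd in levels:
                model = fk.default_model(noise_sd=sd, seed=seed)
                if gt_peak is None:
                    gt_peak = ground_truth(model).moment_curves["ankle"].dfpf.max()
                trial, _ = fk.simulate_trial(model, with_ground_truth=False)
                got = fk.process_trial(trial, "platform").moments["ankle"].dfpf.max()
                xs.append(sd)
                ys.append(abs(got - gt_peak))
        rho = spearmanr(xs, ys).statistic
        assert rho > 0
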