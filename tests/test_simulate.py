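"""Simulator: RR statistics, generating model, scene, k-space, ECG, HDF5."""

import dataclasses

import numpy as np
import pytest

from pacmri import io, recon, simulate
from pacmri.config import AcquisitionConfig, SubjectConfig
from pacmri.errors import SimulationError


class TestRRSequence:
    def test_zero_variance_gives_constant_rr(self):
        cfg = SubjectConfig(seed=0, sd_hr=0.0, mean_hr=60.0, n_beats=5, ectopic_rate=0.0)
        rr, ect = simulate.simulate_rr_sequence(cfg)
        assert np.allclose(rr, 1.000)
        assert not ect.any()

    def test_marginal_statistics_many_beats(self):
        # Law-of-large-numbers check on the stationary marginal.
        cfg = SubjectConfig(seed=3, n_beats=30000, ectopic_rate=0.0)
        rr, _ = simulate.simulate_rr_sequence(cfg)
        hr = 60.0 / rr
        assert abs(hr.mean() - 67.0) < 3.0
        assert abs(hr.std() - 9.5) < 1.5
        assert hr.min() >= 44.0 and hr.max() <= 114.0

    def test_ectopic_differs_from_median_and_predecessor(self):
        cfg = SubjectConfig(seed=5, ectopic_rate=0.15)
        rr, ect = simulate.simulate_rr_sequence(cfg)
        assert ect.sum() >= 1
        med = np.median(rr[~ect])
        for i in np.flatnonzero(ect):
            assert abs(rr[i] - med) > 0.2 * med
            assert abs(rr[i] - rr[i - 1]) > 0.2 * rr[i - 1]

    def test_degenerate_bounds_raise(self):
        cfg = SubjectConfig(seed=0, mean_hr=67.0, sd_hr=0.5, hr_bounds=(110.0, 114.0))
        with pytest.raises(SimulationError):
            simulate.simulate_rr_sequence(cfg)

    def test_determinism(self):
        cfg = SubjectConfig(seed=42)
        rr1, e1 = simulate.simulate_rr_sequence(cfg)
        rr2, e2 = simulate.simulate_rr_sequence(cfg)
        assert np.array_equal(rr1, rr2) and np.array_equal(e1, e2)


class TestEndSystole:
    def test_global_constants_at_60_bpm(self):
        cfg = SubjectConfig(
            seed=0, true_slope=-0.0018, true_intercept=0.456, residual_sd=0.0
        )
        s = simulate.true_end_systole(cfg, np.array([1.0]))
        assert s[0] == pytest.approx(0.348, abs=1e-12)

    def test_flat_model_constant_at_any_hr(self):
        cfg = SubjectConfig(seed=0, true_slope=0.0, true_intercept=0.3, residual_sd=0.0)
        rr = np.array([0.6, 0.9, 1.2])
        assert np.allclose(simulate.true_end_systole(cfg, rr), 0.3)

    def test_residual_sd_monte_carlo(self):
        cfg = SubjectConfig(seed=9, residual_sd=0.014)
        s = simulate.true_end_systole(cfg, np.full(100_000, 60.0 / 67.0))
        assert s.std() == pytest.approx(0.014, abs=0.001)

    def test_inconsistent_config_raises(self):
        cfg = SubjectConfig(seed=0, true_slope=0.0, true_intercept=0.7, residual_sd=0.0)
        with pytest.raises(SimulationError):
            simulate.true_end_systole(cfg, np.array([0.5]))


class TestScene:
    def test_noise_free_zero_outside_vessels(self, clean_subject):
        scene, truth = clean_subject.scene, clean_subject.truth
        vessel = np.concatenate([truth.aorta_pixels] + truth.confounder_pixels)
        outside = np.setdiff1d(np.arange(scene.velocity.shape[0]), vessel)
        assert np.all(scene.velocity[outside, :] == 0.0)

    def test_aorta_positive_at_mid_systole(self, clean_subject):
        scene, truth = clean_subject.scene, clean_subject.truth
        mid = truth.r_times + 0.5 * truth.end_systole_s
        frames = np.searchsorted(scene.times, mid)
        centre = truth.aorta_pixels[len(truth.aorta_pixels) // 2]
        assert np.all(scene.velocity[centre, frames] > 0)

    def test_forward_flow_ends_at_true_end_systole(self, clean_subject):
        # Last positive aortic sample of each cycle within one frame of R + S_i.
        scene, truth = clean_subject.scene, clean_subject.truth
        centre = truth.aorta_pixels[len(truth.aorta_pixels) // 2]
        v = scene.velocity[centre, :]
        for r, rr, s in zip(truth.r_times, truth.rr_durations, truth.end_systole_s):
            m = (scene.times >= r) & (scene.times < r + rr)
            pos = scene.times[m][v[m] > 1e-9]
            assert abs(pos.max() - (r + s)) <= scene.dt + 1e-12


class TestKSpace:
    def test_round_trip_recovers_scene(self, clean_subject):
        vmap = recon.reconstruct(clean_subject.echoes, fov_fraction=1.0)
        scene = clean_subject.scene
        expected = 0.5 * (scene.velocity[:, :-1] + scene.velocity[:, 1:])
        venc = clean_subject.acq.venc_cm_s
        assert np.abs(vmap.velocity - expected).max() < 1e-6 * venc

    def test_zero_scene_gives_zero_phase_difference(self, acq):
        n = acq.matrix_freq
        scene = simulate.VelocityScene(
            velocity=np.zeros((n, 6)),
            magnitude=np.ones((n, 6)),
            times=np.arange(6) * acq.tr_s,
            dt=acq.tr_s,
        )
        echoes = simulate.render_kspace_lines(scene, acq)
        image = np.fft.fft(echoes.samples, axis=-1, norm="ortho")
        pair = image[:, 1:, :] * np.conj(image[:, :-1, :])
        assert np.abs(np.angle(pair)).max() < 1e-12

    def test_half_venc_gives_half_pi_pair_phase(self, acq):
        n = acq.matrix_freq
        v = np.zeros((n, 4))
        v[100, :] = acq.venc_cm_s / 2.0
        scene = simulate.VelocityScene(
            velocity=v, magnitude=np.ones((n, 4)), times=np.arange(4) * acq.tr_s, dt=acq.tr_s
        )
        echoes = simulate.render_kspace_lines(scene, acq)
        image = np.fft.fft(echoes.samples, axis=-1, norm="ortho")
        pair_phase = np.angle(image[:, 1, :] * np.conj(image[:, 0, :]))
        assert abs(abs(pair_phase[0, 100]) - np.pi / 2) < 1e-9
        assert np.abs(pair_phase[0, :100]).max() < 1e-9

    def test_toggle_alternates_and_spacing_is_tr(self, clean_subject):
        e = clean_subject.echoes
        assert np.all(e.venc_toggle[1:] != e.venc_toggle[:-1])
        assert np.allclose(np.diff(e.echo_times), e.config.tr_s)


class TestECG:
    def test_ideal_ecg_detections_equal_truth(self):
        cfg = SubjectConfig(
            seed=21, noise_sd=0.0, r_jitter_sd=0.0, mhd_amplitude=0.0, ectopic_rate=0.0
        )
        subj = simulate.simulate_subject(cfg)
        truth_all = np.concatenate(
            [subj.truth.r_times, [subj.truth.r_times[-1] + subj.truth.rr_durations[-1]]]
        )
        assert np.allclose(subj.ecg.online_detections, truth_all)

    def test_mhd_deflection_inside_ejection_window(self):
        base = dict(seed=22, noise_sd=0.0, r_jitter_sd=0.0, ectopic_rate=0.0)
        with_mhd = simulate.simulate_subject(SubjectConfig(mhd_amplitude=0.4, **base))
        without = simulate.simulate_subject(SubjectConfig(mhd_amplitude=0.0, **base))
        diff = np.abs(with_mhd.ecg.samples - without.ecg.samples).sum(axis=0)
        t = with_mhd.ecg.times
        truth = with_mhd.truth
        inside = np.zeros(len(t), dtype=bool)
        for r, s in zip(truth.r_times, truth.end_systole_s):
            inside |= (t > r) & (t < r + s)
        assert diff[inside].max() > 0.3
        assert diff[~inside].max() < 1e-9

    def test_jitter_rms_matches_config(self):
        devs = []
        for seed in range(4):
            cfg = SubjectConfig(seed=seed, r_jitter_sd=0.010, ectopic_rate=0.0)
            subj = simulate.simulate_subject(cfg)
            truth_all = np.concatenate(
                [subj.truth.r_times, [subj.truth.r_times[-1] + subj.truth.rr_durations[-1]]]
            )
            devs.append(subj.ecg.online_detections - truth_all)
        rms = np.sqrt(np.mean(np.concatenate(devs) ** 2))
        assert rms == pytest.approx(0.010, abs=0.002)


class TestSubjectContainer:
    def test_bit_identical_under_same_seed(self):
        cfg = SubjectConfig(seed=33, n_beats=12)
        a = simulate.simulate_subject(cfg)
        b = simulate.simulate_subject(cfg)
        assert np.array_equal(a.echoes.samples, b.echoes.samples)
        assert np.array_equal(a.ecg.samples, b.ecg.samples)
        assert np.array_equal(a.truth.end_systole_s, b.truth.end_systole_s)

    def test_hdf5_round_trip(self, tmp_path):
        cfg = SubjectConfig(seed=34, n_beats=8)
        subj = simulate.simulate_subject(cfg)
        path = str(tmp_path / "subject.h5")
        io.save_subject(path, subj)
        back = io.load_subject(path)
        assert back.config == subj.config
        assert back.acq == subj.acq
        assert np.array_equal(back.echoes.samples, subj.echoes.samples)
        assert np.array_equal(back.ecg.online_detections, subj.ecg.online_detections)
        assert np.array_equal(back.truth.aorta_pixels, subj.truth.aorta_pixels)
        assert len(back.truth.confounder_pixels) == len(subj.truth.confounder_pixels)

    def test_cohort_subjects_differ(self):
        subjects = simulate.simulate_cohort(3, seed=1, n_beats=8)
        seeds = {s.config.seed for s in subjects}
        assert len(seeds) == 3
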