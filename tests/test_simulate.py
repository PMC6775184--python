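import numpy as np
import pytest

from arrayemg.kinematics import FINGERS, T_EXTENSION, T_FLEXION
from arrayemg.models import msm_torque
from arrayemg.simulate import (
    BASELINE,
    SimConfig,
    _truth_series,
    draw_subject_params,
    generate_activations,
    generate_protocol,
    make_subject,
    motion_cycles,
    source_mixing,
    synthesize_emg,
)


class TestProtocol:
    def test_train_experiment_has_six_8s_motions(self):
        cfg = SimConfig()
        sched = generate_protocol(cfg, "train", "Thumb")
        assert motion_cycles(sched) == 6
        moves = sched.movement_phases()
        assert all(p.finger == "Thumb" for p in moves)
        # each motion cycle spans flex+rest+ext+rest = 8 s
        assert sched.duration == pytest.approx(cfg.calibration_len + 6 * 8.0)

    def test_test_experiment_cycles_all_fingers_twice(self):
        sched = generate_protocol(SimConfig(), "test")
        assert motion_cycles(sched) == 10
        seq = [p.finger for p in sched.phases if p.kind == "flexion"]
        assert seq == [f for f in FINGERS for _ in range(2)]

    def test_calibration_rest_opens_every_experiment(self):
        sched = generate_protocol(SimConfig(), "train", "Pinky")
        first = sched.phases[0]
        assert first.kind == "rest" and first.start == 0.0 and first.end == 4.0

    def test_degenerate_duration_rejected(self):
        with pytest.raises(ValueError):
            generate_protocol(SimConfig(phase_len=0.0), "train", "Thumb")

    def test_unknown_finger_rejected(self):
        with pytest.raises(ValueError, match="finger"):
            generate_protocol(SimConfig(), "train", "Hallux")

    def test_trigger_codes_align_to_phase_boundaries(self):
        cfg = SimConfig(fs_raw=1024.0)
        sched = generate_protocol(cfg, "train", "Index")
        code = sched.trigger_code(cfg.fs_raw)
        i0 = int(cfg.calibration_len * cfg.fs_raw)
        assert np.all(code[:i0] == 0)
        assert code[i0] == 2  # Index flexion starts exactly at the boundary
        assert code[i0 - 1] == 0


class TestActivations:
    def test_rest_only_schedule_stays_at_baseline(self):
        cfg = SimConfig(fs_raw=1024.0, motions_per_train_exp=1)
        sched = generate_protocol(cfg, "train", "Thumb")
        rest_only = type(sched)([sched.phases[0]])
        u = generate_activations(rest_only, cfg, rng_seed=0)
        assert np.allclose(u, BASELINE)

    def test_no_crosstalk_isolates_instructed_finger(self):
        cfg = SimConfig(fs_raw=1024.0, motions_per_train_exp=2, crosstalk=0.0)
        sched = generate_protocol(cfg, "train", "Thumb")
        u = generate_activations(sched, cfg, rng_seed=1)
        thumb = FINGERS.index("Thumb")
        for i in range(len(FINGERS)):
            if i != thumb:
                assert np.allclose(u[:, i], BASELINE)
        assert u[0, thumb].max() > 0.9

    def test_crosstalk_scales_adjacent_finger_exactly(self):
        cfg = SimConfig(fs_raw=1024.0, motions_per_train_exp=2, crosstalk=0.2)
        sched = generate_protocol(cfg, "train", "Thumb")
        u = generate_activations(sched, cfg, rng_seed=2)
        thumb, index = FINGERS.index("Thumb"), FINGERS.index("Index")
        assert u[0, index].max() == pytest.approx(0.2 * u[0, thumb].max())

    def test_amplitudes_stay_in_unit_interval(self):
        cfg = SimConfig(fs_raw=1024.0, motions_per_train_exp=2, crosstalk=0.3)
        sched = generate_protocol(cfg, "test")
        u = generate_activations(sched, cfg, rng_seed=3)
        assert np.all(u >= 0) and np.all(u <= 1)

    def test_deterministic_given_seed(self):
        cfg = SimConfig(fs_raw=1024.0, motions_per_train_exp=1)
        sched = generate_protocol(cfg, "train", "Middle")
        a = generate_activations(sched, cfg, rng_seed=9)
        b = generate_activations(sched, cfg, rng_seed=9)
        assert np.array_equal(a, b)


class TestTruth:
    def test_angles_are_equilibria_of_true_params(self):
        cfg = SimConfig(fs_raw=1024.0, motions_per_train_exp=2)
        sched = generate_protocol(cfg, "train", "Ring")
        params = draw_subject_params(np.random.default_rng(0))
        acts = generate_activations(sched, cfg, rng_seed=4)
        u, angles, _ = _truth_series(acts, params, sched, cfg)
        for i, p in enumerate(params):
            tau = msm_torque(u[0, i], u[1, i], angles[i], p)
            assert np.max(np.abs(tau)) <= 1e-8

    def test_peak_angles_reach_trigger_targets(self):
        params = draw_subject_params(np.random.default_rng(1))
        from arrayemg.models import msm_equilibrium

        for p in params:
            assert msm_equilibrium(1.0, BASELINE, p) == pytest.approx(T_FLEXION, abs=1e-9)
            assert msm_equilibrium(BASELINE, 1.0, p) == pytest.approx(T_EXTENSION, abs=1e-9)
            assert msm_equilibrium(BASELINE, BASELINE, p) == pytest.approx(0.0, abs=1e-9)

    def test_nrmsd_lies_in_unit_interval_and_vanishes_at_rest(self):
        cfg = SimConfig(fs_raw=1024.0, motions_per_train_exp=2)
        sched = generate_protocol(cfg, "train", "Index")
        params = draw_subject_params(np.random.default_rng(2))
        acts = generate_activations(sched, cfg, rng_seed=5)
        _, _, nrmsd = _truth_series(acts, params, sched, cfg)
        assert np.all(nrmsd >= 0) and np.all(nrmsd <= 1)
        from arrayemg.simulate import FS_TRUTH

        tdir = sched.tdir_series(FS_TRUTH, nrmsd.shape[1])
        assert np.allclose(nrmsd[tdir == 0], 0.0)


class TestSynthesis:
    def test_output_shape_matches_layout_and_schedule(self, layout, small_cfg):
        sched = generate_protocol(small_cfg, "train", "Thumb")
        acts = generate_activations(sched, small_cfg, rng_seed=0)
        rec = synthesize_emg(acts, sched, layout, small_cfg, rng_seed=1)
        assert rec.data.shape == (96, int(sched.duration * small_cfg.fs_raw))
        assert rec.trigger is not None and rec.trigger.size == rec.n_samples

    def test_one_hot_mixing_reproduces_source(self, layout, small_cfg):
        import dataclasses

        cfg = dataclasses.replace(small_cfg, snr_db=300.0, artifact_level=0.0, line_freq=50.0)
        sched = generate_protocol(cfg, "train", "Thumb")
        acts = generate_activations(sched, cfg, rng_seed=0)
        mixing = np.zeros((96, 10))
        mixing[17, 0] = 1.0
        rec, parts = synthesize_emg(acts, sched, layout, cfg, rng_seed=1,
                                    mixing=mixing, return_parts=True)
        resid = rec.data[17] - parts["sources"][0] - parts["line"][17]
        assert np.abs(resid).max() < 1e-6 * np.abs(parts["sources"][0]).max()

    def test_mixing_dimension_mismatch_rejected(self, layout, small_cfg):
        sched = generate_protocol(small_cfg, "train", "Thumb")
        acts = generate_activations(sched, small_cfg, rng_seed=0)
        with pytest.raises(ValueError, match="mixing"):
            synthesize_emg(acts, sched, layout, small_cfg, rng_seed=1,
                           mixing=np.zeros((96, 3)))

    def test_broadband_snr_matches_request_within_1db(self, layout, small_cfg):
        import dataclasses

        cfg = dataclasses.replace(small_cfg, motions_per_train_exp=1)
        sched = generate_protocol(cfg, "train", "Middle")
        acts = generate_activations(sched, cfg, rng_seed=0)
        errs = []
        for seed in range(10):
            _, parts = synthesize_emg(acts, sched, layout, cfg, rng_seed=seed,
                                      return_parts=True)
            measured = 10 * np.log10(np.mean(parts["clean"] ** 2) / np.mean(parts["noise"] ** 2))
            errs.append(measured - cfg.snr_db)
        assert np.max(np.abs(errs)) < 1.0

    def test_flexor_sources_project_only_to_flexor_panel(self, layout):
        mixing, locations = source_mixing(layout)
        flexor_idx = [layout.index_of(l) for l in layout.side_labels("flexor")]
        extensor_idx = [layout.index_of(l) for l in layout.side_labels("extensor")]
        for s in range(5):  # flexor sources (blob centres sit between electrodes)
            assert mixing[flexor_idx, s].max() > 0.85
            assert np.allclose(mixing[extensor_idx, s], 0.0)
        for s in range(5, 10):
            assert np.allclose(mixing[flexor_idx, s], 0.0)


class TestDatasets:
    def test_subject_contains_full_train_and_test_sets(self, small_cfg):
        sub = make_subject(small_cfg, 0)
        assert len(sub.train) == 5 * small_cfg.train_exps_per_finger
        fingers = [e.finger for e in sub.train]
        assert fingers == list(FINGERS)  # one per finger, Thumb->Pinky
        assert len(sub.test) == small_cfg.test_exps
        assert all(e.kind == "test" for e in sub.test)

    def test_default_config_would_build_25_train_experiments(self):
        cfg = SimConfig()
        per_subject = len(FINGERS) * cfg.train_exps_per_finger
        assert per_subject == 25  # 5 experiments per finger

    def test_same_seed_is_bit_identical(self, small_cfg):
        a = make_subject(small_cfg, 0)
        b = make_subject(small_cfg, 0)
        assert np.array_equal(a.train[0].recording.data, b.train[0].recording.data)
        assert np.array_equal(a.test[0].truth.angles, b.test[0].truth.angles)

    def test_subjects_draw_distinct_parameters(self, small_cfg):
        a = make_subject(small_cfg, 0)
        b = make_subject(small_cfg, 1)
        assert not np.allclose(a.params[0].l1, b.params[0].l1)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(crosstalk=1.5).validate()
        with pytest.raises(ValueError):
            SimConfig(fs_raw=100.0).validate()
        with pytest.raises(ValueError):
            SimConfig(test_exps=0).validate()
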