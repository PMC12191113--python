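"""The synthetic-session generator: determinism, calibration, perturbations."""

import dataclasses
import filecmp
import os

import numpy as np
import pytest

from gpekit import behavior as bhv
from gpekit import io, synth


class TestSpikeTrainGenerator:
    def test_zero_rate_empty(self):
        train = synth.generate_spike_train(lambda t: np.zeros(t.size), 10.0,
                                           seed=0)
        assert train.spike_times.size == 0

    def test_constant_rate_poisson_count(self):
        train = synth.generate_spike_train(lambda t: np.full(t.size, 50.0),
                                           100.0, seed=1, rate_max=51.0)
        assert abs(train.spike_times.size - 5000) < 3 * np.sqrt(5000)

    def test_step_rate_ratio(self):
        # 10 Hz before t=1 s, 40 Hz after: empirical ratio ~ 4
        def rate(t):
            return np.where(t < 1.0, 10.0, 40.0)
        pre = post = 0
        for seed in range(500):
            st = synth.generate_spike_train(rate, 2.0, seed=seed,
                                            rate_max=41.0).spike_times
            pre += np.sum(st < 1.0)
            post += np.sum(st >= 1.0)
        ratio = post / pre
        se = 4.0 * np.sqrt(1 / pre + 1 / post)
        assert abs(ratio - 4.0) < 3 * se

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            synth.generate_spike_train(lambda t: np.full(t.size, -1.0), 1.0,
                                       seed=0)

    def test_minimum_separation(self):
        st = synth.generate_spike_train(lambda t: np.full(t.size, 200.0),
                                        50.0, seed=2,
                                        rate_max=201.0).spike_times
        assert np.all(np.diff(st) >= 1e-4)


class TestGenerateSession:
    def test_determinism_byte_identical(self, tmp_path):
        bundles = []
        for i in range(2):
            cfg = synth.default_choice(seed=5, n_neurons_per_cluster=(2, 2, 2),
                                       n_trials=25, include_eye=True)
            s, _ = synth.generate_session(cfg)
            bundles.append(io.write_session(s, tmp_path / f"b{i}"))
        files = os.listdir(bundles[0])
        match, mismatch, errors = filecmp.cmpfiles(bundles[0], bundles[1],
                                                   files, shallow=False)
        assert not mismatch and not errors

    def test_task_timing(self, small_session):
        s, _ = small_session
        for t in s.trials:
            assert t.fp_on - t.scene_on == pytest.approx(1.0)
            assert t.target_on - t.fp_on == pytest.approx(0.7)

    def test_degenerate_gains_homogeneous_poisson(self):
        gains = tuple({"scene": 0.0, **{c: 0.0 for c in synth.CONDITIONS}}
                      for _ in range(3))
        cfg = synth.default_choice(seed=8, n_neurons_per_cluster=(3, 3, 3),
                                   n_trials=60, gain_profiles=gains,
                                   rt_coupling=(0.0, 0.0, 0.0),
                                   baseline_jitter_sd=0.0,
                                   include_waveforms=False)
        s, gt = synth.generate_session(cfg)
        for n in s.neurons:
            b = gt.baseline_of[n.neuron_id]
            emp = n.spike_times.size / s.duration
            se = np.sqrt(b / s.duration)
            assert abs(emp - b) < 3.5 * se

    def test_rt_means_match_configured(self):
        cfg = synth.default_choice(seed=9, n_neurons_per_cluster=(0, 0, 0),
                                   n_trials=10_000)
        s, _ = synth.generate_session(cfg)
        good = np.array([t.rt for t in s.trials
                         if t.object_value == "good" and t.rt is not None])
        se = good.std(ddof=1) / np.sqrt(good.size)
        assert abs(good.mean() - 193.5) < 2 * se + 0.6  # + truncation allowance

    def test_baseline_rate_calibration(self, medium_session):
        # per cluster, pooled pre-scene empirical rate within 3 SE of config
        s, gt = medium_session
        scene = s.event_times("scene")
        t_total = scene.size * 0.5
        for k, expected in zip((1, 2, 3), gt.config.baseline_hz):
            ids = [n for n, c in gt.cluster_of.items() if c == k]
            rates = []
            for nid in ids:
                st = s.neuron(nid).spike_times
                lo = np.searchsorted(st, scene - 0.5)
                hi = np.searchsorted(st, scene)
                rates.append(np.sum(hi - lo) / t_total)
            # neuron-level spread dominates: compare the cluster mean with
            # its own standard error
            se = np.std(rates, ddof=1) / np.sqrt(len(rates))
            assert abs(np.mean(rates) - expected) < 3 * se

    def test_latent_drive_rt_coupling_sign(self):
        cfg = synth.default_choice(seed=10, n_neurons_per_cluster=(0, 0, 0),
                                   n_trials=600)
        s, gt = synth.generate_session(cfg)
        rts, gs = [], []
        for t, g in zip(s.trials, gt.latent_drive):
            if t.rt is not None:
                rts.append(t.rt)
                gs.append(g)
        r = np.corrcoef(gs, rts)[0, 1]
        from scipy import stats
        n = len(rts)
        t_stat = r * np.sqrt((n - 2) / (1 - r * r))
        p = 2 * stats.t.sf(abs(t_stat), n - 2)
        assert r < 0 and p < 0.01

    def test_stay_structure_stable_vs_flexible(self):
        cfg = synth.default_choice(seed=11, n_neurons_per_cluster=(0, 0, 0),
                                   n_trials=2500)
        s, _ = synth.generate_session(cfg)
        def stay_rate(scenes):
            rej = [t for t in s.trials if t.scene in scenes
                   and t.object_value == "bad"
                   and t.response in ("return", "stay", "other")]
            return np.mean([t.response == "stay" for t in rej])
        assert stay_rate((1, 2)) > stay_rate((3, 4))

    def test_invalid_config_rejected(self):
        with pytest.raises(synth.ConfigError):
            synth.generate_session(
                synth.default_choice(baseline_hz=(0.0, 1.0, 1.0)))
        with pytest.raises(synth.ConfigError):
            bad_policy = {"stable": {"accept": 0.5, "return": 0.2,
                                     "stay": 0.2, "other": 0.2},
                          "flexible": {"accept": 0.25, "return": 0.25,
                                       "stay": 0.25, "other": 0.25}}
            synth.generate_session(
                synth.default_choice(reject_policy=bad_policy))


class TestEyeTraceGenerator:
    def test_no_saccades_below_threshold(self):
        eye = synth.generate_eye_trace([], seed=1, duration=20.0)
        assert bhv.eye_speed(eye).max() < 40.0

    def test_threshold_crossing_at_scripted_onset(self):
        eye = synth.generate_eye_trace([], seed=2, duration=3.0,
                                       saccades=[(1.180, (15.0, 0.0))])
        onset = bhv.detect_saccade(eye, 1.0)
        assert onset == pytest.approx(1.180, abs=0.002)

    def test_peak_velocity_exceeds_200(self):
        eye = synth.generate_eye_trace([], seed=3, duration=3.0,
                                       saccades=[(1.0, (15.0, 0.0))])
        assert bhv.eye_speed(eye).max() >= 200.0


class TestWaveformGenerator:
    def test_scale_invariant_standardized_shape(self):
        from gpekit.spikes import standardize_waveform
        wf1 = synth.generate_waveform(300.0, seed=4, amplitude_uv=80.0)
        wf2 = synth.generate_waveform(300.0, seed=4, amplitude_uv=800.0)
        s1, *_ = standardize_waveform(wf1)
        s2, *_ = standardize_waveform(wf2)
        assert np.allclose(s1, s2, atol=1e-12)

    def test_noiseless_extrema_are_unit(self):
        from gpekit.spikes import standardize_waveform
        std, trough, peak = standardize_waveform(
            synth.generate_waveform(300.0, seed=5))
        assert std.min() == -1.0 and std[trough] == -1.0
        assert std[peak] == 1.0


class TestInjectionEffect:
    def test_identity_at_factor_one(self):
        cfg = synth.default_choice(seed=1)
        out = synth.apply_injection_effect(cfg)
        assert out.rt_shift_ms == cfg.rt_shift_ms
        assert out.contra_return_to_stay == cfg.contra_return_to_stay
        assert out.gain_profiles == cfg.gain_profiles

    def test_factor_zero_rejected(self):
        cfg = dataclasses.replace(synth.default_choice(),
                                  injection_gain_factor=0.0)
        with pytest.raises(synth.ConfigError):
            synth.apply_injection_effect(cfg)

    def test_return_probability_drops(self):
        cfg = dataclasses.replace(synth.default_choice(seed=3),
                                  injection_gain_factor=0.4)
        post = synth.apply_injection_effect(cfg)
        assert post.contra_return_to_stay > 0
        # fixation-task error rate untouched
        assert post.fix_break_rate == cfg.fix_break_rate

    def test_post_injection_rts_longer(self):
        pre_cfg = synth.default_choice(seed=12,
                                       n_neurons_per_cluster=(0, 0, 0),
                                       n_trials=5000)
        post_cfg = synth.apply_injection_effect(
            dataclasses.replace(pre_cfg, injection_gain_factor=0.4))
        pre, _ = synth.generate_session(pre_cfg)
        post, _ = synth.generate_session(post_cfg)
        def contra_good_rt(s):
            return np.mean([t.rt for t in s.trials
                            if t.laterality == "contra"
                            and t.object_value == "good"
                            and t.rt is not None])
        assert contra_good_rt(post) > contra_good_rt(pre)


class TestPresets:
    def test_injection_layout(self):
        records = synth.injection_pre_post(seed=0)
        agents = {r["agent"] for r in records}
        assert agents == {"antagonist", "saline"}
        for agent in agents:
            sub = [r for r in records if r["agent"] == agent]
            assert len(sub) == 15  # 3 monkeys x 5 sessions
            assert len({r["monkey"] for r in sub}) == 3
        saline = [r for r in records if r["agent"] == "saline"][0]
        assert saline["post"].rt_shift_ms == (0.0, 0.0)

    def test_study_population_counts(self):
        cfgs = synth.study_population_configs()
        per_monkey = {c.monkey_id: sum(c.n_neurons_per_cluster) for c in cfgs}
        assert per_monkey == {"Cr": 111, "Sp": 94}
        cluster_totals = np.sum([c.n_neurons_per_cluster for c in cfgs],
                                axis=0)
        assert list(cluster_totals) == [58, 86, 61]
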