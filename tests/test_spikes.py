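"""PSTH computation, smoothing, Z-transform, waveform metrics, Kruskal-Dunn."""

import numpy as np
import pytest
from scipy import stats

from gpekit import spikes as sp
from gpekit import synth


class TestComputePsth:
    def test_single_spike_definition(self):
        psth = sp.compute_psth(np.array([10.0005]), np.array([10.0]),
                               (0.0, 5.0))
        assert psth.rate[0] == 1000.0
        assert np.all(psth.rate[1:] == 0.0)

    def test_empty_train_all_zero(self):
        psth = sp.compute_psth(np.array([]), np.array([1.0, 2.0]),
                               (-500.0, 500.0))
        assert np.all(psth.rate == 0.0)
        assert psth.rate.size == 1000

    def test_homogeneous_rate_recovered(self):
        rng = np.random.default_rng(0)
        events = 2.0 + 3.0 * np.arange(200)
        train = synth.generate_spike_train(lambda t: np.full(t.size, 50.0),
                                           610.0, rng=rng, rate_max=51.0)
        psth = sp.compute_psth(train.spike_times, events, (-500.0, 500.0))
        total_t = 200 * 1.0
        se = np.sqrt(50.0 / total_t)
        assert abs(psth.rate.mean() - 50.0) < 3 * se

    def test_zero_events_error(self):
        with pytest.raises(ValueError):
            sp.compute_psth(np.array([1.0]), np.array([]), (0.0, 10.0))

    def test_count_conservation(self):
        rng = np.random.default_rng(1)
        st = np.sort(rng.uniform(0, 100, 5000))
        events = np.arange(5.0, 95.0, 3.0)
        window = (-500.0, 800.0)
        psth = sp.compute_psth(st, events, window)
        expected = sum(np.sum((st >= e - 0.5) & (st < e + 0.8))
                       for e in events)
        counted = psth.rate.sum() * 1e-3 * psth.n_trials
        assert counted == pytest.approx(expected, abs=1e-6)

    def test_bin_edge_goes_right(self):
        # half-open bins: a spike exactly at a bin edge counts to the right
        psth = sp.compute_psth(np.array([10.001]), np.array([10.0]),
                               (0.0, 5.0))
        assert psth.rate[1] == 1000.0 and psth.rate[0] == 0.0


class TestSmoothing:
    def test_constant_preserved_exactly(self):
        psth = sp.PSTH(np.full(1000, 30.0), 1.0, (-500.0, 500.0), 10)
        out = sp.smooth_psth(psth, 20.0)
        assert np.allclose(out.rate, 30.0, atol=1e-12)

    def test_impulse_gives_gaussian(self):
        rate = np.zeros(1001)
        rate[500] = 1000.0  # one spike in one 1-ms bin of a single trial
        psth = sp.PSTH(rate, 1.0, (-500.0, 501.0), 1)
        out = sp.smooth_psth(psth, 20.0)
        # closed form: the (edge-renormalized, +-4 sigma truncated) kernel
        k = np.exp(-0.5 * (np.arange(-80, 81) / 20.0) ** 2)
        expected = np.zeros(1001)
        expected[420:581] = 1000.0 * k / k.sum()
        assert np.allclose(out.rate, expected, atol=1e-6)
        # mass is conserved (sum x bin width = 1 spike / trial)
        assert out.rate.sum() * 1e-3 == pytest.approx(1.0, abs=1e-9)

    def test_tiny_sigma_is_identity(self):
        rng = np.random.default_rng(2)
        psth = sp.PSTH(rng.uniform(0, 100, 500), 1.0, (0.0, 500.0), 5)
        out = sp.smooth_psth(psth, 0.1)
        assert np.allclose(out.rate, psth.rate, atol=1e-6)

    def test_mean_preserved(self):
        rng = np.random.default_rng(3)
        psth = sp.PSTH(rng.uniform(0, 80, 1300), 1.0, (-500.0, 800.0), 7)
        out = sp.smooth_psth(psth, 20.0)
        # edge renormalization keeps the trace mean to high accuracy
        assert out.rate.mean() == pytest.approx(psth.rate.mean(), rel=1e-3)


class TestZTransform:
    def two_level(self):
        rate = np.concatenate([np.full(500, 10.0), np.full(500, 20.0)])
        return sp.PSTH(rate, 1.0, (-500.0, 500.0), 10)

    def test_two_level_hand_arithmetic(self):
        nr = sp.z_transform(self.two_level())
        # baseline mean 10 is subtracted, SD over all bins = 5:
        # baseline bins -> 0, post bins -> (20 - 10)/5 = +2
        assert np.allclose(nr.z[:500], 0.0)
        assert np.allclose(nr.z[500:], 2.0)
        assert nr.sd_used == pytest.approx(5.0)

    def test_constant_trace_degenerate(self):
        nr = sp.z_transform(sp.PSTH(np.full(1000, 42.0), 1.0,
                                    (-500.0, 500.0), 3))
        assert nr.degenerate

    def test_offset_invariance(self):
        base = self.two_level()
        shifted = sp.PSTH(base.rate + 7.0, 1.0, base.window_ms, base.n_trials)
        assert np.allclose(sp.z_transform(base).z,
                           sp.z_transform(shifted).z, atol=1e-12)

    def test_scale_invariance(self):
        base = self.two_level()
        scaled = sp.PSTH(base.rate * 3.5, 1.0, base.window_ms, base.n_trials)
        assert np.allclose(sp.z_transform(base).z,
                           sp.z_transform(scaled).z, atol=1e-12)

    def test_baseline_mean_zero(self):
        rng = np.random.default_rng(4)
        psth = sp.PSTH(rng.uniform(0, 60, 1300), 1.0, (-500.0, 800.0), 4)
        nr = sp.z_transform(psth)
        assert abs(nr.z[nr.bin_slice((-500.0, 0.0))].mean()) < 1e-9

    def test_baseline_not_covered_error(self):
        psth = sp.PSTH(np.full(100, 5.0), 1.0, (0.0, 100.0), 1)
        with pytest.raises(ValueError):
            sp.z_transform(psth)

    def test_baseline_sd_scope(self):
        nr = sp.z_transform(self.two_level(), sd_scope="baseline")
        assert nr.degenerate  # baseline bins are constant


class TestWindowMean:
    def test_two_level_post_window(self):
        nr = sp.z_transform(TestZTransform().two_level())
        assert sp.window_mean(nr, (0.0, 500.0)) == pytest.approx(2.0)

    def test_single_bin_window(self):
        nr = sp.z_transform(TestZTransform().two_level())
        assert sp.window_mean(nr, (0.0, 1.0)) == pytest.approx(nr.z[500])

    def test_degenerate_error(self):
        nr = sp.z_transform(sp.PSTH(np.full(1000, 1.0), 1.0,
                                    (-500.0, 500.0), 1))
        with pytest.raises(ValueError):
            sp.window_mean(nr, (0.0, 100.0))


class TestBaselineRate:
    def test_empty_train(self):
        assert sp.baseline_rate(np.array([]), np.array([5.0])) == 0.0

    def test_post_scene_spikes_not_counted(self):
        assert sp.baseline_rate(np.array([5.1, 5.2]), np.array([5.0])) == 0.0

    def test_homogeneous_neuron_within_3_se(self):
        rng = np.random.default_rng(5)
        events = 2.0 + 3.0 * np.arange(500)
        train = synth.generate_spike_train(
            lambda t: np.full(t.size, 42.9), events[-1] + 1.0,
            rng=rng, rate_max=43.0)
        rate = sp.baseline_rate(train.spike_times, events)
        se = np.sqrt(42.9 / (500 * 0.5))
        assert abs(rate - 42.9) < 3 * se


class TestWaveform:
    def test_standardize_definition(self):
        wf = synth.generate_waveform(300.0, seed=0)
        std, trough, peak = sp.standardize_waveform(wf)
        assert std[trough] == -1.0 and std[peak] == 1.0
        assert peak > trough

    def test_scale_and_offset_invariance(self):
        wf = synth.generate_waveform(300.0, seed=0)
        v = wf[:, 1]
        std1, *_ = sp.standardize_waveform(v)
        std2, *_ = sp.standardize_waveform(10.0 * v + 3.0)
        assert np.allclose(std1, std2, atol=1e-12)

    def test_trough_to_peak_arithmetic(self):
        v = np.zeros(40)
        v[10] = -80.0
        v[22] = 40.0
        assert sp.trough_to_peak(v, 40000.0) == pytest.approx(300.0)

    def test_generated_duration_within_one_sample(self):
        for req in (200.0, 300.0, 450.0):
            wf = synth.generate_waveform(req, seed=1)
            assert abs(sp.trough_to_peak(wf) - req) <= 25.0 + 1e-9

    def test_adjacent_peak(self):
        v = np.array([0.0, -1.0, 1.0, 0.0])
        assert sp.trough_to_peak(v, 40000.0) == pytest.approx(25.0)

    def test_monotone_waveform_rejected(self):
        with pytest.raises(ValueError):
            sp.standardize_waveform(np.array([3.0, 2.0, 1.0, 0.0]))


class TestKruskalDunn:
    def test_identical_groups_h_zero(self):
        h, p, _ = sp.kruskal_dunn([1.0, 1.0], [1.0, 1.0], [1.0, 1.0])
        assert h == 0.0 and p == 1.0

    def test_hand_ranked_oracle(self):
        # ranks 1..9, group mean ranks 2, 5, 8:
        # H = 12/(9*10) * 3*((2-5)^2 + 0 + (8-5)^2) = 7.2
        h, p, pairs = sp.kruskal_dunn([1, 2, 3], [4, 5, 6], [7, 8, 9])
        assert h == pytest.approx(7.2, abs=1e-10)
        assert len(pairs) == 3

    def test_two_group_equivalence_with_scipy(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        h, p, pairs = sp.kruskal_dunn(a, b)
        h_ref, p_ref = stats.kruskal(a, b)
        assert h == pytest.approx(h_ref, abs=1e-10)
        # with two groups the Dunn z equals sqrt(H)
        assert pairs["z"].abs().iloc[0] == pytest.approx(np.sqrt(h), abs=1e-8)

    def test_cluster_baseline_rates_differ(self, medium_session):
        # the synthetic clusters reproduce the lower cluster-1 baseline
        s, gt = medium_session
        groups = {1: [], 2: [], 3: []}
        scene = s.event_times("scene")
        for n in s.neurons:
            groups[gt.cluster_of[n.neuron_id]].append(
                sp.baseline_rate(n.spike_times, scene))
        h, p, pairs = sp.kruskal_dunn(*groups.values())
        means = [np.mean(g) for g in groups.values()]
        assert means[0] < means[1] and means[0] < means[2]
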