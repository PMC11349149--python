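import numpy as np
import pytest

from meacomm import (
    SimConfig,
    make_layout,
    propagate_spikes,
    simulate_network,
    stage_config,
    synthesize_raw,
    default_spike_template,
    SpikeTrainSet,
)
from meacomm.processing import robust_noise_sd


def quiet(stage, **kw):
    """Stage config with bursting effectively disabled."""
    return stage_config(stage, burst_interval_s=1e9, **kw)


class TestRegimes:
    def test_day7_has_no_connections(self):
        cfg = quiet("day7", n_rows=2, n_cols=5, base_rate_hz=1.0, duration_s=100, seed=0)
        _, gt = simulate_network(cfg)
        assert gt.n_edges == 0
        assert len(gt.paths) == 0
        assert all(r == "background" for r in gt.roles.values())

    def test_day7_with_connections_is_a_contradiction(self):
        with pytest.raises(ValueError):
            SimConfig(stage="day7", connection_prob=0.5)

    def test_day14_latencies_submillisecond_by_default(self):
        cfg = stage_config("day14", duration_s=30, seed=1)
        _, gt = simulate_network(cfg)
        assert gt.n_edges > 0
        assert all(lat < 1.0 for _, _, lat in gt.edges)

    def test_day21_paths_are_multihop_with_6ms_effective_latency(self):
        cfg = stage_config("day21", duration_s=30, seed=1)
        _, gt = simulate_network(cfg)
        assert all(len(p) == cfg.n_hops + 1 for p in gt.paths)
        assert all(lat == pytest.approx(6.0) for _, _, lat in gt.effective_edges)
        assert all(lat <= 10.0 for _, _, lat in gt.edges)

    def test_stimulation_scales_latency_down(self):
        pre = stage_config("day21", stim_state="pre")
        during = stage_config("day21", stim_state="during")
        post = stage_config("day21", stim_state="post")
        assert during.effective_latency_ms == pytest.approx(0.5 * pre.effective_latency_ms)
        assert post.effective_latency_ms == pytest.approx(0.75 * pre.effective_latency_ms)
        assert during.effective_latency_ms < post.effective_latency_ms < pre.effective_latency_ms


class TestStatistics:
    def test_day7_rate_within_poisson_error(self):
        # 1 Hz for 1000 s: per-electrode counts ~ Poisson(1000)
        cfg = quiet("day7", n_rows=2, n_cols=5, base_rate_hz=1.0,
                    duration_s=1000, seed=3)
        sts, _ = simulate_network(cfg)
        expected = 1000.0
        se = np.sqrt(expected)
        for eid in sts.electrode_ids:
            n = sts.electrode_train(eid).size
            assert abs(n - expected) < 3 * se + 3  # refractory removes a few

    def test_rate_conservation_without_propagation(self):
        cfg = quiet("day7", n_rows=4, n_cols=4, base_rate_hz=2.0,
                    duration_s=500, seed=4)
        sts, _ = simulate_network(cfg)
        total = sts.n_spikes
        expected = 2.0 * 16 * 500
        assert abs(total - expected) < 4 * np.sqrt(expected) + 16 * 4

    def test_seed_determinism_byte_identical_tables(self):
        cfg = stage_config("day21", duration_s=60, seed=42)
        a, _ = simulate_network(cfg)
        b, _ = simulate_network(cfg)
        assert a.to_frame().to_csv(index=False) == b.to_frame().to_csv(index=False)

    def test_different_seeds_differ(self):
        a, _ = simulate_network(stage_config("day14", duration_s=60, seed=1))
        b, _ = simulate_network(stage_config("day14", duration_s=60, seed=2))
        assert a.to_frame().to_csv(index=False) != b.to_frame().to_csv(index=False)

    def test_refractory_period_enforced(self):
        cfg = stage_config("day21", duration_s=60, seed=5)
        sts, _ = simulate_network(cfg)
        for t in sts.trains.values():
            if t.size > 1:
                assert np.diff(t).min() >= cfg.refractory_ms / 1000.0 - 1e-12

    def test_all_times_inside_recording_window(self):
        cfg = stage_config("day21", duration_s=20, seed=6)
        sts, _ = simulate_network(cfg)
        for t in sts.trains.values():
            if t.size:
                assert t[0] >= 0 and t[-1] <= cfg.duration_s


class TestPropagation:
    def test_deterministic_hop_is_exact_shift(self, rng):
        src = np.sort(rng.uniform(0, 100, 300))
        out = propagate_spikes(src, latency_ms=2.0, transmission_prob=1.0,
                               jitter_ms=0.0, rng=rng)
        assert np.allclose(out, src + 0.002)

    def test_follower_is_time_shifted_copy_of_source(self):
        # two electrodes, certain connection, deterministic transmission
        cfg = quiet("day14", n_rows=1, n_cols=2, connection_prob=1.0,
                    latency_ms=2.0, latency_jitter_ms=0.0, transmission_prob=1.0,
                    base_rate_hz=1.0, duration_s=100, seed=7)
        sts, gt = simulate_network(cfg)
        (src, dst, lat), = gt.effective_edges
        assert lat == pytest.approx(2.0)
        a = sts.electrode_train(src)
        b = sts.electrode_train(dst)
        # every source spike has a follower spike exactly 2 ms later
        assert b.size == a.size
        assert np.allclose(b, a + 0.002)

    def test_transmission_prob_thins_follower_train(self, rng):
        src = np.sort(rng.uniform(0, 1000, 5000))
        out = propagate_spikes(src, 2.0, 0.5, 0.0, rng)
        assert abs(out.size - 2500) < 4 * np.sqrt(1250)


class TestRawSynthesis:
    def test_noiseless_insertion_counts(self):
        lay = make_layout(1, 1, 200.0)
        times = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        sts = SpikeTrainSet({("E00", 0): times}, duration_s=1.0)
        raw = synthesize_raw(sts, lay, noise_sd=0.0, fs_hz=20000.0)
        x = raw.samples[0]
        # 5 disjoint negative excursions below half the template depth
        thr = -50.0
        below = x < thr
        n_excursions = int(np.sum(np.diff(below.astype(int)) == 1) + below[0])
        assert n_excursions == 5

    def test_empty_set_gives_zero_mean_noise(self, rng):
        lay = make_layout(2, 2, 200.0)
        sts = SpikeTrainSet({(e, 0): np.empty(0) for e in lay.ids}, duration_s=1.0)
        raw = synthesize_raw(sts, lay, noise_sd=5.0, fs_hz=20000.0, rng=rng)
        assert abs(raw.samples.mean()) < 0.1
        assert raw.samples.std() == pytest.approx(5.0, rel=0.05)

    def test_snr_of_inserted_events(self, rng):
        lay = make_layout(1, 1, 200.0)
        times = np.sort(rng.uniform(0.05, 9.95, 100))
        sts = SpikeTrainSet({("E00", 0): times}, duration_s=10.0)
        tpl = default_spike_template(20000.0, amplitude=100.0)
        raw = synthesize_raw(sts, lay, template=tpl, noise_sd=10.0,
                             fs_hz=20000.0, rng=rng)
        snr = 100.0 / robust_noise_sd(raw.samples[0])
        assert snr == pytest.approx(10.0, rel=0.15)

    def test_channel_order_matches_layout(self, rng):
        lay = make_layout(2, 2, 200.0)
        sts = SpikeTrainSet({("E02", 0): np.array([0.5])}, duration_s=1.0)
        raw = synthesize_raw(sts, lay, noise_sd=0.0, rng=rng)
        active = np.flatnonzero(np.abs(raw.samples).max(axis=1) > 0)
        assert list(active) == [lay.index_of("E02")]
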