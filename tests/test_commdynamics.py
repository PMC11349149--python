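import numpy as np
import pytest

from meacomm import (
    SpikeTrainSet,
    compare_states,
    estimate_latency,
    extract_comm_events,
    fit_speed,
    make_layout,
    network_distance,
    simulate_network,
    stage_config,
)
from meacomm.commdynamics import SpeedFit, speed_points


def brute_force_events(sts, max_sl_ms):
    """O(n^2) oracle over whole-recording first deliveries."""
    deliveries = sorted(
        (float(sts.electrode_train(e)[0]), e)
        for e in sts.electrode_ids
        if sts.electrode_train(e).size
    )
    segments, current = [], []
    for t, e in deliveries:
        if current and (t - current[-1][0]) * 1000.0 > max_sl_ms:
            segments.append(current)
            current = []
        current.append((t, e))
    if current:
        segments.append(current)
    out = []
    for seg in segments:
        if len({e for _, e in seg}) >= 2:
            out.append(((seg[-1][0] - seg[0][0]) * 1000.0, seg[0][1], len(seg)))
    return out


class TestLatency:
    def test_deterministic_shift_recovered(self, rng):
        pre = np.sort(rng.uniform(0, 100, 500))
        est = estimate_latency(pre, pre + 0.002, rng=0)
        assert est.significant
        assert est.latency_ms == pytest.approx(2.0, abs=0.25)

    def test_empty_train_flagged_not_raised(self):
        est = estimate_latency(np.empty(0), np.array([1.0]), rng=0)
        assert not est.significant and not est.has_estimate

    def test_independent_poisson_rarely_significant(self):
        hits = 0
        n_rep = 60
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            a = np.sort(rng.uniform(0, 120, rng.poisson(120)))
            b = np.sort(rng.uniform(0, 120, rng.poisson(120)))
            hits += estimate_latency(a, b, rng=seed).significant
        assert hits <= max(2, 0.03 * n_rep)

    def test_day14_simulation_recovers_configured_latency(self):
        cfg = stage_config("day14", n_rows=1, n_cols=2, connection_prob=1.0,
                           latency_ms=0.8, latency_jitter_ms=0.1,
                           transmission_prob=1.0, burst_interval_s=1e9,
                           base_rate_hz=1.0, duration_s=300, seed=17)
        sts, gt = simulate_network(cfg)
        (src, dst, _), = gt.effective_edges
        est = estimate_latency(sts.electrode_train(src), sts.electrode_train(dst), rng=3)
        assert est.significant
        assert est.latency_ms == pytest.approx(0.8, abs=0.3)


class TestCommEvents:
    def test_worked_chain_example(self):
        # deliveries at 0, 4, 8, 25 ms on four electrodes: the 10 ms rule
        # splits {0,4,8} from {25}; one event with comm_time 8 ms
        trains = {(f"E{i}", 0): np.array([t]) for i, t in
                  enumerate([0.0, 0.004, 0.008, 0.025])}
        sts = SpikeTrainSet(trains, duration_s=1.0)
        events = extract_comm_events(sts, max_sl_ms=10, mode="whole")
        assert len(events) == 1
        ev = events[0]
        assert ev.comm_time_ms == pytest.approx(8.0)
        assert ev.origin == "E0"
        assert ev.n_electrodes == 3

    def test_single_electrode_never_an_event(self):
        sts = SpikeTrainSet({("E0", 0): np.array([0.1, 0.102, 0.104])}, 1.0)
        assert extract_comm_events(sts, mode="whole") == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_chain_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_el = rng.integers(3, 12)
        trains = {
            (f"E{i}", 0): np.sort(rng.uniform(0, 0.5, rng.integers(1, 6)))
            for i in range(n_el)
        }
        sts = SpikeTrainSet(trains, duration_s=1.0)
        got = [(e.comm_time_ms, e.origin, e.n_electrodes)
               for e in extract_comm_events(sts, mode="whole")]
        want = brute_force_events(sts, 10.0)
        assert len(got) == len(want)
        for (ct, o, n), (wct, wo, wn) in zip(got, want):
            assert ct == pytest.approx(wct) and o == wo and n == wn

    def test_invariance_to_relabeling_and_time_shift(self, rng):
        times = {f"E{i}": np.sort(rng.uniform(0, 0.3, 4)) for i in range(6)}
        sts = SpikeTrainSet({(e, 0): t for e, t in times.items()}, 1.0)
        ev1 = extract_comm_events(sts, mode="whole")
        # global shift
        sts_shift = SpikeTrainSet({(e, 0): t + 0.5 for e, t in times.items()}, 2.0)
        ev2 = extract_comm_events(sts_shift, mode="whole")
        assert [e.comm_time_ms for e in ev1] == pytest.approx(
            [e.comm_time_ms for e in ev2]
        )
        # relabeling permutes electrode names only
        mapping = {f"E{i}": f"X{(i + 3) % 6}" for i in range(6)}
        sts_perm = SpikeTrainSet({(mapping[e], 0): t for e, t in times.items()}, 1.0)
        ev3 = extract_comm_events(sts_perm, mode="whole")
        assert [e.comm_time_ms for e in ev3] == pytest.approx(
            [e.comm_time_ms for e in ev1]
        )
        assert [e.origin for e in ev3] == [mapping[e.origin] for e in ev1]

    def test_comm_time_bounded_by_chain_length(self, day14_sim):
        _, layout, sts, _ = day14_sim
        for ev in extract_comm_events(sts, max_sl_ms=10):
            assert ev.comm_time_ms <= (len(layout.ids) - 1) * 10.0 + 1e-9


class TestDistanceAndSpeed:
    def test_network_distance_basics(self):
        lay = make_layout(3, 3, 200.0)
        assert network_distance(lay, "E00", "E00") == 0.0
        assert network_distance(lay, "E00", "E01") == pytest.approx(200.0)
        assert network_distance(lay, "E00", "E04") == pytest.approx(200.0 * np.sqrt(2))
        with pytest.raises(KeyError):
            network_distance(lay, "E00", "zz")

    def test_exact_linear_points(self):
        pts = np.array([[1.0, 200.0], [2.0, 400.0], [3.0, 600.0]])
        fit = fit_speed(pts)
        assert fit.slope_m_s == pytest.approx(0.2)
        assert fit.intercept_um == pytest.approx(0.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.ci95_m_s[0] <= fit.slope_m_s <= fit.ci95_m_s[1]

    def test_matches_closed_form_ols(self, rng):
        t = rng.uniform(0, 10, 40)
        d = 150.0 * t + 30 + rng.normal(0, 20, 40)
        fit = fit_speed(np.column_stack([t, d]))
        # independent closed-form OLS
        tc, dc = t - t.mean(), d - d.mean()
        slope = (tc * dc).sum() / (tc**2).sum()
        intercept = d.mean() - slope * t.mean()
        assert fit.slope_m_s == pytest.approx(slope * 1e-3, rel=1e-9)
        assert fit.intercept_um == pytest.approx(intercept, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_speed(np.array([[1.0, 2.0], [2.0, 3.0]]))
        with pytest.raises(ValueError):
            fit_speed(np.array([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]]))

    def test_speed_recovery_from_line_chain_simulation(self):
        # one wavefront chain: 1 ms per 200 μm hop -> 0.2 m/s
        cfg = stage_config("day21", n_rows=1, n_cols=8, relay_style="line",
                          latency_ms=7.0, n_hops=7, connection_prob=1.0,
                          transmission_prob=1.0, latency_jitter_ms=0.1,
                          base_rate_hz=1.0, burst_rate_hz=40.0,
                          burst_duration_s=0.3, burst_interval_s=3.0,
                          duration_s=120, seed=5)
        lay = make_layout(1, 8, 200.0)
        sts, gt = simulate_network(cfg, lay)
        assert gt.true_velocity_m_s == pytest.approx(0.2)
        fit = fit_speed(extract_comm_events(sts), lay)
        assert fit.slope_m_s == pytest.approx(0.2, rel=0.1)
        assert fit.r_squared > 0.9


class TestCompareStates:
    def _fit(self, v, state):
        return SpeedFit(v, (v, v), 0.0, 1.0, 10, state)

    def test_identical_groups_p_one(self):
        fits = {"pre": [self._fit(1.0, "pre")] * 3, "post": [self._fit(1.0, "post")] * 3}
        out = compare_states(fits)
        assert out["tests"][0]["p"] == pytest.approx(1.0)
        assert out["tests"][0]["mean_diff_m_s"] == 0.0

    def test_separated_groups_tiny_p(self, rng):
        a = [self._fit(1.0 + 1e-6 * rng.normal(), "a") for _ in range(3)]
        b = [self._fit(2.0 + 1e-6 * rng.normal(), "b") for _ in range(3)]
        out = compare_states({"a": a, "b": b})
        assert out["tests"][0]["p"] < 1e-6
        assert out["summary"]["b"]["mean_m_s"] > out["summary"]["a"]["mean_m_s"]

    def test_single_replicate_reports_means_only(self):
        out = compare_states({"a": [self._fit(1.0, "a")], "b": [self._fit(2.0, "b")]})
        assert np.isnan(out["tests"][0]["p"])
        assert out["summary"]["a"]["mean_m_s"] == 1.0
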