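"""Synaptic latency and network communication velocity.

Estimates synaptic latency (SL) from positive-lag cross-correlogram peaks
on simulated day-14 (direct, sub-millisecond) and day-21 (multi-hop, ≈6 ms
effective) connections, then measures the communication velocity of a
propagating wavefront — the slope of network distance against delivery
time over chained communication events (adjacent-delivery gaps ≤ 10 ms) —
before, during and after simulated electrical stimulation.
"""

import numpy as np

from meacomm import (
    estimate_latency,
    extract_comm_events,
    fit_speed,
    make_layout,
    simulate_network,
    stage_config,
)

for stage in ("day14", "day21"):
    cfg = stage_config(stage, duration_s=300.0, seed=4)
    sts, gt = simulate_network(cfg)
    vals = []
    for k, (src, dst, true_ms) in enumerate(gt.effective_edges):
        est = estimate_latency(sts.electrode_train(src), sts.electrode_train(dst),
                               rng=40 + k)
        if est.significant:
            vals.append(est.latency_ms)
    print(f"{stage}: configured SL {gt.effective_edges[0][2]:.1f} ms, "
          f"median estimated {np.median(vals):.2f} ms over {len(vals)} pairs")

print()
lay = make_layout(1, 8, 200.0)
for stim in ("pre", "during", "post"):
    cfg = stage_config("day21", stim_state=stim, n_rows=1, n_cols=8,
                       relay_style="line", latency_ms=14.0, n_hops=7,
                       connection_prob=1.0, transmission_prob=1.0,
                       latency_jitter_ms=0.1, base_rate_hz=1.0,
                       burst_rate_hz=40.0, burst_duration_s=0.3,
                       burst_interval_s=3.0, duration_s=120.0, seed=5)
    sts, gt = simulate_network(cfg, lay)
    fit = fit_speed(extract_comm_events(sts), lay)
    print(f"{stim:>6} stimulation: velocity {fit.slope_m_s:.3f} m/s "
          f"(true {gt.true_velocity_m_s:.3f}, "
          f"95% CI {fit.ci95_m_s[0]:.3f}..{fit.ci95_m_s[1]:.3f}, "
          f"R² {fit.r_squared:.3f}, n={fit.n_points})")
print("\nStimulation halves hop latency while it is on (0.5x) and partially")
print("persists afterwards (0.75x), so velocity orders during > post > pre.")
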