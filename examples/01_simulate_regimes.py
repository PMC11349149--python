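"""Simulate the three developmental regimes of a cultured network.

Generates 5-minute recordings on an 8x8 grid (200 μm pitch) for an
immature (day 7), directly-connected (day 14) and mature multi-synaptic
(day 21) network, and prints their basic activity statistics and true
wiring.  Day 7 has no connections by construction; firing rate, burstiness
and connectivity all grow with maturation.
"""

from meacomm import activity_metrics, simulate_network, stage_config
from meacomm.trains import detect_bursts_set

for stage in ("day7", "day14", "day21"):
    cfg = stage_config(stage, duration_s=300.0, seed=1)
    sts, gt = simulate_network(cfg)
    act = activity_metrics(sts)
    bursts = detect_bursts_set(sts)
    print(
        f"{stage:>6}: {sts.n_spikes:6d} spikes, "
        f"{act['n_active_electrodes']:2d}/64 active electrodes, "
        f"mean rate {act['mean_rate_hz']:5.2f} Hz, "
        f"mean amplitude {act['mean_p2p_amplitude']:6.1f} μV, "
        f"{len(bursts):4d} bursts, "
        f"{gt.n_edges:2d} true synaptic edges in {len(gt.paths)} paths"
    )

print("\nEach line is one regime; edges are the ground-truth directed synaptic")
print("connections the analysis modules should later rediscover from spikes alone.")
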