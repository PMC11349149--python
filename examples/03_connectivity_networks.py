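"""Synchronization and mutual-information communication networks.

Computes the pairwise synchronization score matrix (lag-maximized binned
Pearson correlation in [0, 1]) and the binary mutual-information matrix
(plug-in estimator, bits, 10 ms bins), then thresholds MI at 0.1 bit
(edges) and 0.2 bit (strong edges).  Edge counts grow with maturation and
with electrical stimulation — the network-level signature of developing
synaptic communication.
"""

import numpy as np

from meacomm import build_graph, graph_summary, mi_matrix, simulate_network, stage_config, sync_matrix

for label, stage, stim in [
    ("day 7", "day7", "pre"),
    ("day 14", "day14", "pre"),
    ("day 21", "day21", "pre"),
    ("day 21 + stimulation", "day21", "post"),
]:
    cfg = stage_config(stage, stim_state=stim, duration_s=300.0, seed=2)
    sts, gt = simulate_network(cfg)
    ids = [f"E{i:02d}" for i in range(64)]
    sm = sync_matrix(sts, electrode_ids=ids)
    off = sm.scores[~np.eye(64, dtype=bool)]
    g = build_graph(mi_matrix(sts, electrode_ids=ids))
    s = graph_summary(g)
    print(f"{label:>20}: mean sync {off.mean():.3f}, "
          f"{s['n_edges']:3d} MI edges (> 0.1 bit), "
          f"{s['n_strong_edges']:3d} strong (> 0.2 bit), "
          f"max degree {max(d for _, d in g.degree())}")

print("\nExpected ordering: day21 > day14 > day7 (= 0) edges, and stimulation")
print("raises both counts, the strong count most — strengthened existing links.")
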