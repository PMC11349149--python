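# meacomm

Communication dynamics of cultured neuronal networks on microelectrode
arrays (MEAs): from spike trains — simulated with ground-truth wiring, or
detected and sorted from raw voltage traces — to synchronization matrices,
mutual-information (MI) communication networks, synaptic-latency estimates,
chained communication events and the network communication velocity.

The package is for experimenters and modellers who record cultured networks
on electrode grids and want a tested, reproducible path from spike times to
network-level communication measures, together with a generator that
emulates the three developmental regimes such cultures pass through:

- **immature (day 7)** — sparse independent firing, no connections;
- **directly connected (day 14)** — monosynaptic pairs with synaptic
  latency (SL) below 1 ms;
- **mature (day 21)** — many multi-synaptic paths, so transfer between
  nearby electrodes takes ≈ 6 ms, and a dense MI network.

## The measures

For spike trains `a`, `b` binned at 10 ms over a recording:

- **Synchronization score** — max over lags |ℓ| ≤ 10 ms of the Pearson
  correlation of the lagged count vectors, clipped to [0, 1].
- **Mutual information** — binarized bins, plug-in estimate
  `I(X;Y) = Σ p(x,y) log₂ p(x,y)/(p(x)p(y))` in bits; an edge joins pairs
  with `I > 0.1` bit (strong: `> 0.2` bit); node degree counts incident
  edges.
- **Synaptic latency** — the peak of the (0, 10 ms] cross-correlogram of
  post- relative to pre-spikes, significant against jitter surrogates.
- **Communication event** — pooled first-delivery times per electrode,
  chained while adjacent gaps stay ≤ 10 ms; its communication time is the
  last minus first delivery.
- **Communication velocity** — the slope of the regression of network
  distance from the event origin (μm) on delivery time (ms), in m/s with a
  95% confidence interval.

## Worked example

`examples/` holds one short script per capability. Running
`python examples/04_latency_and_velocity.py` prints:

```
day14: configured SL 0.8 ms, median estimated 0.75 ms over 9 pairs
day21: configured SL 6.0 ms, median estimated 5.75 ms over 10 pairs

   pre stimulation: velocity 0.100 m/s (true 0.100, 95% CI 0.100..0.100, R² 0.998, n=368)
during stimulation: velocity 0.199 m/s (true 0.200, 95% CI 0.197..0.201, R² 0.993, n=368)
  post stimulation: velocity 0.133 m/s (true 0.133, 95% CI 0.132..0.134, R² 0.997, n=368)
```

The first block shows latency recovery on simulated recordings: direct
day-14 connections are estimated at 0.75 ms (correlogram bin centre nearest
the configured 0.8 ms), and multi-hop day-21 paths at 5.75 ms — the
sub-millisecond vs ≈ 6 ms signature that distinguishes direct from relayed
transmission. The second block fits the communication velocity of a
propagating wavefront (200 μm pitch): simulated electrical stimulation
halves the hop latency while on and partially persists afterwards, so the
velocity orders during > post > pre, with the true value inside each CI.

`python examples/03_connectivity_networks.py` shows the network-level
development (edge counts 0 → 13 → 71 across day 7/14/21, with stimulation
raising 71 to 84 and the strong-edge count from 41 to 70), and
`examples/05_full_pipeline.py` runs everything from one config:

```python
from meacomm import PipelineConfig, run_pipeline

config = PipelineConfig.from_dict({
    "seed": 7,
    "simulate": {"stage": "day14", "duration_s": 120.0},
})
report = run_pipeline(config, "day14_demo")
```

which writes spike tables, the sync and MI matrices, the MI graph
(CSV + GraphML), per-pair latencies, communication events and a
deterministic `report.json`. A thin CLI mirrors the stages
(`meacomm run -c config.yml -o out`, plus `simulate`, `bursts`, `sync`,
`minet`, `comm` subcommands).

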