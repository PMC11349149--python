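"""From raw voltage traces back to spike trains.

Synthesizes a 20 kHz extracellular recording from known spike times
(biphasic template + Gaussian noise), splits it at 250 Hz into spike and
LFP bands, detects negative threshold crossings at 5 robust noise SDs, and
sorts the waveforms with PCA + valley-seeking clustering.  With modest
noise the detected times match the generator within a sample.
"""

import numpy as np

from meacomm import (
    bandsplit,
    detect_spikes,
    make_layout,
    simulate_network,
    sort_units,
    stage_config,
    synthesize_raw,
)

cfg = stage_config("day7", n_rows=2, n_cols=2, base_rate_hz=4.0,
                   burst_interval_s=1e9, duration_s=10.0, seed=3)
lay = make_layout(2, 2, 200.0)
sts, _ = simulate_network(cfg, lay)
raw = synthesize_raw(sts, lay, noise_sd=2.0, fs_hz=20000.0, rng=3)
print(f"raw recording: {raw.n_channels} channels x {raw.samples.shape[1]} samples "
      f"({raw.duration_s:.0f} s at {raw.fs_hz:.0f} Hz)")

spike_band, lfp_band = bandsplit(raw)
events = detect_spikes(spike_band, k=5.0)
print(f"detected {events.n_events} events (true spike count {sts.n_spikes})")

sorted_sts = sort_units(events)
for eid in lay.ids:
    a = sts.electrode_train(eid)
    b = sorted_sts.electrode_train(eid)
    if a.size == b.size and a.size:
        err = f"{np.max(np.abs(a - b)) * raw.fs_hz:.2f} samples"
    else:
        err = "n/a (count mismatch)"
    print(f"  {eid}: {a.size:3d} true / {b.size:3d} recovered spikes, "
          f"max timing error {err}")
print("Noise jitters the detected trough by a sample or two (tens of μs); in the")
print("noiseless limit recovery is exact to within half a sample.")
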