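# Methods

`meacomm` analyses the communication dynamics of cultured neuronal networks
recorded on planar microelectrode arrays (MEAs): how synchronized and
information-sharing the electrodes are, how long synaptic transmission takes
between them, and how fast activity propagates across the array. Because
public MEA datasets with known ground-truth wiring do not exist, the package
ships a synthetic-data generator whose parameters define the conditions all
tests and reported numbers are computed under.

## The synthetic network generator

**Background firing.** Every independently firing electrode carries a doubly
stochastic Poisson train: burst windows are drawn from a renewal process
(exponential inter-burst gaps with mean `burst_interval_s`, window length
`burst_duration_s`), and the instantaneous rate switches between
`base_rate_hz` outside bursts and `burst_rate_hz` inside. A 2 ms absolute
refractory period is enforced per electrode after all spikes are merged.

**Connectivity regimes.** Three presets mirror the development of a culture:

| stage | base / burst rate (Hz) | burst window / gap (s) | wiring | latency |
|---|---|---|---|---|
| `day7` | 0.5 / 20 | 0.3 / 30 | none (enforced) | — |
| `day14` | 2.0 / 40 | 0.5 / 8 | direct source→follower pairs, p = 0.10 per adjacent pair | 0.8 ms ± 0.1 ms jitter |
| `day21` | 2.5 / 60 | 1.0 / 5 | multi-hop relay paths, p = 0.35 per adjacent pair | 6 ms effective over 3 hops of 2 ms |

Rates were chosen once to reproduce the qualitative network-level structure
expected of maturing cultures when analysed with the default 10 ms / 0.1 bit
MI network settings: no edges at day 7, a handful of comparatively
high-information edges at day 14 (the MI network exactly rediscovers the
wired pairs), and a dense network with a strong-edge (> 0.2 bit) subset at
day 21. Per-spike peak-to-peak amplitudes (40 / 80 / 120 μV ± 10%) likewise
grow with maturation, in the range typical of planar MEA recordings.

**Propagation.** Each connection is a path of electrodes
`(source, relays…, target)`; every source spike crosses each hop with
probability `transmission_prob`, delayed by the hop latency plus Gaussian
jitter (`latency_jitter_ms`). Electrodes serve in at most one path, so
ground-truth roles stay unambiguous. Pure followers and relays carry no
independent background by default (`follower_rate_scale = 0`); this makes
the propagation contract exact — with transmission 1 and zero jitter the
follower train is a time-shifted copy of the source — and gives clean
ground truth for parameter-recovery experiments. Day-21 paths come in two
geometries: `detour` (default) routes a one-pitch pair through relay
electrodes elsewhere on the grid, so two adjacent electrodes exhibit the
full ≈6 ms multi-synaptic latency at the same distance where a day-14 pair
shows < 1 ms; `line` lays the path along consecutive grid electrodes so
each hop advances one pitch, the configuration with a defined true
propagation speed `pitch / hop_latency` (200 μm per 1 ms hop = 0.2 m/s)
used for velocity-recovery experiments.

**Stimulation.** Electrical stimulation is modelled as multiplicative
factors on the synaptic parameters while `stim_state` is `during`
(latency ×0.5, transmission ×1.3, capped at 1) or `post` (×0.75, ×1.15).
Shorter latencies speed up propagation; stronger transmission densifies the
MI network, with existing (already supra-threshold) links gaining the most —
so the strong-edge count rises faster than the total.

**What the generator does not emulate.** No biophysical membrane dynamics,
no LFP content in the spike statistics, no electrode impedance or noise
spectra, no spatially correlated noise, no plasticity within a recording,
and background electrodes are mutually independent rather than weakly
coupled. Passing tests therefore demonstrate correct estimator behaviour
under the stated statistical structure, not performance on real recordings.

## Raw-trace processing

Raw synthesis inserts one spike template per spike (trough on the spike
time, overlaps sum) into white Gaussian noise at 20 kHz. Processing splits
the signal at 250 Hz into spike and LFP bands with zero-phase 4th-order
Butterworth filters (forward–backward, so downstream latencies carry no
filter delay). Detection thresholds at −k·σ̂ with k = 5 and
σ̂ = MAD/0.6745 (robust to the spikes themselves), aligns events to the
trough, uses a dead time equal to the cutout length (0.6 ms pre + 1.0 ms
post), and drops boundary-truncated events with a count.

Sorting projects cutouts onto their first three principal components and
clusters by valley seeking: a Gaussian KDE (Scott's rule) supplies a
density at every point; each point hill-climbs to the densest of its
⌈√n⌉ nearest neighbours until it reaches a local mode; clusters whose
mutual boundary shows no genuine density valley (densest boundary point ≥
half the smaller mode density) are merged. Before PCA, cutouts are
upsampled 4× and re-centred on a parabolically interpolated trough;
without this, one-sample alignment jitter splits a single waveform shape
into shifted near-copies that cluster apart. Degenerate (zero-variance)
channels and channels with fewer than two events yield a single unit 0.

## Network analyses

**Synchronization score.** Both trains are binned at 10 ms; the score is
the maximum Pearson correlation between the count vectors over integer-bin
lags within ±10 ms, clipped below at zero. Empty or constant count vectors
score 0 by convention. The [0, 1] range makes scores directly comparable
across pairs; the ±10 ms lag window matches the maximum synaptic latency.

**Mutual information.** Binned counts are binarized (any spike → 1) and the
plug-in MI of the 2×2 joint histogram is computed in bits, with 0·log 0 ≡ 0.
The estimator's positive bias for independent trains is ≈ 1/(2N ln 2) bits
— two orders of magnitude below the edge threshold at five minutes of
recording — so no correction is applied by default; a Miller–Madow option
exists. The communication network connects pairs with MI > 0.1 bit, with a
strong subset above 0.2 bit; degrees, counts and the degree distribution
summarize it.

**Synaptic latency.** The cross-correlogram of post-spikes relative to
pre-spikes over (0, 10 ms] in 0.5 ms bins; the latency estimate is the
centre of the peak bin, so a deterministic delay is recovered to within
half a bin. Significance requires the peak to exceed the 99th percentile
of peaks from 100 surrogates (post train jittered uniformly by ±5 ms) *and*
to contain at least 10 coincidences; the count floor reflects that a
latency supported by fewer coincidences is not credible, and keeps the
false-positive rate on unconnected pairs well below the nominal 1%.

**Communication events and velocity.** Within each candidate window
(merged burst windows by default, or the whole recording), each electrode
contributes its first spike; the time-sorted deliveries are split wherever
an adjacent gap exceeds the 10 ms maximum SL, and every maximal segment
touching ≥ 2 distinct electrodes is one communication event with
`comm_time = last − first` delivery. For the velocity, every member
electrode of every event contributes the point (time since the event's
first delivery, Euclidean distance from the origin electrode); ordinary
least squares of distance on time gives the slope in μm/ms, reported in
m/s with a 95% t-interval. Exact fits collapse the interval onto the
slope. Pairwise state comparisons use Welch two-tailed t tests on
replicate velocities, with identical constant groups defined to p = 1.

## Numerical and design choices

- Ties in the correlogram peak resolve to the earliest bin (`argmax`).
- Chain splitting is strict (`gap > max_sl`), so a gap of exactly 10 ms
  keeps the chain.
- Velocity experiments use `line`-geometry chains because only there does
  a true propagation speed exist; `detour` day-21 networks are used for
  latency and MI-network experiments, matching how mature cultures present
  multi-synaptic transfer between nearby electrodes.
- Problem sizes in the test suite and acceptance script — 8×8 grids,
  300 s recordings, 100 surrogates, 500-replicate oracle sweeps — were
  chosen to make every stochastic check statistically comfortable at
  desk scale while the whole suite stays fast.
- The pipeline report is deterministic JSON (sorted keys, no timestamps);
  the config hash and seed are embedded in every report, and identical
  configurations produce byte-identical reports.

## Known limitations

- The valley-seeking merge ratio (0.5) is a heuristic; heavily overlapping
  units with a shallow but real valley may merge.
- Whole-electrode trains are the default unit of analysis for synchrony,
  MI and latency; per-unit analysis is available by filtering the
  `SpikeTrainSet` but is not wired into the pipeline stages.
- Latency significance calibration assumes stationary trains; strongly
  non-stationary inputs (e.g. one-off population bursts) can inflate
  surrogate peaks and cost sensitivity, not specificity.
- The plug-in MI threshold (0.1 bit) is estimator-relative: changing bin
  size or binarization changes what the threshold means.
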