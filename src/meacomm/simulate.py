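"""Synthetic MEA spike data with ground-truth connectivity.

Emulates the three developmental regimes seen in cultured cortical networks
recorded on a microelectrode grid:

* ``day7``  — immature: sparse independent Poisson firing with occasional
  bursts, no functional connections.
* ``day14`` — direct monosynaptic coupling: selected adjacent electrode pairs
  are connected source → follower with a sub-millisecond synaptic latency.
* ``day21`` — mature multi-synaptic network: transfer between electrodes at
  one grid pitch passes through relay electrodes, so the effective pairwise
  latency is several milliseconds (≈6 ms by default) even though the
  end-to-end distance is unchanged.

Electrical stimulation shortens synaptic latencies and strengthens
transmission; its effect is modelled as multiplicative factors applied while
the ``stim_state`` is ``during`` or ``post``.

Background firing is doubly stochastic: burst windows are drawn from a
renewal process and the instantaneous Poisson rate switches between the base
rate and a higher within-burst rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .layout import ElectrodeLayout, grid_neighbors, make_layout
from .trains import SpikeTrainSet

STAGES = ("day7", "day14", "day21")
STIM_STATES = ("pre", "during", "post")

# stimulation scales latency down and transmission up; pre = baseline
LATENCY_SCALE = {"pre": 1.0, "during": 0.5, "post": 0.75}
TRANSMISSION_SCALE = {"pre": 1.0, "during": 1.3, "post": 1.15}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated recording.

    ``latency_ms`` is the *effective* source→target latency of a connection;
    on ``day21`` it is split evenly across ``n_hops`` relay hops.
    ``relay_style`` chooses the day21 path geometry: ``"detour"`` routes a
    one-pitch pair through relay electrodes elsewhere on the grid (adjacent
    pairs then show the full multi-hop latency), ``"line"`` lays the path
    along consecutive grid electrodes so each hop advances one pitch — the
    configuration with a defined true propagation speed of
    ``pitch_um / (latency_ms / n_hops)``.
    """

    stage: str = "day14"
    stim_state: str = "pre"
    n_rows: int = 8
    n_cols: int = 8
    pitch_um: float = 200.0
    base_rate_hz: float = 1.0
    burst_rate_hz: float = 30.0
    burst_duration_s: float = 0.5
    burst_interval_s: float = 15.0
    connection_prob: float = 0.1
    latency_ms: float = 0.8
    latency_jitter_ms: float = 0.1
    transmission_prob: float = 0.8
    n_hops: int = 1
    relay_style: str = "detour"
    follower_rate_scale: float = 0.0
    refractory_ms: float = 2.0
    amplitude_uv: float = 80.0
    duration_s: float = 300.0
    seed: int = 0

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}")
        if self.stim_state not in STIM_STATES:
            raise ValueError(f"stim_state must be one of {STIM_STATES}")
        if self.relay_style not in ("detour", "line"):
            raise ValueError("relay_style must be 'detour' or 'line'")
        for name in ("connection_prob", "transmission_prob", "follower_rate_scale"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in (
            "base_rate_hz",
            "burst_rate_hz",
            "burst_duration_s",
            "burst_interval_s",
            "latency_ms",
            "latency_jitter_ms",
            "refractory_ms",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.n_rows < 1 or self.n_cols < 1 or self.n_hops < 1:
            raise ValueError("n_rows, n_cols, n_hops must be >= 1")
        if self.stage == "day7" and self.connection_prob > 0:
            raise ValueError("day7 is the unconnected regime: connection_prob must be 0")

    @property
    def effective_latency_ms(self) -> float:
        return self.latency_ms * LATENCY_SCALE[self.stim_state]

    @property
    def hop_latency_ms(self) -> float:
        return self.effective_latency_ms / self.n_hops

    @property
    def effective_transmission_prob(self) -> float:
        return min(1.0, self.transmission_prob * TRANSMISSION_SCALE[self.stim_state])


# Developmental presets: firing rate, burstiness, connectivity and spike
# amplitude all increase with maturation; day21 transfer is multi-hop.
_STAGE_PRESETS: dict[str, dict] = {
    "day7": dict(
        base_rate_hz=0.5,
        burst_rate_hz=20.0,
        burst_duration_s=0.3,
        burst_interval_s=30.0,
        connection_prob=0.0,
        latency_ms=0.0,
        n_hops=1,
        amplitude_uv=40.0,
    ),
    "day14": dict(
        base_rate_hz=2.0,
        burst_rate_hz=40.0,
        burst_duration_s=0.5,
        burst_interval_s=8.0,
        connection_prob=0.10,
        latency_ms=0.8,
        latency_jitter_ms=0.1,
        transmission_prob=0.8,
        n_hops=1,
        amplitude_uv=80.0,
    ),
    "day21": dict(
        base_rate_hz=2.5,
        burst_rate_hz=60.0,
        burst_duration_s=1.0,
        burst_interval_s=5.0,
        connection_prob=0.35,
        latency_ms=6.0,
        latency_jitter_ms=0.1,
        transmission_prob=0.9,
        n_hops=3,
        amplitude_uv=120.0,
    ),
}


def stage_config(stage: str, **overrides) -> SimConfig:
    """A :class:`SimConfig` pre-filled with the defaults of one regime."""
    if stage not in STAGES:
        raise ValueError(f"stage must be one of {STAGES}")
    params = dict(_STAGE_PRESETS[stage])
    params.update(overrides)
    return SimConfig(stage=stage, **params)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually wired up.

    ``edges`` are the physical per-hop directed connections with their hop
    latency; ``effective_edges`` collapse each multi-hop path to its
    source→target latency (what a pairwise latency estimator should see).
    ``true_velocity_m_s`` is defined only when every hop advances a fixed
    distance (day14 direct connections and ``line``-style day21 paths).
    """

    edges: tuple[tuple[str, str, float], ...]
    effective_edges: tuple[tuple[str, str, float], ...]
    roles: dict[str, str]
    paths: tuple[tuple[str, ...], ...]
    true_velocity_m_s: float | None

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def _renewal_burst_windows(rng, duration_s, burst_duration_s, burst_interval_s):
    """Burst on/off windows from a renewal process (exponential gaps)."""
    if burst_interval_s <= 0 or burst_duration_s <= 0:
        return []
    windows = []
    t = rng.exponential(burst_interval_s)
    while t < duration_s:
        end = min(t + burst_duration_s, duration_s)
        windows.append((t, end))
        t = end + rng.exponential(burst_interval_s)
    return windows


def _doubly_stochastic_train(rng, duration_s, base_rate_hz, burst_rate_hz,
                             burst_duration_s, burst_interval_s):
    """Inhomogeneous Poisson train whose rate switches to burst_rate in bursts."""
    windows = _renewal_burst_windows(rng, duration_s, burst_duration_s, burst_interval_s)
    # piecewise-constant segments: (start, end, rate)
    segments = []
    cursor = 0.0
    for (b0, b1) in windows:
        if b0 > cursor:
            segments.append((cursor, b0, base_rate_hz))
        segments.append((b0, b1, burst_rate_hz))
        cursor = b1
    if cursor < duration_s:
        segments.append((cursor, duration_s, base_rate_hz))
    parts = []
    for (t0, t1, rate) in segments:
        if rate <= 0:
            continue
        n = rng.poisson(rate * (t1 - t0))
        if n:
            parts.append(rng.uniform(t0, t1, n))
    if not parts:
        return np.empty(0)
    return np.sort(np.concatenate(parts))


def _sample_connections(rng, config: SimConfig):
    """Wire up the grid for the configured regime.

    Returns ``(paths, roles)`` where each path is a tuple of electrode
    indices ``(source, relay..., target)``.  Electrodes participate in at
    most one path so that roles stay unambiguous.
    """
    n = config.n_rows * config.n_cols
    roles = {i: "background" for i in range(n)}
    paths: list[tuple[int, ...]] = []
    if config.stage == "day7" or config.connection_prob == 0:
        return paths, roles

    free = set(range(n))
    if config.relay_style == "line" and config.n_hops > 1:
        # straight chains of n_hops+1 consecutive electrodes along rows
        candidates = []
        for r in range(config.n_rows):
            for c0 in range(config.n_cols - config.n_hops):
                candidates.append(
                    tuple(r * config.n_cols + c0 + k for k in range(config.n_hops + 1))
                )
        rng.shuffle(candidates)
        for path in candidates:
            if not all(e in free for e in path):
                continue
            if rng.random() < config.connection_prob:
                paths.append(path)
                free.difference_update(path)
    else:
        pairs = grid_neighbors(config.n_rows, config.n_cols)
        rng.shuffle(pairs)
        for (a, b) in pairs:
            if a not in free or b not in free:
                continue
            if rng.random() >= config.connection_prob:
                continue
            if rng.random() < 0.5:
                a, b = b, a
            n_relays = config.n_hops - 1
            if n_relays:
                pool = sorted(free - {a, b})
                if len(pool) < n_relays:
                    continue
                relays = list(rng.choice(pool, size=n_relays, replace=False))
            else:
                relays = []
            path = (a, *relays, b)
            paths.append(path)
            free.difference_update(path)

    for path in paths:
        roles[path[0]] = "source"
        for r in path[1:-1]:
            roles[r] = "relay"
        roles[path[-1]] = "follower"
    return paths, roles


def _enforce_refractory(times: np.ndarray, refractory_s: float) -> np.ndarray:
    """Greedy dedup: keep each spike only if >= refractory after the last kept."""
    if times.size == 0 or refractory_s <= 0:
        return np.sort(times)
    t = np.sort(times)
    kept = [t[0]]
    last = t[0]
    for x in t[1:]:
        if x - last >= refractory_s:
            kept.append(x)
            last = x
    return np.asarray(kept)


def propagate_spikes(
    source_times: np.ndarray,
    latency_ms: float,
    transmission_prob: float,
    jitter_ms: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One synaptic hop: each source spike evokes a follower spike with
    probability ``transmission_prob`` at ``t + latency`` plus Gaussian jitter."""
    t = np.asarray(source_times, dtype=float)
    if transmission_prob < 1.0:
        t = t[rng.random(t.size) < transmission_prob]
    out = t + latency_ms / 1000.0
    if jitter_ms > 0 and out.size:
        out = out + rng.normal(0.0, jitter_ms / 1000.0, out.size)
    return np.sort(out)


def simulate_network(
    config: SimConfig, layout: ElectrodeLayout | None = None
) -> tuple[SpikeTrainSet, GroundTruth]:
    """Simulate one recording under the configured regime.

    Returns the spike trains (unit 0 per electrode, with synthetic per-spike
    peak-to-peak amplitudes) and the ground truth wiring.  Identical config
    (including seed) gives identical output.
    """
    if layout is None:
        layout = make_layout(config.n_rows, config.n_cols, config.pitch_um)
    if layout.n_electrodes != config.n_rows * config.n_cols:
        raise ValueError("layout size does not match config grid")
    rng = np.random.default_rng(config.seed)

    paths_idx, roles_idx = _sample_connections(rng, config)
    hop_latency = config.hop_latency_ms
    transmission = config.effective_transmission_prob
    ids = layout.ids

    spikes: dict[int, list[np.ndarray]] = {i: [] for i in range(layout.n_electrodes)}
    for i in range(layout.n_electrodes):
        scale = 1.0
        if roles_idx[i] in ("relay", "follower"):
            scale = config.follower_rate_scale
        if scale > 0:
            spikes[i].append(
                _doubly_stochastic_train(
                    rng,
                    config.duration_s,
                    config.base_rate_hz * scale,
                    config.burst_rate_hz * scale,
                    config.burst_duration_s,
                    config.burst_interval_s,
                )
            )

    for path in paths_idx:
        current = (
            np.sort(np.concatenate(spikes[path[0]])) if spikes[path[0]] else np.empty(0)
        )
        for hop_target in path[1:]:
            current = propagate_spikes(
                current, hop_latency, transmission, config.latency_jitter_ms, rng
            )
            spikes[hop_target].append(current)

    trains: dict[tuple[str, int], np.ndarray] = {}
    amps: dict[tuple[str, int], np.ndarray] = {}
    for i in range(layout.n_electrodes):
        t = np.concatenate(spikes[i]) if spikes[i] else np.empty(0)
        t = t[(t >= 0) & (t <= config.duration_s)]
        t = _enforce_refractory(t, config.refractory_ms / 1000.0)
        trains[(ids[i], 0)] = t
        amps[(ids[i], 0)] = np.maximum(
            rng.normal(config.amplitude_uv, 0.1 * config.amplitude_uv, t.size), 0.0
        )

    edges = []
    effective = []
    for path in paths_idx:
        for a, b in zip(path[:-1], path[1:]):
            edges.append((ids[a], ids[b], hop_latency))
        effective.append((ids[path[0]], ids[path[-1]], config.effective_latency_ms))

    if config.stage == "day14" or config.relay_style == "line":
        hop_dist = config.pitch_um  # every hop advances one pitch
        true_v = hop_dist / hop_latency * 1e-3 if hop_latency > 0 else None
    else:
        true_v = None

    gt = GroundTruth(
        edges=tuple(edges),
        effective_edges=tuple(effective),
        roles={ids[i]: r for i, r in roles_idx.items()},
        paths=tuple(tuple(ids[i] for i in p) for p in paths_idx),
        true_velocity_m_s=true_v,
    )
    return SpikeTrainSet(trains, config.duration_s, amps), gt


# ---------------------------------------------------------------------------
# raw-trace synthesis


def default_spike_template(fs_hz: float = 20000.0, amplitude: float = 100.0,
                           width_ms: float = 1.0) -> np.ndarray:
    """Biphasic negative-leading extracellular spike template."""
    n = max(int(round(width_ms / 1000.0 * fs_hz)), 5)
    t = np.linspace(0, 1, n)
    wave = -np.sin(np.pi * t) * np.exp(-3 * t)
    wave = wave + 0.3 * np.sin(2 * np.pi * t) * np.exp(-5 * t)
    return amplitude * wave / np.abs(wave.min())  # trough = -amplitude


@dataclass
class RawRecording:
    """Multichannel voltage traces, channel-major, aligned to a layout."""

    samples: np.ndarray  # (n_channels, n_samples) float32
    fs_hz: float
    channel_ids: tuple[str, ...]

    def __post_init__(self):
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be > 0")
        self.samples = np.asarray(self.samples, dtype=np.float32)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x time)")
        if len(self.channel_ids) != self.samples.shape[0]:
            raise ValueError("channel_ids length must match sample rows")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.fs_hz


def synthesize_raw(
    sts: SpikeTrainSet,
    layout: ElectrodeLayout,
    template: np.ndarray | None = None,
    noise_sd: float = 5.0,
    fs_hz: float = 20000.0,
    rng: np.random.Generator | int | None = None,
) -> RawRecording:
    """Insert one template per spike into Gaussian noise on its channel.

    The template is placed so that its most negative sample (the trough)
    lands on the spike time; overlapping insertions simply sum.  Per-spike
    amplitudes in the set, when present, scale the template so the trough
    depth equals the stored peak-to-peak amplitude.
    """
    if fs_hz <= 0:
        raise ValueError("fs_hz must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if template is None:
        template = default_spike_template(fs_hz)
    template = np.asarray(template, dtype=float)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    n_samples = int(round(sts.duration_s * fs_hz))
    trough = int(np.argmin(template))
    depth = abs(template[trough]) or 1.0
    if noise_sd > 0:
        data = rng.normal(0.0, noise_sd, (layout.n_electrodes, n_samples))
    else:
        data = np.zeros((layout.n_electrodes, n_samples))
    for (eid, uid), times in sts.trains.items():
        ch = layout.index_of(eid)
        amps = sts.amplitudes.get((eid, uid))
        for k, t in enumerate(times):
            i0 = int(round(t * fs_hz)) - trough
            i1 = i0 + template.size
            if i0 < 0 or i1 > n_samples:
                continue
            w = template
            if amps is not None:
                w = template * (amps[k] / depth)
            data[ch, i0:i1] += w
    return RawRecording(data.astype(np.float32), fs_hz, layout.ids)
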