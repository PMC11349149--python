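"""Synaptic latency, communication events and network communication velocity.

Synaptic latency (SL) between a putative pre- and postsynaptic electrode is
read off the cross-correlogram of post-spike times relative to pre-spike
times over (0, 10 ms]: the latency is the centre of the peak bin, declared
significant only when the peak both exceeds the 99th percentile of peaks
from jitter surrogates and contains enough coincidences to be credible.

A communication event is a chained multi-electrode firing episode: pool the
first-delivery time of each electrode inside a candidate window, sort them,
and split the sequence wherever the gap between adjacent deliveries exceeds
the maximum SL (10 ms).  Each maximal segment touching at least two
electrodes is one event; its communication time is the last minus the first
delivery.  Regressing network distance from the event origin on delivery
time gives the network communication velocity as the slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .layout import ElectrodeLayout
from .trains import SpikeTrainSet, detect_bursts_set

MAX_SL_MS = 10.0


@dataclass(frozen=True)
class LatencyEstimate:
    pre_id: str
    post_id: str
    latency_ms: float  # NaN when no estimate
    peak_count: int
    significant: bool
    threshold_count: float = float("nan")

    @property
    def has_estimate(self) -> bool:
        return not np.isnan(self.latency_ms)


@dataclass(frozen=True)
class CommEvent:
    """One chained multi-electrode firing episode."""

    deliveries: tuple[tuple[str, float], ...]  # (electrode, first-delivery time s)
    origin: str
    comm_time_ms: float
    window: tuple[float, float] | None = None

    def __post_init__(self):
        if len({e for e, _ in self.deliveries}) < 2:
            raise ValueError("a communication event needs >= 2 distinct electrodes")

    @property
    def n_electrodes(self) -> int:
        return len(self.deliveries)

    @property
    def start_s(self) -> float:
        return self.deliveries[0][1]


@dataclass(frozen=True)
class SpeedFit:
    """OLS fit of network distance (μm) on communication time (ms)."""

    slope_m_s: float
    ci95_m_s: tuple[float, float]
    intercept_um: float
    r_squared: float
    n_points: int
    state: str = ""

    def __post_init__(self):
        lo, hi = self.ci95_m_s
        if not (lo <= self.slope_m_s <= hi):
            raise ValueError("confidence interval must contain the slope")


def correlogram(
    pre: np.ndarray,
    post: np.ndarray,
    max_sl_ms: float = MAX_SL_MS,
    bin_ms: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Counts of post spikes at positive delays (0, max_sl] after pre spikes.

    Returns (counts, bin_centers_ms).
    """
    pre = np.sort(np.asarray(pre, dtype=float))
    post = np.sort(np.asarray(post, dtype=float))
    n_bins = int(np.round(max_sl_ms / bin_ms))
    edges_s = np.arange(n_bins + 1) * bin_ms / 1000.0
    counts = np.zeros(n_bins, dtype=int)
    if pre.size and post.size:
        # for each pre spike, post spikes within (t, t+max_sl]
        lo = np.searchsorted(post, pre, side="right")
        hi = np.searchsorted(post, pre + max_sl_ms / 1000.0, side="right")
        deltas = []
        for t, a, b in zip(pre, lo, hi):
            if b > a:
                deltas.append(post[a:b] - t)
        if deltas:
            d = np.concatenate(deltas)
            d = d[d > 0]
            counts, _ = np.histogram(d, bins=edges_s)
    centers = (np.arange(n_bins) + 0.5) * bin_ms
    return counts, centers


def estimate_latency(
    pre: np.ndarray,
    post: np.ndarray,
    max_sl_ms: float = MAX_SL_MS,
    bin_ms: float = 0.5,
    n_surrogates: int = 100,
    surrogate_jitter_ms: float = 5.0,
    min_peak_count: int = 10,
    pre_id: str = "pre",
    post_id: str = "post",
    rng: np.random.Generator | int | None = None,
) -> LatencyEstimate:
    """Synaptic latency from the positive-lag cross-correlogram peak.

    Significance requires the observed peak to exceed the 99th percentile of
    peaks obtained after jittering the post train (uniform
    ±``surrogate_jitter_ms``), and to contain at least ``min_peak_count``
    coincidences.  Empty trains yield a flagged no-estimate result.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.size == 0 or post.size == 0:
        return LatencyEstimate(pre_id, post_id, float("nan"), 0, False)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    counts, centers = correlogram(pre, post, max_sl_ms, bin_ms)
    peak_bin = int(np.argmax(counts))
    peak = int(counts[peak_bin])
    sur_peaks = np.empty(n_surrogates)
    for s in range(n_surrogates):
        jittered = post + rng.uniform(
            -surrogate_jitter_ms / 1000.0, surrogate_jitter_ms / 1000.0, post.size
        )
        c, _ = correlogram(pre, jittered, max_sl_ms, bin_ms)
        sur_peaks[s] = c.max()
    thr = float(np.percentile(sur_peaks, 99))
    significant = bool(peak > thr and peak >= min_peak_count)
    return LatencyEstimate(
        pre_id, post_id, float(centers[peak_bin]), peak, significant, thr
    )


def _chain_split(deliveries: list[tuple[str, float]], max_sl_ms: float):
    """Split time-sorted (electrode, time) deliveries at gaps > max_sl."""
    segments: list[list[tuple[str, float]]] = []
    current: list[tuple[str, float]] = []
    prev_t = None
    for eid, t in deliveries:
        if prev_t is not None and (t - prev_t) * 1000.0 > max_sl_ms:
            segments.append(current)
            current = []
        current.append((eid, t))
        prev_t = t
    if current:
        segments.append(current)
    return segments


def extract_comm_events(
    sts: SpikeTrainSet,
    max_sl_ms: float = MAX_SL_MS,
    mode: str = "bursts",
    burst_max_isi_ms: float = 100.0,
    burst_min_spikes: int = 3,
) -> list[CommEvent]:
    """Communication events from chained first-delivery times.

    ``mode="bursts"`` (default) seeds candidate windows from per-unit bursts
    merged across electrodes into network-burst windows; ``mode="whole"``
    treats the entire recording as a single candidate window.  Within each
    window, each electrode contributes its first spike; the time-sorted
    deliveries are split wherever an adjacent gap exceeds ``max_sl_ms``, and
    every maximal segment spanning >= 2 distinct electrodes becomes one
    event with ``comm_time = last - first`` delivery.
    """
    if mode not in ("bursts", "whole"):
        raise ValueError("mode must be 'bursts' or 'whole'")
    if mode == "whole":
        windows = [(0.0, sts.duration_s)]
    else:
        bursts = detect_bursts_set(sts, burst_max_isi_ms, burst_min_spikes)
        intervals = sorted((b.start_s, b.end_s) for b in bursts)
        windows = []
        for s, e in intervals:
            if windows and s <= windows[-1][1]:
                windows[-1] = (windows[-1][0], max(windows[-1][1], e))
            else:
                windows.append((s, e))
    events: list[CommEvent] = []
    electrode_trains = {e: sts.electrode_train(e) for e in sts.electrode_ids}
    for (w0, w1) in windows:
        deliveries = []
        for eid, t in electrode_trains.items():
            i = np.searchsorted(t, w0, side="left")
            if i < t.size and t[i] <= w1:
                deliveries.append((eid, float(t[i])))
        deliveries.sort(key=lambda d: (d[1], d[0]))
        for seg in _chain_split(deliveries, max_sl_ms):
            if len({e for e, _ in seg}) < 2:
                continue
            events.append(
                CommEvent(
                    deliveries=tuple(seg),
                    origin=seg[0][0],
                    comm_time_ms=(seg[-1][1] - seg[0][1]) * 1000.0,
                    window=(w0, w1),
                )
            )
    return events


def network_distance(layout: ElectrodeLayout, origin: str, target: str) -> float:
    """Planar (Euclidean) distance between two electrodes, μm."""
    return layout.distance(origin, target)


def speed_points(events: list[CommEvent], layout: ElectrodeLayout) -> np.ndarray:
    """(time_ms, distance_um) points: every member electrode of every event,
    measured from the event's origin electrode and first delivery."""
    pts = []
    for ev in events:
        t0 = ev.deliveries[0][1]
        for eid, t in ev.deliveries:
            pts.append(((t - t0) * 1000.0, layout.distance(ev.origin, eid)))
    return np.asarray(pts) if pts else np.empty((0, 2))


def fit_speed(
    events: list[CommEvent] | np.ndarray,
    layout: ElectrodeLayout | None = None,
    state: str = "",
) -> SpeedFit:
    """Network communication velocity: OLS slope of distance on time.

    Accepts either communication events plus a layout, or a pre-computed
    (time_ms, distance_um) point array.  The slope (μm/ms) is reported in
    m/s with a 95% t-interval; needs >= 3 points with >= 2 distinct times.
    """
    if isinstance(events, np.ndarray):
        pts = events
    else:
        if layout is None:
            raise ValueError("layout required when passing events")
        pts = speed_points(events, layout)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points for a speed fit")
    t, d = pts[:, 0], pts[:, 1]
    if np.unique(t).size < 2:
        raise ValueError("degenerate fit: all communication times identical")
    res = stats.linregress(t, d)
    n = t.size
    # exact fits have zero residual SE; the CI collapses onto the slope
    if np.isfinite(res.stderr) and res.stderr > 0:
        half = stats.t.ppf(0.975, n - 2) * res.stderr
    else:
        half = 0.0
    slope = res.slope * 1e-3  # μm/ms -> m/s
    return SpeedFit(
        slope_m_s=float(slope),
        ci95_m_s=(float((res.slope - half) * 1e-3), float((res.slope + half) * 1e-3)),
        intercept_um=float(res.intercept),
        r_squared=float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0,
        n_points=int(n),
        state=state,
    )


def compare_states(fits_by_state: dict[str, list[SpeedFit]]) -> dict:
    """Pairwise two-tailed t tests on replicate velocities across states.

    Returns per-state mean ± SEM and a table of Welch two-sample two-tailed
    t tests for every state pair with >= 2 replicates each.
    """
    summary = {}
    for state, fits in fits_by_state.items():
        v = np.array([f.slope_m_s for f in fits])
        summary[state] = {
            "n": int(v.size),
            "mean_m_s": float(v.mean()) if v.size else float("nan"),
            "sem_m_s": float(stats.sem(v)) if v.size > 1 else float("nan"),
        }
    tests = []
    states = list(fits_by_state)
    for i in range(len(states)):
        for j in range(i + 1, len(states)):
            a = np.array([f.slope_m_s for f in fits_by_state[states[i]]])
            b = np.array([f.slope_m_s for f in fits_by_state[states[j]]])
            row = {"state_a": states[i], "state_b": states[j],
                   "mean_diff_m_s": float(a.mean() - b.mean()) if a.size and b.size
                   else float("nan")}
            if a.size >= 2 and b.size >= 2:
                if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
                    t, p = 0.0, 1.0  # identical constant groups
                else:
                    t, p = stats.ttest_ind(a, b)
                row["t"] = float(t)
                row["p"] = float(p)
            else:
                row["t"] = float("nan")
                row["p"] = float("nan")
            tests.append(row)
    return {"summary": summary, "tests": tests}
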