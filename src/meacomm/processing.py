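"""Raw-trace processing: band split, spike detection, unit sorting.

The spike band (>250 Hz) and local-field-potential band (<250 Hz) are
separated with zero-phase 4th-order Butterworth filters so that downstream
latency estimates are not biased by filter group delay.  Detection uses a
negative amplitude threshold at ``k`` robust noise standard deviations
(median absolute deviation / 0.6745).  Sorting projects the detected
waveform cutouts onto their first three principal components and clusters
them by valley seeking: each point hill-climbs over a k-nearest-neighbour
graph to a local mode of a Gaussian kernel density estimate, and points
reaching the same mode form one unit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.stats import gaussian_kde, median_abs_deviation
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .simulate import RawRecording
from .trains import SpikeTrainSet

logger = logging.getLogger(__name__)

SPIKE_LFP_SPLIT_HZ = 250.0


def bandsplit(
    raw: RawRecording, split_hz: float = SPIKE_LFP_SPLIT_HZ, order: int = 4
) -> tuple[RawRecording, RawRecording]:
    """Split a recording into spike band (high-pass) and LFP band (low-pass).

    Zero-phase (forward-backward) filtering; output shapes equal the input.
    """
    if raw.fs_hz <= 2 * split_hz:
        raise ValueError(
            f"sampling rate {raw.fs_hz} Hz too low for a {split_hz} Hz split"
        )
    sos_hi = signal.butter(order, split_hz, btype="highpass", fs=raw.fs_hz, output="sos")
    sos_lo = signal.butter(order, split_hz, btype="lowpass", fs=raw.fs_hz, output="sos")
    spike = signal.sosfiltfilt(sos_hi, raw.samples, axis=1)
    lfp = signal.sosfiltfilt(sos_lo, raw.samples, axis=1)
    return (
        RawRecording(spike.astype(np.float32), raw.fs_hz, raw.channel_ids),
        RawRecording(lfp.astype(np.float32), raw.fs_hz, raw.channel_ids),
    )


@dataclass
class WaveformSet:
    """Detected spike events with their waveform cutouts.

    ``cutouts`` has one row per event; rows on the same channel are in time
    order.  ``align_index`` is the within-cutout sample of the trough.
    """

    channel_ids: np.ndarray  # (n_events,) str
    times_s: np.ndarray  # (n_events,) float
    cutouts: np.ndarray  # (n_events, cutout_len) float
    align_index: int
    fs_hz: float
    n_dropped: int = 0
    duration_s: float = 0.0

    @property
    def n_events(self) -> int:
        return self.times_s.size

    def channel_events(self, channel_id: str) -> np.ndarray:
        return np.flatnonzero(self.channel_ids == channel_id)


def robust_noise_sd(x: np.ndarray) -> float:
    """Noise SD estimate insensitive to spikes: MAD / 0.6745."""
    return float(median_abs_deviation(x) / 0.6745)


def detect_spikes(
    spike_band: RawRecording,
    k: float = 5.0,
    cutout_ms: tuple[float, float] = (0.6, 1.0),
) -> WaveformSet:
    """Threshold detection of negative-going spikes on every channel.

    Events are troughs below ``-k`` robust noise SDs, aligned to the trough,
    with a dead time equal to the cutout length so overlapping threshold
    crossings yield a single event.  Events whose cutout would fall outside
    the recording are dropped and counted in ``n_dropped``.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    fs = spike_band.fs_hz
    pre = int(round(cutout_ms[0] / 1000.0 * fs))
    post = int(round(cutout_ms[1] / 1000.0 * fs))
    cut_len = pre + post + 1
    dead = cut_len

    ch_out, t_out, w_out = [], [], []
    n_dropped = 0
    for ch, cid in enumerate(spike_band.channel_ids):
        x = spike_band.samples[ch].astype(float)
        thr = -k * robust_noise_sd(x)
        below = np.flatnonzero(x < thr)
        if below.size == 0:
            continue
        # contiguous below-threshold segments -> candidate troughs
        breaks = np.flatnonzero(np.diff(below) > 1)
        seg_starts = np.concatenate([[0], breaks + 1])
        seg_ends = np.concatenate([breaks, [below.size - 1]])
        troughs = []
        for s, e in zip(seg_starts, seg_ends):
            seg = below[s : e + 1]
            troughs.append(seg[np.argmin(x[seg])])
        # dead time between accepted events
        accepted = []
        last = -dead - 1
        for tr in troughs:
            if tr - last >= dead:
                accepted.append(tr)
                last = tr
        for tr in accepted:
            i0, i1 = tr - pre, tr + post + 1
            if i0 < 0 or i1 > x.size:
                n_dropped += 1
                continue
            ch_out.append(cid)
            t_out.append(tr / fs)
            w_out.append(x[i0:i1])
    if n_dropped:
        logger.info("detect_spikes: dropped %d boundary events", n_dropped)
    cutouts = np.asarray(w_out) if w_out else np.empty((0, cut_len))
    return WaveformSet(
        channel_ids=np.asarray(ch_out, dtype=object),
        times_s=np.asarray(t_out, dtype=float),
        cutouts=cutouts,
        align_index=pre,
        fs_hz=fs,
        n_dropped=n_dropped,
        duration_s=spike_band.duration_s,
    )


def valley_seeking_labels(
    points: np.ndarray, k: int | None = None, valley_ratio: float = 0.5
) -> np.ndarray:
    """Mode-seeking cluster labels via kNN hill climbing on a KDE.

    Each point moves to the highest-density point among its k nearest
    neighbours (including itself) until it reaches a fixed point; points
    converging to the same mode share a preliminary label.  Neighbouring
    clusters are then merged unless a genuine density valley separates
    them: the densest boundary point between two clusters must fall below
    ``valley_ratio`` times the lower of their mode densities for the split
    to stand.  ``k`` defaults to ⌈√n⌉.  Labels are dense from 0, ordered by
    decreasing cluster size.
    """
    n = points.shape[0]
    if n == 0:
        return np.empty(0, dtype=int)
    if n == 1:
        return np.zeros(1, dtype=int)
    if k is None:
        k = int(np.ceil(np.sqrt(n)))
    k = min(max(k, 2), n)
    try:
        density = gaussian_kde(points.T)(points.T)  # Scott's rule bandwidth
    except np.linalg.LinAlgError:
        logger.warning("valley seeking: degenerate (singular) point cloud; one unit")
        return np.zeros(n, dtype=int)
    nn = NearestNeighbors(n_neighbors=k).fit(points)
    _, idx = nn.kneighbors(points)
    # next[i]: neighbour of i with the highest density (could be i itself)
    nbr_density = density[idx]
    nxt = idx[np.arange(n), np.argmax(nbr_density, axis=1)]
    # ties / numerics: a point is a mode if no strictly denser neighbour
    is_mode = density[nxt] <= density[np.arange(n)]
    nxt = np.where(is_mode, np.arange(n), nxt)
    # pointer jumping until every point sits on its mode
    root = nxt
    for _ in range(n):
        new = root[root]
        if np.array_equal(new, root):
            break
        root = new

    # merge clusters with no density valley between them (union-find)
    parent = {m: m for m in np.unique(root)}

    def find(m):
        while parent[m] != m:
            parent[m] = parent[parent[m]]
            m = parent[m]
        return m

    merged = True
    while merged:
        merged = False
        mode_of = {}
        for m in parent:
            r = find(m)
            if r not in mode_of or density[m] > density[mode_of[r]]:
                mode_of.setdefault(r, r)
                if density[m] > density[mode_of[r]]:
                    mode_of[r] = m
        saddles: dict[tuple, float] = {}
        for i in range(n):
            ci = find(root[i])
            for j in idx[i]:
                cj = find(root[j])
                if ci == cj:
                    continue
                key = (ci, cj) if ci < cj else (cj, ci)
                s = min(density[i], density[j])
                if s > saddles.get(key, -np.inf):
                    saddles[key] = s
        for (ca, cb), s in saddles.items():
            ra, rb = find(ca), find(cb)
            if ra == rb:
                continue
            floor = valley_ratio * min(density[mode_of[ra]], density[mode_of[rb]])
            if s >= floor:
                parent[rb] = ra
                merged = True
    final = np.array([find(r) for r in root])
    _, labels = np.unique(final, return_inverse=True)
    # relabel by decreasing cluster size
    counts = np.bincount(labels)
    order = np.argsort(-counts, kind="stable")
    remap = np.empty_like(order)
    remap[order] = np.arange(order.size)
    return remap[labels]


def _realign_cutouts(w: np.ndarray, up: int = 4, max_shift: int = 2) -> np.ndarray:
    """Sub-sample alignment of cutouts to their upsampled trough.

    One-sample alignment jitter at detection time otherwise splits a single
    waveform shape into shifted near-copies that cluster apart.  Cutouts are
    upsampled ``up``-fold, re-centred on the trough found within
    ``±max_shift`` original samples of the nominal alignment point, and
    cropped to a common window.
    """
    n, L = w.shape
    wu = signal.resample_poly(w, up, 1, axis=1)
    nu = wu.shape[1]
    center = int(np.argmin(w.mean(axis=0))) * up
    troughs = np.clip(np.argmin(wu, axis=1), 1, nu - 2)
    margin = max_shift * up + 1
    half_pre = center - margin
    half_post = nu - center - margin
    if half_pre <= 0 or half_post <= 0:
        return w
    grid = np.arange(-half_pre, half_post)
    out = np.empty((n, grid.size))
    for i in range(n):
        c = troughs[i]
        # parabolic refinement of the trough to a fractional position
        ym, y0, yp = wu[i, c - 1], wu[i, c], wu[i, c + 1]
        denom = ym - 2 * y0 + yp
        frac = 0.5 * (ym - yp) / denom if abs(denom) > 1e-12 else 0.0
        pos = c + float(np.clip(frac, -0.5, 0.5))
        out[i] = np.interp(pos + grid, np.arange(nu), wu[i])
    return out


def sort_units(
    events: WaveformSet,
    n_components: int = 3,
    knn: int | None = None,
) -> SpikeTrainSet:
    """Sort detected waveforms into single units per channel.

    Cutouts on each channel are projected onto their first three principal
    components and clustered by valley seeking.  Channels with fewer than
    two events, or with degenerate (zero-variance) cutouts, get a single
    unit 0.  Per-spike peak-to-peak amplitudes are carried into the result.
    """
    duration = events.duration_s or (
        float(events.times_s.max()) + 1e-3 if events.n_events else 1.0
    )
    trains: dict[tuple[str, int], np.ndarray] = {}
    amps: dict[tuple[str, int], np.ndarray] = {}
    for cid in dict.fromkeys(events.channel_ids.tolist()):
        sel = events.channel_events(cid)
        w = events.cutouts[sel]
        t = events.times_s[sel]
        p2p = w.max(axis=1) - w.min(axis=1)
        if sel.size < 2:
            labels = np.zeros(sel.size, dtype=int)
        else:
            aligned = _realign_cutouts(w)
            centred = aligned - aligned.mean(axis=0)
            if np.allclose(centred, 0):
                logger.warning("sort_units: zero-variance cutouts on %s; one unit", cid)
                labels = np.zeros(sel.size, dtype=int)
            else:
                nc = min(n_components, aligned.shape[0], aligned.shape[1])
                scores = PCA(n_components=nc).fit_transform(aligned)
                labels = valley_seeking_labels(scores, knn)
        for u in np.unique(labels):
            mask = labels == u
            trains[(str(cid), int(u))] = t[mask]
            amps[(str(cid), int(u))] = p2p[mask]
    return SpikeTrainSet(trains, duration, amps)
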