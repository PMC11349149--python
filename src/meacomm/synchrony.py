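"""Pairwise synchronization scores between electrode spike trains.

The score is the maximum, over integer-bin lags within ±max_lag, of the
Pearson correlation between the binned spike-count vectors of the two
trains, clipped below at zero — a [0, 1] score where identical trains give
1 and independent trains give values near 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trains import SpikeTrainSet

DEFAULT_BIN_MS = 10.0
DEFAULT_MAX_LAG_MS = 10.0


@dataclass(frozen=True)
class SyncMatrix:
    electrode_ids: tuple[str, ...]
    scores: np.ndarray  # symmetric, [0, 1], diagonal 1
    bin_ms: float
    max_lag_ms: float


def bin_counts(times: np.ndarray, duration_s: float, bin_ms: float) -> np.ndarray:
    """Spike counts in consecutive bins covering [0, duration]."""
    if bin_ms <= 0:
        raise ValueError("bin_ms must be > 0")
    n_bins = max(int(np.ceil(duration_s * 1000.0 / bin_ms)), 1)
    edges = np.arange(n_bins + 1) * (bin_ms / 1000.0)
    counts, _ = np.histogram(times, bins=edges)
    return counts


def _lagged_pearson(a: np.ndarray, b: np.ndarray, lag: int) -> float:
    """Pearson correlation of a[t] with b[t+lag] over the overlap."""
    if lag >= 0:
        x, y = a[: a.size - lag] if lag else a, b[lag:]
    else:
        x, y = a[-lag:], b[: b.size + lag]
    if x.size < 2 or x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def sync_score(
    a: np.ndarray,
    b: np.ndarray,
    duration_s: float,
    bin_ms: float = DEFAULT_BIN_MS,
    max_lag_ms: float = DEFAULT_MAX_LAG_MS,
) -> float:
    """Lag-maximized binned Pearson correlation, clipped to [0, 1].

    Empty or constant-count trains score 0 by convention (never NaN).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    ca = bin_counts(a, duration_s, bin_ms)
    cb = bin_counts(b, duration_s, bin_ms)
    max_lag = int(np.floor(max_lag_ms / bin_ms))
    best = max(
        _lagged_pearson(ca, cb, lag) for lag in range(-max_lag, max_lag + 1)
    )
    return float(min(max(best, 0.0), 1.0))


def sync_matrix(
    sts: SpikeTrainSet,
    bin_ms: float = DEFAULT_BIN_MS,
    max_lag_ms: float = DEFAULT_MAX_LAG_MS,
    electrode_ids: list[str] | None = None,
) -> SyncMatrix:
    """Symmetric synchronization matrix over whole-electrode trains.

    Electrodes without spikes appear as zero rows/columns; the diagonal is
    1 for every electrode by definition.
    """
    ids = list(electrode_ids) if electrode_ids is not None else sts.electrode_ids
    n = len(ids)
    if n < 1:
        raise ValueError("at least one electrode required")
    counts = np.stack([bin_counts(sts.electrode_train(e), sts.duration_s, bin_ms)
                       for e in ids])
    max_lag = int(np.floor(max_lag_ms / bin_ms))
    sd = counts.std(axis=1)
    scores = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if sd[i] == 0 or sd[j] == 0:
                continue
            best = max(
                _lagged_pearson(counts[i], counts[j], lag)
                for lag in range(-max_lag, max_lag + 1)
            )
            scores[i, j] = scores[j, i] = min(max(best, 0.0), 1.0)
    np.fill_diagonal(scores, 1.0)
    return SyncMatrix(tuple(ids), scores, bin_ms, max_lag_ms)
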