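"""Spike-train containers, burst detection and activity metrics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class BurstEvent:
    """A run of high-frequency firing on one unit.

    A burst is a maximal run of consecutive spikes whose inter-spike intervals
    are all at most ``max_isi_ms`` and which contains at least ``min_spikes``
    spikes.
    """

    electrode_id: str
    unit_id: int
    start_s: float
    end_s: float
    n_spikes: int

    def __post_init__(self):
        if self.end_s < self.start_s:
            raise ValueError("burst end before start")


class SpikeTrainSet:
    """Sorted spike times per (electrode, unit) over a recording window.

    Times are in seconds within ``[0, duration_s]``.  Unit ids are dense
    integers per electrode (0, 1, ...).  Optional per-spike peak-to-peak
    amplitudes (arbitrary voltage units) may accompany each train.
    """

    def __init__(
        self,
        trains: dict[tuple[str, int], np.ndarray],
        duration_s: float,
        amplitudes: dict[tuple[str, int], np.ndarray] | None = None,
    ):
        if duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        self.duration_s = float(duration_s)
        self.trains: dict[tuple[str, int], np.ndarray] = {}
        self.amplitudes: dict[tuple[str, int], np.ndarray] = {}
        for key, t in trains.items():
            eid, uid = str(key[0]), int(key[1])
            t = np.sort(np.asarray(t, dtype=float))
            if t.size and (t[0] < 0 or t[-1] > duration_s):
                raise ValueError(f"spike times of {key} outside [0, duration]")
            self.trains[(eid, uid)] = t
            if amplitudes and key in amplitudes:
                a = np.asarray(amplitudes[key], dtype=float)
                if a.shape != t.shape:
                    raise ValueError("amplitude/time shape mismatch")
                order = np.argsort(np.asarray(trains[key], dtype=float))
                self.amplitudes[(eid, uid)] = a[order]

    @property
    def electrode_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for eid, _ in self.trains:
            seen.setdefault(eid, None)
        return list(seen)

    @property
    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.trains.values()))

    def electrode_train(self, electrode_id: str) -> np.ndarray:
        """All spike times on one electrode, merged across units, sorted."""
        parts = [t for (eid, _), t in self.trains.items() if eid == electrode_id]
        if not parts:
            return np.empty(0)
        return np.sort(np.concatenate(parts))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (eid, uid), t in sorted(self.trains.items()):
            df = pd.DataFrame({"electrode_id": eid, "unit_id": uid, "time_s": t})
            if (eid, uid) in self.amplitudes:
                df["amplitude"] = self.amplitudes[(eid, uid)]
            rows.append(df)
        if not rows:
            return pd.DataFrame(columns=["electrode_id", "unit_id", "time_s"])
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, duration_s: float) -> "SpikeTrainSet":
        trains: dict[tuple[str, int], np.ndarray] = {}
        amps: dict[tuple[str, int], np.ndarray] = {}
        has_amp = "amplitude" in df.columns
        for (eid, uid), g in df.groupby(["electrode_id", "unit_id"], sort=True):
            key = (str(eid), int(uid))
            trains[key] = g["time_s"].to_numpy(dtype=float)
            if has_amp and g["amplitude"].notna().all():
                amps[key] = g["amplitude"].to_numpy(dtype=float)
        return cls(trains, duration_s, amps or None)


def detect_bursts(
    times: np.ndarray,
    max_isi_ms: float = 100.0,
    min_spikes: int = 3,
    electrode_id: str = "",
    unit_id: int = 0,
) -> list[BurstEvent]:
    """Maximal runs of spikes with every inter-spike interval <= ``max_isi_ms``.

    Runs shorter than ``min_spikes`` are discarded.  The default criteria
    (100 ms, 3 spikes) follow the common max-inter-spike-interval convention
    for cultured networks.
    """
    if max_isi_ms <= 0:
        raise ValueError("max_isi_ms must be > 0")
    if min_spikes < 2:
        raise ValueError("min_spikes must be >= 2")
    t = np.sort(np.asarray(times, dtype=float))
    if t.size < min_spikes:
        return []
    gap = np.diff(t) > max_isi_ms / 1000.0
    # run boundaries: positions where a too-long interval splits the train
    starts = np.concatenate([[0], np.flatnonzero(gap) + 1])
    ends = np.concatenate([np.flatnonzero(gap), [t.size - 1]])
    out = []
    for s, e in zip(starts, ends):
        n = e - s + 1
        if n >= min_spikes:
            out.append(BurstEvent(electrode_id, unit_id, float(t[s]), float(t[e]), int(n)))
    return out


def detect_bursts_set(
    sts: SpikeTrainSet, max_isi_ms: float = 100.0, min_spikes: int = 3
) -> list[BurstEvent]:
    """Burst detection applied to every (electrode, unit) train in a set."""
    out: list[BurstEvent] = []
    for (eid, uid), t in sorted(sts.trains.items()):
        out.extend(detect_bursts(t, max_isi_ms, min_spikes, eid, uid))
    return out


def activity_metrics(sts: SpikeTrainSet, active_rate_hz: float = 0.1) -> dict:
    """Per-electrode firing rates plus the summary activity statistics.

    An electrode is *active* when its merged firing rate is at least
    ``active_rate_hz``.  Returns a dict with a per-electrode table and the
    summary values: number of active electrodes, mean rate over active
    electrodes and mean peak-to-peak amplitude over active electrodes (NaN
    when no amplitudes are available).
    """
    rows = []
    for eid in sts.electrode_ids:
        t = sts.electrode_train(eid)
        rate = t.size / sts.duration_s
        amp_parts = [
            a for (e, _), a in sts.amplitudes.items() if e == eid and a.size
        ]
        amp = float(np.concatenate(amp_parts).mean()) if amp_parts else np.nan
        rows.append(
            {
                "electrode_id": eid,
                "n_spikes": int(t.size),
                "rate_hz": rate,
                "active": rate >= active_rate_hz,
                "mean_p2p_amplitude": amp,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["electrode_id", "n_spikes", "rate_hz", "active", "mean_p2p_amplitude"],
    )
    active = table[table["active"]] if len(table) else table
    return {
        "per_electrode": table,
        "n_active_electrodes": int(active.shape[0]) if len(table) else 0,
        "mean_rate_hz": float(active["rate_hz"].mean()) if len(active) else 0.0,
        "mean_p2p_amplitude": float(active["mean_p2p_amplitude"].mean())
        if len(active) and active["mean_p2p_amplitude"].notna().any()
        else float("nan"),
        "active_rate_hz": active_rate_hz,
    }
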