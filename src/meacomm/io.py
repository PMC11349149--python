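"""Plain-text file formats for every pipeline artefact.

Times are seconds in spike tables; latencies and communication times are
milliseconds in reports.  All delimited files are UTF-8 CSV with a header
line and '.' decimal separator.  Raw traces are flat binary 32-bit floats,
channel-major, with a plain-text sidecar describing shape and scale.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .layout import ElectrodeLayout
from .simulate import GroundTruth, RawRecording
from .trains import SpikeTrainSet

logger = logging.getLogger(__name__)


# -- spike tables -----------------------------------------------------------

def write_spike_table(sts: SpikeTrainSet, path: str | Path) -> None:
    df = sts.to_frame()
    df.to_csv(path, index=False)


def read_spike_table(path: str | Path, duration_s: float | None = None) -> SpikeTrainSet:
    """Read a spike table; unsorted times are sorted with a warning.

    Malformed rows raise with their 1-based line number.  When
    ``duration_s`` is omitted it is taken as the latest spike time.
    """
    df = pd.read_csv(path, dtype={"electrode_id": str})
    required = {"electrode_id", "unit_id", "time_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    times = pd.to_numeric(df["time_s"], errors="coerce")
    units = pd.to_numeric(df["unit_id"], errors="coerce")
    bad = times.isna() | units.isna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise ValueError(f"{path}: malformed row at line {line}")
    df["time_s"] = times
    df["unit_id"] = units.astype(int)
    for _, g in df.groupby(["electrode_id", "unit_id"]):
        if not g["time_s"].is_monotonic_increasing:
            logger.warning("%s: unsorted spike times; sorting on read", path)
            break
    if duration_s is None:
        duration_s = float(df["time_s"].max()) if len(df) else 1.0
        duration_s = max(duration_s, np.finfo(float).tiny)
    return SpikeTrainSet.from_frame(df, duration_s)


# -- layouts and ground truth ----------------------------------------------

def write_layout(layout: ElectrodeLayout, path: str | Path) -> None:
    pd.DataFrame(
        {"id": layout.ids, "x_um": layout.positions[:, 0], "y_um": layout.positions[:, 1]}
    ).to_csv(path, index=False)


def read_layout(path: str | Path) -> ElectrodeLayout:
    df = pd.read_csv(path, dtype={"id": str})
    if not {"id", "x_um", "y_um"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns id, x_um, y_um")
    return ElectrodeLayout(tuple(df["id"]), df[["x_um", "y_um"]].to_numpy(float))


def write_edges(gt: GroundTruth, path: str | Path) -> None:
    pd.DataFrame(gt.edges, columns=["src", "dst", "latency_ms"]).to_csv(path, index=False)


def read_edges(path: str | Path) -> list[tuple[str, str, float]]:
    df = pd.read_csv(path, dtype={"src": str, "dst": str})
    return [(r.src, r.dst, float(r.latency_ms)) for r in df.itertuples()]


# -- raw binary + sidecar ---------------------------------------------------

def write_raw(raw: RawRecording, path: str | Path, scale: float = 1.0) -> None:
    """Flat float32 binary, channel-major, with '<path>.meta' text sidecar."""
    path = Path(path)
    (raw.samples / scale).astype("<f4").tofile(path)
    sidecar = path.with_suffix(path.suffix + ".meta")
    sidecar.write_text(
        "format: meacomm-raw-v1\n"
        f"n_channels: {raw.n_channels}\n"
        f"fs_hz: {raw.fs_hz}\n"
        f"scale: {scale}\n"
        f"dtype: float32-le\n"
        f"channel_ids: {','.join(raw.channel_ids)}\n",
        encoding="utf-8",
    )


def read_raw(path: str | Path) -> RawRecording:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".meta")
    meta: dict[str, str] = {}
    for line in sidecar.read_text(encoding="utf-8").splitlines():
        key, _, value = line.partition(":")
        meta[key.strip()] = value.strip()
    n_channels = int(meta["n_channels"])
    data = np.fromfile(path, dtype="<f4")
    if data.size % n_channels:
        raise ValueError(f"{path}: sample count not divisible by n_channels")
    samples = data.reshape(n_channels, -1) * float(meta.get("scale", 1.0))
    return RawRecording(samples, float(meta["fs_hz"]), tuple(meta["channel_ids"].split(",")))


# -- matrices and graphs ----------------------------------------------------

def write_matrix(ids, matrix: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(matrix, index=list(ids), columns=list(ids)).to_csv(path, index_label="id")


def read_matrix(path: str | Path) -> tuple[tuple[str, ...], np.ndarray]:
    df = pd.read_csv(path, index_col="id")
    df.index = df.index.astype(str)
    return tuple(df.columns.astype(str)), df.to_numpy(float)


def write_graph(g: nx.Graph, path_edgelist: str | Path,
                path_graphml: str | Path | None = None) -> None:
    rows = [
        {"src": u, "dst": v, "mi_bits": d.get("mi_bits"), "strong": bool(d.get("strong"))}
        for u, v, d in sorted(g.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["src", "dst", "mi_bits", "strong"]).to_csv(
        path_edgelist, index=False
    )
    if path_graphml is not None:
        nx.write_graphml(g, path_graphml)


# -- reports ----------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj


def write_json_report(report: dict, path: str | Path) -> None:
    """Deterministic JSON: sorted keys, no timestamps, trailing newline."""
    Path(path).write_text(
        json.dumps(_jsonable(report), indent=2, sort_keys=True, allow_nan=True) + "\n",
        encoding="utf-8",
    )
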