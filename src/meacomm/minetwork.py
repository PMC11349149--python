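"""Mutual-information functional connectivity networks.

Spike trains are discretized into 10 ms bins and binarized (any spike → 1);
pairwise dependence is the plug-in (maximum-likelihood) mutual information
of the 2×2 joint histogram, in bits.  An undirected communication network
connects every electrode pair whose MI exceeds an edge threshold (0.1 bit
by default), with a "strong" subset above a second threshold (0.2 bit).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .synchrony import bin_counts
from .trains import SpikeTrainSet

DEFAULT_BIN_MS = 10.0
EDGE_THRESHOLD_BITS = 0.1
STRONG_THRESHOLD_BITS = 0.2


@dataclass(frozen=True)
class MIMatrix:
    electrode_ids: tuple[str, ...]
    mi_bits: np.ndarray  # symmetric, >= 0; diagonal = per-electrode entropy
    bin_ms: float
    estimator: str = "plugin-binary"


def _entropy_bits(p: np.ndarray) -> float:
    """Shannon entropy of a probability vector, bits, with 0·log0 = 0."""
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def binary_mi_bits(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in MI (bits) of two equal-length binary sequences."""
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise ValueError("sequences must have equal length")
    n = x.size
    if n == 0:
        return 0.0
    n11 = int(np.count_nonzero(x & y))
    n10 = int(np.count_nonzero(x & ~y))
    n01 = int(np.count_nonzero(~x & y))
    n00 = n - n11 - n10 - n01
    joint = np.array([n00, n01, n10, n11], dtype=float) / n
    px = np.array([n00 + n01, n10 + n11], dtype=float) / n
    py = np.array([n00 + n10, n01 + n11], dtype=float) / n
    return _entropy_bits(px) + _entropy_bits(py) - _entropy_bits(joint)


def miller_madow_correction(mi_bits: float, x: np.ndarray, y: np.ndarray) -> float:
    """Miller–Madow bias-corrected MI: subtract (df)/(2N ln 2) per entropy term."""
    n = np.asarray(x).size
    kx = len(np.unique(np.asarray(x, dtype=bool)))
    ky = len(np.unique(np.asarray(y, dtype=bool)))
    kxy = len({(a, b) for a, b in zip(np.asarray(x, bool), np.asarray(y, bool))})
    corr = ((kx - 1) + (ky - 1) - (kxy - 1)) / (2 * n * np.log(2))
    return max(mi_bits - corr, 0.0)


def mutual_information(
    a: np.ndarray,
    b: np.ndarray,
    duration_s: float,
    bin_ms: float = DEFAULT_BIN_MS,
    bias_correction: bool = False,
) -> float:
    """MI in bits between two spike trains binarized at ``bin_ms`` resolution."""
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    x = bin_counts(a, duration_s, bin_ms) > 0
    y = bin_counts(b, duration_s, bin_ms) > 0
    mi = binary_mi_bits(x, y)
    if bias_correction:
        mi = miller_madow_correction(mi, x, y)
    return mi


def mi_matrix(
    sts: SpikeTrainSet,
    bin_ms: float = DEFAULT_BIN_MS,
    electrode_ids: list[str] | None = None,
    bias_correction: bool = False,
) -> MIMatrix:
    """Symmetric pairwise MI matrix; diagonal holds each electrode's entropy."""
    ids = list(electrode_ids) if electrode_ids is not None else sts.electrode_ids
    n = len(ids)
    if n < 1:
        raise ValueError("at least one electrode required")
    occ = np.stack(
        [bin_counts(sts.electrode_train(e), sts.duration_s, bin_ms) > 0 for e in ids]
    )
    mi = np.zeros((n, n))
    for i in range(n):
        p = occ[i].mean()
        mi[i, i] = _entropy_bits(np.array([p, 1 - p]))
        for j in range(i + 1, n):
            v = binary_mi_bits(occ[i], occ[j])
            if bias_correction:
                v = miller_madow_correction(v, occ[i], occ[j])
            mi[i, j] = mi[j, i] = v
    return MIMatrix(tuple(ids), mi, bin_ms,
                    "plugin-binary-mm" if bias_correction else "plugin-binary")


def build_graph(
    mi: MIMatrix,
    edge_threshold: float = EDGE_THRESHOLD_BITS,
    strong_threshold: float = STRONG_THRESHOLD_BITS,
    active: dict[str, bool] | None = None,
) -> nx.Graph:
    """Thresholded communication network.

    Nodes are electrodes (with ``active`` and ``degree`` attributes); an
    undirected edge joins every pair with MI strictly above
    ``edge_threshold``, flagged ``strong`` when above ``strong_threshold``.
    """
    if strong_threshold < edge_threshold:
        raise ValueError("strong_threshold must be >= edge_threshold")
    g = nx.Graph(edge_threshold=edge_threshold, strong_threshold=strong_threshold,
                 bin_ms=mi.bin_ms, estimator=mi.estimator)
    for eid in mi.electrode_ids:
        g.add_node(eid, active=bool(active.get(eid, True)) if active else True)
    n = len(mi.electrode_ids)
    for i in range(n):
        for j in range(i + 1, n):
            w = float(mi.mi_bits[i, j])
            if w > edge_threshold:
                g.add_edge(
                    mi.electrode_ids[i],
                    mi.electrode_ids[j],
                    mi_bits=w,
                    strong=bool(w > strong_threshold),
                )
    for eid in g.nodes:
        g.nodes[eid]["degree"] = g.degree(eid)
    return g


def graph_summary(g: nx.Graph) -> dict:
    """Counts used to summarize a communication network.

    Returns the number of active electrodes, total edges, strong edges and
    the degree distribution (degree → node count).
    """
    n_active = sum(1 for _, d in g.nodes(data=True) if d.get("active", True))
    n_edges = g.number_of_edges()
    n_strong = sum(1 for _, _, d in g.edges(data=True) if d.get("strong"))
    degrees = [d for _, d in g.degree()]
    dist: dict[int, int] = {}
    for d in degrees:
        dist[d] = dist.get(d, 0) + 1
    return {
        "n_active_electrodes": int(n_active),
        "n_edges": int(n_edges),
        "n_strong_edges": int(n_strong),
        "degree_distribution": dict(sorted(dist.items())),
    }
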