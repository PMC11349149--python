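"""Planar electrode layouts.

All distances downstream of the communication-velocity analysis come from the
layout, so positions are stored in micrometres and distances are Euclidean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ElectrodeLayout:
    """Electrode identifiers with planar coordinates (μm)."""

    ids: tuple[str, ...]
    positions: np.ndarray  # shape (n, 2), μm

    _index: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array")
        if pos.shape[0] != len(self.ids):
            raise ValueError("ids and positions length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("electrode ids must be unique")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        object.__setattr__(self, "_index", {e: i for i, e in enumerate(self.ids)})

    @property
    def n_electrodes(self) -> int:
        return len(self.ids)

    def index_of(self, electrode_id: str) -> int:
        try:
            return self._index[electrode_id]
        except KeyError:
            raise KeyError(f"unknown electrode id {electrode_id!r}") from None

    def position_of(self, electrode_id: str) -> np.ndarray:
        return self.positions[self.index_of(electrode_id)]

    def distance(self, a: str, b: str) -> float:
        """Euclidean distance between two electrodes, μm."""
        return float(np.linalg.norm(self.position_of(a) - self.position_of(b)))

    def pairwise_distances(self) -> np.ndarray:
        d = self.positions[:, None, :] - self.positions[None, :, :]
        return np.sqrt((d ** 2).sum(axis=-1))


def make_layout(n_rows: int, n_cols: int, pitch_um: float = 200.0) -> ElectrodeLayout:
    """Rectangular electrode grid with uniform pitch.

    Electrodes are laid out row-major; ids are ``E00``, ``E01``, ... zero-padded
    to a constant width.  Grid-adjacent electrodes are exactly ``pitch_um`` apart.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("n_rows and n_cols must be >= 1")
    if pitch_um <= 0:
        raise ValueError("pitch_um must be > 0")
    n = n_rows * n_cols
    width = max(2, len(str(n - 1)))
    ids = [f"E{i:0{width}d}" for i in range(n)]
    rows, cols = np.divmod(np.arange(n), n_cols)
    positions = np.column_stack([cols * pitch_um, rows * pitch_um]).astype(float)
    return ElectrodeLayout(tuple(ids), positions)


def grid_neighbors(n_rows: int, n_cols: int) -> list[tuple[int, int]]:
    """Index pairs of 4-neighbourhood adjacent electrodes on a row-major grid."""
    pairs = []
    for r in range(n_rows):
        for c in range(n_cols):
            i = r * n_cols + c
            if c + 1 < n_cols:
                pairs.append((i, i + 1))
            if r + 1 < n_rows:
                pairs.append((i, i + n_cols))
    return pairs
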