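"""Per-cell time-series container shared by simulation, acquisition and analysis."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TraceSet", "CHANNEL_NADPH", "CHANNEL_CALCIUM"]

CHANNEL_NADPH = "nadph"
CHANNEL_CALCIUM = "calcium_ratio"
_CHANNELS = (CHANNEL_NADPH, CHANNEL_CALCIUM)


@dataclass
class TraceSet:
    """One channel's traces for a set of cells on a common time base.

    Parameters
    ----------
    channel : {"nadph", "calcium_ratio"}
        Signal type: raw NAD(P)H autofluorescence (RFU) or FURA ratio.
    times_min : (T,) array
        Sample times in minutes, strictly increasing; all cells share the
        cycle time base (within-cycle stage offsets are folded into the
        nominal time point).
    values : (N, T) array
        One row per cell.
    cell_ids : list of str, length N
    """

    channel: str
    times_min: np.ndarray
    values: np.ndarray
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.channel not in _CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; expected one of {_CHANNELS}")
        if self.times_min.ndim != 1 or self.times_min.size < 2:
            raise ValueError("need at least 2 samples per trace")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.values.shape[1] != self.times_min.size:
            raise ValueError(
                f"values have {self.values.shape[1]} columns but there are "
                f"{self.times_min.size} timestamps"
            )
        if len(self.cell_ids) != self.values.shape[0]:
            raise ValueError("one cell_id required per trace row")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell_ids must be unique")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.times_min.size

    def get(self, cell_id: str) -> np.ndarray:
        return self.values[self.cell_ids.index(cell_id)]

    def subset(self, cell_ids: list[str]) -> "TraceSet":
        idx = [self.cell_ids.index(c) for c in cell_ids]
        return TraceSet(self.channel, self.times_min.copy(), self.values[idx], list(cell_ids))

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (cell, time point)."""
        n, t = self.values.shape
        return pd.DataFrame(
            {
                "cell_id": np.repeat(self.cell_ids, t),
                "time_min": np.tile(self.times_min, n),
                "value": self.values.ravel(),
                "channel": self.channel,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TraceSet":
        channels = frame["channel"].unique()
        if len(channels) != 1:
            raise ValueError(f"trace table mixes channels {sorted(channels)}")
        wide = frame.pivot(index="cell_id", columns="time_min", values="value")
        wide = wide.sort_index(axis=1)
        if wide.isna().any().any():
            raise ValueError("cells do not share a common time base")
        return cls(
            channel=str(channels[0]),
            times_min=wide.columns.to_numpy(dtype=float),
            values=wide.to_numpy(dtype=float),
            cell_ids=[str(c) for c in wide.index],
        )
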