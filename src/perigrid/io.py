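"""Readers and writers for the pipeline's plain-text interchange formats.

All tabular data are CSV with a header row; protocols and reports are JSON;
rendered region stacks are multi-page TIFF.  Floats round-trip losslessly
(shortest-repr formatting on write, exact parse on read).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthetic import CellGroundTruth, StainRecord
from .traces import TraceSet

__all__ = [
    "write_cells_csv",
    "read_cells_csv",
    "write_traces_csv",
    "read_traces_csv",
    "write_stains_csv",
    "read_stains_csv",
    "write_tiff_stack",
    "read_tiff_stack",
    "write_json",
    "read_json",
]

CELL_COLUMNS = [
    "cell_id",
    "type",
    "x_um",
    "y_um",
    "square_id",
    "response_param",
    "rfu_kcn_true",
    "rfu_fccp_true",
    "baseline_rfu",
    "drift_slope",
    "noise_sd",
]

STAIN_COLUMNS = [
    "x_um",
    "y_um",
    "square_id",
    "insulin_intensity",
    "glucagon_intensity",
    "source_cell_id",
]


def write_cells_csv(cells: list[CellGroundTruth], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "cell_id": c.cell_id,
                "type": c.type_label,
                "x_um": c.centroid_um[0],
                "y_um": c.centroid_um[1],
                "square_id": c.square_id,
                "response_param": c.response_param,
                "rfu_kcn_true": c.rfu_kcn_true,
                "rfu_fccp_true": c.rfu_fccp_true,
                "baseline_rfu": c.baseline_rfu,
                "drift_slope": c.drift_slope,
                "noise_sd": c.noise_sd,
            }
            for c in cells
        ],
        columns=CELL_COLUMNS,
    )
    frame.to_csv(path, index=False)


def read_cells_csv(path: str | Path) -> pd.DataFrame:
    """Live-session cell table (ROI centroids plus any generator columns)."""
    frame = pd.read_csv(path, dtype={"cell_id": str, "square_id": str}, float_precision="round_trip")
    required = {"cell_id", "x_um", "y_um", "square_id"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: cell table lacks columns {sorted(missing)}")
    return frame


def cells_from_frame(frame: pd.DataFrame) -> list[CellGroundTruth]:
    """Rebuild ground-truth records from a full generator cell table."""
    return [
        CellGroundTruth(
            cell_id=row["cell_id"],
            type_label=row["type"],
            centroid_um=(float(row["x_um"]), float(row["y_um"])),
            square_id=row["square_id"],
            response_param=float(row["response_param"]),
            rfu_kcn_true=float(row["rfu_kcn_true"]),
            rfu_fccp_true=float(row["rfu_fccp_true"]),
            baseline_rfu=float(row["baseline_rfu"]),
            drift_slope=float(row["drift_slope"]),
            noise_sd=float(row["noise_sd"]),
        )
        for _, row in frame.iterrows()
    ]


def write_traces_csv(traceset: TraceSet, path: str | Path) -> None:
    """Long format: cell_id, time_min, value, channel."""
    traceset.to_frame().to_csv(path, index=False)


def read_traces_csv(path: str | Path) -> TraceSet:
    frame = pd.read_csv(path, dtype={"cell_id": str, "channel": str}, float_precision="round_trip")
    missing = {"cell_id", "time_min", "value", "channel"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: trace table lacks columns {sorted(missing)}")
    return TraceSet.from_frame(frame)


def write_stains_csv(records: list[StainRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "x_um": r.centroid_um[0],
                "y_um": r.centroid_um[1],
                "square_id": r.square_id,
                "insulin_intensity": r.insulin_intensity,
                "glucagon_intensity": r.glucagon_intensity,
                "source_cell_id": r.source_cell_id if r.source_cell_id else "",
            }
            for r in records
        ],
        columns=STAIN_COLUMNS,
    )
    frame.to_csv(path, index=False)


def read_stains_csv(path: str | Path) -> list[StainRecord]:
    frame = pd.read_csv(path, dtype={"square_id": str, "source_cell_id": str}, float_precision="round_trip")
    missing = set(STAIN_COLUMNS[:-1]) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: stain table lacks columns {sorted(missing)}")
    records = []
    for _, row in frame.iterrows():
        src = row.get("source_cell_id", "")
        records.append(
            StainRecord(
                centroid_um=(float(row["x_um"]), float(row["y_um"])),
                square_id=row["square_id"],
                insulin_intensity=float(row["insulin_intensity"]),
                glucagon_intensity=float(row["glucagon_intensity"]),
                source_cell_id=None if pd.isna(src) or src == "" else str(src),
            )
        )
    return records


def write_tiff_stack(stack: np.ndarray, path: str | Path, metadata: dict | None = None) -> None:
    """Multi-page TIFF, one page per frame."""
    tifffile.imwrite(
        path,
        np.asarray(stack, dtype=np.float32),
        photometric="minisblack",
        metadata=metadata or {},
    )


def read_tiff_stack(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def write_json(data: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
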