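"""Per-cell response statistics from normalized perifusion traces.

NAD(P)H traces are calibrated per cell against the plateaus forced by the
electron-transport blocker KCN (maximal NAD(P)H, defined as 100%) and the
uncoupler FCCP (minimal, defined as 0%), making responses comparable across
cells regardless of dye-free signal scale.  The glucose response statistic
is the *minimum* of the two steady-state changes seen across the up- and
down-steps of glucose — a drift-robust choice: a monotone baseline drift
inflates one delta but deflates the other, so their minimum cannot
manufacture a false positive.

Calcium (FURA ratio) responses need no plateau calibration; the statistic
is simply the steady-state ratio change on the glucose up-step, because the
ratio does not fully return to baseline after the down-step.

Steady states are means over fixed windows, by default the 35–45 min
interval after each glucose transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .protocol import Protocol
from .traces import CHANNEL_CALCIUM, CHANNEL_NADPH, TraceSet

__all__ = [
    "Window",
    "WindowSpec",
    "ResponseRecord",
    "EmptyWindowError",
    "DegenerateCalibrationError",
    "steady_state",
    "normalize_trace",
    "response_min_change",
    "calcium_response",
    "windows_from_protocol",
    "analyze_traces",
]

SS_DELAY_MIN = (35.0, 45.0)  # steady-state window, minutes after a glucose step
BASELINE_SPAN_MIN = 10.0
CALIBRATION_SPAN_MIN = 5.0

QC_OK = "ok"
QC_DEGENERATE_CALIBRATION = "degenerate_calibration"
QC_MISSING_WINDOW = "missing_window"


class EmptyWindowError(ValueError):
    """A steady-state window holds no samples."""


class DegenerateCalibrationError(ValueError):
    """Per-cell KCN plateau does not exceed the FCCP plateau."""


@dataclass(frozen=True)
class Window:
    label: str
    start_min: float
    end_min: float

    def __post_init__(self) -> None:
        if not self.start_min < self.end_min:
            raise ValueError(f"window {self.label!r}: start must precede end")


@dataclass(frozen=True)
class WindowSpec:
    """Named analysis windows for one channel's protocol."""

    windows: dict[str, Window] = field(default_factory=dict)

    def __getitem__(self, label: str) -> Window:
        return self.windows[label]

    def __contains__(self, label: str) -> bool:
        return label in self.windows


def windows_from_protocol(protocol: Protocol, channel: str = CHANNEL_NADPH) -> WindowSpec:
    """Default window placement for a stepped-glucose protocol.

    baseline: the last 10 min of the initial glucose segment;
    high_glucose / post_return (or stimulated, for calcium): 35–45 min after
    the corresponding glucose transition; kcn / fccp: the last 5 min of the
    respective calibration segment.
    """
    first = protocol.segments[0]
    up = protocol.glucose_step_up_min()
    wins = {
        "baseline": Window("baseline", max(0.0, first.end_min - BASELINE_SPAN_MIN), first.end_min),
    }
    lo, hi = SS_DELAY_MIN
    if channel == CHANNEL_NADPH:
        wins["high_glucose"] = Window("high_glucose", up + lo, up + hi)
        down = protocol.glucose_step_down_min()
        wins["post_return"] = Window("post_return", down + lo, down + hi)
        for cond in ("kcn", "fccp"):
            seg = [s for s in protocol.segments if s.condition == cond]
            if seg:
                wins[cond] = Window(
                    cond, seg[-1].end_min - CALIBRATION_SPAN_MIN, seg[-1].end_min
                )
    else:
        wins["stimulated"] = Window("stimulated", up + lo, up + hi)
    return WindowSpec(wins)


@dataclass
class ResponseRecord:
    """Scalar response of one cell plus its component deltas and QC state."""

    cell_id: str
    statistic: float
    delta_up: float | None = None
    delta_down: float | None = None
    qc_flags: tuple[str, ...] = (QC_OK,)


def steady_state(times_min: np.ndarray, values: np.ndarray, window: Window) -> float:
    """Mean of the samples falling in the closed interval [start, end]."""
    times_min = np.asarray(times_min, dtype=float)
    values = np.asarray(values, dtype=float)
    mask = (times_min >= window.start_min) & (times_min <= window.end_min)
    if not mask.any():
        raise EmptyWindowError(
            f"window {window.label!r} [{window.start_min}, {window.end_min}] min "
            "contains no samples"
        )
    return float(values[mask].mean())


def normalize_trace(
    times_min: np.ndarray,
    values: np.ndarray,
    kcn_window: Window,
    fccp_window: Window,
) -> tuple[np.ndarray, float, float]:
    """Rescale a raw NAD(P)H trace to percent of its KCN–FCCP span.

    The steady-state plateau under KCN defines 100% and under FCCP 0%, per
    cell.  Returns (normalized trace, RFU_KCN, RFU_FCCP).  Raises
    :class:`DegenerateCalibrationError` when the span is not positive; such
    cells are excluded from analysis and surfaced in QC output.
    """
    rfu_kcn = steady_state(times_min, values, kcn_window)
    rfu_fccp = steady_state(times_min, values, fccp_window)
    if not rfu_kcn > rfu_fccp:
        raise DegenerateCalibrationError(
            f"RFU_KCN ({rfu_kcn:.3g}) must exceed RFU_FCCP ({rfu_fccp:.3g})"
        )
    norm = 100.0 * (np.asarray(values, dtype=float) - rfu_fccp) / (rfu_kcn - rfu_fccp)
    return norm, rfu_kcn, rfu_fccp


def response_min_change(
    times_min: np.ndarray,
    normalized: np.ndarray,
    baseline_window: Window,
    high_window: Window,
    post_window: Window,
    cell_id: str = "",
) -> ResponseRecord:
    """Drift-robust NAD(P)H response: min of the up-step and down-step deltas.

    delta_up  = SS(high glucose) - SS(baseline);
    delta_down = SS(high glucose) - SS(post-return);
    statistic = min(delta_up, delta_down).  Both components are retained.
    """
    ss_base = steady_state(times_min, normalized, baseline_window)
    ss_high = steady_state(times_min, normalized, high_window)
    ss_post = steady_state(times_min, normalized, post_window)
    d_up = ss_high - ss_base
    d_down = ss_high - ss_post
    return ResponseRecord(
        cell_id=cell_id,
        statistic=float(min(d_up, d_down)),
        delta_up=float(d_up),
        delta_down=float(d_down),
    )


def calcium_response(
    times_min: np.ndarray,
    values: np.ndarray,
    baseline_window: Window,
    stimulated_window: Window,
    cell_id: str = "",
) -> ResponseRecord:
    """Calcium response: steady-state ratio change on the glucose up-step."""
    ss_base = steady_state(times_min, values, baseline_window)
    ss_stim = steady_state(times_min, values, stimulated_window)
    d = ss_stim - ss_base
    return ResponseRecord(cell_id=cell_id, statistic=float(d), delta_up=float(d))


def analyze_traces(traceset: TraceSet, windows: WindowSpec) -> pd.DataFrame:
    """Score every cell in a trace set.

    Returns a response table with one row per cell: ``cell_id``,
    ``statistic``, ``delta_up``, ``delta_down``, calibration plateaus (NaN
    for calcium) and a ``qc_flag``.  Cells whose KCN/FCCP calibration is
    degenerate get a flag and a NaN statistic instead of aborting the run.
    """
    rows = []
    t = traceset.times_min
    for i, cell_id in enumerate(traceset.cell_ids):
        raw = traceset.values[i]
        row = {
            "cell_id": cell_id,
            "statistic": np.nan,
            "delta_up": np.nan,
            "delta_down": np.nan,
            "rfu_kcn": np.nan,
            "rfu_fccp": np.nan,
            "qc_flag": QC_OK,
        }
        try:
            if traceset.channel == CHANNEL_NADPH:
                norm, rfu_kcn, rfu_fccp = normalize_trace(t, raw, windows["kcn"], windows["fccp"])
                rec = response_min_change(
                    t, norm, windows["baseline"], windows["high_glucose"],
                    windows["post_return"], cell_id,
                )
                row.update(rfu_kcn=rfu_kcn, rfu_fccp=rfu_fccp)
            elif traceset.channel == CHANNEL_CALCIUM:
                rec = calcium_response(
                    t, raw, windows["baseline"], windows["stimulated"], cell_id
                )
            else:
                raise ValueError(f"unknown channel {traceset.channel!r}")
        except DegenerateCalibrationError:
            row["qc_flag"] = QC_DEGENERATE_CALIBRATION
        except (EmptyWindowError, KeyError):
            row["qc_flag"] = QC_MISSING_WINDOW
        else:
            row.update(
                statistic=rec.statistic,
                delta_up=rec.delta_up,
                delta_down=np.nan if rec.delta_down is None else rec.delta_down,
            )
        rows.append(row)
    return pd.DataFrame(rows)
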