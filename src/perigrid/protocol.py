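"""Perifusion protocols: timed sequences of bath conditions.

A protocol is an ordered, contiguous list of segments, each holding one
condition (a glucose concentration, or a calibration agent such as KCN or
FCCP) for a time interval in minutes.  The reference NAD(P)H protocol steps
glucose 3 -> 20 -> 3 mM and ends with KCN then FCCP to pin each cell's
metabolic ceiling and floor; the reference calcium protocol steps glucose
4 -> 20 -> 4 mM with no calibration tail.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

__all__ = [
    "Segment",
    "Protocol",
    "nadph_reference_protocol",
    "calcium_reference_protocol",
]

GLUCOSE = "glucose"
KCN = "kcn"
FCCP = "fccp"

_TIME_TOL_MIN = 1e-9


@dataclass(frozen=True)
class Segment:
    condition: str
    level: float  # mM for glucose; 1.0 flag for KCN/FCCP
    start_min: float
    end_min: float

    def __post_init__(self) -> None:
        if not self.start_min < self.end_min:
            raise ValueError(
                f"segment {self.condition!r}: start {self.start_min} must precede "
                f"end {self.end_min}"
            )

    @property
    def duration_min(self) -> float:
        return self.end_min - self.start_min


@dataclass(frozen=True)
class Protocol:
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol must contain at least one segment")
        if abs(self.segments[0].start_min) > _TIME_TOL_MIN:
            raise ValueError("first segment must start at t = 0")
        for prev, nxt in zip(self.segments, self.segments[1:]):
            if abs(prev.end_min - nxt.start_min) > _TIME_TOL_MIN:
                raise ValueError(
                    f"segments must be contiguous: {prev.condition!r} ends at "
                    f"{prev.end_min} but {nxt.condition!r} starts at {nxt.start_min}"
                )

    @property
    def end_min(self) -> float:
        return self.segments[-1].end_min

    def segment_at(self, t_min: float) -> Segment:
        """Segment active at time t (closed at segment starts)."""
        if t_min < -_TIME_TOL_MIN or t_min > self.end_min + _TIME_TOL_MIN:
            raise ValueError(f"t = {t_min} min outside protocol [0, {self.end_min}]")
        for seg in self.segments:
            if t_min < seg.end_min:
                return seg
        return self.segments[-1]

    def glucose_segments(self) -> list[Segment]:
        return [s for s in self.segments if s.condition == GLUCOSE]

    def glucose_step_up_min(self) -> float:
        """Time of the low -> high glucose transition."""
        segs = self.glucose_segments()
        if len(segs) < 2:
            raise ValueError("protocol has no glucose step")
        low = min(s.level for s in segs)
        for prev, nxt in zip(segs, segs[1:]):
            if nxt.level > prev.level == low:
                return nxt.start_min
        raise ValueError("no upward glucose step found")

    def glucose_step_down_min(self) -> float:
        """Time of the high -> low glucose return, if present."""
        segs = self.glucose_segments()
        for prev, nxt in zip(segs, segs[1:]):
            if nxt.level < prev.level:
                return nxt.start_min
        raise ValueError("no downward glucose step found")

    def to_dict(self) -> dict:
        return {
            "segments": [
                {
                    "condition": s.condition,
                    "level": s.level,
                    "start_min": s.start_min,
                    "end_min": s.end_min,
                }
                for s in self.segments
            ]
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Protocol":
        return cls(
            tuple(
                Segment(d["condition"], float(d["level"]), float(d["start_min"]), float(d["end_min"]))
                for d in data["segments"]
            )
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "Protocol":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _protocol(rows: Iterable[tuple[str, float, float, float]]) -> Protocol:
    return Protocol(tuple(Segment(*row) for row in rows))


def nadph_reference_protocol() -> Protocol:
    """Glucose 3 -> 20 -> 3 mM, then KCN and FCCP calibration plateaus.

    Segment lengths leave the full 35–45 min steady-state window inside both
    the high-glucose and the post-return segments, and give the calibration
    agents ~15 min to plateau before their read-out windows.
    """
    return _protocol(
        [
            (GLUCOSE, 3.0, 0.0, 20.0),
            (GLUCOSE, 20.0, 20.0, 70.0),
            (GLUCOSE, 3.0, 70.0, 115.0),
            (KCN, 1.0, 115.0, 135.0),
            (FCCP, 1.0, 135.0, 155.0),
        ]
    )


def calcium_reference_protocol() -> Protocol:
    """Glucose 4 -> 20 -> 4 mM for calcium-ratio imaging (no calibration tail)."""
    return _protocol(
        [
            (GLUCOSE, 4.0, 0.0, 20.0),
            (GLUCOSE, 20.0, 20.0, 70.0),
            (GLUCOSE, 4.0, 70.0, 110.0),
        ]
    )
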