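"""Run configuration: schema-validated parameters for simulate/analyze runs.

All defaults mirror the reference experiment: 120-s sampling, steady-state
windows 35–45 min after each glucose step, per-cell KCN/FCCP calibration,
4%-wide NAD(P)H bins over 0–52% (0.1-ratio bins over 0–0.7 for calcium), a
4% response threshold and a 10 µm matching tolerance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, Field, model_validator

from .protocol import Protocol, calcium_reference_protocol, nadph_reference_protocol
from .stats import (
    CALCIUM_BIN_WIDTH,
    CALCIUM_RANGE,
    DEFAULT_RESPONSE_THRESHOLD,
    NADPH_BIN_WIDTH,
    NADPH_RANGE,
)
from .synthetic import (
    PopulationSpec,
    ResponseDistribution,
    islet_calcium_population_spec,
    islet_nadph_population_spec,
)
from .traces import CHANNEL_CALCIUM, CHANNEL_NADPH

__all__ = ["RunConfig", "GridConfig", "PopulationConfig", "load_config"]

_CHANNEL_MAP = {"nadph": CHANNEL_NADPH, "calcium": CHANNEL_CALCIUM}


class GridConfig(BaseModel):
    square_size_um: float = Field(150.0, gt=0)
    n_rows: int = Field(133, ge=1)
    n_cols: int = Field(133, ge=1)


class DistributionConfig(BaseModel):
    mean: float
    sd: float = Field(ge=0)
    lo: float | None = None
    hi: float | None = None

    def to_distribution(self) -> ResponseDistribution:
        return ResponseDistribution(self.mean, self.sd, self.lo, self.hi)


class PopulationConfig(BaseModel):
    """Overrides applied to the channel's reference population spec."""

    n_cells: int | None = Field(None, ge=1)
    composition: dict[str, float] | None = None
    response_distributions: dict[str, DistributionConfig] | None = None
    exact_quota: bool | None = None
    n_regions: int | None = Field(None, ge=1)
    unstained_fraction: float | None = Field(None, ge=0, le=1)
    co_stain_fraction: float | None = Field(None, ge=0, le=1)
    centroid_jitter_um: float | None = Field(None, ge=0)
    session_offset_um: tuple[float, float] | None = None
    noise_sd: float | None = Field(None, ge=0)
    drift_slope_sd: float | None = Field(None, ge=0)
    min_spacing_um: float | None = Field(None, gt=0)
    edge_margin_um: float | None = Field(None, ge=0)


class RunConfig(BaseModel):
    """Full configuration of a simulate or analyze run."""

    channel: Literal["nadph", "calcium"] = "nadph"
    seed: int = 0
    grid: GridConfig = Field(default_factory=GridConfig)
    population: PopulationConfig = Field(default_factory=PopulationConfig)
    protocol: dict | None = None  # Protocol.to_dict(); channel default if None
    sampling_period_s: float = Field(120.0, gt=0)
    time_constant_min: float = Field(3.0, ge=0)
    bin_width: float | None = Field(None, gt=0)
    range_lo: float | None = None
    range_hi: float | None = None
    response_threshold: float = DEFAULT_RESPONSE_THRESHOLD
    matching_tolerance_um: float = Field(10.0, gt=0)
    insulin_threshold: float = Field(100.0, gt=0)
    glucagon_threshold: float = Field(100.0, gt=0)

    @model_validator(mode="after")
    def _check_range(self) -> "RunConfig":
        lo, hi = self.effective_range()
        if not lo < hi:
            raise ValueError("range_lo must be < range_hi")
        if self.protocol is not None:
            Protocol.from_dict(self.protocol)  # structural validation
        return self

    # -- resolved (channel-aware) accessors -------------------------------

    @property
    def trace_channel(self) -> str:
        return _CHANNEL_MAP[self.channel]

    def effective_protocol(self) -> Protocol:
        if self.protocol is not None:
            return Protocol.from_dict(self.protocol)
        if self.channel == "nadph":
            return nadph_reference_protocol()
        return calcium_reference_protocol()

    def effective_bin_width(self) -> float:
        if self.bin_width is not None:
            return self.bin_width
        return NADPH_BIN_WIDTH if self.channel == "nadph" else CALCIUM_BIN_WIDTH

    def effective_range(self) -> tuple[float, float]:
        default = NADPH_RANGE if self.channel == "nadph" else CALCIUM_RANGE
        return (
            default[0] if self.range_lo is None else self.range_lo,
            default[1] if self.range_hi is None else self.range_hi,
        )

    def population_spec(self) -> PopulationSpec:
        base = (
            islet_nadph_population_spec()
            if self.channel == "nadph"
            else islet_calcium_population_spec()
        )
        overrides = {
            k: v for k, v in self.population.model_dump().items() if v is not None
        }
        if "response_distributions" in overrides:
            overrides["response_distributions"] = {
                lab: DistributionConfig(**d).to_distribution()
                for lab, d in overrides["response_distributions"].items()
            }
        if "session_offset_um" in overrides:
            overrides["session_offset_um"] = tuple(overrides["session_offset_um"])
        from dataclasses import replace

        return replace(base, seed=self.seed, **overrides)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Read a JSON config file (schema-validated); missing file -> defaults."""
    data = {} if path is None else json.loads(Path(path).read_text())
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig.model_validate(data)
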