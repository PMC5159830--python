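"""Synthetic perifusion-imaging experiments with known ground truth.

Everything the analysis pipeline consumes can be generated here: a mixed
population of islet-like cells seeded into gridded coverslip squares, raw
fluorescence traces under a stepped-glucose protocol (with first-order
plateau kinetics, linear acquisition drift and Gaussian read noise), a
post-fixation immunostain table with centroid jitter between imaging
sessions, and rendered region images for exercising ROI extraction.

Cell types follow the islet convention: *beta* cells respond to a glucose
step with a large positive NAD(P)H (or calcium-ratio) excursion, *alpha*
cells with a near-zero or slightly negative one, and *other* cells carry an
alpha-like response but stain for neither hormone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps

from .grid import GridLayout
from .protocol import FCCP, GLUCOSE, KCN, Protocol
from .traces import CHANNEL_CALCIUM, CHANNEL_NADPH, TraceSet

__all__ = [
    "ResponseDistribution",
    "PopulationSpec",
    "CellGroundTruth",
    "StainRecord",
    "islet_nadph_population_spec",
    "islet_calcium_population_spec",
    "sample_population",
    "simulate_traces",
    "simulate_staining",
    "render_region_image",
]

BETA = "beta"
ALPHA = "alpha"
OTHER = "other"
CELL_TYPES = (BETA, ALPHA, OTHER)

_FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class ResponseDistribution:
    """Per-type distribution of the true response magnitude.

    Units are % of the KCN–FCCP span for NAD(P)H and ratio units for
    calcium.  Optional truncation bounds give distributions with disjoint
    supports (used to model populations that cannot cross a classification
    threshold).
    """

    mean: float
    sd: float
    lo: float | None = None
    hi: float | None = None

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.lo is not None and self.hi is not None and self.lo >= self.hi:
            raise ValueError("truncation bounds must satisfy lo < hi")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.sd == 0:
            draws = np.full(n, self.mean)
            if self.lo is not None:
                draws = np.maximum(draws, self.lo)
            if self.hi is not None:
                draws = np.minimum(draws, self.hi)
            return draws
        if self.lo is None and self.hi is None:
            return rng.normal(self.mean, self.sd, size=n)
        a = -np.inf if self.lo is None else (self.lo - self.mean) / self.sd
        b = np.inf if self.hi is None else (self.hi - self.mean) / self.sd
        dist = sps.truncnorm(a, b, loc=self.mean, scale=self.sd)
        return dist.ppf(rng.uniform(size=n))


@dataclass(frozen=True)
class PopulationSpec:
    """Parameters of a synthetic coverslip population.

    Defaults reproduce the reference dispersed-islet NAD(P)H experiment:
    183 beta, 32 alpha and 12 hormone-negative cells (227 total, the sum of
    the reported per-type counts) over 10 imaged regions; beta responses
    ~N(27, 12.2) % and alpha ~N(-5, 9.1) %
    of the per-cell KCN–FCCP span (sds back-computed from the composite
    SEMs).  Raw-signal scale: baseline ~280 RFU between an FCCP floor near
    50 RFU and a KCN ceiling near 500 RFU, with small linear drift and read
    noise appropriate to a cooled CCD at 200 ms integration.
    """

    n_cells: int = 227
    composition: dict[str, float] = field(
        default_factory=lambda: {BETA: 183 / 227, ALPHA: 32 / 227, OTHER: 12 / 227}
    )
    response_distributions: dict[str, ResponseDistribution] = field(
        default_factory=lambda: {
            BETA: ResponseDistribution(27.0, 12.2),
            ALPHA: ResponseDistribution(-5.0, 9.1),
            OTHER: ResponseDistribution(-5.0, 9.1),
        }
    )
    channel: str = CHANNEL_NADPH
    exact_quota: bool = True
    n_regions: int = 10
    cell_radius_um: float = 7.5
    min_spacing_um: float = 15.0
    edge_margin_um: float = 10.0
    # raw-signal scale (RFU for NAD(P)H; ratio units for calcium)
    baseline_mean: float = 280.0
    baseline_sd: float = 30.0
    fccp_floor_mean: float = 50.0
    fccp_floor_sd: float = 10.0
    span_mean: float = 450.0
    span_sd: float = 40.0
    drift_slope_sd: float = 0.01  # RFU/min
    noise_sd: float = 2.0  # RFU per sample
    # staining model
    unstained_fraction: float = 0.0
    co_stain_fraction: float = 0.0
    centroid_jitter_um: float = 2.0
    session_offset_um: tuple[float, float] = (3.0, -4.0)
    positive_stain_mean: float = 900.0
    positive_stain_sd: float = 120.0
    negative_stain_sd: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if any(f < 0 or f > 1 for f in self.composition.values()):
            raise ValueError("composition fractions must lie in [0, 1]")
        if abs(sum(self.composition.values()) - 1.0) > _FRACTION_TOL:
            raise ValueError(
                f"composition fractions must sum to 1, got {sum(self.composition.values())}"
            )
        unknown = set(self.composition) - set(CELL_TYPES)
        if unknown:
            raise ValueError(f"unknown cell types in composition: {sorted(unknown)}")
        missing = set(self.composition) - set(self.response_distributions)
        if missing:
            raise ValueError(f"no response distribution for types: {sorted(missing)}")
        for frac_name in ("unstained_fraction", "co_stain_fraction"):
            f = getattr(self, frac_name)
            if not 0 <= f <= 1:
                raise ValueError(f"{frac_name} must lie in [0, 1]")
        if self.centroid_jitter_um < 0 or self.noise_sd < 0 or self.drift_slope_sd < 0:
            raise ValueError("sds must be >= 0")
        if self.n_regions < 1 or self.n_regions > self.n_cells:
            raise ValueError("n_regions must be in [1, n_cells]")


def islet_nadph_population_spec(**overrides) -> PopulationSpec:
    """The reference dispersed-islet NAD(P)H population (224 cells, 183/32/12)."""
    return replace(PopulationSpec(), **overrides) if overrides else PopulationSpec()


def islet_calcium_population_spec(**overrides) -> PopulationSpec:
    """The reference dispersed-islet calcium experiment: 54 cells in 2 regions,
    40 beta / 14 alpha, responses 0.33 vs 0.051 ratio units (sds from SEMs)."""
    spec = PopulationSpec(
        n_cells=54,
        composition={BETA: 40 / 54, ALPHA: 14 / 54},
        response_distributions={
            BETA: ResponseDistribution(0.33, 0.054 * np.sqrt(40)),
            ALPHA: ResponseDistribution(0.051, 0.013 * np.sqrt(14)),
        },
        channel=CHANNEL_CALCIUM,
        n_regions=2,
        baseline_mean=1.0,
        baseline_sd=0.05,
        fccp_floor_mean=0.0,
        fccp_floor_sd=0.0,
        span_mean=1.0,
        span_sd=0.0,
        drift_slope_sd=2e-5,
        noise_sd=0.005,
    )
    return replace(spec, **overrides) if overrides else spec


@dataclass
class CellGroundTruth:
    """Latent state of one synthetic cell."""

    cell_id: str
    type_label: str
    centroid_um: tuple[float, float]
    square_id: str
    response_param: float  # % of KCN-FCCP span (nadph) or ratio units (calcium)
    rfu_kcn_true: float
    rfu_fccp_true: float
    baseline_rfu: float
    drift_slope: float  # RFU/min
    noise_sd: float  # RFU

    def __post_init__(self) -> None:
        if not self.rfu_kcn_true > self.rfu_fccp_true >= 0:
            raise ValueError(
                f"cell {self.cell_id}: need RFU_KCN > RFU_FCCP >= 0, got "
                f"{self.rfu_kcn_true} vs {self.rfu_fccp_true}"
            )


@dataclass
class StainRecord:
    """One cell's appearance in the post-fixation immunostain image.

    ``source_cell_id`` is generator ground truth retained for validation; the
    identity-mapping stage never reads it.
    """

    centroid_um: tuple[float, float]
    square_id: str
    insulin_intensity: float
    glucagon_intensity: float
    source_cell_id: str | None = None

    def __post_init__(self) -> None:
        if self.insulin_intensity < 0 or self.glucagon_intensity < 0:
            raise ValueError("stain intensities must be >= 0")


def _quota_counts(n: int, fractions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n among labels."""
    labels = sorted(fractions)
    raw = {lab: n * fractions[lab] for lab in labels}
    counts = {lab: int(np.floor(raw[lab])) for lab in labels}
    short = n - sum(counts.values())
    for lab in sorted(labels, key=lambda l: raw[l] - counts[l], reverse=True)[:short]:
        counts[lab] += 1
    return counts


def _place_in_square(
    n: int,
    origin: tuple[float, float],
    size: float,
    margin: float,
    min_spacing: float,
    rng: np.random.Generator,
    max_tries: int = 20_000,
) -> np.ndarray:
    """Rejection-sample n centroids with a hard minimum spacing."""
    lo, hi = margin, size - margin
    if hi <= lo:
        raise ValueError("edge margin leaves no room inside the square")
    placed: list[np.ndarray] = []
    tries = 0
    while len(placed) < n:
        cand = rng.uniform(lo, hi, size=2)
        if all(np.hypot(*(cand - p)) >= min_spacing for p in placed):
            placed.append(cand)
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} cells with {min_spacing} µm spacing in a "
                f"{size} µm square; reduce density"
            )
    return np.array(placed) + np.asarray(origin)


def sample_population(
    spec: PopulationSpec, layout: GridLayout, rng: np.random.Generator | None = None
) -> list[CellGroundTruth]:
    """Draw a ground-truth cell population on the gridded coverslip.

    Cells are distributed as evenly as possible over ``spec.n_regions``
    randomly chosen grid squares (one imaged region per square).  Type labels
    follow ``spec.composition`` either by exact quota (largest remainder,
    shuffled) or multinomially; response magnitudes are drawn per type.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    # pick distinct region squares
    flat = rng.choice(layout.n_squares, size=spec.n_regions, replace=False)
    squares = [layout.square_id(int(i // layout.n_cols), int(i % layout.n_cols)) for i in flat]

    per_region = _quota_counts(
        spec.n_cells, {sq: 1 / spec.n_regions for sq in squares}
    )

    # type labels
    labels_order = sorted(spec.composition)
    if spec.exact_quota:
        counts = _quota_counts(spec.n_cells, spec.composition)
        labels = np.repeat(labels_order, [counts[lab] for lab in labels_order])
        rng.shuffle(labels)
    else:
        draws = rng.multinomial(1, [spec.composition[lab] for lab in labels_order], size=spec.n_cells)
        labels = np.array(labels_order)[draws.argmax(axis=1)]

    responses = np.empty(spec.n_cells)
    for lab in labels_order:
        mask = labels == lab
        responses[mask] = spec.response_distributions[lab].sample(int(mask.sum()), rng)

    fccp = np.clip(
        rng.normal(spec.fccp_floor_mean, spec.fccp_floor_sd, spec.n_cells), 0.0, None
    )
    span = np.clip(rng.normal(spec.span_mean, spec.span_sd, spec.n_cells), 1e-6, None)
    kcn = fccp + span
    baseline = np.clip(
        rng.normal(spec.baseline_mean, spec.baseline_sd, spec.n_cells),
        fccp + 1e-6,
        kcn,
    )
    drift = rng.normal(0.0, spec.drift_slope_sd, spec.n_cells)

    cells: list[CellGroundTruth] = []
    i = 0
    for sq in squares:
        n_here = per_region[sq]
        origin = layout.square_origin_um(sq)
        pts = _place_in_square(
            n_here, origin, layout.square_size_um, spec.edge_margin_um,
            spec.min_spacing_um, rng,
        )
        for p in pts:
            cells.append(
                CellGroundTruth(
                    cell_id=f"cell{i:04d}",
                    type_label=str(labels[i]),
                    centroid_um=(float(p[0]), float(p[1])),
                    square_id=sq,
                    response_param=float(responses[i]),
                    rfu_kcn_true=float(kcn[i]),
                    rfu_fccp_true=float(fccp[i]),
                    baseline_rfu=float(baseline[i]),
                    drift_slope=float(drift[i]),
                    noise_sd=spec.noise_sd,
                )
            )
            i += 1
    return cells


def _segment_targets(
    cells: list[CellGroundTruth], protocol: Protocol, channel: str
) -> np.ndarray:
    """(n_cells, n_segments) plateau targets in raw units."""
    glucose_levels = [s.level for s in protocol.glucose_segments()]
    low = min(glucose_levels) if glucose_levels else None
    n, m = len(cells), len(protocol.segments)
    targets = np.empty((n, m))
    for j, seg in enumerate(protocol.segments):
        for i, c in enumerate(cells):
            if seg.condition == GLUCOSE:
                stimulated = low is not None and seg.level > low
                if channel == CHANNEL_NADPH:
                    step = c.response_param / 100.0 * (c.rfu_kcn_true - c.rfu_fccp_true)
                else:
                    step = c.response_param
                targets[i, j] = c.baseline_rfu + (step if stimulated else 0.0)
            elif seg.condition == KCN:
                targets[i, j] = c.rfu_kcn_true
            elif seg.condition == FCCP:
                targets[i, j] = c.rfu_fccp_true
            else:
                raise ValueError(f"no trace model for condition {seg.condition!r}")
    return targets


def simulate_traces(
    cells: list[CellGroundTruth],
    protocol: Protocol,
    sampling_period_s: float = 120.0,
    time_constant_min: float = 3.0,
    seed: int | None = 0,
    channel: str | None = None,
) -> TraceSet:
    """Simulate raw per-cell traces under a perifusion protocol.

    Each cell's noiseless signal relaxes toward the active segment's plateau
    with first-order kinetics (``time_constant_min``; 0 means instantaneous),
    on top of which a per-cell linear drift and i.i.d. Gaussian read noise
    are added.  Samples are taken every ``sampling_period_s`` starting at
    t = 0 (the stage-scan cycle period; per-region offsets within a cycle
    are folded into the nominal time point).
    """
    if not cells:
        raise ValueError("no cells to simulate")
    if not protocol.segments:
        raise ValueError("protocol is empty")
    if sampling_period_s <= 0:
        raise ValueError("sampling_period_s must be > 0")
    if channel is None:
        channel = CHANNEL_NADPH
    rng = np.random.default_rng(seed)

    period_min = sampling_period_s / 60.0
    times = np.arange(0.0, protocol.end_min + 1e-9, period_min)
    targets = _segment_targets(cells, protocol, channel)

    n = len(cells)
    clean = np.empty((n, times.size))
    state = targets[:, 0].copy()  # start equilibrated at the first plateau
    tau = float(time_constant_min)
    for j, seg in enumerate(protocol.segments):
        # A sample taken at the switch instant still sees the previous
        # plateau (the signal is continuous across a condition change), so
        # segment membership is (start, end], with t = 0 in the first.
        first = j == 0
        in_seg = (times <= seg.end_min + 1e-9) & (
            (times > seg.start_min + 1e-9) | (first & (times >= -1e-9))
        )
        dt = times[in_seg] - seg.start_min
        if tau > 0:
            decay = np.exp(-dt / tau)
            clean[:, in_seg] = targets[:, j : j + 1] + np.outer(state - targets[:, j], decay)
            state = targets[:, j] + (state - targets[:, j]) * np.exp(-seg.duration_min / tau)
        else:
            clean[:, in_seg] = targets[:, j : j + 1]
            state = targets[:, j].copy()

    drift = np.array([c.drift_slope for c in cells])
    noise_sd = np.array([c.noise_sd for c in cells])
    values = clean + np.outer(drift, times)
    values += rng.normal(size=values.shape) * noise_sd[:, None]
    return TraceSet(channel, times, values, [c.cell_id for c in cells])


def simulate_staining(
    cells: list[CellGroundTruth],
    spec: PopulationSpec,
    layout: GridLayout | None = None,
    rng: np.random.Generator | None = None,
) -> list[StainRecord]:
    """Simulate the post-fixation insulin/glucagon immunostain table.

    Beta cells stain insulin-positive, alpha cells glucagon-positive, and
    ``other`` cells stain for neither hormone.  A quota
    ``unstained_fraction`` of hormone-positive cells additionally fails to
    stain, and ``co_stain_fraction`` of stained cells light up in both
    channels.  Stained-image centroids are the live centroids displaced by a
    rigid between-session offset plus i.i.d. Gaussian jitter; when a layout
    is supplied the record's square address is read off the grid at the
    stained position (a cell jittered across an etched line lands in the
    neighbouring square, as it would to the experimenter's eye), otherwise
    the source cell's square is kept.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    n = len(cells)
    idx_hormone = np.array([i for i, c in enumerate(cells) if c.type_label != OTHER])

    unstained = np.zeros(n, dtype=bool)
    for i, c in enumerate(cells):
        if c.type_label == OTHER:
            unstained[i] = True
    n_extra = int(round(spec.unstained_fraction * idx_hormone.size))
    if n_extra > 0:
        drop = rng.choice(idx_hormone, size=n_extra, replace=False)
        unstained[drop] = True

    stained_idx = np.flatnonzero(~unstained)
    n_co = int(round(spec.co_stain_fraction * stained_idx.size))
    co = np.zeros(n, dtype=bool)
    if n_co > 0:
        co[rng.choice(stained_idx, size=n_co, replace=False)] = True

    offset = np.asarray(spec.session_offset_um, dtype=float)
    records: list[StainRecord] = []
    for i, c in enumerate(cells):
        jitter = rng.normal(0.0, spec.centroid_jitter_um, size=2)
        pos = np.asarray(c.centroid_um) + offset + jitter
        ins_pos = (not unstained[i] and c.type_label == BETA) or co[i]
        glu_pos = (not unstained[i] and c.type_label == ALPHA) or co[i]
        ins = (
            max(0.0, rng.normal(spec.positive_stain_mean, spec.positive_stain_sd))
            if ins_pos
            else abs(rng.normal(0.0, spec.negative_stain_sd))
        )
        glu = (
            max(0.0, rng.normal(spec.positive_stain_mean, spec.positive_stain_sd))
            if glu_pos
            else abs(rng.normal(0.0, spec.negative_stain_sd))
        )
        if layout is not None:
            try:
                square = layout.locate(float(pos[0]), float(pos[1]))
            except ValueError:  # jittered off the coverslip edge
                square = c.square_id
        else:
            square = c.square_id
        records.append(
            StainRecord(
                centroid_um=(float(pos[0]), float(pos[1])),
                square_id=square,
                insulin_intensity=float(ins),
                glucagon_intensity=float(glu),
                source_cell_id=c.cell_id,
            )
        )
    return records


def render_region_image(
    cells: list[CellGroundTruth],
    layout: GridLayout,
    intensity_map: dict[str, float],
    image_size_px: int = 256,
    background: float = 0.0,
    cell_radius_um: float = 7.5,
    square_id: str | None = None,
) -> tuple[np.ndarray, dict]:
    """Render one grid square's cells as flat disks on a dark background.

    All cells must share one square (``square_id`` may name it explicitly,
    and must when ``cells`` is empty).  Returns the image (float64,
    ``image_size_px`` square) and metadata holding the µm/px scale and the
    square's origin so that pixel and stage coordinates interconvert.
    """
    squares = {c.square_id for c in cells}
    if square_id is not None:
        squares.add(square_id)
    if len(squares) != 1:
        if not squares:
            raise ValueError("square_id is required when rendering an empty region")
        raise ValueError(f"cells span multiple squares: {sorted(squares)}")
    square_id = squares.pop()
    origin = np.asarray(layout.square_origin_um(square_id))
    size = layout.square_size_um
    um_per_px = size / image_size_px

    from .acquisition import disk_mask  # shared center-in pixel rule

    img = np.full((image_size_px, image_size_px), float(background))
    for c in cells:
        rel = (np.asarray(c.centroid_um) - origin) / um_per_px
        if not (0 <= rel[0] <= image_size_px and 0 <= rel[1] <= image_size_px):
            raise ValueError(f"cell {c.cell_id} lies outside square {square_id}")
        r_px = cell_radius_um / um_per_px
        mask = disk_mask((image_size_px, image_size_px), rel[0], rel[1], r_px)
        img[mask] = intensity_map.get(c.cell_id, 0.0)
    meta = {
        "square_id": square_id,
        "um_per_px": um_per_px,
        "origin_um": tuple(origin),
        "cell_radius_um": cell_radius_um,
    }
    return img, meta
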