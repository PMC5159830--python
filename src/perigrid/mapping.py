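"""Map post-fixation immunostain identities back onto live-imaging ROIs.

The etched grid guarantees that a square seen during live imaging is the
same square seen after fixation and staining, so matching is done square by
square: a small rigid offset between the two imaging sessions is estimated
per square, then live and stained centroids are paired greedily by
ascending distance, one-to-one, within a distance tolerance.  Each matched
cell inherits a type label from its stain intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .grid import GridLayout
from .synthetic import StainRecord

__all__ = [
    "LABEL_BETA",
    "LABEL_ALPHA",
    "LABEL_UNCLASSIFIED",
    "LABEL_AMBIGUOUS",
    "LABEL_UNMATCHED",
    "MatchResult",
    "estimate_square_offset",
    "match_cells",
    "assign_identity",
    "build_identity_table",
]

LABEL_BETA = "beta"
LABEL_ALPHA = "alpha"
LABEL_UNCLASSIFIED = "unclassified"
LABEL_AMBIGUOUS = "ambiguous"
LABEL_UNMATCHED = "unmatched"

DEFAULT_TOLERANCE_UM = 10.0  # about one cell radius
DEFAULT_STAIN_THRESHOLD = 100.0


@dataclass
class MatchResult:
    """Outcome of live-to-stained centroid matching.

    ``matches`` has one row per live cell: the index of its stain record in
    the input list (-1 when unmatched) and the residual distance after the
    per-square offset.  ``square_offsets_um`` records the rigid offset
    (stained minus live) estimated for each square.
    """

    matches: pd.DataFrame
    square_offsets_um: dict[str, tuple[float, float]] = field(default_factory=dict)


def estimate_square_offset(
    live_xy: np.ndarray,
    stained_xy: np.ndarray,
    half_range_um: float = 75.0,
    step_um: float = 1.0,
) -> np.ndarray:
    """Rigid translation (stained minus live) within one square.

    Grid search over +-half_range_um at step_um resolution for the offset
    minimizing the sum over stained centroids of the squared distance to
    the nearest live centroid.  Returns (0, 0) when either side is empty.
    """
    live = np.atleast_2d(np.asarray(live_xy, dtype=float))
    stained = np.atleast_2d(np.asarray(stained_xy, dtype=float))
    if live.size == 0 or stained.size == 0:
        return np.zeros(2)
    steps = np.arange(-half_range_um, half_range_um + step_um / 2, step_um)
    ox, oy = np.meshgrid(steps, steps, indexing="ij")
    offsets = np.column_stack([ox.ravel(), oy.ravel()])
    tree = cKDTree(live)
    # all shifted stained points in one query
    shifted = (stained[None, :, :] - offsets[:, None, :]).reshape(-1, 2)
    d, _ = tree.query(shifted, k=1)
    cost = (d.reshape(len(offsets), -1) ** 2).sum(axis=1)
    return offsets[int(np.argmin(cost))].copy()


def _greedy_pairs(
    live: np.ndarray, stained: np.ndarray, tolerance: float
) -> list[tuple[int, int, float]]:
    """One-to-one greedy matching by ascending pair distance."""
    if live.size == 0 or stained.size == 0:
        return []
    d = np.linalg.norm(live[:, None, :] - stained[None, :, :], axis=2)
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    used_live: set[int] = set()
    used_stained: set[int] = set()
    pairs = []
    for i, j in order:
        if d[i, j] > tolerance:
            break
        if i in used_live or j in used_stained:
            continue
        pairs.append((int(i), int(j), float(d[i, j])))
        used_live.add(int(i))
        used_stained.add(int(j))
    return pairs


def match_cells(
    live_cells: pd.DataFrame,
    stains: list[StainRecord],
    layout: GridLayout,
    tolerance_um: float = DEFAULT_TOLERANCE_UM,
) -> MatchResult:
    """Pair live ROIs with stain records square by square.

    ``live_cells`` needs columns ``cell_id``, ``x_um``, ``y_um`` and
    ``square_id``.  Within each square the estimated session offset is
    removed from the stained centroids, then pairs are accepted greedily in
    ascending distance order up to ``tolerance_um``; leftover cells on
    either side stay unmatched.  Cross-square matches are never made.
    """
    required = {"cell_id", "x_um", "y_um", "square_id"}
    missing = required - set(live_cells.columns)
    if missing:
        raise ValueError(f"live cell table lacks columns: {sorted(missing)}")

    stain_square = {}
    for j, rec in enumerate(stains):
        stain_square.setdefault(rec.square_id, []).append(j)

    rows = []
    offsets: dict[str, tuple[float, float]] = {}
    for square_id, group in live_cells.groupby("square_id", sort=True):
        live_xy = group[["x_um", "y_um"]].to_numpy(dtype=float)
        jdx = stain_square.get(square_id, [])
        stained_xy = np.array([stains[j].centroid_um for j in jdx], dtype=float)
        offset = estimate_square_offset(live_xy, stained_xy, layout.square_size_um / 2)
        offsets[str(square_id)] = (float(offset[0]), float(offset[1]))
        shifted = stained_xy - offset if stained_xy.size else stained_xy
        pairs = {i: (j, dist) for i, j, dist in _greedy_pairs(live_xy, shifted, tolerance_um)}
        for i, (_, cell) in enumerate(group.iterrows()):
            j, dist = pairs.get(i, (-1, np.nan))
            rows.append(
                {
                    "cell_id": cell["cell_id"],
                    "square_id": square_id,
                    "stain_index": jdx[j] if j >= 0 else -1,
                    "distance_um": dist,
                }
            )
    matches = pd.DataFrame(rows)
    if not matches.empty:
        assigned = matches.loc[matches["stain_index"] >= 0, "stain_index"]
        assert assigned.is_unique, "a stain record was matched to two live cells"
    return MatchResult(matches=matches, square_offsets_um=offsets)


def assign_identity(
    stain: StainRecord | None,
    insulin_threshold: float = DEFAULT_STAIN_THRESHOLD,
    glucagon_threshold: float = DEFAULT_STAIN_THRESHOLD,
) -> str:
    """Type label from stain intensities.

    Insulin-positive only -> beta; glucagon-positive only -> alpha; neither
    -> unclassified (hormone-negative); both -> ambiguous (double-positive,
    excluded from type statistics); no stain record -> unmatched.
    """
    if insulin_threshold <= 0 or glucagon_threshold <= 0:
        raise ValueError("stain thresholds must be > 0")
    if stain is None:
        return LABEL_UNMATCHED
    ins = stain.insulin_intensity >= insulin_threshold
    glu = stain.glucagon_intensity >= glucagon_threshold
    if ins and glu:
        return LABEL_AMBIGUOUS
    if ins:
        return LABEL_BETA
    if glu:
        return LABEL_ALPHA
    return LABEL_UNCLASSIFIED


def build_identity_table(
    live_cells: pd.DataFrame,
    stains: list[StainRecord],
    layout: GridLayout,
    tolerance_um: float = DEFAULT_TOLERANCE_UM,
    insulin_threshold: float = DEFAULT_STAIN_THRESHOLD,
    glucagon_threshold: float = DEFAULT_STAIN_THRESHOLD,
) -> pd.DataFrame:
    """Match then label every live cell; one row per live cell.

    Columns: ``cell_id``, ``label``, ``stain_index``, ``distance_um``.
    """
    result = match_cells(live_cells, stains, layout, tolerance_um)
    table = result.matches.copy()
    table["label"] = [
        assign_identity(
            stains[j] if j >= 0 else None, insulin_threshold, glucagon_threshold
        )
        for j in table["stain_index"]
    ]
    return table[["cell_id", "label", "stain_index", "distance_um", "square_id"]]
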