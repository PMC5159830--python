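"""Per-type frequency distributions, summaries and error rates.

The end point of the pipeline: histogram the per-cell response statistic by
immunostain-derived type (4%-wide bins for NAD(P)H, 0.1-ratio bins for
calcium), summarize each type (n, mean, SEM), and count classification
errors against a response threshold — a glucagon-stained (alpha) cell that
responds like a beta cell is a false positive, an insulin-stained (beta)
cell that fails to respond is a false negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mapping import (
    LABEL_ALPHA,
    LABEL_AMBIGUOUS,
    LABEL_BETA,
    LABEL_UNCLASSIFIED,
    LABEL_UNMATCHED,
)

__all__ = [
    "FrequencyDistribution",
    "ClassificationReport",
    "bin_responses",
    "summarize_by_type",
    "classify_fp_fn",
    "exclusion_summary",
    "NADPH_BIN_WIDTH",
    "CALCIUM_BIN_WIDTH",
    "DEFAULT_RESPONSE_THRESHOLD",
]

NADPH_BIN_WIDTH = 4.0  # percent of the KCN-FCCP span
NADPH_RANGE = (0.0, 52.0)
CALCIUM_BIN_WIDTH = 0.1  # ratio units
CALCIUM_RANGE = (0.0, 0.7)
# One NAD(P)H bin width; motivated by the observation that no cell of a pure
# beta-cell line responded below this.
DEFAULT_RESPONSE_THRESHOLD = 4.0


@dataclass
class FrequencyDistribution:
    """Left-closed right-open histogram per type label.

    ``edges`` are the interior bin edges over [range_lo, range_hi]; values
    falling below/at-or-above the range accumulate into open-ended
    underflow/overflow bins so that no cell is dropped (responses can be
    negative even when the display range starts at 0).
    """

    bin_width: float
    edges: np.ndarray
    counts: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        """Interior bins plus the two open-ended edge bins."""
        return len(self.edges) + 1

    def bin_labels(self) -> list[str]:
        inner = [
            f"[{lo:g}, {hi:g})" for lo, hi in zip(self.edges[:-1], self.edges[1:])
        ]
        return [f"(-inf, {self.edges[0]:g})"] + inner + [f"[{self.edges[-1]:g}, inf)"]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"bin": self.bin_labels()})
        for label in sorted(self.counts):
            frame[label] = self.counts[label]
        return frame


def bin_responses(
    responses: pd.DataFrame,
    bin_width: float,
    range_lo: float,
    range_hi: float,
) -> FrequencyDistribution:
    """Histogram the ``statistic`` column per ``label``.

    Bins are left-closed right-open, ``bin_width`` wide from ``range_lo``
    to ``range_hi``; out-of-range values land in the open edge bins.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if not range_lo < range_hi:
        raise ValueError("range_lo must be < range_hi")
    n_inner = int(np.ceil((range_hi - range_lo) / bin_width - 1e-9))
    edges = range_lo + bin_width * np.arange(n_inner + 1)
    dist = FrequencyDistribution(bin_width=bin_width, edges=edges)
    for label, group in responses.groupby("label", sort=True):
        vals = group["statistic"].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        inner, _ = np.histogram(vals, bins=edges)
        # np.histogram closes the last bin; move top-edge hits to overflow
        at_top = int(np.sum(vals == edges[-1]))
        inner[-1] -= at_top
        under = int(np.sum(vals < edges[0]))
        over = int(np.sum(vals >= edges[-1]))
        dist.counts[str(label)] = np.concatenate([[under], inner, [over]])
    return dist


def summarize_by_type(
    responses: pd.DataFrame, labels: tuple[str, ...] = (LABEL_BETA, LABEL_ALPHA)
) -> pd.DataFrame:
    """n, mean and SEM of the response statistic per type label.

    SEM uses the sample standard deviation (n-1 denominator).  Labels with
    no cells are absent from the output rather than reported as zero; labels
    outside ``labels`` (unclassified, ambiguous, unmatched) are summarized
    too but carry no weight in the beta/alpha contrast.
    """
    rows = []
    for label, group in responses.groupby("label", sort=True):
        vals = group["statistic"].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            continue
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan
        rows.append(
            {
                "label": str(label),
                "n": int(vals.size),
                "mean": float(vals.mean()),
                "sem": sd / np.sqrt(vals.size) if vals.size > 1 else np.nan,
                "in_contrast": label in labels,
            }
        )
    return pd.DataFrame(rows, columns=["label", "n", "mean", "sem", "in_contrast"])


@dataclass
class ClassificationReport:
    """Error rates and per-type summaries for one analyzed experiment."""

    threshold: float
    summary: pd.DataFrame
    fp_count: int
    fp_rate: float
    fn_count: int
    fn_rate: float
    n_beta: int
    n_alpha: int
    excluded: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "per_type": self.summary.drop(columns="in_contrast").to_dict("records"),
            "fp_count": self.fp_count,
            "fp_rate": self.fp_rate,
            "fn_count": self.fn_count,
            "fn_rate": self.fn_rate,
            "n_beta": self.n_beta,
            "n_alpha": self.n_alpha,
            "excluded": self.excluded,
        }


def classify_fp_fn(
    responses: pd.DataFrame,
    threshold: float = DEFAULT_RESPONSE_THRESHOLD,
) -> ClassificationReport:
    """Count classification errors against a response threshold.

    ``responses`` needs ``statistic`` and ``label`` columns (one row per
    live cell).  A false positive is a glucagon-stained (alpha) cell with
    statistic >= threshold; a false negative an insulin-stained (beta) cell
    with statistic < threshold.  Rates are relative to each type's count of
    cells with a valid statistic.  Unclassified, ambiguous and unmatched
    cells, and cells without a valid statistic, are excluded and tallied.
    """
    valid = responses[~responses["statistic"].isna()]
    beta = valid[valid["label"] == LABEL_BETA]
    alpha = valid[valid["label"] == LABEL_ALPHA]
    fp = int((alpha["statistic"] >= threshold).sum())
    fn = int((beta["statistic"] < threshold).sum())

    excluded = {
        label: int((responses["label"] == label).sum())
        for label in (LABEL_UNCLASSIFIED, LABEL_AMBIGUOUS, LABEL_UNMATCHED)
    }
    excluded["invalid_statistic"] = int(responses["statistic"].isna().sum())

    return ClassificationReport(
        threshold=float(threshold),
        summary=summarize_by_type(valid),
        fp_count=fp,
        fp_rate=fp / len(alpha) if len(alpha) else 0.0,
        fn_count=fn,
        fn_rate=fn / len(beta) if len(beta) else 0.0,
        n_beta=int(len(beta)),
        n_alpha=int(len(alpha)),
        excluded=excluded,
    )


def exclusion_summary(identity_table: pd.DataFrame, ndigits: int | None = 0) -> float:
    """Percent of imaged cells left unclassified by the immunostain.

    ``ndigits=0`` (default) rounds to the nearest integer percent for
    display; pass ``None`` for the exact value.
    """
    if identity_table.empty:
        raise ValueError("identity table is empty")
    pct = 100.0 * (identity_table["label"] == LABEL_UNCLASSIFIED).sum() / len(identity_table)
    return float(pct) if ndigits is None else float(round(pct, ndigits))
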