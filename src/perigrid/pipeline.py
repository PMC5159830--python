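"""The two end-to-end workflows: fixture simulation and trace analysis."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .grid import GridLayout
from .io import (
    read_cells_csv,
    read_stains_csv,
    read_traces_csv,
    write_cells_csv,
    write_json,
    write_stains_csv,
    write_traces_csv,
)
from .mapping import build_identity_table
from .responses import analyze_traces, windows_from_protocol
from .stats import ClassificationReport, bin_responses, classify_fp_fn, exclusion_summary
from .synthetic import sample_population, simulate_staining, simulate_traces

__all__ = ["run_simulate", "run_analyze"]

log = logging.getLogger("perigrid")


def _layout(config: RunConfig) -> GridLayout:
    g = config.grid
    return GridLayout(g.square_size_um, g.n_rows, g.n_cols)


def _manifest(config: RunConfig, extra: dict | None = None) -> dict:
    manifest = {
        "package": "perigrid",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.model_dump(mode="json"),
    }
    manifest.update(extra or {})
    return manifest


def run_simulate(config: RunConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate a complete synthetic experiment bundle on disk.

    Writes ``cells.csv`` (ground truth + live centroids), ``traces.csv``
    (long-format raw traces), ``stains.csv`` (post-fixation table),
    ``protocol.json`` and ``manifest.json``.  Identical config and seed
    reproduce byte-identical files.
    """
    import numpy as np

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout = _layout(config)
    spec = config.population_spec()
    protocol = config.effective_protocol()

    log.info("simulate: %d cells over %d regions (channel %s, seed %d)",
             spec.n_cells, spec.n_regions, config.channel, config.seed)

    cells = sample_population(spec, layout, rng=np.random.default_rng([config.seed, 0]))
    traceset = simulate_traces(
        cells,
        protocol,
        sampling_period_s=config.sampling_period_s,
        time_constant_min=config.time_constant_min,
        seed=[config.seed, 1],
        channel=config.trace_channel,
    )
    stains = simulate_staining(cells, spec, layout, rng=np.random.default_rng([config.seed, 2]))

    paths = {
        "cells": out / "cells.csv",
        "traces": out / "traces.csv",
        "stains": out / "stains.csv",
        "protocol": out / "protocol.json",
        "manifest": out / "manifest.json",
    }
    write_cells_csv(cells, paths["cells"])
    write_traces_csv(traceset, paths["traces"])
    write_stains_csv(stains, paths["stains"])
    protocol.to_json(paths["protocol"])
    write_json(_manifest(config, {"n_cells": len(cells)}), paths["manifest"])
    log.info("simulate: bundle written to %s", out)
    return paths


def run_analyze(
    config: RunConfig,
    traces_path: str | Path,
    stains_path: str | Path,
    cells_path: str | Path,
    out_dir: str | Path,
) -> ClassificationReport:
    """Analyze a trace + stain bundle into a classification report.

    Steps: score every trace (per-cell KCN/FCCP normalization for NAD(P)H),
    map stain identities onto live ROIs through the grid, histogram
    responses per type, and count threshold errors.  Writes
    ``responses.csv``, ``frequency.csv``, ``report.json``, ``qc.csv`` and
    ``manifest.json``.  Per-cell calibration failures are logged and
    excluded, never fatal.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout = _layout(config)

    traceset = read_traces_csv(traces_path)
    stains = read_stains_csv(stains_path)
    live = read_cells_csv(cells_path)
    log.info("analyze: %d traces, %d stain records, %d live ROIs",
             traceset.n_cells, len(stains), len(live))

    windows = windows_from_protocol(config.effective_protocol(), traceset.channel)
    response_table = analyze_traces(traceset, windows)
    for _, row in response_table[response_table["qc_flag"] != "ok"].iterrows():
        log.warning("analyze: cell %s excluded (%s)", row["cell_id"], row["qc_flag"])

    identity = build_identity_table(
        live,
        stains,
        layout,
        tolerance_um=config.matching_tolerance_um,
        insulin_threshold=config.insulin_threshold,
        glucagon_threshold=config.glucagon_threshold,
    )
    merged = response_table.merge(identity, on="cell_id", how="left", validate="1:1")
    merged["label"] = merged["label"].fillna("unmatched")

    lo, hi = config.effective_range()
    freq = bin_responses(
        merged[merged["label"].isin(["beta", "alpha"])],
        config.effective_bin_width(),
        lo,
        hi,
    )
    report = classify_fp_fn(merged, config.response_threshold)
    pct_unclassified = exclusion_summary(identity)
    log.info(
        "analyze: FP %d/%d (rate %.4g), FN %d/%d (rate %.4g), %g%% unclassified",
        report.fp_count, report.n_alpha, report.fp_rate,
        report.fn_count, report.n_beta, report.fn_rate, pct_unclassified,
    )

    merged.to_csv(out / "responses.csv", index=False)
    freq.to_frame().to_csv(out / "frequency.csv", index=False)
    qc = merged[(merged["qc_flag"] != "ok") | (~merged["label"].isin(["beta", "alpha"]))]
    qc[["cell_id", "label", "qc_flag"]].to_csv(out / "qc.csv", index=False)
    report_dict = report.to_dict()
    report_dict["percent_unclassified"] = pct_unclassified
    write_json(report_dict, out / "report.json")
    write_json(_manifest(config), out / "manifest.json")
    return report
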