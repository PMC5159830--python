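from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

from perigrid import (
    assign_identity,
    build_identity_table,
    estimate_square_offset,
    islet_nadph_population_spec,
    match_cells,
    sample_population,
    simulate_staining,
)
from perigrid.mapping import _greedy_pairs
from perigrid.synthetic import StainRecord


def _live_frame(cells):
    return pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "x_um": [c.centroid_um[0] for c in cells],
            "y_um": [c.centroid_um[1] for c in cells],
            "square_id": [c.square_id for c in cells],
        }
    )


class TestEstimateSquareOffset:
    def test_recovers_known_shift(self, rng):
        live = rng.uniform(20, 130, size=(12, 2))
        stained = live + np.array([5.0, -3.0])
        offset = estimate_square_offset(live, stained)
        assert np.allclose(offset, [5, -3], atol=1.0)

    def test_identical_clouds_give_zero(self, rng):
        live = rng.uniform(0, 150, size=(8, 2))
        assert np.allclose(estimate_square_offset(live, live), [0, 0])

    def test_single_cell_pair(self):
        offset = estimate_square_offset(np.array([[50.0, 50.0]]), np.array([[57.0, 46.0]]))
        assert np.allclose(offset, [7, -4], atol=0.5)

    def test_empty_side_falls_back_to_zero(self, rng):
        live = rng.uniform(0, 150, size=(5, 2))
        assert np.allclose(estimate_square_offset(live, np.empty((0, 2))), [0, 0])
        assert np.allclose(estimate_square_offset(np.empty((0, 2)), live), [0, 0])


class TestMatchCells:
    def _population(self, layout, jitter=0.0, offset=(0.0, 0.0), seed=0):
        spec = islet_nadph_population_spec(
            n_cells=40,
            n_regions=4,
            centroid_jitter_um=jitter,
            session_offset_um=offset,
        )
        cells = sample_population(spec, layout, np.random.default_rng(seed))
        stains = simulate_staining(cells, spec, layout, np.random.default_rng(seed + 1))
        return cells, stains

    def test_zero_jitter_matches_every_cell_exactly(self, layout):
        cells, stains = self._population(layout)
        result = match_cells(_live_frame(cells), stains, layout)
        assert (result.matches["stain_index"] >= 0).all()
        assert np.allclose(result.matches["distance_um"], 0.0, atol=1e-9)
        for _, row in result.matches.iterrows():
            assert stains[row["stain_index"]].source_cell_id == row["cell_id"]

    def test_session_offset_is_removed(self, layout):
        cells, stains = self._population(layout, offset=(6.0, -8.0))
        result = match_cells(_live_frame(cells), stains, layout)
        for off in result.square_offsets_um.values():
            assert np.allclose(off, [6, -8], atol=1.0)
        for _, row in result.matches.iterrows():
            assert stains[row["stain_index"]].source_cell_id == row["cell_id"]

    def test_small_jitter_recovers_ground_truth(self, layout):
        cells, stains = self._population(layout, jitter=2.0, offset=(3.0, -4.0))
        result = match_cells(_live_frame(cells), stains, layout)
        matched = result.matches[result.matches["stain_index"] >= 0]
        correct = sum(
            stains[row["stain_index"]].source_cell_id == row["cell_id"]
            for _, row in matched.iterrows()
        )
        assert correct == len(cells)

    def test_missing_stain_record_leaves_cell_unmatched(self, layout):
        cells, stains = self._population(layout)
        dropped = stains[0].source_cell_id
        result = match_cells(_live_frame(cells), stains[1:], layout)
        row = result.matches.set_index("cell_id").loc[dropped]
        assert row["stain_index"] == -1

    def test_one_to_one_matching(self, layout):
        cells, stains = self._population(layout, jitter=3.0)
        result = match_cells(_live_frame(cells), stains, layout)
        assigned = result.matches[result.matches["stain_index"] >= 0]["stain_index"]
        assert assigned.is_unique

    def test_offset_equivariance(self, layout):
        """A constant shift of all stained centroids changes no assignment."""
        cells, stains = self._population(layout, jitter=2.0)
        result_a = match_cells(_live_frame(cells), stains, layout)
        shifted = [
            replace(s, centroid_um=(s.centroid_um[0] + 9.0, s.centroid_um[1] + 5.0))
            for s in stains
        ]
        result_b = match_cells(_live_frame(cells), shifted, layout)
        pd.testing.assert_series_equal(
            result_a.matches["stain_index"], result_b.matches["stain_index"]
        )


class TestGreedyVsOptimal:
    def test_agrees_with_optimal_assignment_under_small_jitter(self):
        """Greedy matching equals the exhaustive minimum-cost assignment on
        small squares when jitter << spacing (>=99% of seeded trials)."""
        rng = np.random.default_rng(2024)
        agree = 0
        trials = 400
        for _ in range(trials):
            n = rng.integers(2, 11)
            # points with >= 30 um spacing, jitter sd < 1/4 spacing
            pts = []
            while len(pts) < n:
                cand = rng.uniform(0, 150, 2)
                if all(np.hypot(*(cand - p)) >= 30 for p in pts):
                    pts.append(cand)
            live = np.array(pts)
            stained = live + rng.normal(0, 2.0, size=live.shape)
            pairs = _greedy_pairs(live, stained, tolerance=np.inf)
            greedy = {i: j for i, j, _ in pairs}
            d = np.linalg.norm(live[:, None] - stained[None, :], axis=2)
            rows, cols = linear_sum_assignment(d)
            optimal = dict(zip(rows.tolist(), cols.tolist()))
            agree += greedy == optimal
        assert agree / trials >= 0.99


class TestAssignIdentity:
    def _rec(self, ins, glu):
        return StainRecord((0, 0), "R001C001", ins, glu)

    @pytest.mark.parametrize(
        "ins,glu,label",
        [
            (900, 10, "beta"),
            (10, 900, "alpha"),
            (10, 10, "unclassified"),
            (900, 900, "ambiguous"),
        ],
    )
    def test_labels(self, ins, glu, label):
        assert assign_identity(self._rec(ins, glu), 100, 100) == label

    def test_no_record_is_unmatched(self):
        assert assign_identity(None) == "unmatched"

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            assign_identity(self._rec(1, 1), 0, 100)


def test_identity_table_has_one_row_per_live_cell(layout):
    spec = islet_nadph_population_spec(n_cells=30, n_regions=3)
    cells = sample_population(spec, layout, np.random.default_rng(5))
    stains = simulate_staining(cells, spec, layout, np.random.default_rng(6))
    table = build_identity_table(_live_frame(cells), stains, layout)
    assert sorted(table["cell_id"]) == sorted(c.cell_id for c in cells)
    assert table["cell_id"].is_unique
    assert set(table["label"]) <= {"beta", "alpha", "unclassified", "ambiguous", "unmatched"}
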