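from collections import Counter
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats as sps

from perigrid import (
    PopulationSpec,
    ResponseDistribution,
    analyze_traces,
    extract_roi_traces,
    islet_nadph_population_spec,
    render_region_image,
    sample_population,
    simulate_staining,
    simulate_traces,
    windows_from_protocol,
)
from perigrid.acquisition import CircleRoi


def _cells(spec, layout, seed=0):
    return sample_population(spec, layout, np.random.default_rng(seed))


class TestSamplePopulation:
    def test_exact_quota_reproduces_reference_counts(self, default_spec, layout):
        cells = _cells(default_spec, layout)
        counts = Counter(c.type_label for c in cells)
        assert counts == {"beta": 183, "alpha": 32, "other": 12}

    def test_seed_determinism(self, default_spec, layout):
        a = _cells(default_spec, layout, seed=42)
        b = _cells(default_spec, layout, seed=42)
        assert a == b

    def test_single_type_composition(self, layout):
        spec = islet_nadph_population_spec(
            n_cells=100, composition={"beta": 1.0}, n_regions=5
        )
        cells = _cells(spec, layout)
        assert len(cells) == 100
        assert all(c.type_label == "beta" for c in cells)

    def test_invalid_composition_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            PopulationSpec(composition={"beta": 0.6, "alpha": 0.6})

    def test_generator_invariants(self, default_spec, layout):
        layout_cells = _cells(default_spec, layout)
        for c in layout_cells:
            assert c.rfu_kcn_true > c.rfu_fccp_true >= 0
            x0, y0 = layout.square_origin_um(c.square_id)
            assert x0 <= c.centroid_um[0] <= x0 + layout.square_size_um
            assert y0 <= c.centroid_um[1] <= y0 + layout.square_size_um

    def test_sample_means_track_generator_means(self, layout):
        """Law-of-large-numbers check at n = 10,000 per type."""
        spec = islet_nadph_population_spec(
            n_cells=20_000,
            composition={"beta": 0.5, "alpha": 0.5},
            n_regions=2000,
            min_spacing_um=5.0,
        )
        cells = _cells(spec, layout, seed=3)
        for label in ("beta", "alpha"):
            dist = spec.response_distributions[label]
            vals = np.array([c.response_param for c in cells if c.type_label == label])
            assert abs(vals.mean() - dist.mean) < 3 * dist.sd / np.sqrt(vals.size)

    def test_multinomial_composition_unbiased(self, layout):
        """Pooled type counts over 200 multinomial draws pass a chi-square GOF test."""
        spec = islet_nadph_population_spec(exact_quota=False, n_cells=50, n_regions=5)
        rng = np.random.default_rng(7)
        totals = Counter()
        n_rep = 200
        for _ in range(n_rep):
            totals.update(c.type_label for c in sample_population(spec, layout, rng))
        labels = sorted(spec.composition)
        observed = [totals[lab] for lab in labels]
        expected = [spec.composition[lab] * spec.n_cells * n_rep for lab in labels]
        assert sps.chisquare(observed, expected).pvalue > 0.01

    def test_truncated_response_distribution_respects_bounds(self, rng):
        dist = ResponseDistribution(27.0, 12.2, lo=8.0)
        draws = dist.sample(5000, rng)
        assert draws.min() >= 8.0
        assert abs(np.median(draws) - sps.truncnorm(
            (8 - 27) / 12.2, np.inf, loc=27, scale=12.2).median()) < 1.0


class TestSimulateTraces:
    def test_seed_determinism(self, default_spec, layout, nadph_protocol):
        cells = _cells(default_spec, layout)
        a = simulate_traces(cells, nadph_protocol, seed=9)
        b = simulate_traces(cells, nadph_protocol, seed=9)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.times_min, b.times_min)

    def test_noiseless_instantaneous_plateaus_exact(self, layout, nadph_protocol):
        spec = islet_nadph_population_spec(
            n_cells=5, n_regions=1, noise_sd=0.0, drift_slope_sd=0.0
        )
        cells = _cells(spec, layout)
        ts = simulate_traces(cells, nadph_protocol, time_constant_min=0.0, seed=0)
        for i, c in enumerate(cells):
            trace = ts.values[i]
            t = ts.times_min
            span = c.rfu_kcn_true - c.rfu_fccp_true
            high = c.baseline_rfu + c.response_param / 100 * span
            # a sample at a switch instant still shows the previous plateau
            assert np.allclose(trace[t <= 20], c.baseline_rfu)
            assert np.allclose(trace[(t > 20) & (t <= 70)], high)
            assert np.allclose(trace[(t > 115) & (t <= 135)], c.rfu_kcn_true)
            assert np.allclose(trace[t > 135], c.rfu_fccp_true)

    def test_noiseless_statistic_equals_response_param(
        self, layout, nadph_protocol, nadph_windows
    ):
        """Full scoring chain returns the generator's response exactly."""
        spec = islet_nadph_population_spec(
            n_cells=8, n_regions=1, noise_sd=0.0, drift_slope_sd=0.0
        )
        cells = _cells(spec, layout)
        ts = simulate_traces(cells, nadph_protocol, time_constant_min=0.0, seed=0)
        table = analyze_traces(ts, nadph_windows).set_index("cell_id")
        for c in cells:
            assert table.loc[c.cell_id, "statistic"] == pytest.approx(
                c.response_param, abs=1e-9
            )

    def test_empty_cell_list_rejected(self, nadph_protocol):
        with pytest.raises(ValueError):
            simulate_traces([], nadph_protocol)


class TestSimulateStaining:
    def test_zero_jitter_preserves_centroids(self, layout, default_spec):
        spec = replace(default_spec, centroid_jitter_um=0.0, session_offset_um=(0.0, 0.0))
        cells = _cells(spec, layout)
        stains = simulate_staining(cells, spec, layout, np.random.default_rng(1))
        by_src = {s.source_cell_id: s for s in stains}
        for c in cells:
            assert by_src[c.cell_id].centroid_um == pytest.approx(c.centroid_um)

    def test_unstained_quota_yields_double_negatives(self, layout):
        spec = islet_nadph_population_spec(
            n_cells=224,
            composition={"beta": 1.0},
            unstained_fraction=12 / 224,
            n_regions=10,
        )
        cells = _cells(spec, layout)
        stains = simulate_staining(cells, spec, layout, np.random.default_rng(2))
        negatives = [
            s for s in stains if s.insulin_intensity < 100 and s.glucagon_intensity < 100
        ]
        assert len(negatives) == 12

    def test_other_cells_never_stain(self, layout, default_spec):
        cells = _cells(default_spec, layout)
        stains = simulate_staining(cells, default_spec, layout, np.random.default_rng(3))
        truth = {c.cell_id: c.type_label for c in cells}
        for s in stains:
            if truth[s.source_cell_id] == "other":
                assert s.insulin_intensity < 100 and s.glucagon_intensity < 100

    def test_no_costaining_when_fraction_zero(self, layout, default_spec):
        cells = _cells(default_spec, layout)
        stains = simulate_staining(cells, default_spec, layout, np.random.default_rng(4))
        assert not any(
            s.insulin_intensity >= 100 and s.glucagon_intensity >= 100 for s in stains
        )

    def test_costain_fraction_produces_double_positives(self, layout):
        spec = islet_nadph_population_spec(co_stain_fraction=0.1)
        cells = _cells(spec, layout)
        stains = simulate_staining(cells, spec, layout, np.random.default_rng(5))
        n_double = sum(
            s.insulin_intensity >= 100 and s.glucagon_intensity >= 100 for s in stains
        )
        assert n_double == round(0.1 * 215)  # 215 hormone-positive cells


class TestRenderRegionImage:
    def test_empty_region_is_uniform_background(self, small_layout):
        img, meta = render_region_image(
            [], small_layout, {}, image_size_px=64, background=7.0, square_id="R001C001"
        )
        assert img.shape == (64, 64)
        assert np.all(img == 7.0)
        assert meta["um_per_px"] == pytest.approx(150 / 64)

    def test_single_cell_roi_mean_equals_intensity(self, small_layout, default_spec):
        spec = replace(default_spec, n_cells=1, n_regions=1, composition={"beta": 1.0})
        cells = _cells(spec, small_layout)
        img, meta = render_region_image(cells, small_layout, {cells[0].cell_id: 100.0},
                                        image_size_px=256)
        scale = meta["um_per_px"]
        origin = np.array(meta["origin_um"])
        rel = (np.array(cells[0].centroid_um) - origin) / scale
        roi = CircleRoi(cells[0].cell_id, rel[0], rel[1], 7.5 / scale)
        stack = np.stack([img, img])
        ts = extract_roi_traces(stack, [roi], np.array([0.0, 2.0]))
        assert ts.values[0, 0] == pytest.approx(100.0)

    def test_two_cells_recover_set_intensities(self, small_layout):
        spec = islet_nadph_population_spec(
            n_cells=2, n_regions=1, composition={"beta": 1.0}, min_spacing_um=40.0
        )
        cells = _cells(spec, small_layout, seed=11)
        intensities = {cells[0].cell_id: 80.0, cells[1].cell_id: 160.0}
        img, meta = render_region_image(cells, small_layout, intensities, image_size_px=256)
        scale = meta["um_per_px"]
        origin = np.array(meta["origin_um"])
        rois = [
            CircleRoi(c.cell_id, *((np.array(c.centroid_um) - origin) / scale), 7.5 / scale)
            for c in cells
        ]
        ts = extract_roi_traces(np.stack([img, img]), rois, np.array([0.0, 2.0]))
        for c in cells:
            assert ts.get(c.cell_id)[0] == pytest.approx(intensities[c.cell_id])

    def test_cells_from_different_squares_rejected(self, small_layout, default_spec):
        spec = replace(default_spec, n_cells=4, n_regions=2)
        cells = _cells(spec, small_layout)
        assert len({c.square_id for c in cells}) == 2
        with pytest.raises(ValueError, match="squares"):
            render_region_image(cells, small_layout, {})
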