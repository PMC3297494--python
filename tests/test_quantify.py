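"""Per-cell ratio measurement, segmentation, collections, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ratioquant import (
    Channel,
    ChannelImage,
    LabelMask,
    SyntheticSampleSpec,
    draw_cell_truths,
    generate_field,
    measure_cell,
    measure_field,
    render_field,
    segment_cells,
    select_cell_collection,
    summarize_sample,
)
from ratioquant.quantify import CellMeasurement


def _img(arr, channel=Channel.GREEN_NAIP):
    return ChannelImage(np.asarray(arr, dtype=np.uint16), channel, 16, "000", "s1")


def _cells(ratios, sample_id="s1"):
    return [
        CellMeasurement(sample_id, "000", i + 1, r * 100.0, 100.0, r, 50)
        for i, r in enumerate(ratios)
    ]


class TestMeasureCell:
    def test_uniform_cell_ratio(self):
        mask = LabelMask(np.ones((4, 4), dtype=np.int64))
        m = measure_cell(_img(np.full((4, 4), 100)), _img(np.full((4, 4), 200),
                         Channel.RED_GAPDH), mask, 1)
        assert m.ratio == 0.5
        assert m.n_pixels == 16

    def test_zero_green_gives_zero_ratio(self):
        mask = LabelMask(np.ones((3, 3), dtype=np.int64))
        m = measure_cell(_img(np.zeros((3, 3))), _img(np.full((3, 3), 50),
                         Channel.RED_GAPDH), mask, 1)
        assert m.ratio == 0.0

    def test_three_pixel_hand_oracle(self):
        # green {10,20,30}, red {40,50,60}: means 20 and 50, ratio 0.4
        green = np.zeros((2, 3), dtype=np.uint16)
        red = np.zeros((2, 3), dtype=np.uint16)
        mask = np.zeros((2, 3), dtype=np.int64)
        green[0] = [10, 20, 30]
        red[0] = [40, 50, 60]
        mask[0] = 1
        m = measure_cell(_img(green), _img(red, Channel.RED_GAPDH), LabelMask(mask), 1)
        assert m.green_mean == 20.0
        assert m.red_mean == 50.0
        assert m.ratio == 0.4
        assert m.n_pixels == 3

    def test_zero_red_mean_excludes_with_warning(self, caplog):
        mask = LabelMask(np.ones((3, 3), dtype=np.int64))
        with caplog.at_level("WARNING", logger="ratioquant.quantify"):
            m = measure_cell(_img(np.full((3, 3), 10)), _img(np.zeros((3, 3)),
                             Channel.RED_GAPDH), mask, 1)
        assert m is None
        assert any("housekeeping" in r.message for r in caplog.records)

    def test_small_cell_excluded(self, caplog):
        mask = np.zeros((5, 5), dtype=np.int64)
        mask[0, 0] = 1
        with caplog.at_level("WARNING", logger="ratioquant.quantify"):
            m = measure_cell(_img(np.full((5, 5), 10)), _img(np.full((5, 5), 20),
                             Channel.RED_GAPDH), LabelMask(mask), 1, min_cell_area=4)
        assert m is None

    def test_absent_cell_id_raises(self):
        mask = LabelMask(np.ones((3, 3), dtype=np.int64))
        with pytest.raises(ValueError, match="not present"):
            measure_cell(_img(np.ones((3, 3))), _img(np.ones((3, 3)),
                         Channel.RED_GAPDH), mask, 9)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            measure_cell(_img(np.ones((3, 3))), _img(np.ones((4, 4)),
                         Channel.RED_GAPDH), LabelMask(np.ones((3, 3), dtype=np.int64)), 1)


class TestMeasureField:
    def test_agrees_with_measure_cell_per_label(self, noise_free_spec):
        truths, green, red, mask = generate_field(noise_free_spec, 0)
        by_field = {m.cell_id: m for m in measure_field(green, red, mask)}
        for t in truths:
            single = measure_cell(green, red, mask, t.cell_id)
            assert by_field[t.cell_id] == single

    def test_border_cells_excluded(self):
        mask = np.zeros((6, 6), dtype=np.int64)
        mask[0, 0:3] = 1        # touches the border
        mask[2:4, 2:4] = 2      # interior
        green = _img(np.full((6, 6), 10))
        red = _img(np.full((6, 6), 20), Channel.RED_GAPDH)
        out = measure_field(green, red, LabelMask(mask))
        assert [m.cell_id for m in out] == [2]
        out_all = measure_field(green, red, LabelMask(mask), exclude_border=False)
        assert [m.cell_id for m in out_all] == [1, 2]

    def test_zero_noise_ratios_equal_truth_exactly(self, noise_free_spec):
        for idx in range(noise_free_spec.n_images):
            truths, green, red, mask = generate_field(noise_free_spec, idx)
            measured = {m.cell_id: m.ratio for m in measure_field(green, red, mask)}
            for t in truths:
                assert measured[t.cell_id] == t.true_ratio


class TestInvariances:
    def test_common_gain_leaves_ratios_unchanged(self, noise_free_spec):
        truths, green, red, mask = generate_field(noise_free_spec, 0)
        base = measure_field(green, red, mask)
        g3 = ChannelImage(green.pixels * 3, green.channel, 16, green.field_id, green.sample_id)
        r3 = ChannelImage(red.pixels * 3, red.channel, 16, red.field_id, red.sample_id)
        scaled = measure_field(g3, r3, mask)
        for b, s in zip(base, scaled):
            assert s.ratio == b.ratio

    def test_green_only_gain_scales_ratios_exactly(self, noise_free_spec):
        truths, green, red, mask = generate_field(noise_free_spec, 0)
        base = measure_field(green, red, mask)
        g3 = ChannelImage(green.pixels * 3, green.channel, 16, green.field_id, green.sample_id)
        scaled = measure_field(g3, red, mask)
        for b, s in zip(base, scaled):
            # exact in real arithmetic; allow 1-ulp from the float product
            assert s.ratio == pytest.approx(3 * b.ratio, rel=1e-15)

    def test_additive_offset_pulls_ratios_toward_one(self, noise_free_spec):
        truths, green, red, mask = generate_field(noise_free_spec, 0)
        base = measure_field(green, red, mask)
        off = 500
        g_off = ChannelImage(green.pixels + off, green.channel, 16, "000", "s1")
        r_off = ChannelImage(red.pixels + off, red.channel, 16, "000", "s1")
        shifted = measure_field(g_off, r_off, mask)
        for b, s in zip(base, shifted):
            assert abs(s.ratio - 1) < abs(b.ratio - 1)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(g=st.integers(0, 1000), r=st.integers(1, 1000))
    def test_ratio_is_mean_quotient(self, g, r):
        green = _img(np.full((5, 5), g))
        red = _img(np.full((5, 5), r), Channel.RED_GAPDH)
        mask = LabelMask(np.ones((5, 5), dtype=np.int64))
        m = measure_cell(green, red, mask, 1)
        assert m.ratio == g / r


class TestSegmentCells:
    def test_synthetic_field_recovers_cell_count(self, noise_free_spec):
        truths, _, red, _ = generate_field(noise_free_spec, 0)
        seg = segment_cells(red, min_cell_area=10)
        assert len(seg.cell_ids) == len(truths)

    def test_constant_image_gives_empty_mask(self):
        red = _img(np.full((32, 32), 5), Channel.RED_GAPDH)
        assert segment_cells(red).cell_ids == []

    def test_small_components_removed(self):
        arr = np.zeros((20, 20), dtype=np.uint16)
        arr[2:12, 2:7] = 300    # area 50
        arr[15:17, 15:19] = 300  # area 8
        seg = segment_cells(_img(arr, Channel.RED_GAPDH), min_cell_area=20)
        assert len(seg.cell_ids) == 1
        assert int((seg.labels > 0).sum()) == 50

    def test_labels_assigned_in_raster_order(self):
        arr = np.zeros((20, 20), dtype=np.uint16)
        arr[10:14, 1:5] = 300   # lower-left, later in raster order
        arr[1:5, 10:14] = 300   # upper-right, earlier
        seg = segment_cells(_img(arr, Channel.RED_GAPDH), min_cell_area=4)
        assert seg.labels[2, 12] == 1
        assert seg.labels[12, 2] == 2


class TestSelectCellCollection:
    def test_subset_size_and_determinism(self):
        cells = _cells(np.linspace(0.4, 0.8, 50))
        a = select_cell_collection(cells, 30, seed=3)
        b = select_cell_collection(cells, 30, seed=3)
        assert len(a) == 30
        assert len({c.cell_id for c in a}) == 30
        assert a == b
        c = select_cell_collection(cells, 30, seed=4)
        assert a != c

    def test_shortfall_returns_all_with_warning(self, caplog):
        cells = _cells(np.linspace(0.4, 0.8, 20))
        with caplog.at_level("WARNING", logger="ratioquant.quantify"):
            out = select_cell_collection(cells, 30, seed=0)
        assert out == cells
        assert any("30-cell" in r.message for r in caplog.records)

    def test_empty_sample_unanalyzable(self):
        with pytest.raises(ValueError, match="unanalyzable"):
            select_cell_collection([], 30, seed=0)

    def test_inclusion_frequencies_uniform(self):
        # 200 resamplings of 100 cells at k=30: each cell's inclusion count
        # is Binomial(200, 0.3); check all 100 cells within +-4 sigma
        # (family-wise bounds across the 100 simultaneous checks)
        cells = _cells(np.linspace(0.1, 1.0, 100))
        counts = np.zeros(101)
        for rep in range(200):
            for c in select_cell_collection(cells, 30, seed=1000 + rep):
                counts[c.cell_id] += 1
        mean, sigma = 200 * 0.3, np.sqrt(200 * 0.3 * 0.7)
        assert counts[1:].sum() == 200 * 30
        assert np.all(np.abs(counts[1:] - mean) < 4 * sigma)


class TestSummarizeSample:
    def test_constant_ratios(self):
        s = summarize_sample(_cells([0.6] * 30), group_label="HL")
        assert s.mean_ratio == pytest.approx(0.6, abs=1e-15)
        assert s.sd_ratio == pytest.approx(0.0, abs=1e-15)
        assert s.n_cells == 30

    def test_hand_formula_oracle(self):
        s = summarize_sample(_cells([0.4, 0.6]))
        assert s.mean_ratio == pytest.approx(0.5, abs=1e-15)
        assert s.sd_ratio == pytest.approx(0.1414213562, abs=1e-9)

    def test_single_cell_convention(self, caplog):
        with caplog.at_level("WARNING", logger="ratioquant.quantify"):
            s = summarize_sample(_cells([0.7]))
        assert s.mean_ratio == 0.7
        assert s.sd_ratio == 0.0

    def test_mixed_samples_rejected(self):
        cells = _cells([0.5], "a") + _cells([0.6], "b")
        with pytest.raises(ValueError, match="mixes"):
            summarize_sample(cells)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_sample([])


class TestEstimatorRecovery:
    def test_sample_mr_recovers_true_mean_under_noise(self):
        # with noise on, M.R should sit within 3 * SD/sqrt(n) of truth in
        # nearly all replicates; allow one failure in ten seeds
        from ratioquant.pipeline import simulate_sample_summary

        hits = 0
        for seed in range(10):
            spec = SyntheticSampleSpec(
                sample_id=f"rec{seed}", n_images=2, cells_per_image=15,
                true_mean_ratio=0.6, between_cell_sd=0.05,
                pixel_noise_sd=30.0, image_shape=(128, 128),
                cell_radius_range=(4, 8), seed=seed,
            )
            s = simulate_sample_summary(spec, k_cells=30)
            se = s.sd_ratio / np.sqrt(s.n_cells)
            hits += abs(s.mean_ratio - 0.6) < 3 * se
        assert hits >= 9
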