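import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from clonemark.io_formats import SegRecord, ValidationError
from clonemark.scna import (
    WindowGrid,
    _grid_layout,
    call_regions,
    classify_level,
    classify_levels,
    cosine_similarity,
    g_scores,
    permutation_null,
    segments_to_windows,
)

GENOME = {"1": 10_000, "2": 10_000}


def seg(sample, chrom, start, end, log2):
    return SegRecord(sample, chrom, start, end, log2)


def noise_grid(values: np.ndarray, genome=GENOME) -> WindowGrid:
    order, slices, n = _grid_layout(genome, 1000)
    assert values.shape[1] == n
    return WindowGrid(
        genome=dict(genome),
        window_size=1000,
        chrom_order=order,
        chrom_slices=slices,
        samples=tuple(f"s{i}" for i in range(values.shape[0])),
        values=values,
    )


class TestSegmentsToWindows:
    def test_segment_covering_three_windows(self):
        grid = segments_to_windows([seg("a", "1", 1, 3000, 0.5)], GENOME)
        sl = grid.chrom_slices["1"]
        assert np.allclose(grid.values[0, sl][:3], 0.5)
        assert np.isnan(grid.values[0, sl][3:]).all()

    def test_half_covered_window_weighted_mean(self):
        segs = [seg("a", "1", 1, 500, 1.0), seg("a", "1", 501, 1000, 0.0)]
        grid = segments_to_windows(segs, GENOME)
        assert grid.values[0, grid.chrom_slices["1"].start] == pytest.approx(0.5)

    def test_uncovered_chromosome_is_missing(self):
        grid = segments_to_windows([seg("a", "1", 1, 1000, 0.0)], GENOME)
        assert np.isnan(grid.values[0, grid.chrom_slices["2"]]).all()

    def test_segment_beyond_chromosome_rejected(self):
        with pytest.raises(ValidationError):
            segments_to_windows([seg("a", "1", 1, 20_000, 0.0)], GENOME)

    def test_conserves_length_weighted_mean(self):
        rng = np.random.default_rng(2)
        segs, pos = [], 1
        while pos < 10_000:
            ln = int(rng.choice([500, 1000, 1500, 2500]))
            end = min(pos + ln - 1, 10_000)
            segs.append(seg("a", "1", pos, end, float(rng.normal())))
            pos = end + 1
        grid = segments_to_windows(segs, GENOME)
        total_from_segs = sum((s.end - s.start + 1) * s.log2_ratio for s in segs)
        sl = grid.chrom_slices["1"]
        vals = grid.values[0, sl]
        assert np.nansum(vals) * 1000 == pytest.approx(total_from_segs, rel=1e-9)


class TestGScores:
    def test_all_zero_grid(self):
        grid = noise_grid(np.zeros((3, 20)))
        g_amp, g_del = g_scores(grid)
        assert not g_amp.any() and not g_del.any()

    def test_two_sample_average(self):
        vals = np.zeros((2, 20))
        vals[0, 0] = 1.0
        g_amp, g_del = g_scores(noise_grid(vals))
        assert g_amp[0] == pytest.approx(0.5)
        assert g_del[0] == 0.0

    def test_sign_flip_swaps_directions(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(4, 20))
        ga1, gd1 = g_scores(noise_grid(vals))
        ga2, gd2 = g_scores(noise_grid(-vals))
        assert np.allclose(ga1, gd2) and np.allclose(gd1, ga2)

    def test_missing_excluded_from_denominator(self):
        vals = np.full((2, 20), np.nan)
        vals[0, 0] = 1.0
        g_amp, _ = g_scores(noise_grid(vals))
        assert g_amp[0] == pytest.approx(1.0)  # only one informative sample


class TestPermutationAndRegions:
    def test_all_zero_grid_has_no_significant_windows(self):
        grid = noise_grid(np.zeros((3, 20)))
        perm = permutation_null(grid, n_perm=200, seed=0)
        assert not perm.sig_amp.any() and not perm.sig_del.any()

    def test_planted_amplification_is_significant(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 0.1, size=(10, 20))
        vals[:, 5:8] += 1.5  # amplified in all samples
        grid = noise_grid(vals)
        perm = permutation_null(grid, n_perm=500, seed=2)
        assert perm.sig_amp[5:8].all()
        regions = call_regions(perm, grid)
        amp = [r for r in regions if r.direction == "amp"]
        assert any(r.windows[0] <= 5 and r.windows[1] >= 8 for r in amp)

    def test_two_runs_make_two_regions(self):
        order, slices, n = _grid_layout({"1": 10_000}, 1000)
        grid = noise_grid(np.zeros((2, n)), {"1": 10_000})
        from clonemark.scna import PermutationResult

        p = np.ones(n)
        p[2] = p[3] = p[6] = 0.01  # two runs split by window 4-5
        g = np.zeros(n)
        g[[2, 3, 6]] = 0.5
        perm = PermutationResult(n_perm=100, p_amp=p, p_del=np.ones(n), g_amp=g, g_del=np.zeros(n))
        regions = call_regions(perm, grid)
        assert len(regions) == 2
        assert [(r.windows) for r in regions] == [(2, 4), (6, 7)]

    def test_unimodal_run_peak_at_mode(self):
        order, slices, n = _grid_layout({"1": 10_000}, 1000)
        grid = noise_grid(np.zeros((2, n)), {"1": 10_000})
        from clonemark.scna import PermutationResult

        p = np.ones(n)
        p[:10] = 0.01
        g = np.zeros(n)
        g[:10] = [0.1, 0.2, 0.3, 0.5, 1.0, 0.99, 0.5, 0.3, 0.2, 0.1]
        perm = PermutationResult(n_perm=100, p_amp=p, p_del=np.ones(n), g_amp=g, g_del=np.zeros(n))
        (region,) = call_regions(perm, grid)
        assert region.peak == (4, 6)
        assert region.g_score == pytest.approx(1.0)


class TestLevelClassification:
    @pytest.mark.parametrize(
        "m,level",
        [
            (1.2, 2),
            (0.91, 2),
            (0.9, 1),  # boundary -> less extreme tier
            (0.5, 1),
            (0.1, 0),
            (0.0, 0),
            (-0.1, 0),
            (-0.5, -1),
            (-1.3, -1),  # boundary -> less extreme tier
            (-1.31, -2),
        ],
    )
    def test_threshold_tiers(self, m, level):
        assert classify_level(m) == level

    def test_levels_table_missing_when_uncovered(self):
        segs = [seg("a", "1", 1, 3000, 1.0), seg("b", "2", 1, 3000, 0.0)]
        grid = segments_to_windows(segs, GENOME)
        from clonemark.scna import FocalRegion

        region = FocalRegion(
            chrom="1", start=0, end=3000, direction="amp", g_score=1.0,
            p_value=0.01, windows=(0, 3), peak=(0, 3),
        )
        levels = classify_levels([region], grid)
        assert levels.loc["amp:1:0-3000", "a"] == 2
        assert np.isnan(levels.loc["amp:1:0-3000", "b"])


class TestCosine:
    def make_levels(self, a, b):
        return pd.DataFrame({"a": a, "b": b}, dtype=float)

    def test_identical_nonzero_vectors(self):
        lv = self.make_levels([2, 0, -2], [2, 0, -2])
        assert cosine_similarity(lv, "a", "b") == pytest.approx(1.0)

    def test_opposite_vectors(self):
        lv = self.make_levels([2, 0, -2], [-2, 0, 2])
        assert cosine_similarity(lv, "a", "b") == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        lv = self.make_levels([2, 1, 0, 0], [2, 0, 0, -1])
        assert cosine_similarity(lv, "a", "b") == pytest.approx(0.8)

    def test_all_zero_vector_returns_zero(self):
        lv = self.make_levels([0, 0], [1, 0])
        assert cosine_similarity(lv, "a", "b") == 0.0

    def test_no_common_regions_is_error(self):
        lv = self.make_levels([np.nan, 1], [1, np.nan])
        with pytest.raises(ValueError):
            cosine_similarity(lv, "a", "b")

    @given(st.lists(st.integers(-2, 2), min_size=1, max_size=12), st.integers(0, 5))
    def test_symmetric_and_invariant_to_double_neutral_padding(self, a, n_pad):
        rng = np.random.default_rng(sum(map(abs, a)) + n_pad)
        b = list(rng.integers(-2, 3, size=len(a)))
        lv = self.make_levels(a, b)
        if not (any(a) and any(b)):
            return
        c1 = cosine_similarity(lv, "a", "b")
        assert c1 == pytest.approx(cosine_similarity(lv, "b", "a"))
        padded = self.make_levels(a + [0] * n_pad, b + [0] * n_pad)
        assert cosine_similarity(padded, "a", "b") == pytest.approx(c1)
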