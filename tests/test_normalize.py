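import numpy as np
import pytest

from gbskaryo.counts import CountMatrix, SampleSheet
from gbskaryo.genome import Chromosome, GenomeModel, make_bins
from gbskaryo.normalize import (
    control_reference,
    log2_ratio,
    normalize_counts,
    read_normalized,
    rebin,
    scale_cpm,
    write_normalized,
)


def grid_of(n_bins, width=1_000_000):
    genome = GenomeModel((Chromosome("1A", "A", n_bins * width, width),))
    return make_bins(genome, width)


def matrix_of(counts, width=1_000_000):
    counts = np.atleast_2d(np.asarray(counts, dtype=np.int64))
    grid = grid_of(counts.shape[1], width)
    samples = tuple(f"s{i}" for i in range(counts.shape[0]))
    return CountMatrix(grid, samples, counts)


class TestScaleCpm:
    def test_direct_formula(self):
        m = matrix_of([[200, 2_000_000 - 200]])
        scaled = scale_cpm(m)
        assert scaled[0, 0] == pytest.approx(100.0)

    def test_uniform_counts(self):
        scaled = scale_cpm(matrix_of([[7, 7, 7, 7]]))
        np.testing.assert_allclose(scaled[0], 250_000.0)

    def test_matches_independent_oracle(self, rng):
        counts = rng.integers(1, 1000, size=(1, 10))
        scaled = scale_cpm(matrix_of(counts))
        oracle = np.array([c / counts.sum() * 1e6 for c in counts[0]])
        np.testing.assert_allclose(scaled[0], oracle)

    def test_per_sample_sum_is_one_million(self, rng):
        counts = rng.integers(0, 500, size=(5, 40)) + 1
        scaled = scale_cpm(matrix_of(counts))
        np.testing.assert_allclose(scaled.sum(axis=1), 1e6, rtol=1e-6)

    def test_zero_total_names_sample(self):
        with pytest.raises(ValueError, match="s0"):
            scale_cpm(matrix_of([[0, 0, 0]]))


class TestControlReference:
    def test_mean_of_controls(self):
        scaled = np.array([[100.0], [120.0], [999.0]])
        sheet = SampleSheet(("a", "b", "c"), ("control", "control", "test"))
        mean, masked = control_reference(scaled, ("a", "b", "c"), sheet)
        assert mean[0] == pytest.approx(110.0)
        assert not masked[0]

    def test_zero_control_mean_masks_bin(self):
        scaled = np.array([[0.0, 50.0]])
        sheet = SampleSheet(("a",), ("control",))
        _, masked = control_reference(scaled, ("a",), sheet)
        assert masked.tolist() == [True, False]

    def test_matches_brute_force_column_means(self, rng):
        scaled = rng.uniform(10, 100, size=(3, 5))
        sheet = SampleSheet(("a", "b", "c"), ("control",) * 3)
        mean, _ = control_reference(scaled, ("a", "b", "c"), sheet)
        for b in range(5):
            assert mean[b] == pytest.approx(sum(scaled[s][b] for s in range(3)) / 3)

    def test_no_controls_is_error(self):
        sheet = SampleSheet(("a", "b"), ("control", "test"))
        with pytest.raises(ValueError):
            control_reference(np.ones((1, 3)), ("b",), sheet)


class TestLog2Ratio:
    def test_half_dosage(self):
        ratio = log2_ratio(np.array([[50.0]]), np.array([100.0]),
                           np.array([False]), pseudo=0.0)
        assert ratio[0, 0] == pytest.approx(-1.0)

    def test_identity(self):
        ratio = log2_ratio(np.array([[100.0]]), np.array([100.0]),
                           np.array([False]), pseudo=0.25)
        assert ratio[0, 0] == 0.0

    def test_floor_applied(self):
        # log2(0.5 / 100.5) ~ -7.65 -> floored to -5
        ratio = log2_ratio(np.array([[0.0]]), np.array([100.0]),
                           np.array([False]), pseudo=0.5, ratio_floor=-5.0)
        assert ratio[0, 0] == -5.0

    def test_masked_bins_are_nan_not_zero(self):
        ratio = log2_ratio(np.array([[100.0, 100.0]]), np.array([100.0, 0.0]),
                           np.array([False, True]))
        assert ratio[0, 0] == 0.0
        assert np.isnan(ratio[0, 1])

    def test_negative_pseudo_rejected(self):
        with pytest.raises(ValueError):
            log2_ratio(np.ones((1, 1)), np.ones(1), np.zeros(1, bool), pseudo=-1)

    def test_identical_controls_give_exact_zero(self):
        """With identical control vectors the pseudocount cancels exactly."""
        counts = np.tile(np.array([3, 17, 400, 9], dtype=np.int64), (3, 1))
        m = matrix_of(counts)
        sheet = SampleSheet(m.samples, ("control",) * 3)
        norm = normalize_counts(m, sheet)
        assert (norm.log2ratio[:, ~norm.masked] == 0.0).all()


class TestRebin:
    def test_sum_conserves(self):
        grid = grid_of(5)
        table, coarse = rebin(grid, np.array([1, 2, 3, 4, 5], float),
                              5_000_000, "sum")
        assert len(table) == 1
        assert coarse[0] == 15

    def test_mean_skips_masked(self):
        grid = grid_of(5)
        vals = np.array([-1.0, -1.0, np.nan, -1.0, -1.0])
        masked = np.array([False, False, True, False, False])
        _, coarse = rebin(grid, vals, 5_000_000, "mean", masked)
        assert coarse[0] == pytest.approx(-1.0)

    def test_partial_group_matches_hand_grouping(self):
        grid = grid_of(7)
        vals = np.arange(1.0, 8.0)
        table, coarse = rebin(grid, vals, 5_000_000, "sum")
        # hand grouping: bins 0-4 then 5-6
        assert coarse.tolist() == [15.0, 13.0]
        assert table["end"].tolist() == [5_000_000, 7_000_000]

    def test_all_members_masked_gives_nan(self):
        grid = grid_of(6)
        vals = np.zeros(6)
        masked = np.array([False] * 5 + [True])
        _, coarse = rebin(grid, vals, 5_000_000, "mean", masked)
        assert np.isnan(coarse[1])

    def test_incompatible_width_rejected(self):
        with pytest.raises(ValueError):
            rebin(grid_of(5), np.zeros(5), 2_500_001, "sum")

    def test_sum_conservation_property(self, rng):
        """Per-chromosome totals survive rebinning at any multiple."""
        genome = GenomeModel(
            (
                Chromosome("1A", "A", 13_000_000, 5_000_000),
                Chromosome("1R", "R", 7_000_000, 3_000_000),
            )
        )
        grid = make_bins(genome, 1_000_000)
        vals = rng.uniform(0, 100, grid.n_bins)
        for factor in (2, 3, 5):
            _, coarse = rebin(grid, vals, factor * 1_000_000, "sum")
            assert np.nansum(coarse) == pytest.approx(vals.sum())


class TestNormalizedIO:
    def test_round_trip(self, tmp_path, rng):
        counts = rng.integers(1, 500, size=(3, 8))
        m = matrix_of(counts)
        sheet = SampleSheet(m.samples, ("control", "control", "test"))
        norm = normalize_counts(m, sheet)
        path = tmp_path / "norm.tsv"
        write_normalized(norm, path)
        back = read_normalized(path, m.grid)
        assert back.samples == norm.samples
        np.testing.assert_allclose(back.scaled, norm.scaled, rtol=1e-9)
        np.testing.assert_allclose(back.log2ratio, norm.log2ratio, rtol=1e-9)
        np.testing.assert_array_equal(back.masked, norm.masked)
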