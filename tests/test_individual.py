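"""Per-sample depth pipeline: counting, corrections, normalization, IO."""

from dataclasses import replace

import numpy as np
import pysam
import pytest

from cnvpop.dupdb import DupWindowRecord
from cnvpop.individual import (
    SampleDepthProfile,
    absolute_correction,
    count_raw_depth,
    gc_correction,
    normalize,
    read_profile,
    sex_correction,
    write_profile,
)
from cnvpop.windows import WindowGrid, build_window_grid

from conftest import make_grid


def write_sam(path, reads, chrom_lengths):
    """reads: list of (chrom, start, length, flag)."""
    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": c, "LN": L} for c, L in chrom_lengths.items()],
    }
    chroms = list(chrom_lengths)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, (chrom, start, length, flag) in enumerate(reads):
            a = pysam.AlignedSegment()
            a.query_name = f"r{i}"
            a.flag = flag
            a.reference_id = chroms.index(chrom)
            a.reference_start = start
            a.mapping_quality = 60
            a.cigartuples = [(0, length)]
            a.query_sequence = "A" * length
            out.write(a)


class TestRawCounting:
    def test_read_center_hits_both_overlapping_windows(self, tmp_path):
        grid = make_grid(10, window_size=800)
        sam = tmp_path / "s.sam"
        # 100-bp read at [350,450): center 400 lies in [0,800) and [400,1200)
        write_sam(sam, [("chr1", 350, 100, 0)], grid.chrom_lengths)
        prof = count_raw_depth(sam, grid)
        assert prof.depths[0] == 1 and prof.depths[1] == 1
        assert prof.depths[2:].sum() == 0

    @pytest.mark.parametrize("flag", [0x100, 0x400, 0x4])
    def test_flag_mask_excludes_read(self, tmp_path, flag):
        grid = make_grid(10, window_size=800)
        sam = tmp_path / "s.sam"
        write_sam(sam, [("chr1", 350, 100, flag), ("chr1", 1000, 100, 0)],
                  grid.chrom_lengths)
        prof = count_raw_depth(sam, grid)
        assert prof.depths.sum() == 2  # only the clean read, in 2 windows

    def test_no_usable_reads_is_an_error(self, tmp_path):
        grid = make_grid(4, window_size=800)
        sam = tmp_path / "s.sam"
        write_sam(sam, [("chr1", 100, 100, 0x400)], grid.chrom_lengths)
        with pytest.raises(ValueError, match="no usable reads"):
            count_raw_depth(sam, grid)

    def test_unknown_chrom_warned_and_skipped(self, tmp_path):
        grid = make_grid(4, window_size=800)
        sam = tmp_path / "s.sam"
        write_sam(sam, [("chrZ", 100, 100, 0), ("chr1", 500, 100, 0)],
                  {"chrZ": 5000, **grid.chrom_lengths})
        with pytest.warns(UserWarning, match="chrZ"):
            prof = count_raw_depth(sam, grid)
        assert prof.depths.sum() > 0

    def test_uniform_coverage_matches_expectation(self, tmp_path):
        """x20 coverage, 100-bp reads, 800-bp windows -> mean ~ 160."""
        from cnvpop.simulate import (
            simulate_counts, simulate_population, simulate_reference, write_sam as sim_sam,
        )

        truth = simulate_reference(200_000, seed=5)
        grid = build_window_grid(truth.sequences, 800)
        geno = simulate_population(truth, 1, seed=6)
        sam = tmp_path / "sim.sam"
        sim_sam(truth, geno, 0, grid, sam, coverage=20, read_length=100, seed=7)
        prof = count_raw_depth(sam, grid)
        interior = prof.depths[2:-2]  # chromosome ends lose read placements
        assert np.mean(interior) == pytest.approx(160, rel=0.03)


class TestAbsoluteCorrection:
    def grid_and_record(self, links, n=8):
        grid = make_grid(n)
        full = {int(i): (int(i),) for i in range(n)}
        for k, v in links.items():
            full[k] = tuple(sorted(v))
        return grid, DupWindowRecord(full, grid.window_size)

    def test_pair_sums_on_both_sides(self):
        grid, rec = self.grid_and_record({0: (0, 4), 4: (0, 4)})
        raw = SampleDepthProfile("s", "raw", np.arange(8, dtype=float), 400)
        raw.depths[0], raw.depths[4] = 3.0, 5.0
        out = absolute_correction(raw, rec, grid)
        assert out.depths[0] == 8.0 and out.depths[4] == 8.0

    def test_self_link_is_identity(self):
        grid, rec = self.grid_and_record({})
        raw = SampleDepthProfile("s", "raw", np.full(8, 7.0), 400)
        out = absolute_correction(raw, rec, grid)
        assert np.array_equal(out.depths, raw.depths)

    def test_triple_group(self):
        grid, rec = self.grid_and_record(
            {0: (0, 3, 6), 3: (0, 3, 6), 6: (0, 3, 6)}
        )
        raw = SampleDepthProfile("s", "raw", np.full(8, 2.0), 400)
        out = absolute_correction(raw, rec, grid)
        assert out.depths[0] == out.depths[3] == out.depths[6] == 6.0

    def test_group_conservation(self, rng):
        """Sum over a closed link group of size t equals t x raw sum."""
        grid, rec = self.grid_and_record({1: (1, 3, 5), 3: (1, 3, 5), 5: (1, 3, 5)})
        raw = SampleDepthProfile("s", "raw", rng.poisson(50, 8).astype(float), 400)
        out = absolute_correction(raw, rec, grid)
        group = [1, 3, 5]
        assert out.depths[group].sum() == pytest.approx(3 * raw.depths[group].sum())

    def test_requires_raw_stage(self):
        grid, rec = self.grid_and_record({})
        prof = SampleDepthProfile("s", "normalized", np.ones(8), 400)
        with pytest.raises(ValueError, match="raw"):
            absolute_correction(prof, rec, grid)


def grid_with_gc(gc_values, window_size=400):
    n = len(gc_values)
    g = make_grid(n, window_size)
    return replace(g, gc=np.asarray(gc_values, dtype=float), _row_of=None)


class TestGCCorrection:
    def test_direct_substitution(self):
        # bin 40 mean 12; bin 60 mean (12+4)/2 = 8; depth 4 -> 12/8*4 = 6
        grid = grid_with_gc([0.40, 0.60, 0.60])
        prof = SampleDepthProfile("s", "absolute", np.array([12.0, 12.0, 4.0]), 400)
        out, model = gc_correction(prof, grid, min_bin_windows=1)
        assert model.rd40 == pytest.approx(12.0)
        assert out.depths[2] == pytest.approx(6.0)

    def test_reference_bin_windows_are_fixed_points(self):
        grid = grid_with_gc([0.40, 0.40, 0.55, 0.55])
        prof = SampleDepthProfile("s", "absolute", np.array([9.0, 11.0, 20.0, 22.0]), 400)
        out, _ = gc_correction(prof, grid, min_bin_windows=1)
        np.testing.assert_allclose(out.depths[:2], prof.depths[:2])

    def test_equal_bin_mean_is_identity(self):
        grid = grid_with_gc([0.40, 0.40, 0.50, 0.50])
        prof = SampleDepthProfile("s", "absolute", np.array([10.0, 14.0, 14.0, 10.0]), 400)
        out, _ = gc_correction(prof, grid, min_bin_windows=1)
        np.testing.assert_allclose(out.depths, prof.depths)

    def test_planted_bias_removed(self):
        """Multiplicative GC-bias curve flattens to within 2% across bins."""
        from cnvpop.simulate import simulate_counts, simulate_population, simulate_reference

        truth = simulate_reference(2_000_000, seed=11)
        grid = build_window_grid(truth.sequences, 400)
        geno = simulate_population(truth, 1, seed=12)
        bias = lambda gc: 0.6 + 1.2 * np.abs(gc - 0.3)  # smooth, monotone over observed GC
        prof = list(simulate_counts(truth, geno, grid, gc_bias=bias, seed=13).values())[0]
        prof = replace(prof, stage="absolute")
        out, model = gc_correction(prof, grid)
        bins = np.clip(np.floor(grid.gc * 100 + 0.5).astype(int), 0, 100)
        means = []
        for b in np.unique(bins):
            sel = bins == b
            if sel.sum() >= 200:
                means.append(out.depths[sel].mean())
        means = np.array(means)
        assert means.max() / means.min() < 1.02

    def test_unpopulated_reference_errors(self):
        grid = grid_with_gc([0.50, 0.50])
        prof = SampleDepthProfile("s", "absolute", np.array([1.0, 1.0]), 400)
        with pytest.raises(ValueError, match="min_bin_windows"):
            gc_correction(prof, grid, min_bin_windows=100)


def two_chrom_grid(n_auto=11, n_sex=7, sex_name="chrX", window_size=400):
    step = window_size // 2
    chroms = ["chr1", sex_name]
    lengths = {
        "chr1": (n_auto - 1) * step + window_size,
        sex_name: (n_sex - 1) * step + window_size,
    }
    n = n_auto + n_sex
    return WindowGrid(
        window_size=window_size,
        step=step,
        chroms=chroms,
        chrom_lengths=lengths,
        index=np.arange(n, dtype=np.int64),
        chrom_id=np.array([0] * n_auto + [1] * n_sex, dtype=np.int32),
        start=np.concatenate(
            [np.arange(n_auto, dtype=np.int64) * step, np.arange(n_sex, dtype=np.int64) * step]
        ),
        gc=np.full(n, 0.5),
        gap=np.zeros(n),
    )


class TestSexCorrection:
    def profile(self, auto_depth, sex_depth, grid):
        d = np.concatenate([np.full(11, auto_depth), np.full(7, sex_depth)])
        return SampleDepthProfile("s", "gc_corrected", d, grid.window_size)

    def test_heterogametic_doubled(self):
        grid = two_chrom_grid()
        out = sex_correction(self.profile(10.0, 5.0, grid), grid, "chrX")
        assert out.inferred_sex == "heterogametic"
        assert np.all(out.depths[11:] == 10.0)

    def test_homogametic_unchanged(self):
        grid = two_chrom_grid()
        out = sex_correction(self.profile(10.0, 10.0, grid), grid, "chrX")
        assert out.inferred_sex == "homogametic"
        assert np.all(out.depths[11:] == 10.0)

    def test_exact_ratio_boundary_is_homogametic(self):
        grid = two_chrom_grid()
        out = sex_correction(self.profile(10.0, 6.0, grid), grid, "chrX")
        assert out.inferred_sex == "homogametic"
        assert np.all(out.depths[11:] == 6.0)

    def test_unknown_sex_chrom_lists_available(self):
        grid = two_chrom_grid()
        with pytest.raises(ValueError, match="chr1"):
            sex_correction(self.profile(10, 5, grid), grid, "chrW")

    def test_unplaced_scaffolds_never_corrected(self):
        grid = two_chrom_grid(sex_name="chrX")
        grid = replace(grid, chroms=["scaffold_9", "chrX"], chrom_lengths={
            "scaffold_9": grid.chrom_lengths["chr1"], "chrX": grid.chrom_lengths["chrX"]
        }, _row_of=None)
        # only unplaced + sex chrom: no placed autosome -> sex stays unknown
        out = sex_correction(self.profile(10.0, 5.0, grid), grid, "chrX")
        assert out.inferred_sex == "unknown"
        assert np.all(out.depths == self.profile(10.0, 5.0, grid).depths)


class TestNormalize:
    def test_median_division(self):
        prof = SampleDepthProfile("s", "gc_corrected", np.array([8.0, 16.0, 4.0]), 400)
        out = normalize(prof)
        assert out.stage == "normalized"
        np.testing.assert_allclose(out.depths, [1.0, 2.0, 0.5])

    def test_constant_vector_maps_to_ones(self):
        prof = SampleDepthProfile("s", "gc_corrected", np.full(5, 3.3), 400)
        np.testing.assert_allclose(normalize(prof).depths, 1.0)

    def test_zero_median_rejected(self):
        prof = SampleDepthProfile("s", "gc_corrected", np.zeros(5), 400)
        with pytest.raises(ValueError, match="median"):
            normalize(prof)

    def test_median_is_one_after_normalization(self, rng):
        prof = SampleDepthProfile(
            "s", "gc_corrected", rng.poisson(160, 1001).astype(float), 400
        )
        out = normalize(prof)
        assert abs(np.median(out.depths) - 1.0) < 1e-6

    def test_diploid_sample_concentrates_near_one(self):
        """x20 coverage: >95% of windows within 25% of the diploid level."""
        from cnvpop.simulate import simulate_counts, simulate_population, simulate_reference
        from cnvpop.pipeline import correct_profile

        truth = simulate_reference(1_000_000, seed=21)
        grid = build_window_grid(truth.sequences, 800)
        geno = simulate_population(truth, 1, seed=22)
        raw = list(simulate_counts(truth, geno, grid, coverage=20, seed=23).values())[0]
        out = correct_profile(raw, grid)
        frac = np.mean((out.depths > 0.75) & (out.depths < 1.25))
        assert frac > 0.95


class TestProfileIO:
    def test_round_trip_bitwise(self, tmp_path, rng):
        grid = make_grid(20)
        prof = SampleDepthProfile(
            "sampleA", "normalized", rng.random(20), 400, inferred_sex="heterogametic"
        )
        path = tmp_path / "p.tsv"
        write_profile(prof, path, grid)
        back = read_profile(path, grid)
        assert back.sample_id == "sampleA"
        assert back.stage == "normalized"
        assert back.inferred_sex == "heterogametic"
        assert np.array_equal(back.depths, prof.depths)

    def test_window_size_mismatch_refused(self, tmp_path, rng):
        grid = make_grid(20)
        prof = SampleDepthProfile("s", "normalized", rng.random(20), 400)
        path = tmp_path / "p.tsv"
        write_profile(prof, path, grid)
        other = make_grid(20, window_size=800)
        with pytest.raises(ValueError, match="mismatch"):
            read_profile(path, other)


def test_stage_order_is_enforced():
    grid = make_grid(4)
    raw = SampleDepthProfile("s", "raw", np.ones(4), 400)
    with pytest.raises(ValueError):
        gc_correction(raw, grid, min_bin_windows=1)
    with pytest.raises(ValueError):
        sex_correction(raw, grid, "chr1")
    with pytest.raises(ValueError):
        normalize(raw)
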