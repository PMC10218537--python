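import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import spearmanr

from rbliquid.bins import (BinnedCounts, compute_log_ratio, count_reads_in_bins,
                           extract_off_target_reads, gc_normalize, read_counts_tsv,
                           read_probe_bed, read_ratio_tsv, write_counts_tsv,
                           write_ratio_tsv)
from rbliquid.genome import ChromSpec, make_bin_grid
from rbliquid.simulate import SampleSimConfig, TruthProfile, gc_bias_curve, \
    simulate_sample_counts


def _reads(chrom, positions):
    return pd.DataFrame({"chrom": chrom, "pos": positions})


class TestOffTarget:
    def test_read_inside_probe_removed_and_outside_kept(self):
        probes = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})
        reads = _reads("chr1", [150, 250])
        kept = extract_off_target_reads(reads, probes, pad=0)
        assert kept["pos"].tolist() == [250]

    def test_empty_probe_set_keeps_everything(self):
        reads = _reads("chr1", [1, 2, 3])
        kept = extract_off_target_reads(
            reads, pd.DataFrame(columns=["chrom", "start", "end"]), pad=0)
        assert len(kept) == len(reads)

    def test_uniform_reads_against_brute_force_membership(self):
        rng = np.random.default_rng(0)
        pos = rng.integers(0, 100_000, size=1_000)
        reads = _reads("chr1", pos)
        # probes covering 10% of the chromosome
        probes = pd.DataFrame({
            "chrom": "chr1",
            "start": np.arange(0, 100_000, 10_000),
            "end": np.arange(0, 100_000, 10_000) + 1_000,
        })
        kept = extract_off_target_reads(reads, probes, pad=0)
        # independent oracle: per-read scan over every interval
        outside = [
            p for p in pos
            if not any(s <= p < e for s, e in zip(probes["start"], probes["end"]))
        ]
        assert sorted(kept["pos"]) == sorted(outside)
        assert len(kept) == pytest.approx(900, abs=40)

    @given(pad1=st.integers(0, 500), pad2=st.integers(0, 500))
    def test_padding_is_monotone(self, pad1, pad2):
        lo, hi = sorted([pad1, pad2])
        reads = _reads("chr1", list(range(0, 5_000, 37)))
        probes = pd.DataFrame({"chrom": ["chr1"] * 2, "start": [500, 3_000],
                               "end": [700, 3_100]})
        n_lo = len(extract_off_target_reads(reads, probes, pad=lo))
        n_hi = len(extract_off_target_reads(reads, probes, pad=hi))
        assert n_hi <= n_lo

    def test_malformed_probe_interval_rejected(self):
        probes = pd.DataFrame({"chrom": ["chr1"], "start": [200], "end": [100]})
        with pytest.raises(ValueError, match="end <= start"):
            extract_off_target_reads(_reads("chr1", [1]), probes)

    def test_bed_reader_flags_offending_line(self, tmp_path):
        bed = tmp_path / "probes.bed"
        bed.write_text("chr1\t10\t20\nchr1\t50\t40\n")
        with pytest.raises(ValueError, match="line 2"):
            read_probe_bed(bed)
        bed.write_text("chr1\t10\t20\n# comment\nchr2\t5\t9\n")
        df = read_probe_bed(bed)
        assert len(df) == 2

    def test_midpoint_uses_read_length(self):
        # read starts before the probe but its midpoint falls inside
        reads = pd.DataFrame({"chrom": ["chr1"], "pos": [90], "length": [40]})
        probes = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})
        assert len(extract_off_target_reads(reads, probes, pad=0)) == 0


class TestBinCounting:
    def test_boundary_read_goes_to_right_bin(self, tiny_grid):
        # half-open bins: a read exactly at a bin start belongs to that bin
        counts = count_reads_in_bins(_reads("chr1", [1_000]), tiny_grid)
        assert counts.counts[1] == 1
        assert counts.counts.sum() == 1

    def test_no_reads_gives_zero_counts(self, tiny_grid):
        counts = count_reads_in_bins(_reads("chr1", []), tiny_grid)
        assert counts.counts.sum() == 0

    def test_unknown_chromosome_tallied_not_dropped(self, tiny_grid):
        counts = count_reads_in_bins(_reads("chrZ", [5]), tiny_grid)
        assert counts.skipped_reads == 1
        assert counts.counts.sum() == 0

    def test_uniform_reads_spread_within_binomial_bound(self, single_chrom_grid):
        grid = single_chrom_grid(10)
        rng = np.random.default_rng(1)
        reads = _reads("chr1", rng.integers(0, 10_000, size=10_000))
        counts = count_reads_in_bins(reads, grid)
        sigma = np.sqrt(10_000 * 0.1 * 0.9)
        assert np.all(np.abs(counts.counts - 1_000) < 4 * sigma)
        assert counts.counts.sum() == 10_000

    def test_agrees_with_naive_membership_scan(self, tiny_grid):
        rng = np.random.default_rng(2)
        chroms = rng.choice(["chr1", "chr2"], size=200)
        pos = rng.integers(0, 10_000, size=200)
        reads = pd.DataFrame({"chrom": chroms, "pos": pos})
        counts = count_reads_in_bins(reads, tiny_grid)
        naive = np.zeros(tiny_grid.n_bins, dtype=int)
        for c, p in zip(chroms, pos):  # O(reads x bins) oracle
            for k in range(tiny_grid.n_bins):
                if (tiny_grid.chrom_col[k] == c
                        and tiny_grid.starts[k] <= p < tiny_grid.ends[k]):
                    naive[k] += 1
        assert np.array_equal(counts.counts, naive)


def _biased_counts(grid, coeffs, base=100.0):
    bias = gc_bias_curve(grid.gc, coeffs)
    return BinnedCounts("s", grid, np.round(base * bias).astype(int))


class TestGcNormalize:
    @pytest.fixture
    def big_grid(self):
        return make_bin_grid([ChromSpec("chr1", 5_000_000, 2_500_000)], 1_000,
                             gc_seed=4)

    def test_gc_independent_counts_preserved_up_to_median(self, big_grid):
        counts = BinnedCounts("s", big_grid, np.full(big_grid.n_bins, 80))
        out = gc_normalize(counts)
        ok = ~np.isnan(out)
        assert ok.mean() > 0.95
        assert np.allclose(out[ok], 80.0, rtol=0.02)

    def test_exact_quadratic_bias_flattened(self, big_grid):
        counts = _biased_counts(big_grid, (0.2, 3.0, -2.8), base=100.0)
        out = gc_normalize(counts)
        ok = ~np.isnan(out)
        assert np.nanmedian(out) == pytest.approx(np.median(counts.counts), rel=0.02)
        assert np.std(out[ok]) / np.mean(out[ok]) < 0.05  # flat within fit tolerance

    def test_injected_bias_decorrelated_from_gc(self, big_grid):
        # monotone-increasing bias over the sampled GC range
        cfg = SampleSimConfig(0.0, mean_reads_per_bin=200,
                              gc_bias_coefficients=(0.1, 2.0, 0.0), seed=5)
        counts = simulate_sample_counts(big_grid, TruthProfile([]), cfg)
        raw_rho = spearmanr(counts.counts, big_grid.gc).statistic
        out = gc_normalize(counts)
        ok = ~np.isnan(out)
        rho = spearmanr(out[ok], big_grid.gc[ok]).statistic
        assert abs(raw_rho) > 0.5  # the bias was really there
        assert abs(rho) < 0.1

    def test_idempotent_within_tolerance(self, big_grid):
        cfg = SampleSimConfig(0.0, mean_reads_per_bin=200,
                              gc_bias_coefficients=(0.5, 1.5, -1.2), seed=6)
        counts = simulate_sample_counts(big_grid, TruthProfile([]), cfg)
        once = gc_normalize(counts)
        ok = ~np.isnan(once)
        twice = gc_normalize(
            BinnedCounts("s", big_grid, np.where(ok, np.round(once), 0).astype(int)))
        both = ok & ~np.isnan(twice)
        rel = np.abs(twice[both] - once[both]) / np.median(once[both])
        assert np.median(rel) < 0.02
        assert np.quantile(rel, 0.95) < 0.10

    def test_refuses_tiny_grids_and_dead_signal(self, tiny_grid):
        with pytest.raises(ValueError, match="fewer than"):
            gc_normalize(BinnedCounts("s", tiny_grid, np.ones(tiny_grid.n_bins, int)))
        grid = make_bin_grid([ChromSpec("chr1", 100_000, 50_000)], 1_000)
        with pytest.raises(ValueError, match="no signal"):
            gc_normalize(BinnedCounts("s", grid, np.zeros(grid.n_bins, int)))


class TestLogRatio:
    def test_identical_profiles_give_zero(self, single_chrom_grid):
        grid = single_chrom_grid(100)
        vals = np.full(grid.n_bins, 55.0)
        profile = compute_log_ratio(vals, vals, grid)
        assert np.allclose(profile.log2, 0.0)

    def test_doubled_chromosome_is_plus_one(self):
        chroms = [ChromSpec(f"chr{i}", 100_000, 50_000) for i in range(1, 5)]
        grid = make_bin_grid(chroms, 1_000)
        control = np.full(grid.n_bins, 50.0)
        sample = control.copy()
        sample[grid.chrom_slice("chr4")] *= 2
        profile = compute_log_ratio(sample, control, grid)
        assert np.allclose(profile.log2[grid.chrom_slice("chr4")], 1.0)
        assert np.allclose(profile.log2[grid.chrom_slice("chr1")], 0.0)

    def test_zero_control_bins_masked_with_reason(self, single_chrom_grid):
        grid = single_chrom_grid(100)
        control = np.full(grid.n_bins, 40.0)
        control[3] = 0.0
        profile = compute_log_ratio(np.full(grid.n_bins, 40.0), control, grid)
        assert np.isnan(profile.log2[3])
        assert profile.mask_reason[3] == "zero_control"

    def test_grid_mismatch_rejected(self, single_chrom_grid):
        grid = single_chrom_grid(10)
        with pytest.raises(ValueError):
            compute_log_ratio(np.ones(5), np.ones(5), grid)

    def test_synthetic_single_copy_loss_recovers_minus_one(self):
        from rbliquid.simulate import TruthSegment
        grid = make_bin_grid([ChromSpec("chr1", 4_000_000, 2_000_000),
                              ChromSpec("chr2", 4_000_000, 2_000_000)], 10_000,
                             gc_seed=6)
        truth = TruthProfile([TruthSegment("chr1", 0, 2_000_000, 1.0)])
        cfg = SampleSimConfig(1.0, mean_reads_per_bin=500, dispersion=np.inf, seed=9)
        sample = simulate_sample_counts(grid, truth, cfg)
        ctrl = simulate_sample_counts(grid, TruthProfile([]),
                                      SampleSimConfig(0.0, 500, seed=10,
                                                      dispersion=np.inf))
        profile = compute_log_ratio(gc_normalize(sample), gc_normalize(ctrl), grid)
        lost = (grid.chrom_col == "chr1") & (grid.ends <= 2_000_000)
        seg_mean = np.nanmean(profile.log2[lost])
        assert seg_mean == pytest.approx(-1.0, abs=0.1)


class TestTsvRoundTrip:
    def test_counts_round_trip(self, tiny_grid, tmp_path):
        counts = BinnedCounts("s", tiny_grid,
                              np.arange(tiny_grid.n_bins, dtype=np.int64))
        path = tmp_path / "counts.tsv"
        write_counts_tsv(counts, path)
        back = read_counts_tsv(path, tiny_grid)
        assert np.array_equal(back.counts, counts.counts)

    def test_ratio_round_trip_preserves_masks(self, single_chrom_grid, tmp_path):
        grid = single_chrom_grid(60)
        log2 = np.zeros(grid.n_bins)
        log2[5] = np.nan
        reason = np.full(grid.n_bins, None, dtype=object)
        reason[5] = "zero_control"
        from rbliquid.bins import CopyRatioProfile
        profile = CopyRatioProfile(grid=grid, log2=log2, mask_reason=reason)
        path = tmp_path / "ratio.tsv"
        write_ratio_tsv(profile, path)
        back = read_ratio_tsv(path, grid)
        assert np.isnan(back.log2[5])
        assert back.mask_reason[5] == "zero_control"
        assert np.allclose(back.log2[~np.isnan(back.log2)], 0.0)
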