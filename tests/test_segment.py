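import numpy as np
import pandas as pd
import pytest

from rbliquid.segment import (cbs_segment, profile_from_segments, prune_segments,
                              read_seg_file, segments_to_seg_file, _max_t_scan)
from helpers import segmented_from_values


def brute_force_best_arc(x: np.ndarray, min_width: int):
    """Independent oracle: explicit two-sample t over every admissible arc."""
    n = len(x)
    best = (-np.inf, -1, -1)
    for i in range(0, n - min_width + 1):
        for j in range(i + min_width, n + 1):
            left, mid, right = i, j - i, n - j
            if mid < min_width or (n - mid) < min_width:
                continue
            if (left and left < min_width) or (right and right < min_width):
                continue
            arc = x[i:j]
            rest = np.concatenate([x[:i], x[j:]])
            m1, m2 = arc.mean(), rest.mean()
            ss = ((arc - m1) ** 2).sum() + ((rest - m2) ** 2).sum()
            var = ss / (n - 2) * (1 / len(arc) + 1 / len(rest))
            if var <= 0:
                t = np.inf if m1 != m2 else 0.0
            else:
                t = abs(m1 - m2) / np.sqrt(var)
            if t > best[0]:
                best = (t, i, j)
    return best


class TestMaxTScan:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 40)
        if seed % 2:
            x[15:30] += 1.5
        t, i, j = _max_t_scan(x, min_width=3)
        t_o, i_o, j_o = brute_force_best_arc(x, min_width=3)
        n = len(x)
        assert {b for b in (i, j) if 0 < b < n} == \
               {b for b in (i_o, j_o) if 0 < b < n}
        assert t == pytest.approx(t_o)

    def test_constant_input_finds_nothing(self):
        t, i, j = _max_t_scan(np.full(30, 1.5), min_width=3)
        assert (i, j) == (-1, -1)


class TestCbs:
    def test_constant_profile_one_segment_per_chromosome(self, tiny_grid):
        seg = segmented_from_values(tiny_grid, np.zeros(tiny_grid.n_bins))
        assert len(seg.segments) == 2
        assert set(seg.segments["chrom"]) == {"chr1", "chr2"}

    def test_noise_free_step_recovered_exactly(self, single_chrom_grid):
        grid = single_chrom_grid(100)
        x = np.concatenate([np.zeros(50), np.ones(50)])
        seg = segmented_from_values(grid, x)
        assert len(seg.segments) == 2
        assert seg.segments.iloc[0]["end"] == 50 * 1_000
        assert seg.segments["mean"].tolist() == [0.0, 1.0]

    def test_noisy_step_boundary_within_two_bins(self, single_chrom_grid):
        grid = single_chrom_grid(200)
        rng = np.random.default_rng(42)
        x = np.where(np.arange(200) < 120, 0.0, 1.0) + rng.normal(0, 0.2, 200)
        seg = segmented_from_values(grid, x, n_perm=500, alpha=0.01)
        boundaries = (seg.segments["start"].to_numpy() // 1_000)[1:]
        assert np.any(np.abs(boundaries - 120) <= 2)

    def test_masked_bins_excluded_from_segments(self, single_chrom_grid):
        grid = single_chrom_grid(60)
        x = np.zeros(60)
        x[10:14] = np.nan
        seg = segmented_from_values(grid, x)
        assert int(seg.segments["n_bins"].sum()) == 56
        assert np.isnan(seg.seg_mean[11])

    def test_conservation_of_chromosome_mean(self, single_chrom_grid):
        grid = single_chrom_grid(120)
        rng = np.random.default_rng(5)
        x = rng.normal(0, 0.3, 120)
        x[40:] += 1.2
        seg = segmented_from_values(grid, x)
        weighted = np.sum(seg.segments["mean"] * seg.segments["n_bins"])
        assert weighted / 120 == pytest.approx(x.mean())

    def test_splits_never_cross_chromosomes(self, tiny_grid):
        # step placed across the chr1/chr2 boundary must not join chromosomes
        x = np.concatenate([np.zeros(10), np.ones(10)])
        seg = segmented_from_values(tiny_grid, x)
        for _, row in seg.segments.iterrows():
            assert row["end"] <= 10_000

    def test_invalid_alpha_rejected(self, tiny_grid):
        with pytest.raises(ValueError):
            segmented_from_values(tiny_grid, np.zeros(20), alpha=1.5)

    def test_low_permutation_count_warns(self, tiny_grid):
        with pytest.warns(UserWarning, match="n_perm"):
            segmented_from_values(tiny_grid, np.zeros(20), n_perm=50)

    def test_deterministic_given_seed(self, single_chrom_grid):
        grid = single_chrom_grid(150)
        rng = np.random.default_rng(8)
        x = rng.normal(0, 0.25, 150)
        x[60:100] += 0.9
        a = segmented_from_values(grid, x, seed=3)
        b = segmented_from_values(grid, x, seed=3)
        pd.testing.assert_frame_equal(a.segments, b.segments)


class TestPrune:
    def _two_step_profile(self, grid, delta, sd, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, sd, grid.n_bins)
        x[grid.n_bins // 2:] += delta
        return segmented_from_values(grid, x, n_perm=200)

    def test_undo_sd_zero_is_identity(self, single_chrom_grid):
        grid = single_chrom_grid(100)
        seg = self._two_step_profile(grid, 2.0, 0.2, seed=1)
        pruned = prune_segments(seg, undo_sd=0.0)
        pd.testing.assert_frame_equal(pruned.segments, seg.segments)

    def test_forced_merge_of_artificial_split(self, single_chrom_grid):
        # paint an artificial 2-segment table over near-identical data and
        # verify the 3-SD rule removes the boundary
        grid = single_chrom_grid(40)
        rng = np.random.default_rng(3)
        x = rng.normal(0, 0.2, 40)
        seg = segmented_from_values(grid, x)
        from rbliquid.segment import SegmentedProfile
        forced = pd.DataFrame({
            "chrom": ["chr1", "chr1"], "start": [0, 20_000],
            "end": [20_000, 40_000], "n_bins": [20, 20],
            "mean": [x[:20].mean(), x[20:].mean()],
        })
        seg_mean = np.where(np.arange(40) < 20, x[:20].mean(), x[20:].mean())
        forced_profile = SegmentedProfile(grid=grid, seg_mean=seg_mean,
                                          segments=forced, bin_log2=x)
        pruned = prune_segments(forced_profile, undo_sd=3.0)
        assert len(pruned.segments) == 1
        assert pruned.segments.iloc[0]["mean"] == pytest.approx(x.mean())

    @pytest.mark.parametrize("seed", range(4))
    def test_pruning_never_increases_segment_count(self, single_chrom_grid, seed):
        grid = single_chrom_grid(120)
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 0.3, 120) + np.repeat(rng.normal(0, 0.6, 6), 20)
        seg = segmented_from_values(grid, x, n_perm=200)
        pruned = prune_segments(seg, undo_sd=3.0)
        assert len(pruned.segments) <= len(seg.segments)


class TestSegIo:
    def test_round_trip(self, single_chrom_grid):
        grid = single_chrom_grid(60)
        x = np.concatenate([np.zeros(20), np.full(20, 1.37), np.full(20, -0.52)])
        seg = segmented_from_values(grid, x)
        text = segments_to_seg_file(seg, sample_id="caseA")
        back = read_seg_file(text)
        assert back.attrs["sample_id"] == "caseA"
        pd.testing.assert_frame_equal(
            back, seg.segments.astype({"start": int, "end": int}), check_dtype=False)

    def test_empty_profile_writes_header_only(self, single_chrom_grid):
        grid = single_chrom_grid(10)
        from rbliquid.segment import SegmentedProfile
        empty = SegmentedProfile(
            grid=grid, seg_mean=np.full(10, np.nan),
            segments=pd.DataFrame(columns=["chrom", "start", "end", "n_bins", "mean"]))
        text = segments_to_seg_file(empty)
        assert text.strip() == "ID\tchrom\tloc.start\tloc.end\tnum.mark\tseg.mean"

    def test_three_segment_fixture_has_three_rows(self, single_chrom_grid):
        grid = single_chrom_grid(60)
        x = np.concatenate([np.zeros(20), np.ones(20), np.zeros(20)])
        seg = segmented_from_values(grid, x)
        text = segments_to_seg_file(seg)
        assert len(text.strip().splitlines()) == 1 + 3

    def test_profile_from_segments_paints_means(self, single_chrom_grid):
        grid = single_chrom_grid(10)
        table = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [0, 4_000],
                              "end": [4_000, 10_000], "n_bins": [4, 6],
                              "mean": [0.5, -0.5]})
        painted = profile_from_segments(grid, table)
        assert np.allclose(painted.seg_mean[:4], 0.5)
        assert np.allclose(painted.seg_mean[4:], -0.5)


class TestTypeIControl:
    def test_pure_noise_rarely_split(self, single_chrom_grid):
        # permutation validity: at alpha=0.05 about 5% of noise-only
        # chromosomes may split; allow Monte-Carlo slack over 60 seeds
        grid = single_chrom_grid(80)
        splits = 0
        for seed in range(60):
            rng = np.random.default_rng(1_000 + seed)
            seg = segmented_from_values(grid, rng.normal(0, 1, 80),
                                        alpha=0.05, n_perm=400, seed=seed)
            splits += len(seg.segments) > 1
        assert splits / 60 <= 0.12
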