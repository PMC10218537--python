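"""Circular binary segmentation (CBS) of per-bin copy-ratio profiles.

CBS recursively looks for the arc of the (circularized) chromosome whose
mean most differs from its complement, measured by the two-sample
t-statistic maximized over all arc endpoints (i, j).  Significance of the
best arc is assessed by permuting the bin ratios within the chromosome;
significant arcs split the chromosome and the pieces are re-examined.  The
result is a piecewise-constant segment-mean profile — the object the
concordance statistic and the gain/loss callers consume.

The permutation test uses curtailed sampling: permutations stop as soon as
the exceedance count already guarantees p >= alpha.  The accept/reject
decision is identical to running every permutation.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bins import CopyRatioProfile
from .genome import GenomeBins

__all__ = [
    "SegmentedProfile",
    "cbs_segment",
    "prune_segments",
    "segments_to_seg_file",
    "read_seg_file",
    "profile_from_segments",
]

SEG_COLUMNS = ["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]


@dataclass
class SegmentedProfile:
    """Piecewise-constant segmentation of a copy-ratio profile.

    ``seg_mean`` carries each unmasked bin's segment mean (NaN where the
    underlying bin was masked); ``segments`` is the per-segment table.
    ``bin_log2`` retains the raw per-bin ratios so pruning can estimate
    within-segment noise.
    """

    grid: GenomeBins
    seg_mean: np.ndarray
    segments: pd.DataFrame
    bin_log2: np.ndarray | None = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.seg_mean = np.asarray(self.seg_mean, dtype=float)
        if self.seg_mean.shape != (self.grid.n_bins,):
            raise ValueError("seg_mean length does not match grid")

    @property
    def unmasked(self) -> np.ndarray:
        return ~np.isnan(self.seg_mean)


# ---------------------------------------------------------------------------
# max-t arc scan
# ---------------------------------------------------------------------------

def _arc_valid_mask(n: int, length: int, min_width: int) -> np.ndarray:
    """Which arc start positions i (arc = [i, i+length)) are admissible.

    Every resulting piece — the arc and each nonempty flank — must hold at
    least ``min_width`` bins, so segments never fall below the width floor.
    """
    i = np.arange(n - length + 1)
    left_ok = (i == 0) | (i >= min_width)
    right = n - (i + length)
    right_ok = (right == 0) | (right >= min_width)
    return left_ok & right_ok


def _t2_for_length(S: np.ndarray, Q: np.ndarray, n: int, length: int) -> np.ndarray:
    """Squared two-sample t for every arc of ``length`` (rows = sequences)."""
    L2 = n - length
    s1 = S[..., length:] - S[..., : n - length + 1]
    q1 = Q[..., length:] - Q[..., : n - length + 1]
    total, qtotal = S[..., -1:], Q[..., -1:]
    m1 = s1 / length
    m2 = (total - s1) / L2
    ss = (q1 - length * m1**2) + ((qtotal - q1) - L2 * m2**2)
    var = ss / max(n - 2, 1) * (1.0 / length + 1.0 / L2)
    diff2 = (m1 - m2) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = diff2 / var
    # zero pooled variance: infinite t if the means differ, 0 if identical
    t2 = np.where(var <= 0, np.where(diff2 > 0, np.inf, 0.0), t2)
    return t2


def _max_t_scan(x: np.ndarray, min_width: int) -> tuple[float, int, int]:
    """Best arc (i, j) by |t|; ties broken by smallest i, then smallest j."""
    n = len(x)
    S = np.concatenate([[0.0], np.cumsum(x)])
    Q = np.concatenate([[0.0], np.cumsum(x * x)])
    best_t2, best_i, best_j = -np.inf, -1, -1
    for length in range(min_width, n - min_width + 1):
        t2 = _t2_for_length(S, Q, n, length)
        t2 = np.where(_arc_valid_mask(n, length, min_width), t2, -np.inf)
        k = int(np.argmax(t2))
        v = float(t2[k])
        if v > best_t2 or (v == best_t2 and (k < best_i or (k == best_i and k + length < best_j))):
            best_t2, best_i, best_j = v, k, k + length
    if best_i < 0 or best_t2 <= 0:
        return 0.0, -1, -1
    return float(np.sqrt(best_t2)) if np.isfinite(best_t2) else np.inf, best_i, best_j


def _perm_max_t2(X: np.ndarray, min_width: int) -> np.ndarray:
    """Max squared t over admissible arcs, for each row of ``X``."""
    n = X.shape[-1]
    zeros = np.zeros(X.shape[:-1] + (1,))
    S = np.concatenate([zeros, np.cumsum(X, axis=-1)], axis=-1)
    Q = np.concatenate([zeros, np.cumsum(X * X, axis=-1)], axis=-1)
    best = np.full(X.shape[0], -np.inf)
    for length in range(min_width, n - min_width + 1):
        t2 = _t2_for_length(S, Q, n, length)
        t2 = np.where(_arc_valid_mask(n, length, min_width), t2, -np.inf)
        np.maximum(best, t2.max(axis=-1), out=best)
    return best


def _split_significant(
    x: np.ndarray,
    t_obs: float,
    rng: np.random.Generator,
    alpha: float,
    n_perm: int,
    min_width: int,
    chunk: int = 100,
) -> bool:
    """Permutation p-value < alpha for the observed max |t|?

    Curtailed: once exceedances reach the count that forces p >= alpha the
    remaining permutations cannot change the decision and are skipped.
    """
    t2_obs = t_obs**2 if np.isfinite(t_obs) else np.inf
    # p = (1 + c) / (1 + n_perm) >= alpha  <=>  c >= alpha*(1+n_perm) - 1
    stop_count = int(np.ceil(alpha * (1 + n_perm) - 1))
    exceed = 0
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perms = np.array([rng.permutation(x) for _ in range(m)])
        exceed += int(np.sum(_perm_max_t2(perms, min_width) >= t2_obs))
        done += m
        if exceed >= stop_count:
            return False
    return (1 + exceed) / (1 + n_perm) < alpha


# ---------------------------------------------------------------------------
# recursive segmentation
# ---------------------------------------------------------------------------

def _segment_chromosome(
    x: np.ndarray,
    rng: np.random.Generator,
    alpha: float,
    n_perm: int,
    min_width: int,
) -> list[tuple[int, int]]:
    """Segment one chromosome's unmasked ratio vector; returns index ranges."""
    out: list[tuple[int, int]] = []

    def recurse(lo: int, hi: int) -> None:
        n = hi - lo
        if n < 2 * min_width:
            out.append((lo, hi))
            return
        t_obs, i, j = _max_t_scan(x[lo:hi], min_width)
        if i < 0 or t_obs <= 0 or not _split_significant(
            x[lo:hi], t_obs, rng, alpha, n_perm, min_width
        ):
            out.append((lo, hi))
            return
        cuts = [lo + i for i in (i, j) if 0 < i < n]
        bounds = [lo, *sorted(set(cuts)), hi]
        for a, b in zip(bounds, bounds[1:]):
            recurse(a, b)

    recurse(0, len(x))
    return sorted(out)


def cbs_segment(
    profile: CopyRatioProfile,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_width: int = 3,
    seed: int = 0,
) -> SegmentedProfile:
    """Segment each chromosome of a copy-ratio profile independently.

    Parameters follow common DNAcopy-style practice: permutation
    significance ``alpha`` (default 0.01), ``n_perm`` permutations (1000),
    and a minimum segment width of 3 bins.  One seeded generator stream per
    chromosome keeps results reproducible regardless of evaluation order.
    Splits never cross chromosome boundaries.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives a coarse permutation p-value", stacklevel=2)
    grid = profile.grid
    seg_mean = np.full(grid.n_bins, np.nan)
    rows = []
    for ci, chrom in enumerate(grid.chrom_names):
        sl = grid.chrom_slice(chrom)
        local = np.arange(sl.start, sl.stop)
        ok = profile.unmasked[sl]
        idx = local[ok]
        if idx.size == 0:
            continue
        x = profile.log2[idx]
        rng = np.random.default_rng([seed, ci])
        if idx.size < 2 * min_width:
            ranges = [(0, idx.size)]
        else:
            ranges = _segment_chromosome(x, rng, alpha, n_perm, min_width)
        for lo, hi in ranges:
            bins_here = idx[lo:hi]
            mean = float(np.mean(x[lo:hi]))
            seg_mean[bins_here] = mean
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(grid.starts[bins_here[0]]),
                    "end": int(grid.ends[bins_here[-1]]),
                    "n_bins": int(hi - lo),
                    "mean": mean,
                }
            )
    segments = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_bins", "mean"])
    return SegmentedProfile(
        grid=grid, seg_mean=seg_mean, segments=segments,
        bin_log2=profile.log2.copy(), sample_id=profile.sample_id,
    )


def prune_segments(seg: SegmentedProfile, undo_sd: float = 3.0) -> SegmentedProfile:
    """Merge adjacent segments that differ by less than ``undo_sd`` noise SDs.

    The noise scale is the pooled within-segment SD of the two candidate
    segments' raw bin ratios, estimated robustly from adjacent-bin first
    differences (MAD-based).  The robust estimator keeps the scale anchored
    to bin-level noise even when an earlier merge left a step inside a
    segment — a moment-based SD would inflate there and let low-amplitude
    merges cascade into swallowing genuine high-amplitude focal events.
    Merging repeats to a fixpoint; ``undo_sd=0`` is the identity.
    """
    if undo_sd < 0:
        raise ValueError("undo_sd must be non-negative")
    if seg.bin_log2 is None:
        raise ValueError("pruning needs the raw per-bin ratios (bin_log2)")

    grid = seg.grid
    # reconstruct per-segment bin index lists
    segs: list[dict] = []
    for _, row in seg.segments.iterrows():
        sl = grid.chrom_slice(row["chrom"])
        idx = np.arange(sl.start, sl.stop)
        sel = (
            (grid.starts[idx] >= row["start"])
            & (grid.ends[idx] <= row["end"])
            & ~np.isnan(seg.seg_mean[idx])
        )
        segs.append({"chrom": row["chrom"], "bins": idx[sel]})

    def pooled_noise_sd(bins_a: np.ndarray, bins_b: np.ndarray) -> float:
        # MAD of within-segment adjacent-bin differences; d = x[i+1] - x[i]
        # has SD sqrt(2) x bin noise, and MAD/0.6745 estimates that SD
        diffs = np.concatenate([np.diff(seg.bin_log2[b]) for b in (bins_a, bins_b)])
        if diffs.size == 0:
            return 0.0
        return float(np.median(np.abs(diffs)) / (0.6745 * np.sqrt(2.0)))

    changed = True
    while changed:
        changed = False
        for k in range(len(segs) - 1):
            a, b = segs[k], segs[k + 1]
            if a["chrom"] != b["chrom"]:
                continue
            m1 = float(seg.bin_log2[a["bins"]].mean())
            m2 = float(seg.bin_log2[b["bins"]].mean())
            pooled = pooled_noise_sd(a["bins"], b["bins"])
            if abs(m1 - m2) < undo_sd * pooled:
                segs[k] = {"chrom": a["chrom"], "bins": np.concatenate([a["bins"], b["bins"]])}
                del segs[k + 1]
                changed = True
                break

    seg_mean = np.full(grid.n_bins, np.nan)
    rows = []
    for s in segs:
        bins = s["bins"]
        mean = float(seg.bin_log2[bins].mean())
        seg_mean[bins] = mean
        rows.append(
            {
                "chrom": s["chrom"],
                "start": int(grid.starts[bins[0]]),
                "end": int(grid.ends[bins[-1]]),
                "n_bins": len(bins),
                "mean": mean,
            }
        )
    return SegmentedProfile(
        grid=grid, seg_mean=seg_mean,
        segments=pd.DataFrame(rows, columns=["chrom", "start", "end", "n_bins", "mean"]),
        bin_log2=seg.bin_log2, sample_id=seg.sample_id,
    )


# ---------------------------------------------------------------------------
# SEG (IGV dialect) I/O
# ---------------------------------------------------------------------------

def segments_to_seg_file(seg: SegmentedProfile, sample_id: str | None = None) -> str:
    """IGV-style SEG text; coordinates 1-based inclusive."""
    sid = sample_id if sample_id is not None else (seg.sample_id or "sample")
    lines = ["\t".join(SEG_COLUMNS)]
    for _, row in seg.segments.iterrows():
        lines.append(
            "\t".join(
                [
                    sid, str(row["chrom"]), str(int(row["start"]) + 1),
                    str(int(row["end"])), str(int(row["n_bins"])), repr(float(row["mean"])),
                ]
            )
        )
    return "\n".join(lines) + "\n"


def read_seg_file(source: str | Path) -> pd.DataFrame:
    """Parse SEG text (or a path to it) back to the internal segment table."""
    text = Path(source).read_text() if isinstance(source, Path) else str(source)
    if "\n" not in text and Path(text).exists():
        text = Path(text).read_text()
    df = pd.read_csv(io.StringIO(text), sep="\t")
    if list(df.columns) != SEG_COLUMNS:
        raise ValueError(f"unexpected SEG columns: {list(df.columns)}")
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].astype(str),
            "start": df["loc.start"].astype(int) - 1,
            "end": df["loc.end"].astype(int),
            "n_bins": df["num.mark"].astype(int),
            "mean": df["seg.mean"].astype(float),
        }
    )
    out.attrs["sample_id"] = str(df["ID"].iloc[0]) if len(df) else ""
    return out


def profile_from_segments(grid: GenomeBins, segments: pd.DataFrame,
                          sample_id: str = "") -> SegmentedProfile:
    """Paint a segment table onto a grid (e.g. after reading a SEG file)."""
    seg_mean = np.full(grid.n_bins, np.nan)
    mids = (grid.starts + grid.ends) // 2
    for _, row in segments.iterrows():
        hit = (grid.chrom_col == row["chrom"]) & (mids >= row["start"]) & (mids < row["end"])
        seg_mean[hit] = row["mean"]
    return SegmentedProfile(grid=grid, seg_mean=seg_mean,
                            segments=segments.copy(), sample_id=sample_id)
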