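"""Binned read counting and copy-ratio profile construction.

Two entry modes mirror how cfDNA copy number is profiled in practice:

* ``targeted`` — hybrid-capture panels yield mostly on-target reads, but the
  off-target fraction is an unbiased (if sparse) sample of the genome.  Reads
  near probes are removed and the remainder counted in wide (500-kb) bins.
* ``wgs`` — low-pass whole-genome reads counted on a genome-wide grid
  (classically ~5000 bins).

Counts are GC-normalized against a smooth coverage-vs-GC curve and expressed
as log2 ratios to a copy-neutral (female gDNA) control profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genome import GenomeBins

__all__ = [
    "BinnedCounts",
    "CopyRatioProfile",
    "extract_off_target_reads",
    "count_reads_in_bins",
    "gc_normalize",
    "compute_log_ratio",
    "read_probe_bed",
    "read_positions_tsv",
    "read_counts_tsv",
    "write_counts_tsv",
    "write_ratio_tsv",
    "read_ratio_tsv",
    "DEFAULT_PROBE_PAD",
]

#: Hybrid-capture pulldown enriches probe flanks too; reads within this many
#: bp of a probe are treated as on-target.
DEFAULT_PROBE_PAD = 500


@dataclass
class BinnedCounts:
    """Raw per-bin read counts for one sample on a fixed grid."""

    sample_id: str
    grid: GenomeBins
    counts: np.ndarray
    mode: Literal["targeted", "wgs"] = "wgs"
    skipped_reads: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (self.grid.n_bins,):
            raise ValueError(
                f"counts length {self.counts.shape} != grid bins {self.grid.n_bins}"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


@dataclass
class CopyRatioProfile:
    """Per-bin log2(sample/control) with masking.

    Masked bins carry NaN in ``log2`` and a reason string in ``mask_reason``
    (``zero_control``, ``gc_out_of_support``, ``no_sample`` ...).
    """

    grid: GenomeBins
    log2: np.ndarray
    mask_reason: np.ndarray = field(default=None)  # type: ignore[assignment]
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.log2 = np.asarray(self.log2, dtype=float)
        if self.log2.shape != (self.grid.n_bins,):
            raise ValueError("log2 length does not match grid")
        if self.mask_reason is None:
            self.mask_reason = np.full(self.grid.n_bins, None, dtype=object)
        if not np.all(np.isfinite(self.log2[self.unmasked])):
            raise ValueError("unmasked bins must be finite")

    @property
    def unmasked(self) -> np.ndarray:
        return ~np.isnan(self.log2)


# ---------------------------------------------------------------------------
# read handling
# ---------------------------------------------------------------------------

def read_positions_tsv(path: str | Path) -> pd.DataFrame:
    """Aligned read positions: columns chrom, pos[, length]; tab-separated."""
    df = pd.read_csv(path, sep="\t")
    if not {"chrom", "pos"}.issubset(df.columns):
        raise ValueError("positions TSV needs columns 'chrom' and 'pos'")
    return df


def read_probe_bed(path: str | Path) -> pd.DataFrame:
    """Probe intervals from a 3+ column BED; rejects malformed lines."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"BED line {lineno} has fewer than 3 columns: {line!r}")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"BED line {lineno} has end <= start: {line!r}")
            rows.append((chrom, start, end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _read_midpoints(reads: pd.DataFrame) -> np.ndarray:
    pos = reads["pos"].to_numpy(dtype=np.int64)
    if "length" in reads.columns:
        return pos + reads["length"].to_numpy(dtype=np.int64) // 2
    return pos


def extract_off_target_reads(
    reads: pd.DataFrame, probes: pd.DataFrame, pad: int = DEFAULT_PROBE_PAD
) -> pd.DataFrame:
    """Keep reads whose midpoint is outside every probe interval padded by ``pad``.

    More padding can only remove reads, never add them (masking is monotone).
    """
    if pad < 0:
        raise ValueError("pad must be non-negative")
    if np.any(probes["end"].to_numpy() <= probes["start"].to_numpy()):
        bad = probes[probes["end"] <= probes["start"]].iloc[0]
        raise ValueError(f"malformed probe interval (end <= start): {bad.to_dict()}")
    if probes.empty:
        return reads.reset_index(drop=True)

    mids = _read_midpoints(reads)
    keep = np.ones(len(reads), dtype=bool)
    read_chroms = reads["chrom"].to_numpy()
    for chrom, sub in probes.groupby("chrom", sort=False):
        sel = read_chroms == chrom
        if not sel.any():
            continue
        # merge padded intervals so searchsorted gives unambiguous membership
        iv = sub.sort_values("start")
        starts = np.maximum(iv["start"].to_numpy() - pad, 0)
        ends = iv["end"].to_numpy() + pad
        merged_s, merged_e = [], []
        for s, e in zip(starts, ends):
            if merged_e and s <= merged_e[-1]:
                merged_e[-1] = max(merged_e[-1], e)
            else:
                merged_s.append(s)
                merged_e.append(e)
        ms = np.asarray(merged_s)
        me = np.asarray(merged_e)
        m = mids[sel]
        idx = np.searchsorted(ms, m, side="right") - 1
        inside = (idx >= 0) & (m < me[np.clip(idx, 0, len(me) - 1)])
        keep[np.flatnonzero(sel)[inside]] = False
    return reads[keep].reset_index(drop=True)


def count_reads_in_bins(
    reads: pd.DataFrame, grid: GenomeBins, sample_id: str = "sample",
    mode: Literal["targeted", "wgs"] = "targeted",
) -> BinnedCounts:
    """Assign each read to exactly one bin by midpoint (0-based half-open).

    Reads on chromosomes absent from the grid, or beyond the chromosome end,
    are tallied in ``skipped_reads`` rather than silently dropped.
    """
    counts = np.zeros(grid.n_bins, dtype=np.int64)
    skipped = 0
    mids = _read_midpoints(reads)
    read_chroms = reads["chrom"].to_numpy()
    for chrom in pd.unique(read_chroms):
        sel = read_chroms == chrom
        if chrom not in grid.chrom_names:
            skipped += int(sel.sum())
            continue
        sl = grid.chrom_slice(chrom)
        starts = grid.starts[sl]
        chrom_end = grid.ends[sl][-1]
        m = mids[sel]
        in_range = (m >= 0) & (m < chrom_end)
        skipped += int((~in_range).sum())
        idx = np.searchsorted(starts, m[in_range], side="right") - 1
        np.add.at(counts, sl.start + idx, 1)
    return BinnedCounts(sample_id=sample_id, grid=grid, counts=counts, mode=mode,
                        skipped_reads=skipped)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def gc_normalize(
    counts: BinnedCounts,
    grid: GenomeBins | None = None,
    span: float = 0.3,
    min_bins: int = 50,
) -> np.ndarray:
    """Divide counts by a smooth expected-count-vs-GC curve.

    The curve is a LOWESS fit (span 0.3) through median counts in 1%-GC
    strata — robust to the copy-altered minority of bins.  Output is rescaled
    so its median matches the input median; bins whose GC lies outside the
    fitted support are returned as NaN.
    """
    grid = grid or counts.grid
    if not grid.same_grid(counts.grid):
        raise ValueError("grid mismatch")
    c = counts.counts.astype(float)
    if grid.n_bins < min_bins:
        raise ValueError(f"refusing to fit GC curve on fewer than {min_bins} bins")
    if np.all(c == 0):
        raise ValueError("no signal: all bin counts are zero")

    gc = grid.gc
    strata = np.floor(gc * 100).astype(int)
    stratum_ids = np.unique(strata)
    med_gc = np.array([gc[strata == s].mean() for s in stratum_ids])
    med_count = np.array([np.median(c[strata == s]) for s in stratum_ids])
    keep = med_count > 0
    if keep.sum() < 2:
        raise ValueError("not enough GC strata with signal to fit a curve")
    fitted = lowess(med_count[keep], med_gc[keep], frac=span, return_sorted=True)
    fx, fy = fitted[:, 0], np.maximum(fitted[:, 1], 1e-12)

    support = (gc >= fx[0]) & (gc <= fx[-1])
    expected = np.interp(gc, fx, fy)
    out = np.full(grid.n_bins, np.nan)
    out[support] = c[support] / expected[support]
    valid = support & np.isfinite(out)
    med_in = np.median(c[valid])
    med_out = np.median(out[valid])
    if med_out > 0:
        out[valid] *= med_in / med_out
    return out


def compute_log_ratio(
    sample_norm: np.ndarray,
    control_norm: np.ndarray,
    grid: GenomeBins,
    sample_id: str = "",
) -> CopyRatioProfile:
    """log2(sample/control), median-centered on autosomal unmasked bins.

    Bins with zero/absent control signal are masked (``zero_control``); bins
    already NaN on either side keep a GC-support mask.
    """
    sample_norm = np.asarray(sample_norm, dtype=float)
    control_norm = np.asarray(control_norm, dtype=float)
    if sample_norm.shape != (grid.n_bins,) or control_norm.shape != (grid.n_bins,):
        raise ValueError("profile length does not match grid")

    reason = np.full(grid.n_bins, None, dtype=object)
    log2 = np.full(grid.n_bins, np.nan)
    nan_mask = np.isnan(sample_norm) | np.isnan(control_norm)
    reason[np.isnan(sample_norm)] = "gc_out_of_support"
    reason[np.isnan(control_norm)] = "gc_out_of_support"
    zero_ctrl = (~nan_mask) & (control_norm <= 0)
    reason[zero_ctrl] = "zero_control"
    ok = ~nan_mask & ~zero_ctrl
    with np.errstate(divide="ignore"):
        log2[ok] = np.log2(sample_norm[ok]) - np.log2(control_norm[ok])
    neg_inf = ok & ~np.isfinite(log2)
    reason[neg_inf] = "zero_sample"
    log2[neg_inf] = np.nan
    ok &= np.isfinite(np.where(np.isnan(log2), np.inf, log2)) & ~np.isnan(log2)

    centering = log2[ok & grid.autosomal_mask()]
    if centering.size:
        log2 -= np.median(centering)
    return CopyRatioProfile(grid=grid, log2=log2, mask_reason=reason, sample_id=sample_id)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def write_counts_tsv(counts: BinnedCounts, path: str | Path) -> None:
    df = counts.grid.to_frame()[["chrom", "start", "end", "gc"]].copy()
    df["count"] = counts.counts
    df.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path, grid: GenomeBins, sample_id: str = "sample",
                    mode: Literal["targeted", "wgs"] = "wgs") -> BinnedCounts:
    df = pd.read_csv(path, sep="\t")
    if len(df) != grid.n_bins:
        raise ValueError("counts TSV row count does not match grid")
    if not (np.array_equal(df["chrom"].to_numpy(), grid.chrom_col)
            and np.array_equal(df["start"].to_numpy(), grid.starts)):
        raise ValueError("counts TSV coordinates do not match grid")
    return BinnedCounts(sample_id=sample_id, grid=grid,
                        counts=df["count"].to_numpy(), mode=mode)


def write_ratio_tsv(profile: CopyRatioProfile, path: str | Path) -> None:
    df = profile.grid.to_frame()[["chrom", "start", "end"]].copy()
    df["log2ratio"] = profile.log2
    df["masked"] = [r if r is not None else "" for r in profile.mask_reason]
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_ratio_tsv(path: str | Path, grid: GenomeBins, sample_id: str = "") -> CopyRatioProfile:
    df = pd.read_csv(path, sep="\t", keep_default_na=True)
    if len(df) != grid.n_bins:
        raise ValueError("ratio TSV row count does not match grid")
    reason = np.array(
        [r if isinstance(r, str) and r else None for r in df["masked"]], dtype=object
    )
    return CopyRatioProfile(grid=grid, log2=df["log2ratio"].to_numpy(dtype=float),
                            mask_reason=reason, sample_id=sample_id)
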