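"""Size-weighted bin-ratio concordance between two segmented profiles.

Two copy-number profiles (targeted vs low-pass WGS of the same sample, or
tumor vs aqueous humor of the same eye) are compared bin by bin: the
segmented means are divided on the linear copy-ratio scale, a bin is
concordant when the ratio falls inside [0.8, 1.2] (values strictly outside
are discordant), and the indicator is averaged with bin-width weights to a
single score in [0, 1].

The band is not symmetric under inversion (r -> 1/r), so the orientation —
which profile is the numerator — is part of the statistic and must be
stated explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeBins
from .segment import SegmentedProfile

__all__ = ["ConcordanceResult", "bin_ratio", "concordance_score",
           "DEFAULT_BAND", "MIN_DENOMINATOR_RATIO"]

#: Concordance band on the linear copy-ratio scale (inclusive on both ends).
DEFAULT_BAND = (0.8, 1.2)

#: Denominator bins whose linear segmented ratio falls below this are masked
#: instead of producing an unstable bin ratio.
MIN_DENOMINATOR_RATIO = 2.0**-6


@dataclass
class ConcordanceResult:
    orientation: str
    ratio: np.ndarray          # per-bin linear ratio, NaN where masked
    indicator: np.ndarray      # 1.0 concordant, 0.0 discordant, NaN masked
    score: float
    n_bins_used: int
    grid: GenomeBins

    def per_bin_frame(self) -> pd.DataFrame:
        df = self.grid.to_frame()[["chrom", "start", "end"]].copy()
        df["ratio"] = self.ratio
        df["concordant"] = self.indicator
        return df


def bin_ratio(
    numerator: SegmentedProfile,
    denominator: SegmentedProfile,
) -> np.ndarray:
    """Per-bin linear ratio of segmented copy ratios: 2^(mean_num - mean_den).

    Bins masked in either profile are NaN, as are bins whose denominator
    implies essentially zero copy number (ratio < 2^-6).
    """
    if not numerator.grid.same_grid(denominator.grid):
        raise ValueError("profiles are on different grids")
    num, den = numerator.seg_mean, denominator.seg_mean
    ratio = np.full(numerator.grid.n_bins, np.nan)
    ok = ~np.isnan(num) & ~np.isnan(den)
    den_linear = np.zeros(numerator.grid.n_bins)
    den_linear[ok] = 2.0 ** den[ok]
    ok &= den_linear >= MIN_DENOMINATOR_RATIO
    ratio[ok] = 2.0 ** (num[ok] - den[ok])
    return ratio


def concordance_score(
    ratios: np.ndarray,
    grid: GenomeBins,
    band_low: float = DEFAULT_BAND[0],
    band_high: float = DEFAULT_BAND[1],
    orientation: str = "numerator/denominator",
) -> ConcordanceResult:
    """Width-weighted fraction of bins whose ratio lies inside the band.

    A bin is concordant iff ``band_low <= ratio <= band_high`` (boundary
    values count as concordant; only ratios strictly outside the band are
    discordant).  Bin weights are bin widths normalized by the total width
    compared, so truncated end-of-chromosome bins count proportionally.
    Y-chromosome bins, if present, are excluded.
    """
    if band_low >= band_high:
        raise ValueError("band_low must be below band_high")
    ratios = np.asarray(ratios, dtype=float)
    if ratios.shape != (grid.n_bins,):
        raise ValueError("ratio length does not match grid")

    usable = ~np.isnan(ratios) & ~np.isin(grid.chrom_col, ["chrY", "Y"])
    if not usable.any():
        raise ValueError("no comparable bins: every bin is masked")

    indicator = np.full(grid.n_bins, np.nan)
    indicator[usable] = (
        (ratios[usable] >= band_low) & (ratios[usable] <= band_high)
    ).astype(float)
    weights = grid.widths.astype(float)
    score = float(
        np.sum(indicator[usable] * weights[usable]) / np.sum(weights[usable])
    )
    return ConcordanceResult(
        orientation=orientation, ratio=ratios, indicator=indicator,
        score=score, n_bins_used=int(usable.sum()), grid=grid,
    )
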