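"""Reference genome plumbing: chromosome specs, arm boundaries, and the bin grid.

Copy-number profiling here works on a fixed grid of genomic bins
(500 kb by default, mirroring common off-target cfDNA practice).  The grid
carries per-bin GC fraction (for coverage-bias normalization) and a p/q arm
label (for arm-level gain/loss calling).  Both the full-size hg19 frame and
a proportionally scaled-down genome — convenient for fast simulation — are
supported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChromSpec",
    "GenomeBins",
    "make_bin_grid",
    "hg19_chrom_specs",
    "scaled_chrom_specs",
    "scaled_gene_loci",
    "GENE_LOCI_HG19",
    "HG19_CHROMS",
]

# hg19 chromosome lengths and centromere positions (midpoint of the acen
# cytobands, rounded), from UCSC cytoBand annotation.  Y is deliberately
# absent: the copy-number baseline is a female gDNA control.
HG19_CHROMS: dict[str, tuple[int, int]] = {
    "chr1": (249_250_621, 125_000_000),
    "chr2": (243_199_373, 93_300_000),
    "chr3": (198_022_430, 91_000_000),
    "chr4": (191_154_276, 50_400_000),
    "chr5": (180_915_260, 48_400_000),
    "chr6": (171_115_067, 61_000_000),
    "chr7": (159_138_663, 59_900_000),
    "chr8": (146_364_022, 45_600_000),
    "chr9": (141_213_431, 49_000_000),
    "chr10": (135_534_747, 40_200_000),
    "chr11": (135_006_516, 53_700_000),
    "chr12": (133_851_895, 35_800_000),
    "chr13": (115_169_878, 17_900_000),
    "chr14": (107_349_540, 17_600_000),
    "chr15": (102_531_392, 19_000_000),
    "chr16": (90_354_753, 36_600_000),
    "chr17": (81_195_210, 24_000_000),
    "chr18": (78_077_248, 17_200_000),
    "chr19": (59_128_983, 26_500_000),
    "chr20": (63_025_520, 27_500_000),
    "chr21": (48_129_895, 13_200_000),
    "chr22": (51_304_566, 14_700_000),
    "chrX": (155_270_560, 60_600_000),
}

# hg19 loci of the four panel genes (UCSC RefSeq, outermost transcript
# boundaries, rounded to the annotated gene span).
GENE_LOCI_HG19: dict[str, tuple[str, int, int]] = {
    "RB1": ("chr13", 48_877_883, 49_056_122),
    "MYCN": ("chr2", 16_080_683, 16_087_129),
    "BCOR": ("chrX", 39_909_068, 40_036_582),
    "CREBBP": ("chr16", 3_775_055, 3_930_121),
}


@dataclass(frozen=True)
class ChromSpec:
    """A chromosome with a centromere splitting it into p and q arms."""

    name: str
    length: int
    centromere: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.name}: length must be positive")
        if not 0 < self.centromere < self.length:
            raise ValueError(
                f"{self.name}: centromere {self.centromere} not inside (0, {self.length})"
            )

    @property
    def short_name(self) -> str:
        """Chromosome label without any 'chr' prefix (used in arm labels like '6p')."""
        return self.name.removeprefix("chr")


def hg19_chrom_specs() -> list[ChromSpec]:
    """The 22 autosomes plus X at full hg19 size."""
    return [ChromSpec(name, length, cen) for name, (length, cen) in HG19_CHROMS.items()]


def scaled_chrom_specs(total_bp: int = 1_000_000_000) -> list[ChromSpec]:
    """Autosomes + X with lengths proportional to hg19, shrunk to ``total_bp``.

    Keeps relative chromosome and arm sizes (and hence the arm structure the
    signature caller depends on) while making whole-genome simulations cheap.
    """
    full = sum(length for length, _ in HG19_CHROMS.values())
    scale = total_bp / full
    return [
        ChromSpec(name, max(2, int(round(length * scale))), max(1, int(round(cen * scale))))
        for name, (length, cen) in HG19_CHROMS.items()
    ]


def scaled_gene_loci(total_bp: int = 1_000_000_000) -> dict[str, tuple[str, int, int]]:
    """Panel gene loci mapped onto the scaled genome of :func:`scaled_chrom_specs`."""
    full = sum(length for length, _ in HG19_CHROMS.values())
    scale = total_bp / full
    return {
        gene: (chrom, int(round(start * scale)), max(int(round(start * scale)) + 1, int(round(end * scale))))
        for gene, (chrom, start, end) in GENE_LOCI_HG19.items()
    }


class GenomeBins:
    """A fixed, sorted, per-chromosome-contiguous grid of genomic bins.

    Bins are 0-based half-open.  Each bin carries a GC fraction and a p/q arm
    label.  Instances are immutable in intent: downstream objects hold a
    reference and compare grids with :meth:`same_grid`.
    """

    def __init__(self, df: pd.DataFrame, chroms: Sequence[ChromSpec]):
        required = {"chrom", "start", "end", "gc", "arm"}
        if not required.issubset(df.columns):
            raise ValueError(f"grid frame missing columns: {required - set(df.columns)}")
        self.df = df.reset_index(drop=True)
        self.chroms = list(chroms)
        self._by_name = {c.name: c for c in self.chroms}
        # contiguous index ranges per chromosome
        self._slices: dict[str, slice] = {}
        chrom_arr = self.df["chrom"].to_numpy()
        for name in dict.fromkeys(chrom_arr):
            idx = np.flatnonzero(chrom_arr == name)
            self._slices[name] = slice(int(idx[0]), int(idx[-1]) + 1)

    # -- basic accessors -------------------------------------------------
    @property
    def n_bins(self) -> int:
        return len(self.df)

    @property
    def chrom_names(self) -> list[str]:
        return [c.name for c in self.chroms]

    @property
    def starts(self) -> np.ndarray:
        return self.df["start"].to_numpy()

    @property
    def ends(self) -> np.ndarray:
        return self.df["end"].to_numpy()

    @property
    def gc(self) -> np.ndarray:
        return self.df["gc"].to_numpy()

    @property
    def widths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def chrom_col(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    def chrom_slice(self, name: str) -> slice:
        return self._slices[name]

    def chrom_spec(self, name: str) -> ChromSpec:
        return self._by_name[name]

    def arm_labels(self) -> np.ndarray:
        """Per-bin labels like '1p', '13q' (no 'chr' prefix)."""
        shorts = np.array([self._by_name[c].short_name for c in self.chrom_col])
        return np.char.add(shorts, self.df["arm"].to_numpy().astype(str))

    def autosomal_mask(self) -> np.ndarray:
        return ~np.isin(self.chrom_col, ["chrX", "X", "chrY", "Y"])

    def same_grid(self, other: "GenomeBins") -> bool:
        return (
            self.n_bins == other.n_bins
            and np.array_equal(self.chrom_col, other.chrom_col)
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.ends, other.ends)
        )

    def to_frame(self) -> pd.DataFrame:
        return self.df.copy()


def _generate_gc(n: int, seed: int | None) -> np.ndarray:
    """Synthetic per-bin GC fractions: unimodal around 0.45, clipped to [0.30, 0.65]."""
    rng = np.random.default_rng(seed)
    return np.clip(rng.normal(0.45, 0.06, size=n), 0.30, 0.65)


def make_bin_grid(
    chroms: Iterable[ChromSpec],
    bin_width: int,
    gc: np.ndarray | Mapping[str, np.ndarray] | None = None,
    gc_seed: int | None = 0,
) -> GenomeBins:
    """Tile each chromosome with ``bin_width`` bins (last bin truncated).

    Parameters
    ----------
    chroms
        Chromosome specs; order is preserved.
    bin_width
        Bin width in bp; must be positive.
    gc
        Per-bin GC fractions in grid order, or None to generate smooth
        synthetic values from ``gc_seed``.
    """
    chroms = list(chroms)
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not chroms:
        raise ValueError("empty chromosome list")
    names = [c.name for c in chroms]
    if len(set(names)) != len(names):
        raise ValueError("chromosome names must be unique")

    rows = []
    for c in chroms:
        starts = np.arange(0, c.length, bin_width, dtype=np.int64)
        ends = np.minimum(starts + bin_width, c.length)
        mids = (starts + ends) // 2
        arms = np.where(mids < c.centromere, "p", "q")
        rows.append(
            pd.DataFrame({"chrom": c.name, "start": starts, "end": ends, "arm": arms})
        )
    df = pd.concat(rows, ignore_index=True)

    if gc is None:
        df["gc"] = _generate_gc(len(df), gc_seed)
    else:
        gc_arr = np.asarray(gc, dtype=float)
        if gc_arr.shape != (len(df),):
            raise ValueError(f"gc length {gc_arr.shape} does not match {len(df)} bins")
        if np.any((gc_arr < 0) | (gc_arr > 1)):
            raise ValueError("gc fractions must lie in [0, 1]")
        df["gc"] = gc_arr

    return GenomeBins(df[["chrom", "start", "end", "gc", "arm"]], chroms)
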