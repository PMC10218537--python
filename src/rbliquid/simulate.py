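"""Synthetic paired aqueous-humor / tumor cfDNA generator.

Emulates the study design the rest of the package analyzes: a shared tumor
copy-number truth profile observed through two samples with different tumor
fractions (the AH is typically purer than a contaminated tumor biopsy),
GC-dependent coverage bias, overdispersed (negative-binomial) bin counts,
and clonal variants whose expected allele fraction follows tumor fraction
and local copy number.  Every stochastic step is driven by explicit seeds.

The expected VAF model: in a sample with tumor fraction ``tf``, a locus with
tumor copy number ``cn_t`` contributes ``tf*cn_t + (1-tf)*2`` allele copies
per (diploid-equivalent) cell.  A somatic variant present at multiplicity
``m`` in tumor cells is carried by ``tf*m`` of those; a germline variant is
additionally on 1 of 2 alleles of every normal cell::

    somatic:  VAF = tf*m / (tf*cn_t + (1-tf)*2)
    germline: VAF = (tf*m + (1-tf)) / (tf*cn_t + (1-tf)*2)
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .bins import BinnedCounts
from .genome import (ChromSpec, GenomeBins, make_bin_grid, scaled_chrom_specs,
                     scaled_gene_loci)
from .variants import VariantRecord

__all__ = [
    "TruthSegment",
    "TruthProfile",
    "SampleSimConfig",
    "TruthVariant",
    "PairedCase",
    "SimulatedSample",
    "expected_vaf",
    "expected_bin_counts",
    "gc_bias_curve",
    "simulate_sample_counts",
    "simulate_control_counts",
    "simulate_variant_reads",
    "simulate_paired_case",
    "load_truth_config",
    "rb_signature_truth",
]


@dataclass(frozen=True)
class TruthSegment:
    chrom: str
    start: int
    end: int
    tumor_cn: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"segment end {self.end} <= start {self.start}")
        if self.tumor_cn < 0:
            raise ValueError("tumor copy number must be non-negative")


@dataclass
class TruthProfile:
    """Ground-truth tumor copy number; uncovered regions are diploid."""

    segments: list[TruthSegment] = field(default_factory=list)
    ploidy: float = 2.0

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[TruthSegment]] = {}
        for seg in self.segments:
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom, segs in by_chrom.items():
            segs = sorted(segs, key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping truth segments on {chrom}")

    def tumor_cn_per_bin(self, grid: GenomeBins) -> np.ndarray:
        """Tumor copy number of each bin (assigned by bin midpoint)."""
        cn = np.full(grid.n_bins, self.ploidy, dtype=float)
        mids = (grid.starts + grid.ends) // 2
        chroms = grid.chrom_col
        for seg in self.segments:
            hit = (chroms == seg.chrom) & (mids >= seg.start) & (mids < seg.end)
            cn[hit] = seg.tumor_cn
        return cn


@dataclass(frozen=True)
class SampleSimConfig:
    """Knobs for one simulated sample.

    ``gc_bias_coefficients`` are (c0, c1, c2) of a multiplicative quadratic
    in GC fraction, normalized to mean 1 over the grid; ``dispersion`` is the
    negative-binomial size parameter (variance = mu + mu^2/dispersion), with
    ``inf`` giving the Poisson limit.
    """

    tumor_fraction: float
    mean_reads_per_bin: float = 100.0
    gc_bias_coefficients: tuple[float, float, float] = (1.0, 0.0, 0.0)
    dispersion: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must lie in [0, 1]")
        if self.mean_reads_per_bin <= 0:
            raise ValueError("mean_reads_per_bin must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


@dataclass(frozen=True)
class TruthVariant:
    """A planted variant with its tumor-cell allele configuration."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = "other"
    origin: str = "somatic"  # germline variants are het (1 of 2) in normal cells
    multiplicity: float = 1.0
    locus_tumor_cn: float = 2.0
    effect_class: str = "deleterious"  # planted variants model pathogenic drivers

    def __post_init__(self) -> None:
        if self.origin not in ("germline", "somatic"):
            raise ValueError("origin must be 'germline' or 'somatic'")
        if self.multiplicity > self.locus_tumor_cn:
            raise ValueError("multiplicity cannot exceed locus tumor copy number")
        if self.multiplicity < 0 or self.locus_tumor_cn < 0:
            raise ValueError("multiplicity and copy number must be non-negative")


def expected_vaf(
    tumor_fraction: float,
    locus_tumor_cn: float,
    multiplicity: float,
    origin: str = "somatic",
) -> float:
    tf = tumor_fraction
    denom = tf * locus_tumor_cn + (1.0 - tf) * 2.0
    if denom == 0:
        raise ValueError(
            "undefined VAF: homozygous-deleted locus yields no reads "
            "(tumor_fraction=1 with locus copy number 0)"
        )
    numer = tf * multiplicity
    if origin == "germline":
        numer += (1.0 - tf) * 1.0
    elif origin != "somatic":
        raise ValueError("origin must be 'germline' or 'somatic'")
    return numer / denom


def gc_bias_curve(gc: np.ndarray, coefficients: Sequence[float]) -> np.ndarray:
    """Quadratic multiplicative bias in GC, clipped positive, mean-normalized to 1."""
    c0, c1, c2 = coefficients
    bias = c0 + c1 * gc + c2 * gc**2
    bias = np.maximum(bias, 1e-6)
    return bias / bias.mean()


def expected_bin_counts(
    grid: GenomeBins, truth: TruthProfile, cfg: SampleSimConfig
) -> np.ndarray:
    """Noise-free expected count per bin (mean equals ``mean_reads_per_bin``)."""
    tf = cfg.tumor_fraction
    cn = truth.tumor_cn_per_bin(grid)
    mixture = (tf * cn + (1.0 - tf) * 2.0) / 2.0
    expected = mixture * gc_bias_curve(grid.gc, cfg.gc_bias_coefficients)
    return expected * (cfg.mean_reads_per_bin / expected.mean())


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    mu = np.maximum(mu, 1e-12)
    if np.isinf(dispersion):
        return rng.poisson(mu)
    p = dispersion / (dispersion + mu)
    return rng.negative_binomial(dispersion, p)


def simulate_sample_counts(
    grid: GenomeBins,
    truth: TruthProfile,
    cfg: SampleSimConfig,
    sample_id: str = "sample",
    mode: str = "wgs",
) -> BinnedCounts:
    """Draw negative-binomial per-bin counts around the expected profile."""
    truth_chroms = {seg.chrom for seg in truth.segments}
    missing = truth_chroms - set(grid.chrom_names)
    if missing:
        raise ValueError(f"truth segments on chromosomes absent from grid: {sorted(missing)}")
    rng = np.random.default_rng(cfg.seed)
    mu = expected_bin_counts(grid, truth, cfg)
    counts = _draw_counts(rng, mu, cfg.dispersion)
    return BinnedCounts(sample_id=sample_id, grid=grid, counts=counts, mode=mode)  # type: ignore[arg-type]


def simulate_control_counts(
    grid: GenomeBins, cfg: SampleSimConfig, sample_id: str = "control"
) -> BinnedCounts:
    """A copy-neutral (flat diploid) control sample — the profiling baseline."""
    flat = replace(cfg, tumor_fraction=0.0)
    return simulate_sample_counts(grid, TruthProfile([]), flat, sample_id=sample_id)


def simulate_variant_reads(
    variants: Sequence[TruthVariant],
    tumor_fraction: float,
    depth_mean: float = 200.0,
    depth_dispersion: float = 20.0,
    seed: int = 0,
) -> list[VariantRecord]:
    """Per site: total depth ~ NB(mean, dispersion); alt ~ Binomial(depth, E[VAF])."""
    if depth_mean <= 0 or depth_dispersion <= 0:
        raise ValueError("depth mean and dispersion must be positive")
    rng = np.random.default_rng(seed)
    out = []
    for v in variants:
        depth = int(_draw_counts(rng, np.array([depth_mean]), depth_dispersion)[0])
        vaf = expected_vaf(tumor_fraction, v.locus_tumor_cn, v.multiplicity, v.origin)
        alt = int(rng.binomial(depth, vaf)) if depth > 0 else 0
        out.append(
            VariantRecord(
                chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
                total_depth=depth, alt_depth=alt,
                gene=v.gene if v.gene in {"RB1", "BCOR", "CREBBP", "MYCN"} else "other",
                effect_class=v.effect_class,
                origin_claim=v.origin,
            )
        )
    return out


@dataclass
class SimulatedSample:
    counts: BinnedCounts
    variant_records: list[VariantRecord]
    config: SampleSimConfig


@dataclass
class PairedCase:
    """One synthetic case: AH + tumor samples sharing a truth bundle."""

    grid: GenomeBins
    truth: TruthProfile
    truth_variants: list[TruthVariant]
    ah: SimulatedSample
    tumor: SimulatedSample
    control: BinnedCounts


def simulate_paired_case(
    grid: GenomeBins,
    truth: TruthProfile,
    variants: Sequence[TruthVariant],
    cfg_ah: SampleSimConfig,
    cfg_tumor: SampleSimConfig,
    cfg_control: SampleSimConfig | None = None,
    variant_depth_mean: float = 200.0,
    variant_depth_dispersion: float = 20.0,
) -> PairedCase:
    """Simulate a full paired case from one shared truth bundle.

    The default clinical scenario has the AH purer than the tumor biopsy
    (``cfg_tumor.tumor_fraction < cfg_ah.tumor_fraction``): necrotic or
    calcified biopsies carry many normal cells, diluting both copy-ratio
    amplitude and VAFs.  Variant-read seeds derive deterministically from
    each sample's count seed.
    """
    if cfg_control is None:
        cfg_control = replace(cfg_ah, tumor_fraction=0.0, seed=(cfg_ah.seed + 104729) % 2**31)
    samples = {}
    for label, cfg in (("ah", cfg_ah), ("tumor", cfg_tumor)):
        counts = simulate_sample_counts(grid, truth, cfg, sample_id=label)
        records = simulate_variant_reads(
            variants, cfg.tumor_fraction,
            depth_mean=variant_depth_mean,
            depth_dispersion=variant_depth_dispersion,
            seed=(cfg.seed * 2 + 1) % 2**31,
        )
        samples[label] = SimulatedSample(counts=counts, variant_records=records, config=cfg)
    control = simulate_control_counts(grid, cfg_control)
    return PairedCase(
        grid=grid, truth=truth, truth_variants=list(variants),
        ah=samples["ah"], tumor=samples["tumor"], control=control,
    )


def rb_signature_truth(
    total_bp: int = 1_000_000_000,
    bin_width: int = 500_000,
    focal_width_bins: int = 5,
    gain_cn: float = 3.0,
    loss_cn: float = 1.0,
    mycn_cn: float = 10.0,
) -> tuple[list[ChromSpec], TruthProfile, dict[str, tuple[str, int, int]]]:
    """The canonical retinoblastoma truth scenario on a scaled genome.

    Plants the recurrent arm-level signature (1q/2p/6p gain, 13q/16q loss)
    plus the two diagnostic focal events: a MYCN amplification inside the
    gained 2p and a biallelic (copy 0) RB1 deletion inside the lost 13q.
    Focal spans are snapped to bin boundaries and cover ``focal_width_bins``
    bins.  Returns (chromosome specs, truth profile, gene loci).
    """
    specs = scaled_chrom_specs(total_bp)
    loci = scaled_gene_loci(total_bp)
    by_name = {c.name: c for c in specs}

    def focal_span(gene: str) -> tuple[str, int, int]:
        chrom, gstart, gend = loci[gene]
        mid_bin = ((gstart + gend) // 2) // bin_width
        start = max(0, (mid_bin - focal_width_bins // 2) * bin_width)
        end = min(by_name[chrom].length, start + focal_width_bins * bin_width)
        return chrom, start, end

    segments: list[TruthSegment] = []
    for chrom in ("chr1", "chr6"):
        c = by_name[chrom]
        arm = (c.centromere, c.length) if chrom == "chr1" else (0, c.centromere)
        segments.append(TruthSegment(chrom, arm[0], arm[1], gain_cn))

    # 2p gain with the MYCN amplification nested inside it
    c2 = by_name["chr2"]
    _, m_start, m_end = focal_span("MYCN")
    segments += [
        TruthSegment("chr2", 0, m_start, gain_cn),
        TruthSegment("chr2", m_start, m_end, mycn_cn),
        TruthSegment("chr2", m_end, c2.centromere, gain_cn),
    ]

    # 13q loss with the biallelic RB1 deletion nested inside it
    c13 = by_name["chr13"]
    _, r_start, r_end = focal_span("RB1")
    segments += [
        TruthSegment("chr13", c13.centromere, r_start, loss_cn),
        TruthSegment("chr13", r_start, r_end, 0.0),
        TruthSegment("chr13", r_end, c13.length, loss_cn),
    ]

    c16 = by_name["chr16"]
    segments.append(TruthSegment("chr16", c16.centromere, c16.length, loss_cn))
    return specs, TruthProfile(segments), loci


# ---------------------------------------------------------------------------
# config file loading
# ---------------------------------------------------------------------------

def load_truth_config(path: str | Path) -> dict:
    """Parse a YAML truth/config file into simulator objects.

    Expected top-level keys: ``chromosomes`` (name/length/centromere),
    ``bin_width``, optional ``gc_seed``, ``segments``
    (chrom/start/end/tumor_cn), ``variants``, and per-sample sections
    ``ah`` / ``tumor`` (/ optional ``control``) with SampleSimConfig fields.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    chroms = [
        ChromSpec(c["name"], int(c["length"]), int(c["centromere"]))
        for c in raw["chromosomes"]
    ]
    grid = make_bin_grid(chroms, int(raw["bin_width"]), gc_seed=int(raw.get("gc_seed", 0)))
    truth = TruthProfile(
        [
            TruthSegment(s["chrom"], int(s["start"]), int(s["end"]), float(s["tumor_cn"]))
            for s in raw.get("segments", [])
        ]
    )
    variants = [
        TruthVariant(
            chrom=v["chrom"], pos=int(v["pos"]), ref=v["ref"], alt=v["alt"],
            gene=v.get("gene", "other"), origin=v.get("origin", "somatic"),
            multiplicity=float(v.get("multiplicity", 1.0)),
            locus_tumor_cn=float(v.get("locus_tumor_cn", 2.0)),
            effect_class=v.get("effect_class", "deleterious"),
        )
        for v in raw.get("variants", [])
    ]

    def cfg_of(section: dict) -> SampleSimConfig:
        return SampleSimConfig(
            tumor_fraction=float(section["tumor_fraction"]),
            mean_reads_per_bin=float(section.get("mean_reads_per_bin", 100.0)),
            gc_bias_coefficients=tuple(section.get("gc_bias_coefficients", (1.0, 0.0, 0.0))),
            dispersion=float(section.get("dispersion", 150.0)),
            seed=int(section.get("seed", 0)),
        )

    out = {"grid": grid, "truth": truth, "variants": variants}
    for key in ("ah", "tumor", "control"):
        if key in raw:
            out[key] = cfg_of(raw[key])
    out["raw"] = raw
    return out
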