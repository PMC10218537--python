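"""SNV QC and paired-sample comparison logic.

Variant calling and functional annotation happen upstream (e.g. Mutect2 +
Annovar); this module consumes per-site depths and annotation labels and
implements the downstream rules: VAF computation, the depth-QC gate,
aqueous-humor/tumor sharing classification, rescue of QC-failing sites by
independent evidence, and germline confirmation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "VariantRecord",
    "PairedVariantComparison",
    "compute_vaf",
    "apply_depth_filter",
    "pair_variants",
    "rescue_by_external_evidence",
    "confirm_germline",
    "read_vcf",
    "write_vcf",
    "DEFAULT_DEPTH_CUTOFF",
]

#: QC gate: a site passes iff total depth >= this cutoff, so depths of 7 and
#: 9 reads fail while 10 passes.
DEFAULT_DEPTH_CUTOFF = 10

VALID_EFFECTS = {"deleterious", "tolerated", "unknown"}
VALID_ORIGINS = {"germline", "somatic", "unknown"}


@dataclass
class VariantRecord:
    """One observed variant at one site in one sample.

    ``effect_class`` and ``origin_claim`` are consumed from upstream
    annotation; ``qc_pass`` is None until a depth filter runs.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    total_depth: int
    alt_depth: int
    gene: str = "other"
    effect_class: str = "unknown"
    origin_claim: str = "unknown"
    qc_pass: bool | None = None

    def __post_init__(self) -> None:
        if self.total_depth < 0:
            raise ValueError("total_depth must be non-negative")
        if not 0 <= self.alt_depth <= self.total_depth:
            raise ValueError(
                f"alt_depth {self.alt_depth} outside [0, total_depth={self.total_depth}]"
            )
        if self.effect_class not in VALID_EFFECTS:
            raise ValueError(f"effect_class {self.effect_class!r} invalid")
        if self.origin_claim not in VALID_ORIGINS:
            raise ValueError(f"origin_claim {self.origin_claim!r} invalid")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def vaf(self) -> float:
        """Alt reads over total reads; NaN (masked) at zero depth."""
        return compute_vaf(self)


def compute_vaf(record: VariantRecord) -> float:
    if record.total_depth == 0:
        return math.nan
    return record.alt_depth / record.total_depth


def apply_depth_filter(
    records: Iterable[VariantRecord], cutoff: int = DEFAULT_DEPTH_CUTOFF
) -> list[VariantRecord]:
    """Set ``qc_pass = total_depth >= cutoff``; failing records are kept.

    Records are never silently dropped at this stage — discards happen only
    in :func:`rescue_by_external_evidence` where cross-sample context exists.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return [replace(r, qc_pass=r.total_depth >= cutoff) for r in records]


@dataclass
class PairedVariantComparison:
    """Site-keyed outer join of one AH and one tumor record set.

    ``table`` has one row per (chrom, pos, ref, alt) with columns:
    status (shared|ah_only|tumor_only|discarded), vaf_ah, vaf_tumor,
    depth_ah, depth_tumor, qc_ah, qc_tumor, rescue_ah, rescue_tumor,
    gene, effect_class, origin_claim.
    """

    table: pd.DataFrame
    rescued_keys: list[tuple[str, int, str, str]] = field(default_factory=list)

    def summary(self) -> dict[str, int]:
        counts = self.table["status"].value_counts()
        return {
            "shared": int(counts.get("shared", 0)),
            "ah_only": int(counts.get("ah_only", 0)),
            "tumor_only": int(counts.get("tumor_only", 0)),
            "discarded": int(counts.get("discarded", 0)),
        }

    def status_of(self, key: tuple[str, int, str, str]) -> str:
        row = self.table[
            (self.table["chrom"] == key[0])
            & (self.table["pos"] == key[1])
            & (self.table["ref"] == key[2])
            & (self.table["alt"] == key[3])
        ]
        if row.empty:
            raise KeyError(f"site {key} not in comparison")
        return str(row["status"].iloc[0])


def _records_frame(records: Sequence[VariantRecord], side: str) -> pd.DataFrame:
    keys = [r.key for r in records]
    if len(set(keys)) != len(keys):
        dup = [k for k in keys if keys.count(k) > 1][0]
        raise ValueError(f"duplicate variant key within one sample: {dup}")
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in records],
            "pos": [r.pos for r in records],
            "ref": [r.ref for r in records],
            "alt": [r.alt for r in records],
            f"vaf_{side}": [r.vaf for r in records],
            f"depth_{side}": [r.total_depth for r in records],
            f"qc_{side}": [bool(r.qc_pass) for r in records],
            f"gene_{side}": [r.gene for r in records],
            f"effect_{side}": [r.effect_class for r in records],
            f"origin_{side}": [r.origin_claim for r in records],
        }
    )


def _classify(row: pd.Series) -> str:
    ah = bool(row["present_ah"])
    tm = bool(row["present_tumor"])
    if ah and tm:
        return "shared"
    if ah:
        return "ah_only"
    if tm:
        return "tumor_only"
    return "discarded"


def pair_variants(
    ah_records: Sequence[VariantRecord], tumor_records: Sequence[VariantRecord]
) -> PairedVariantComparison:
    """Join AH and tumor calls on (chrom, pos, ref, alt).

    A side counts as "present" only when its record passed the depth QC;
    records failing QC are carried through (depths, VAFs, qc flags) so that
    rescue logic can later reinstate them.  Both record sets must already be
    QC-annotated.
    """
    for recs, name in ((ah_records, "AH"), (tumor_records, "tumor")):
        if any(r.qc_pass is None for r in recs):
            raise ValueError(f"{name} records lack QC annotation; run apply_depth_filter first")

    ah_df = _records_frame(ah_records, "ah")
    tm_df = _records_frame(tumor_records, "tumor")
    merged = ah_df.merge(tm_df, on=["chrom", "pos", "ref", "alt"], how="outer")

    merged["qc_ah"] = merged["qc_ah"].astype(object).where(merged["qc_ah"].notna(), False)
    merged["qc_tumor"] = merged["qc_tumor"].astype(object).where(merged["qc_tumor"].notna(), False)
    merged["in_ah"] = merged["depth_ah"].notna()
    merged["in_tumor"] = merged["depth_tumor"].notna()
    merged["rescue_ah"] = False
    merged["rescue_tumor"] = False
    merged["present_ah"] = merged["qc_ah"].astype(bool)
    merged["present_tumor"] = merged["qc_tumor"].astype(bool)
    merged["status"] = merged.apply(_classify, axis=1)

    # annotation columns: prefer the AH copy, fall back to tumor
    for col in ("gene", "effect", "origin"):
        merged[col if col == "gene" else f"{col}_class" if col == "effect" else "origin_claim"] = (
            merged[f"{col}_ah"].where(merged[f"{col}_ah"].notna(), merged[f"{col}_tumor"])
        )
    merged = merged.rename(columns={"effect": "effect_class", "origin": "origin_claim"})

    cols = [
        "chrom", "pos", "ref", "alt", "status",
        "vaf_ah", "vaf_tumor", "depth_ah", "depth_tumor",
        "qc_ah", "qc_tumor", "rescue_ah", "rescue_tumor",
        "in_ah", "in_tumor", "gene", "effect_class", "origin_claim",
    ]
    merged = merged[cols].sort_values(["chrom", "pos", "ref", "alt"]).reset_index(drop=True)
    return PairedVariantComparison(table=merged)


def rescue_by_external_evidence(
    comparison: PairedVariantComparison,
    evidence: Sequence[tuple[tuple[str, int, str, str], str]] = (),
) -> PairedVariantComparison:
    """Reinstate QC-failing observations backed by independent evidence.

    ``evidence`` pairs a site key with a free-text reason (e.g. "present at
    diagnosis and in enucleated tumor").  A QC-failing observation at an
    evidenced site is counted as present (rescue flag set).  QC-failing
    observations with no evidence stay absent; a site with no surviving
    observation on either side is marked ``discarded``.
    """
    table = comparison.table.copy()
    key_cols = ["chrom", "pos", "ref", "alt"]
    keys = list(map(tuple, table[key_cols].to_numpy()))
    index = {k: i for i, k in enumerate(keys)}

    rescued: list[tuple[str, int, str, str]] = []
    for site, _reason in evidence:
        site = (site[0], int(site[1]), site[2], site[3])
        if site not in index:
            raise KeyError(f"evidence refers to unknown site {site}")
        i = index[site]
        for side in ("ah", "tumor"):
            if bool(table.at[i, f"in_{side}"]) and not bool(table.at[i, f"qc_{side}"]):
                table.at[i, f"rescue_{side}"] = True
        rescued.append(site)

    table["present_ah"] = table["qc_ah"].astype(bool) | table["rescue_ah"].astype(bool)
    table["present_tumor"] = table["qc_tumor"].astype(bool) | table["rescue_tumor"].astype(bool)
    table["status"] = table.apply(_classify, axis=1)
    return PairedVariantComparison(table=table, rescued_keys=rescued)


def confirm_germline(
    records: Sequence[VariantRecord],
    germline_variants: Sequence[tuple[str, int, str, str]],
) -> dict[tuple[str, int, str, str], bool]:
    """Per germline site: True iff present with passing QC in ``records``."""
    passing = {r.key for r in records if r.qc_pass}
    return {tuple(site): tuple(site) in passing for site in germline_variants}


# ---------------------------------------------------------------------------
# VCF I/O (minimal dialect: FORMAT DP + AD on a single sample, INFO GENE /
# EFFECT / ORIGIN when available)
# ---------------------------------------------------------------------------

def write_vcf(
    records: Sequence[VariantRecord],
    path: str | Path,
    sample_id: str = "SAMPLE",
    contigs: Mapping[str, int] | None = None,
) -> None:
    header = pysam.VariantHeader()
    seen = dict(contigs or {})
    for r in records:
        seen.setdefault(r.chrom, 0)
        seen[r.chrom] = max(seen[r.chrom], r.pos + 1)
    for name, length in seen.items():
        header.contigs.add(name, length=length)
    header.info.add("GENE", 1, "String", "Gene symbol from annotation")
    header.info.add("EFFECT", 1, "String", "deleterious|tolerated|unknown")
    header.info.add("ORIGIN", 1, "String", "germline|somatic|unknown")
    header.formats.add("DP", 1, "Integer", "Total read depth at the site")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.add_sample(sample_id)

    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for r in sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt)):
            rec = vcf.new_record(
                contig=r.chrom, start=r.pos - 1, stop=r.pos, alleles=(r.ref, r.alt)
            )
            rec.info["GENE"] = r.gene
            rec.info["EFFECT"] = r.effect_class
            rec.info["ORIGIN"] = r.origin_claim
            rec.samples[sample_id]["DP"] = r.total_depth
            rec.samples[sample_id]["AD"] = (r.total_depth - r.alt_depth, r.alt_depth)
            vcf.write(rec)


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read variant records; multi-allelic rows are split into biallelic ones.

    Depths come from the first sample's FORMAT DP/AD (AD split per alt);
    annotation from INFO GENE/EFFECT/ORIGIN when present.
    """
    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if not rec.alts:
                continue
            def info_str(key: str, default: str) -> str:
                try:
                    return str(rec.info.get(key, default))
                except (KeyError, ValueError):  # key absent from header
                    return default

            gene = info_str("GENE", "other")
            effect = info_str("EFFECT", "unknown")
            origin = info_str("ORIGIN", "unknown")
            if samples:
                fmt = rec.samples[samples[0]]
                ad = fmt.get("AD")
                dp = fmt.get("DP")
            else:
                ad, dp = None, rec.info.get("DP")
            for ai, alt in enumerate(rec.alts):
                alt_depth = int(ad[ai + 1]) if ad is not None and ad[ai + 1] is not None else 0
                total = int(dp) if dp is not None else (int(sum(x or 0 for x in ad)) if ad else 0)
                out.append(
                    VariantRecord(
                        chrom=rec.contig,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        total_depth=total,
                        alt_depth=min(alt_depth, total),
                        gene=gene if gene in {"RB1", "BCOR", "CREBBP", "MYCN"} else "other",
                        effect_class=effect if effect in VALID_EFFECTS else "unknown",
                        origin_claim=origin if origin in VALID_ORIGINS else "unknown",
                    )
                )
    return out
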