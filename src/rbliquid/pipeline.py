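"""End-to-end per-case orchestration and cohort summaries.

``run_case`` reproduces the per-patient workflow: profile the aqueous-humor
and tumor samples (bin counts → GC normalization → log ratio vs control →
segmentation), score their concordance, call arm/focal SCNAs and the
RB-SCNA signature, QC and pair the variant calls, and fold everything into
one report.  ``cohort_summary`` aggregates reports the way a study table
would.  No logic lives only in the CLI: every subcommand calls the same
functions exposed here.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bins import (BinnedCounts, compute_log_ratio, gc_normalize,
                   read_counts_tsv, write_counts_tsv, write_ratio_tsv)
from .concord import bin_ratio, concordance_score
from .genome import (ChromSpec, GenomeBins, make_bin_grid, scaled_chrom_specs,
                     scaled_gene_loci)
from .segment import SegmentedProfile, cbs_segment, prune_segments, segments_to_seg_file
from .signatures import (ScnaCallSet, call_arm_events, classify_rb_signature,
                         detect_focal_events)
from .simulate import (SampleSimConfig, TruthProfile, TruthSegment, TruthVariant,
                       simulate_paired_case, simulate_sample_counts)
from .variants import (PairedVariantComparison, VariantRecord, apply_depth_filter,
                       confirm_germline, pair_variants, read_vcf,
                       rescue_by_external_evidence)

__all__ = ["CaseReport", "SegmentationParams", "run_case", "cohort_summary",
           "profile_sample"]

log = logging.getLogger("rbliquid")


@dataclass(frozen=True)
class SegmentationParams:
    alpha: float = 0.01
    n_perm: int = 1000
    min_width: int = 3
    undo_sd: float = 3.0
    seed: int = 0


@dataclass
class CaseReport:
    """Per-case analysis summary (the per-patient row of a cohort figure)."""

    case_id: str
    scna: dict[str, dict] = field(default_factory=dict)           # sample -> ScnaCallSet dict
    concordance: dict[str, float] = field(default_factory=dict)   # comparison -> score
    variant_summary: dict[str, int] = field(default_factory=dict)
    germline_confirmations: dict[str, dict[str, bool]] = field(default_factory=dict)
    somatic_alteration_identified: bool = False
    seeds: dict[str, int] = field(default_factory=dict)
    version: str = __version__

    def to_json(self, indent: int = 2) -> str:
        def germ_key(d: dict) -> dict:
            return {"|".join(map(str, k)): v for k, v in d.items()}

        payload = dataclasses.asdict(self)
        payload["germline_confirmations"] = {
            s: germ_key(d) for s, d in self.germline_confirmations.items()
        }
        return json.dumps(payload, indent=indent, sort_keys=True)


def profile_sample(
    counts: BinnedCounts,
    control: BinnedCounts,
    params: SegmentationParams = SegmentationParams(),
) -> SegmentedProfile:
    """Counts → GC-normalized log ratio vs control → pruned segmentation."""
    sample_norm = gc_normalize(counts)
    control_norm = gc_normalize(control)
    profile = compute_log_ratio(sample_norm, control_norm, counts.grid,
                                sample_id=counts.sample_id)
    seg = cbs_segment(profile, alpha=params.alpha, n_perm=params.n_perm,
                      min_width=params.min_width, seed=params.seed)
    return prune_segments(seg, undo_sd=params.undo_sd)


def _call_scna(seg: SegmentedProfile,
               gene_loci: Mapping[str, tuple[str, int, int]]) -> ScnaCallSet:
    arms = call_arm_events(seg)
    focal = detect_focal_events(seg, gene_loci)
    return classify_rb_signature(arms, focal)


def _load_config(config: Mapping[str, Any] | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _build_synthetic(cfg: dict):
    genome = cfg.get("genome", {})
    if "chromosomes" in cfg:
        chroms = [ChromSpec(c["name"], int(c["length"]), int(c["centromere"]))
                  for c in cfg["chromosomes"]]
        gene_loci = {g: (v[0], int(v[1]), int(v[2]))
                     for g, v in cfg.get("gene_loci", {}).items()}
    else:
        total_bp = int(genome.get("total_bp", 1_000_000_000))
        chroms = scaled_chrom_specs(total_bp)
        gene_loci = scaled_gene_loci(total_bp)
    bin_width = int(genome.get("bin_width", cfg.get("bin_width", 500_000)))
    grid = make_bin_grid(chroms, bin_width, gc_seed=int(cfg.get("gc_seed", 0)))

    truth = TruthProfile([
        TruthSegment(s["chrom"], int(s["start"]), int(s["end"]), float(s["tumor_cn"]))
        for s in cfg.get("segments", [])
    ])
    variants = [
        TruthVariant(
            chrom=v["chrom"], pos=int(v["pos"]), ref=v.get("ref", "A"),
            alt=v.get("alt", "T"), gene=v.get("gene", "other"),
            origin=v.get("origin", "somatic"),
            multiplicity=float(v.get("multiplicity", 1.0)),
            locus_tumor_cn=float(v.get("locus_tumor_cn", 2.0)),
            effect_class=v.get("effect_class", "deleterious"),
        )
        for v in cfg.get("variants", [])
    ]

    def sample_cfg(section: Mapping[str, Any], default_seed: int) -> SampleSimConfig:
        return SampleSimConfig(
            tumor_fraction=float(section["tumor_fraction"]),
            mean_reads_per_bin=float(section.get("mean_reads_per_bin", 100.0)),
            gc_bias_coefficients=tuple(section.get("gc_bias_coefficients", (1.0, 0.0, 0.0))),
            dispersion=float(section.get("dispersion", 150.0)),
            seed=int(section.get("seed", default_seed)),
        )

    base_seed = int(cfg.get("seed", 0))
    cfg_ah = sample_cfg(cfg.get("ah", {"tumor_fraction": 0.75}), base_seed * 10 + 1)
    cfg_tumor = sample_cfg(cfg.get("tumor", {"tumor_fraction": 0.35}), base_seed * 10 + 2)
    return grid, truth, variants, cfg_ah, cfg_tumor, gene_loci


def run_case(config: Mapping[str, Any] | str | Path,
             outdir: str | Path | None = None) -> CaseReport:
    """Execute the full per-case workflow described by one config.

    Synthetic mode (``mode: synthetic``) simulates a paired case from the
    configured truth; real-data mode reads counts TSVs and VCFs.  All
    randomness flows from seeds in the config, so re-running reproduces the
    report byte for byte.  Stage failures propagate with the stage name.
    """
    cfg = _load_config(config)
    case_id = str(cfg.get("case_id", "case"))
    params = SegmentationParams(**{**{"seed": int(cfg.get("seed", 0))},
                                   **cfg.get("segmentation", {})})
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    mode = cfg.get("mode", "synthetic")
    if mode == "synthetic":
        grid, truth, tvariants, cfg_ah, cfg_tumor, gene_loci = _build_synthetic(cfg)
        log.info("case %s: simulating paired samples (tf_ah=%.2f tf_tumor=%.2f, seed=%d)",
                 case_id, cfg_ah.tumor_fraction, cfg_tumor.tumor_fraction, params.seed)
        case = simulate_paired_case(grid, truth, tvariants, cfg_ah, cfg_tumor)
        counts = {"ah": case.ah.counts, "tumor": case.tumor.counts}
        control = case.control
        records = {"ah": case.ah.variant_records, "tumor": case.tumor.variant_records}
        seeds = {"ah": cfg_ah.seed, "tumor": cfg_tumor.seed, "segmentation": params.seed}
    elif mode == "real":
        chroms = [ChromSpec(c["name"], int(c["length"]), int(c["centromere"]))
                  for c in cfg["chromosomes"]]
        grid = make_bin_grid(chroms, int(cfg["bin_width"]),
                             gc_seed=int(cfg.get("gc_seed", 0)))
        gene_loci = {g: (v[0], int(v[1]), int(v[2]))
                     for g, v in cfg.get("gene_loci", {}).items()}
        counts = {}
        for label in ("ah", "tumor"):
            if f"{label}_counts_tsv" in cfg:
                counts[label] = read_counts_tsv(cfg[f"{label}_counts_tsv"], grid,
                                                sample_id=label)
        if not counts:
            raise ValueError("real-data config names no sample counts")
        control = read_counts_tsv(cfg["control_counts_tsv"], grid, sample_id="control")
        records = {}
        for label in ("ah", "tumor"):
            if f"{label}_vcf" in cfg:
                records[label] = read_vcf(cfg[f"{label}_vcf"])
        seeds = {"segmentation": params.seed}
    else:
        raise ValueError(f"unknown mode {mode!r}")

    # --- copy-number stage ------------------------------------------------
    segs: dict[str, SegmentedProfile] = {}
    scna: dict[str, dict] = {}
    scna_sets: dict[str, ScnaCallSet] = {}
    for label, c in counts.items():
        try:
            segs[label] = profile_sample(c, control, params)
        except Exception as exc:
            raise RuntimeError(f"stage profile_sample failed for sample {label!r}") from exc
        scna_sets[label] = _call_scna(segs[label], gene_loci)
        scna[label] = scna_sets[label].to_dict()
        if outdir is not None:
            header = f"# rbliquid {__version__} case={case_id} sample={label} seed={params.seed}\n"
            (outdir / f"{case_id}.{label}.seg").write_text(
                header + segments_to_seg_file(segs[label], sample_id=f"{case_id}.{label}"))
            write_counts_tsv(c, outdir / f"{case_id}.{label}.counts.tsv")

    # --- concordance stage ------------------------------------------------
    concordance: dict[str, float] = {}
    if "ah" in segs and "tumor" in segs:
        ratios = bin_ratio(segs["tumor"], segs["ah"])  # tumor / AH orientation
        concordance["tumor_vs_ah"] = concordance_score(
            ratios, grid, orientation="tumor/ah").score

    # optional second assay of the same samples (targeted vs WGS analog)
    if mode == "synthetic" and cfg.get("simulate_wgs_assay", False):
        for label, sample_cfg in (("ah", cfg_ah), ("tumor", cfg_tumor)):
            wgs_cfg = replace(sample_cfg, seed=(sample_cfg.seed + 7919) % 2**31)
            wgs_counts = simulate_sample_counts(grid, truth, wgs_cfg,
                                                sample_id=f"{label}_wgs", mode="wgs")
            wgs_seg = profile_sample(wgs_counts, control, params)
            ratios = bin_ratio(segs[label], wgs_seg)  # targeted / WGS orientation
            concordance[f"targeted_vs_wgs_{label}"] = concordance_score(
                ratios, grid, orientation="targeted/wgs").score

    # --- variant stage ----------------------------------------------------
    variant_summary: dict[str, int] = {}
    comparison: PairedVariantComparison | None = None
    qc_records: dict[str, list[VariantRecord]] = {
        label: apply_depth_filter(recs) for label, recs in records.items()
    }
    if "ah" in qc_records and "tumor" in qc_records:
        comparison = pair_variants(qc_records["ah"], qc_records["tumor"])
        evidence = [((e["chrom"], int(e["pos"]), e["ref"], e["alt"]), e.get("reason", ""))
                    for e in cfg.get("rescue_evidence", [])]
        comparison = rescue_by_external_evidence(comparison, evidence)
        variant_summary = comparison.summary()
        if outdir is not None:
            comparison.table.to_csv(outdir / f"{case_id}.variants.tsv", sep="\t", index=False)

    germline_conf: dict[str, dict] = {}
    germline_sites = [tuple(s) for s in cfg.get("germline_sites", [])]
    if not germline_sites and mode == "synthetic":
        germline_sites = [(v.chrom, v.pos, v.ref, v.alt)
                          for v in tvariants if v.origin == "germline"]
    for label, recs in qc_records.items():
        if germline_sites:
            germline_conf[label] = confirm_germline(recs, germline_sites)

    # --- verdict ----------------------------------------------------------
    any_scna = any(s.rb_scna_positive or s.other_scna_present for s in scna_sets.values())
    pathogenic_snv = False
    if comparison is not None:
        tab = comparison.table
        pathogenic_snv = bool(
            ((tab["effect_class"] == "deleterious")
             & tab["status"].isin(["shared", "ah_only", "tumor_only"])).any()
        )
    else:
        for recs in qc_records.values():
            pathogenic_snv |= any(r.qc_pass and r.effect_class == "deleterious" for r in recs)

    report = CaseReport(
        case_id=case_id,
        scna=scna,
        concordance=concordance,
        variant_summary=variant_summary,
        germline_confirmations=germline_conf,
        somatic_alteration_identified=bool(any_scna or pathogenic_snv),
        seeds=seeds,
    )
    if outdir is not None:
        (outdir / f"{case_id}.report.json").write_text(report.to_json())
    return report


def cohort_summary(reports: Sequence[CaseReport]) -> dict[str, Any]:
    """Aggregate per-case reports into study-level counts and medians."""
    if not reports:
        raise ValueError("cohort_summary needs at least one report")
    n = len(reports)

    def any_scna(r: CaseReport) -> bool:
        return any(s["rb_scna_positive"] or s["other_scna_present"] for s in r.scna.values())

    def any_rb(r: CaseReport) -> bool:
        return any(s["rb_scna_positive"] for s in r.scna.values())

    shared = sum(r.variant_summary.get("shared", 0) for r in reports)
    total_snv = sum(
        r.variant_summary.get("shared", 0)
        + r.variant_summary.get("ah_only", 0)
        + r.variant_summary.get("tumor_only", 0)
        for r in reports
    )
    conc: dict[str, list[float]] = {}
    for r in reports:
        for key, val in r.concordance.items():
            conc.setdefault(key, []).append(val)

    out: dict[str, Any] = {
        "n_cases": n,
        "n_with_any_scna": sum(any_scna(r) for r in reports),
        "n_with_rb_scna": sum(any_rb(r) for r in reports),
        "n_somatic_alteration": sum(r.somatic_alteration_identified for r in reports),
        "snvs_shared": shared,
        "snvs_total": total_snv,
    }
    for key, vals in conc.items():
        arr = np.asarray(vals, dtype=float)
        out[f"median_concordance_{key}"] = float(np.median(arr))
        out[f"sd_concordance_{key}"] = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return out
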