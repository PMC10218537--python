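"""Arm-level SCNA calling, focal gene events, and the RB-SCNA signature.

Retinoblastoma genomes recurrently show a characteristic alteration set —
gain of 1q, 2p and 6p, loss of 13q (the RB1 arm) and 16q — here called the
RB-SCNA signature.  Focal, high-amplitude events hitting the panel genes
(biallelic RB1 deletion, MYCN amplification) carry the same diagnostic
weight.  Other recurrent arms (e.g. 17q, 7q, 20q) are reported as ordinary
arm calls but never flip the signature verdict.

Manual inspection of segmented profiles is replaced by explicit rules: an
arm is called gained (lost) when at least ``min_fraction`` of its unmasked
bins have segmented mean beyond ±``arm_thresh``; a focal event is a short
(< 10 Mb) segment overlapping a panel gene with mean beyond ±0.5, flagged
"deep" at amplification / biallelic-loss amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .segment import SegmentedProfile

__all__ = [
    "ArmCall",
    "FocalEvent",
    "ScnaCallSet",
    "call_arm_events",
    "detect_focal_events",
    "classify_rb_signature",
    "RB_SIGNATURE_ARMS",
    "PANEL_GENES",
]

#: The recurrent retinoblastoma arm-level alteration set.
RB_SIGNATURE_ARMS = {("1q", "gain"), ("2p", "gain"), ("6p", "gain"),
                     ("13q", "loss"), ("16q", "loss")}

PANEL_GENES = ("RB1", "MYCN", "BCOR", "CREBBP")


@dataclass(frozen=True)
class ArmCall:
    arm: str                  # e.g. "6p", "13q"
    direction: str            # gain | loss | neutral
    median_log2: float
    fraction_beyond: float    # fraction of unmasked arm bins past the threshold
    n_bins: int
    no_data: bool = False


@dataclass(frozen=True)
class FocalEvent:
    gene: str
    direction: str            # gain | loss
    segment_mean: float
    segment_length: int       # bp
    deep_flag: bool           # amplification / biallelic-loss amplitude
    chrom: str = ""
    start: int = 0
    end: int = 0


@dataclass
class ScnaCallSet:
    arm_calls: list[ArmCall] = field(default_factory=list)
    focal_events: list[FocalEvent] = field(default_factory=list)
    rb_scna_positive: bool = False
    other_scna_present: bool = False
    contributing: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "rb_scna_positive": self.rb_scna_positive,
            "other_scna_present": self.other_scna_present,
            "contributing": list(self.contributing),
            "arm_calls": [
                {"arm": a.arm, "direction": a.direction,
                 "median_log2": a.median_log2, "fraction_beyond": a.fraction_beyond}
                for a in self.arm_calls if a.direction != "neutral"
            ],
            "focal_events": [
                {"gene": f.gene, "direction": f.direction, "mean": f.segment_mean,
                 "length": f.segment_length, "deep": f.deep_flag}
                for f in self.focal_events
            ],
        }


def call_arm_events(
    seg: SegmentedProfile,
    gain_thresh: float = 0.2,
    loss_thresh: float = -0.2,
    min_fraction: float = 0.5,
) -> list[ArmCall]:
    """Call each chromosome arm gained/lost/neutral from segmented bin means.

    An arm is gained (lost) when at least ``min_fraction`` of its unmasked
    bins carry a segmented mean >= ``gain_thresh`` (<= ``loss_thresh``).
    Arms with no unmasked bins are returned neutral with ``no_data`` set.
    """
    grid = seg.grid
    labels = grid.arm_labels()
    calls: list[ArmCall] = []
    seen: set[str] = set()
    for label in labels:
        if label in seen:
            continue
        seen.add(label)
        vals = seg.seg_mean[labels == label]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            calls.append(ArmCall(label, "neutral", float("nan"), 0.0, 0, no_data=True))
            continue
        frac_gain = float(np.mean(vals >= gain_thresh))
        frac_loss = float(np.mean(vals <= loss_thresh))
        if frac_gain >= min_fraction and frac_gain >= frac_loss:
            direction, frac = "gain", frac_gain
        elif frac_loss >= min_fraction:
            direction, frac = "loss", frac_loss
        else:
            direction, frac = "neutral", max(frac_gain, frac_loss)
        calls.append(ArmCall(label, direction, float(np.median(vals)), frac, int(vals.size)))
    return calls


def detect_focal_events(
    seg: SegmentedProfile,
    gene_loci: Mapping[str, tuple[str, int, int]],
    focal_max_length: int = 10_000_000,
    gain_thresh: float = 0.5,
    loss_thresh: float = -0.5,
    deep_gain: float = 1.5,
    deep_loss: float = -1.0,
) -> list[FocalEvent]:
    """Find short high-amplitude segments overlapping the panel gene loci.

    Segments at least ``focal_max_length`` long are left to the arm caller.
    Genes on chromosomes absent from the grid are skipped.
    """
    events: list[FocalEvent] = []
    chrom_names = set(seg.grid.chrom_names)
    for gene, (chrom, gstart, gend) in gene_loci.items():
        if chrom not in chrom_names:
            continue
        sub = seg.segments[seg.segments["chrom"] == chrom]
        for _, row in sub.iterrows():
            length = int(row["end"] - row["start"])
            if length >= focal_max_length:
                continue
            if row["end"] <= gstart or row["start"] >= gend:
                continue
            mean = float(row["mean"])
            if mean >= gain_thresh:
                events.append(FocalEvent(gene, "gain", mean, length,
                                         deep_flag=mean >= deep_gain,
                                         chrom=chrom, start=int(row["start"]),
                                         end=int(row["end"])))
            elif mean <= loss_thresh:
                events.append(FocalEvent(gene, "loss", mean, length,
                                         deep_flag=mean <= deep_loss,
                                         chrom=chrom, start=int(row["start"]),
                                         end=int(row["end"])))
    return events


def classify_rb_signature(
    arm_calls: list[ArmCall], focal_events: list[FocalEvent]
) -> ScnaCallSet:
    """Combine arm and focal calls into the RB-SCNA signature verdict.

    Positive iff at least one signature arm event (1q/2p/6p gain, 13q/16q
    loss) or a focal RB1 loss / MYCN gain is present.  Any non-signature
    arm gain/loss sets ``other_scna_present`` instead.
    """
    contributing: list[str] = []
    other = False
    for call in arm_calls:
        if call.direction == "neutral":
            continue
        if (call.arm, call.direction) in RB_SIGNATURE_ARMS:
            contributing.append(f"{call.arm} {call.direction}")
        else:
            other = True
    for ev in focal_events:
        if (ev.gene, ev.direction) in {("RB1", "loss"), ("MYCN", "gain")}:
            deep = " (deep)" if ev.deep_flag else ""
            contributing.append(f"focal {ev.gene} {ev.direction}{deep}")
    return ScnaCallSet(
        arm_calls=arm_calls,
        focal_events=focal_events,
        rb_scna_positive=bool(contributing),
        other_scna_present=other,
        contributing=contributing,
    )
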