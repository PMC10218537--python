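# Methods

## Scope and model

`rbliquid` analyzes paired liquid-biopsy samples from retinoblastoma (RB)
eyes — aqueous humor (AH) cfDNA and tumor tissue — for two classes of
somatic alteration from a single targeted-sequencing assay:

* **somatic copy-number alterations (SCNAs)**, profiled from reads binned
  genome-wide (off-target reads in targeted mode; all reads in low-pass
  WGS mode), and
* **single-nucleotide variants (SNVs)** in the panel genes *RB1*, *BCOR*,
  *CREBBP* and *MYCN*, consumed as upstream calls with per-site depths.

The sample model throughout is a two-population mixture: a fraction `tf`
(tumor fraction) of the DNA derives from tumor cells carrying copy number
`cn_t(x)` at locus `x`, the rest from diploid normal cells. Expected
relative coverage of a bin is therefore `(tf·cn_t + (1−tf)·2)/2`, and the
expected variant allele fraction (VAF) of a clonal variant at multiplicity
`m` is

```
somatic:   VAF = tf·m / (tf·cn_t + (1−tf)·2)
germline:  VAF = (tf·m + (1−tf)) / (tf·cn_t + (1−tf)·2)
```

with the germline baseline heterozygous (1 of 2 alleles) in normal cells.
The denominator vanishes only for `tf = 1` with a homozygously deleted
locus; that case is reported as an undefined VAF rather than a number.
Both the simulator and the qualitative expectations the tests assert
(e.g. AH VAF > tumor VAF whenever the AH is purer) follow from these two
formulas. Subclonal structure is deliberately out of scope: one tumor
clone, one `tf` per sample.

## Copy-number profiling

Reads are assigned to bins by midpoint (0-based, half-open bins; the last
bin of a chromosome is truncated). In targeted mode, reads whose midpoint
falls within a probe interval padded by 500 bp on both sides are removed
first: hybrid-capture pulldown enriches probe flanks, and the off-target
remainder approximates a uniform low-pass sample of the genome. The
default grid uses 500-kb bins; a "wgs" convention of ~5000 equal-width
bins over the genome is equally supported (equal-width, not
equal-mappability — mappability tracks are an external dependency this
package avoids).

GC bias is removed by dividing each bin count by a LOWESS curve (span 0.3)
fitted through median counts in 1%-GC strata; medians make the fit robust
to the copy-altered minority of bins, and the output is rescaled to
preserve the overall median. Bins with GC outside the fitted support are
masked. The per-bin statistic is `log2(sample/control)` against a
copy-neutral female gDNA control profile normalized the same way,
median-centered over unmasked autosomal bins. The X chromosome is retained
(female control); Y is excluded throughout.

## Segmentation (CBS)

Segmentation is a from-scratch circular binary segmentation: on each
chromosome, the arc `[i, j)` of the circularized bin sequence maximizing
the two-sample |t| between arc and complement is found exhaustively
(prefix-sum scan over all admissible arcs; ties broken by smallest `i`,
then smallest `j`), and accepted when its within-chromosome permutation
p-value is below `alpha`. Accepted splits recurse on the pieces. Arcs are
admissible only when the arc and every nonempty flank hold at least
`min_width` bins, so no output segment falls below the width floor.

Numerical details:

* Zero pooled variance (noise-free steps) yields infinite |t|, handled
  explicitly; a constant sequence yields t = 0 and no split.
* The permutation test permutes bin values within the chromosome under
  test, one seeded generator stream per chromosome, so results do not
  depend on evaluation order. Permutations are *curtailed*: sampling stops
  as soon as the exceedance count already guarantees p ≥ alpha, which is
  decision-identical to running all permutations.
* Defaults: `alpha = 0.01`, `n_perm = 1000`, `min_width = 3`,
  `undo_sd = 3` — the common defaults for this algorithm family; all are
  exposed in configuration. Long recovery experiments in this repository
  use `n_perm = 250`, which still resolves p-values well below 0.01.

Pruning merges adjacent segments whose mean difference is below
`undo_sd` × the pooled within-segment noise SD, repeatedly to a fixpoint.
The noise SD is estimated robustly as `MAD(within-segment first
differences) / (0.6745·√2)`. A moment-based SD was tried first and proved
self-defeating: once a low-amplitude merge leaves a step inside a
segment, its moment SD inflates and subsequent merges cascade until
genuine deep focal events are absorbed. The difference-based MAD stays
anchored to bin-level noise regardless of how heterogeneous a segment has
become.

A practical consequence of `undo_sd = 3` at shallow depth (~100
reads/bin, per-bin log2 noise ≈ 0.25–0.35): single-arm events of moderate
amplitude (|log2| ≈ 0.2–0.5) are often merged back into whole-chromosome
segments. The arm caller then sees the merged chromosome mean, which
still crosses the ±0.2 call threshold when the altered arm dominates the
chromosome, but arm-level resolution is reduced — at this noise level the
undo rule trades resolution for stability, exactly as it does in standard
practice. Deep focal events (|log2| ≳ 1) always survive.

## Concordance statistic

Two segmented profiles on the same grid are compared by dividing their
segmented means on the linear copy-ratio scale, `r = 2^(mean_num −
mean_den)`. A bin is concordant iff `0.8 ≤ r ≤ 1.2` (values exactly on
the boundary are concordant; discordance is strictly outside the band).
The score is the bin-width-weighted mean of the indicator over bins
unmasked in both profiles — "normalized for size" is read as width
weighting, so truncated end-of-chromosome bins count proportionally — and
lies in [0, 1].

The band brackets 1 multiplicatively but is not symmetric under
inversion (1/0.8 ≠ 1.2), so the orientation (which profile is the
numerator) is part of the statistic and is always stated: targeted/WGS
and tumor/AH in this package. Denominator bins implying essentially zero
copy number (linear ratio < 2⁻⁶) are masked rather than producing
unstable ratios. Y-chromosome bins are excluded; X is compared.

## SCNA calls and the RB-SCNA signature

Manual inspection of segmented profiles is replaced by explicit rules,
all exposed in configuration:

* **Arm calls**: an arm is gained (lost) when ≥ 50% of its unmasked bins
  carry segmented mean ≥ +0.2 (≤ −0.2); the arm median is reported. Arms
  without data are neutral with a flag.
* **Focal events**: a segment shorter than 10 Mb overlapping a panel-gene
  locus with mean ≥ +0.5 (≤ −0.5) is a focal gain (loss); means beyond
  +1.5 / −1.0 set the "deep" flag (amplification / biallelic-loss
  amplitude). Whole-arm events exceed the length gate and are left to the
  arm caller.
* **Signature**: the recurrent RB alteration set is {1q gain, 2p gain,
  6p gain, 13q loss, 16q loss}; a case is RB-SCNA positive when at least
  one signature arm event or a focal RB1 loss / MYCN gain is present.
  Other recurrent arms (17q, 7q, 20q, …) are reported as ordinary calls
  and set `other_scna_present` without flipping the signature verdict.

Gene loci and arm boundaries for hg19 ship as a small table (UCSC
cytoband/RefSeq-derived, acen-midpoint centromeres); scaled synthetic
genomes carry proportionally scaled loci.

## Variant QC and pairing

VAF is alt depth / total depth, undefined at zero depth. The QC gate is
`total_depth ≥ 10`: depths of 7 or 9 reads fail, 10 passes. Failing
records are retained with `qc_pass = False`, never silently dropped. AH
and tumor call sets are outer-joined on (chrom, pos, ref, alt)
(multi-allelic records are split first); a side counts as present only
with a QC-passing record. Two downstream rules mirror how low-depth
observations are adjudicated clinically:

* a QC-failing observation backed by independent evidence (e.g. the same
  variant at high depth in a diagnostic sample) is **rescued** and counted
  as present;
* a QC-failing observation with no cross-sample support is **discarded**
  from summaries.

Germline sites (known from a separate blood test) are confirmed per
sample iff present with passing QC.

## Synthetic data: what it emulates, what it does not

The generator produces paired AH/tumor samples from one shared truth:
per-bin expected counts follow the mixture model above times a
multiplicative quadratic GC bias (mean-normalized to 1, invertible by the
normalizer), with negative-binomial noise. Defaults: 100 reads/bin
(low-pass regime), NB size 150 (variance/mean ≈ 1.7 at that depth —
the modest overdispersion typical of GC-corrected 500-kb cfDNA bins;
`dispersion = inf` gives the exact Poisson limit used in closed-form
tests). Variant reads are binomial draws at the model VAF, with NB site
depths (mean 200). Default tumor fractions are 0.75 (AH) vs 0.35
(tumor): the literature reports no numeric values, and these encode the
qualitative observation that tumor biopsies of treated, often necrotic
eyes carry substantial normal-cell contamination while AH is an enriched
tumor-DNA source. All randomness flows from explicit seeds; identical
configuration gives bit-identical output.

The default scaled genome keeps 22 autosomes + X with hg19-proportional
lengths shrunk to 1 Gb (≈ 2000 half-megabase bins), so whole-genome runs
take well under a minute; the full-size hg19 grid is equally
constructible. The canonical test scenario plants the five signature arms
(gains at copy 3, losses at copy 1) plus a 5-bin MYCN amplification
(copy 10) inside the gained 2p and a 5-bin biallelic RB1 deletion inside
the lost 13q.

Not emulated: fragment-size distributions, read-level artifacts,
mappability/blacklist structure, replication timing, subclonal mixtures,
sequencing-error-driven false variant calls. Passing recovery tests
therefore demonstrates correctness of the statistical pipeline under the
stated mixture model, not robustness to every artifact of real
libraries.

## Experiment sizes

The recovery experiments in `tests/test_acceptance.py` and
`scripts/acceptance.py` use: 2000-bin scaled genomes at 100 reads/bin for
signature recovery (200 replicates in the test suite, 50 in the script);
200-bin single-chromosome profiles (step 1.0, noise SD 0.2) for
changepoint recovery; 100-bin pure-noise profiles for type-I control
(200 seeds); 10,000 sites × depth 200 for VAF recovery; and a ~600-bin
genome over 50 seeds for the concordance-vs-tumor-fraction sweep. These
sizes make every experiment reproducible on a single CPU in minutes while
keeping Monte-Carlo error well inside the asserted margins.

## Known limitations

* Concordance has no significance model — it is a descriptive statistic,
  as in the underlying methodology.
* Arm-level resolution at shallow depth is limited by the undo rule (see
  above); lowering `undo_sd` recovers resolution at the cost of
  occasional oversegmentation.
* The VAF model assumes clonal variants; subclonal fractions would need
  an extra multiplicity parameter per sample.
* Equal-width WGS bins ignore mappability variation; real data with
  strong mappability structure should be pre-filtered upstream.
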