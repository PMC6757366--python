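# barrierseq

ChIP-seq downstream analysis of condition-dependent CTCF occupancy and
chromatin barrier function: peak classification by motif vs repeat
content, condition-exclusive peak algebra, flank signal/AUC statistics,
and an upstream–downstream histone-mark asymmetry caller — together with
a synthetic-data generator that plants known barrier asymmetries so
every stage can be validated against ground truth.

## Who this is for

CTCF partitions the genome into domains and can act as a chromatin
barrier: a site separating flanking regions with contrasting histone
methylation (e.g. H3K9me3). When a cofactor is perturbed (here a control
vs knockdown design, "CT" vs "KD"), CTCF occupancy can shift between
repeat-derived binding sites and canonical sequence motifs, and barrier
activity can be lost or gained at individual sites. `barrierseq` is for
analysts who have peak sets (BED), coverage tracks (bedGraph), repeat
annotations and motif models, and want a tested, deterministic
implementation of the downstream inference.

## The core statistic

For a peak with flanking windows of *w* bases (default 10 kb) abutting
its edges, and a coverage track of one histone mark, let `up` and `down`
be the total signal left and right of the peak (genome orientation).
With pseudocount 1:

    M = log2(up + 1) − log2(down + 1)
    A = (log2(up + 1) + log2(down + 1)) / 2
    ΔM = M(KD) − M(CT)

A CT-exclusive peak is called a barrier **LOSS** when `|M_CT| > t_M` and
`|ΔM| > t_ΔM`; a KD-exclusive peak is a **GAIN** when `|M_KD| > t_M` and
`|ΔM| > t_ΔM`. Default thresholds per mark: H3K9me3 1.5/1.5, H3K4me3
2/2, H3K27me3 1/1. Calls are fixed-threshold classifications; no
p-values or multiple-testing corrections are involved.

Around the caller sit the supporting stages: PWM log-odds scanning of
peak sequences on both strands (overlapping hits counted, tandem 2×
pairs at any spacing), MOTIF_ONLY / REPEAT_ONLY / OTHER classification,
bedtools-style exclusive/shared peak sets at a configurable overlap
fraction, deepTools-style binned flank matrices with AUC differences,
read-density distributions, per-sample correlation, and RNA asymmetry
across called barriers versus matched controls.

## Worked example

```sh
python examples/04_call_barriers.py
```

builds a 1.5 Mb synthetic landscape (60 peaks, 15 planted barrier-loss
and 5 barrier-gain sites with |M| = 2.5) and calls barriers:

```
call
NONE    60
LOSS    15
GAIN     5

      peak   m_ct   m_kd  delta_m exclusive_set call
peak_00002  2.507 -0.010   -2.517            CT LOSS
peak_00003 -2.478 -0.006    2.472            CT LOSS
...
20/20 calls match the planted truth (20 barriers planted)
RNA |log2 up/down|: barriers median=2.50  controls median=0.01  p=3.39e-06
```

Measured M at planted sites recovers the planted ±2.5 asymmetry to
within Poisson sampling error (~0.01 at 5 reads/base over 10 kb), every
call matches the truth table, and RNA asymmetry across the loss sites is
strongly elevated over matched non-barrier controls. The other examples
(`01`–`03`) show dataset generation, the motif/repeat classification
with its repeat-to-motif occupancy shift, and flank profiles/ΔAUC.

A thin CLI covers the two batch stages:

```sh
barrierseq simulate --outdir out/ --seed 1
barrierseq barrier --peaks-ct peaks_CT.bed --peaks-kd peaks_KD.bed \
    --track-ct h3k9me3_ct.bedGraph --track-kd h3k9me3_kd.bedGraph \
    --chrom-sizes chrom.sizes --mark H3K9me3 --flank 10000 --out barriers
```

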