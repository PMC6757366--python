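# Methods

## Coordinate model and interval engine

All coordinates are 0-based half-open (BED convention) throughout; any
1-based rendering would be a display concern and none is needed. Peaks,
repeats and domains are `GenomicInterval`s inside an overlap-indexed
`IntervalSet` (interval trees per chromosome); every overlap, subtract
and closest-distance result is contractually identical to a quadratic
brute-force scan, and the test suite enforces this on random instances,
with `bedtools` as an additional independent oracle on a small fixture.
Closest distances are measured between nearest edges (0 for overlapping
pairs) or between midpoints; note that `bedtools closest -d` counts a
bookended pair as distance 1 whereas this package reports the pure gap
(bookended = 0). Records with no partner on the chromosome carry the
sentinel distance −1.

Coverage is a dense float64 array per chromosome (`CoverageTrack`), read
from 4-column bedGraph with overlapping records rejected as ambiguous.
Querying outside chromosome bounds is an error; all flank-window
policies (drop vs clip) live in the callers. Dense storage is a
deliberate simplification: the package targets desk-scale genomes (tens
of Mb); at 5 Mb/chromosome a full five-track two-condition dataset is
~400 MB of RAM.

## Motif scanning

PWMs are probability matrices over ACGT with a background model, parsed
from MEME minimal format (hand-written reader/writer, ~40 lines; no
installed library parses this dialect reliably). Scores are log2 odds in
bits after adding a pseudo-probability of 1e−3 per cell (FIMO-like), so
the consensus attains the maximum score and zeros never produce −∞.
Scanning reports every window on both strands scoring at or above the
threshold — overlapping occurrences retained, counts from the two
strands combined; windows containing N are skipped, not scored. Hit
coordinates are genome coordinates of the window regardless of strand.
Tandem (2×) search forms all unordered pairs of single hits within a
sequence, any spacing and strand combination, so k hits give k(k−1)/2
pairs. There is no universal score threshold for a PWM; the default is
80% of the consensus score, which for the high-information synthetic
motif is effectively consensus-only and recovers every planted instance.
Column shuffling draws a never-identity permutation of positions,
preserving per-column weights and total information content — the
classic specificity control. Equivalence with per-window rescoring and
with Biopython's PSSM scores is enforced in tests.

## Peak classification

A peak is MOTIF_ONLY iff it has ≥ 1 motif hit and zero repeat-overlap
bases; REPEAT_ONLY iff it has 0 hits and ≥ `min_repeat_bases` (default
1) of repeat overlap; everything ambiguous — both features or neither —
is OTHER. The three classes partition any peak set by construction.
Repeat classes follow the RepeatMasker vocabulary (LINE, SINE, LTR, DNA,
Simple_repeat, other) read from the BED name field (`class` or
`class/family`); same-class overlapping records are merged before
counting so no base is double-counted within a class.

## Exclusive-peak algebra

A peak of set A is *shared* iff at least `min_overlap_fraction` of its
own length is covered by peaks of B (merged across partners), else
A-exclusive; symmetric for B. The default fraction is 1e−9 — the
bedtools any-overlap default — because a stricter criterion would be an
undocumented assumption; the parameter is exposed everywhere. Strand is
ignored; a peak's "center" is floor((start+end)/2). Domain-level
counting assigns a peak to a domain iff its midpoint lies inside it,
with an explicit outside-bucket so totals are conserved.

## Flank profiles and AUC

`flank_profile` re-implements the computeMatrix contract: windows of
±`flank_bases` around the anchor midpoint (or around the anchor start in
boundary mode, or around a body rescaled to a fixed length in
scaled-region mode), binned at `bin_bases`, bin value = **mean** per-base
signal (deepTools default; not the sum). Anchors whose window overruns a
chromosome end are dropped, not zero-padded — padding would deflate
column means — and counted. AUC is the column-mean profile summed and
multiplied by bin width, so units are read·bases and
ΔAUC(a,b) = −ΔAUC(b,a) exactly. No depth normalization is applied by
default (the magnitudes are therefore library-size dependent); a
counts-per-million rescale can be applied to the tracks by the caller
before profiling. Typical bin defaults follow the use case: 10 bp bins
for 1 kb peak flanks, 1 kb bins for 50 kb domain-boundary flanks.

Read-density distributions tile the genome into fixed bins (partial tail
bins excluded), sample uniformly without replacement, and always report
the zero class, so read-free regions are visible. Sample correlation is
Pearson r on per-bin sums over the shared tiling; a zero-variance track
yields missing values rather than an arbitrary number.

## The barrier caller

Flank counts sum the track over `[start−w, start)` and `[end, end+w)` —
windows abut the peak edges and exclude the peak body. Peaks whose
windows cross a chromosome end are dropped (logged), again to avoid
asymmetric truncation masquerading as signal. M, A and ΔM are as defined
in the README; the pseudocount is 1 read, chosen so empty flanks give
M = 0 against other empty flanks and remain finite against any count.

Call logic: only condition-exclusive peaks are candidates; the |M|
condition is evaluated in the condition where the peak is actually
CTCF-bound (CT for LOSS candidates, KD for GAIN). Both conditions use
magnitudes: barrier asymmetry in either genomic direction qualifies,
since planted and real asymmetries are two-sided. Swapping the
conditions exactly exchanges LOSS and GAIN sets, and raising either
threshold is monotone non-increasing in the number of calls — both are
enforced as tests. Sign concordance between the CTCF change and the
histone change is *not* required, and no per-track depth scaling is
applied by default (an optional scale factor per condition exists).

`rna_asymmetry` compares per-site |log2(up/down)| RNA signal between
called barrier sites and an equal-size control set sampled from
NONE-call peaks, using a two-sided Wilcoxon rank-sum (Mann–Whitney U)
test — exact when sample sizes permit and there are no ties. A paired
test was considered and rejected: there is no natural pairing between
unrelated genomic sites, and under label exchangeability the rank-sum
test is already a permutation test, which is what makes the null
calibration check (type-I ≈ nominal under label permutation) exact. An
all-tied degenerate input reports statistic 0 and p = 1.

## The synthetic-data generator

The generator is first-class, tested code and defines the study
conditions. Defaults (the reference landscape): 2 chromosomes × 5 Mb,
2000 control-condition peaks split 0.4/0.3/0.3 into motif/repeat/other,
occupancy shift 0.5 — half of the repeat peaks are CT-exclusive, matched
one-for-one by new KD-exclusive motif peaks, giving 2300 distinct peaks
(300 exclusive on each side) — 200 planted LOSS + 100 planted GAIN
barriers with |M| = 2.5 on H3K9me3, Poisson background 5 reads/base,
peak enrichment +20 reads/base, peak widths N(400, 50²) clipped, 10 kb
flanks. The planted |M| = 2.5 is a free modeling choice (thresholds, not
magnitudes, are prescribed); 2.5 sits comfortably above the 1.5
threshold while remaining in the range real M distributions span.

Layout: every feature (peak, decoy repeat, decoy motif) occupies a
non-overlapping slot; slots are assigned to chromosomes with probability
proportional to remaining capacity and separated by multinomially
distributed random gaps, which guarantees non-overlap in one pass and
raises a capacity error when the requested density cannot fit. Barrier
peaks get wide slots (2·(flank + 500) + max peak width) so their flank
windows are free of other peaks' steps; an edge margin of flank + 2 kb
keeps every window inside the chromosome. Sequence is i.i.d. uniform
ACGT with the motif consensus written at recorded positions on a random
strand; repeat-class peaks are wrapped in a LINE or SINE interval
extending 100–1200 bases beyond the peak.

Noise is Poisson per base — the minimal read-count model; no fragment
structure, GC bias or dispersion beyond Poisson is simulated. The
H3K9me3 asymmetry is a step exactly at the peak center: the rate is
multiplied by 2^(+M/2) on one side and 2^(−M/2) on the other across the
peak's whole slot, so the planted log2 up/down ratio is exactly ±M
(sign drawn per site and recorded) and the geometric-mean rate is
unchanged. LOSS barriers carry the step in CT with flat KD flanks, GAIN
the reverse. The RNA rate is background × 2^(−coupling · s), where s is
the CT H3K9me3 log2 multiplier field — transcript asymmetry mirrors the
repressive mark inversely and deterministically in rate (a z-score
standardization of the local mark level was considered and rejected: on
a landscape where the multiplier field is piecewise constant it reduces
to the same field up to an unstable affine factor). All randomness comes
from named child streams of a single `SeedSequence`, so one seed gives
bit-identical FASTA/BED/bedGraph/TSV outputs across runs and platforms.

What the generator does *not* emulate — mappability, repeat-induced
multi-mapping artifacts, fragment-length smoothing, copy-number
variation, correlated marks — bounds what passing tests show: they
validate the inference machinery against its own model assumptions, not
robustness to real-data artifacts.

## Problem sizes and calibration checks

Parameter-recovery runs use the full reference landscape over seeds
1–10 (mean sensitivity ≥ 0.95, mean FDR ≤ 0.05 against the truth table;
in practice both are ~1.0 and ~0.005). At 5 reads/base over 10 kb flanks
the Poisson sampling error of M is ~0.011 (1 sd), so a planted 2.5 is
measured within ±0.05 essentially always; the rare false positive is a
NONE exclusive peak squeezed between two barrier slots whose flanks
straddle opposite step directions. Null-calibration series (planted
|M| = 0: call rate ≤ 0.01/peak over 200 replicates; RNA-test type-I
≤ 0.07 at nominal 0.05 over 200 label permutations) run on a
scaled-down landscape (1 chromosome × 1 Mb, 40 control peaks) — the
statistics and code paths are identical to full scale and the checks
are distributional, so the smaller landscape is a pure efficiency
choice.

## Known limitations

- Dense coverage arrays cap practical genome size at tens of Mb.
- No p-value calibration of motif scores (no claimed equivalence to any
  scanner's p < 1e−4 default); thresholds are score-fraction based.
- ΔAUC magnitudes are depth-dependent; normalize tracks first if
  comparing across libraries.
- The barrier caller's thresholds are fixed per mark, not adaptive; the
  M statistic ignores within-flank spatial structure by design.
- BigWig input/output and BAM parsing are out of scope; convert to
  bedGraph upstream.
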