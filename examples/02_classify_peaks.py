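"""Classify peaks by motif vs repeat content and summarize the shift.

Scans each peak's sequence with the CTCF-like PWM on both strands
(overlapping occurrences counted), overlaps peaks with the repeat
annotation, and assigns MOTIF_ONLY / REPEAT_ONLY / OTHER. With an
occupancy shift planted, the KD peak set is motif-richer and
repeat-poorer than CT.
"""

from collections import Counter

from barrierseq import SyntheticConfig, classify_peaks, peak_summary, simulate
from barrierseq.motifs import count_hits_per_interval, scan_tandem

config = SyntheticConfig(
    n_chroms=1, chrom_length=1_500_000, n_peaks=60,
    fraction_motif_peaks=0.3, fraction_repeat_peaks=0.5, fraction_other=0.2,
    occupancy_shift=0.8, n_barrier_loss=15, n_barrier_gain=5,
    n_decoy_repeats=5, n_decoy_motifs=5, seed=11,
)
ds = simulate(config)
land = ds.landscape
threshold = land.pwm.default_threshold()  # 80% of the consensus score

for cond in ("CT", "KD"):
    peaks = ds.peaks[cond]
    hits = count_hits_per_interval(land.sequences, peaks, land.pwm, threshold)
    classes = Counter(
        c.klass.value for c in classify_peaks(peaks, hits, land.repeats)
    )
    tandem = sum(
        len(scan_tandem(land.sequences[p.chrom][p.start:p.end], land.pwm,
                        threshold))
        for p in peaks
    )
    row = peak_summary(peaks, hits, land.repeats, tandem_count=tandem,
                       sample=cond).iloc[0]
    print(f"{cond}: {dict(classes)}")
    print(f"    motifs/peak={row.motifs_per_peak:.3f}  "
          f"repeat fraction={row.repeat_fraction:.3f}  "
          f"tandem pairs={row.tandem_motif_pairs}")

print()
print("KD shows more motifs per peak and less repeat content than CT —")
print("the planted repeat-to-motif occupancy shift, recovered from sequence")
print("and annotation alone.")
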