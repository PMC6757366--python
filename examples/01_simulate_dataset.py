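"""Generate a small synthetic dataset with planted ground truth.

Builds a 1.5 Mb single-chromosome landscape with repeat- and motif-borne
CTCF peaks, a repeat-to-motif occupancy shift between the CT (control)
and KD (knockdown) conditions, and planted H3K9me3 barrier asymmetries,
then writes every file the analysis consumes plus the truth table.
"""

from barrierseq import SyntheticConfig, simulate, write_outputs

config = SyntheticConfig(
    n_chroms=1,
    chrom_length=1_500_000,
    n_peaks=60,
    fraction_motif_peaks=0.3,
    fraction_repeat_peaks=0.5,
    fraction_other=0.2,
    occupancy_shift=0.8,     # 80% of repeat peaks are CT-exclusive
    n_barrier_loss=15,       # H3K9me3 step present in CT, flat in KD
    n_barrier_gain=5,        # the reverse
    n_decoy_repeats=5,
    n_decoy_motifs=5,
    seed=11,
)
dataset = simulate(config)
write_outputs(dataset, "scratch/example_dataset")

print(f"peaks: CT={len(dataset.peaks['CT'])}  KD={len(dataset.peaks['KD'])}")
print("truth table:")
print(dataset.truth.groupby(["membership", "class", "barrier"]).size())
print()
print("Each row counts distinct peaks by condition membership, motif/repeat")
print("class and planted barrier status; 'both' peaks are shared between")
print("conditions, CT/KD rows are condition-exclusive.")
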