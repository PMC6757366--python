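"""Call chromatin-barrier changes from H3K9me3 flank asymmetries.

For every peak, H3K9me3 signal is summed in the 10 kb flanks on either
side and converted to M = log2(up) - log2(down) per condition. A
CT-exclusive peak with |M_CT| > 1.5 and |dM| > 1.5 is a barrier LOSS; a
KD-exclusive peak with |M_KD| > 1.5 and |dM| > 1.5 is a GAIN. RNA signal
asymmetry across the LOSS sites is then compared with matched controls.
"""

from barrierseq import SyntheticConfig, rna_asymmetry, simulate
from barrierseq.barrier import BarrierCall, barrier_pipeline, records_table

config = SyntheticConfig(
    n_chroms=1, chrom_length=1_500_000, n_peaks=60,
    fraction_motif_peaks=0.3, fraction_repeat_peaks=0.5, fraction_other=0.2,
    occupancy_shift=0.8, n_barrier_loss=15, n_barrier_gain=5,
    n_decoy_repeats=5, n_decoy_motifs=5, seed=11,
)
ds = simulate(config)
sets, records = barrier_pipeline(
    ds.peaks["CT"], ds.peaks["KD"],
    ds.tracks["H3K9me3_CT"], ds.tracks["H3K9me3_KD"],
    mark="H3K9me3", flank_bases=config.flank_bases,
)
table = records_table(records)
print(table["call"].value_counts().to_string())
print()
called = table[table.call != "NONE"]
print(called[["peak", "m_ct", "m_kd", "delta_m", "exclusive_set", "call"]]
      .head(8).round(3).to_string(index=False))

truth = dict(zip(ds.truth.peak, ds.truth.barrier))
tp = sum(1 for _, r in called.iterrows() if truth[r.peak] == r.call)
print(f"\n{tp}/{len(called)} calls match the planted truth "
      f"({(ds.truth.barrier != 'NONE').sum()} barriers planted)")

rna = rna_asymmetry(records, ds.tracks["RNA"], config.flank_bases,
                    calls=("LOSS",), seed=0)
print(f"RNA |log2 up/down|: barriers median={rna.median_barrier:.2f}  "
      f"controls median={rna.median_control:.2f}  p={rna.pvalue:.2e}")
print()
print("M magnitudes near the planted 2.5 at called sites, near 0 elsewhere;")
print("transcript asymmetry mirrors the H3K9me3 step at CT barriers.")
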