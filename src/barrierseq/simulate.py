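"""Synthetic genome, peak and coverage simulator with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage can be tested against a known answer:

* a miniature genome of i.i.d. uniform sequence with non-overlapping
  labeled repeats (LINE/SINE) and embedded motif instances on both
  strands;
* condition-specific peak sets (CT = control, KD = knockdown) in which a
  configurable fraction of repeat-borne peaks is CT-exclusive while an
  equal number of new motif-borne peaks is KD-exclusive — the
  repeat-to-motif occupancy shift;
* Poisson read coverage: a flat background rate everywhere plus extra
  enrichment inside that condition's peaks (CTCF track);
* step-function H3K9me3 asymmetries across designated barrier peaks:
  the per-base rate is multiplied by 2^(+M/2) upstream and 2^(-M/2)
  downstream of the peak center (sign random, recorded), across the full
  flank window, so the planted log2 upstream/downstream ratio is exactly
  the configured |M|. LOSS barriers carry the step in CT with flat KD
  flanks; GAIN barriers the reverse;
* an RNA track whose local rate is 2^(-rna_coupling * s) where s is the
  log2 H3K9me3 rate multiplier in CT, so transcript asymmetry mirrors
  the planted H3K9me3 asymmetry at CT barriers;
* a truth table recording, per distinct peak, its condition membership,
  class, barrier status and planted M values.

Identical seeds give bit-identical outputs: every randomness source is a
named child stream of one ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import CoverageTrack, Genome, GenomicInterval, IntervalSet
from . import io as bio
from .motifs import PWM, reverse_complement, write_meme_pwm

__all__ = [
    "SyntheticConfig",
    "Landscape",
    "SyntheticDataset",
    "DEFAULT_CTCF_PWM",
    "simulate_landscape",
    "simulate_peaks_and_coverage",
    "simulate",
    "write_outputs",
]

MARKS = ("CTCF", "H3K4me3", "H3K9me3", "H3K27me3")
CONDITIONS = ("CT", "KD")

# fixed spawn order of RNG streams; changing this changes every output
_STREAMS = (
    "layout", "sequence", "widths", "signs",
    "CTCF_CT", "CTCF_KD", "H3K4me3_CT", "H3K4me3_KD",
    "H3K9me3_CT", "H3K9me3_KD", "H3K27me3_CT", "H3K27me3_KD", "RNA",
)


def _rng_streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


def _default_pwm() -> PWM:
    """A strong 15-bp CTCF-like motif (dominant base 0.97 per position)."""
    consensus = "CCACCAGGGGGCGCT"
    probs = np.full((len(consensus), 4), 0.01)
    for i, b in enumerate(consensus):
        probs[i, "ACGT".index(b)] = 0.97
    return PWM(name="CTCF_synthetic", probs=probs)


DEFAULT_CTCF_PWM = _default_pwm()


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic landscape.

    Defaults describe the reference simulation: 2 chromosomes of 5 Mb,
    2000 control-condition peaks split 0.4/0.3/0.3 into motif-only /
    repeat-only / other, an occupancy shift of 0.5 (half of the repeat
    peaks are CT-exclusive, matched by new KD-exclusive motif peaks),
    200 planted barrier-loss and 100 barrier-gain sites with |M| = 2.5
    on H3K9me3, Poisson background of 5 reads/base and peak enrichment
    of 20 reads/base, and 10 kb flank windows.
    """

    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_peaks: int = 2000
    fraction_motif_peaks: float = 0.4
    fraction_repeat_peaks: float = 0.3
    fraction_other: float = 0.3
    occupancy_shift: float = 0.5
    peak_width_mean: float = 400.0
    peak_width_sd: float = 50.0
    background_rate: float = 5.0
    peak_enrichment: float = 20.0
    n_barrier_loss: int = 200
    n_barrier_gain: int = 100
    planted_abs_M: float = 2.5
    rna_coupling: float = 1.0
    flank_bases: int = 10_000
    line_fraction: float = 0.6
    n_decoy_repeats: int = 100
    n_decoy_motifs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.fraction_motif_peaks + self.fraction_repeat_peaks + self.fraction_other
        if total > 1 + 1e-9:
            raise ValueError("peak class fractions must sum to <= 1")
        if not (0 <= self.occupancy_shift <= 1):
            raise ValueError("occupancy_shift must be in [0, 1]")
        if self.planted_abs_M < 0:
            raise ValueError("planted_abs_M must be >= 0")
        if self.background_rate < 0 or self.peak_enrichment < 0:
            raise ValueError("rates must be non-negative")

    # derived composition of the peak scaffold
    @property
    def n_repeat_peaks(self) -> int:
        return round(self.n_peaks * self.fraction_repeat_peaks)

    @property
    def n_motif_peaks(self) -> int:
        return round(self.n_peaks * self.fraction_motif_peaks)

    @property
    def n_other_peaks(self) -> int:
        return self.n_peaks - self.n_repeat_peaks - self.n_motif_peaks

    @property
    def n_shifted(self) -> int:
        """CT-exclusive repeat peaks = KD-exclusive new motif peaks."""
        return round(self.n_repeat_peaks * self.occupancy_shift)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class _PeakSpec:
    """Internal scaffold entry tying a peak to its slot and planted truth."""

    name: str
    interval: GenomicInterval
    slot: tuple[str, int, int]
    klass: str                       # MOTIF_ONLY / REPEAT_ONLY / OTHER
    membership: str                  # CT / KD / both
    barrier: str = "NONE"            # LOSS / GAIN / NONE
    planted_m: float = 0.0           # signed planted M (H3K9me3)


@dataclass
class Landscape:
    """Output of :func:`simulate_landscape` plus the internal peak scaffold."""

    genome: Genome
    repeats: IntervalSet
    motif_placements: IntervalSet
    sequences: dict[str, str]
    pwm: PWM
    scaffold: list[_PeakSpec] = field(repr=False, default_factory=list)


@dataclass
class SyntheticDataset:
    """Everything the downstream pipeline consumes, plus the ground truth."""

    config: SyntheticConfig
    landscape: Landscape
    peaks: dict[str, IntervalSet]                  # per condition
    tracks: dict[str, CoverageTrack]               # "<MARK>_<COND>" and "RNA"
    truth: pd.DataFrame


# ---------------------------------------------------------------------------
# slot allocation


def _allocate_slots(
    config: SyntheticConfig, items: list[tuple[str, int]], rng: np.random.Generator
) -> list[tuple[str, int, int]]:
    """Place non-overlapping slots of given widths at random positions.

    *items* are (kind, width) pairs; returns (chrom, start, end) per item
    in the same order. Raises if the requested feature density exceeds
    chromosome capacity.
    """
    margin = config.flank_bases + 2000  # keep every flank window inside
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    capacity = {c: config.chrom_length - 2 * margin for c in chroms}
    if min(capacity.values()) <= 0:
        raise ValueError("chromosomes too short for the flank margin")
    order = rng.permutation(len(items))
    assignment: dict[str, list[int]] = {c: [] for c in chroms}
    remaining = dict(capacity)
    for idx in order:
        width = items[idx][1]
        open_chroms = [c for c in chroms if remaining[c] >= width]
        if not open_chroms:
            raise ValueError(
                "requested feature density exceeds chromosome capacity"
            )
        weights = np.array([remaining[c] for c in open_chroms], dtype=float)
        chrom = open_chroms[rng.choice(len(open_chroms), p=weights / weights.sum())]
        assignment[chrom].append(idx)
        remaining[chrom] -= width
    slots: list[tuple[str, int, int] | None] = [None] * len(items)
    for chrom in chroms:
        idxs = assignment[chrom]
        rng.shuffle(idxs)
        widths = [items[i][1] for i in idxs]
        free = capacity[chrom] - sum(widths)
        gaps = rng.multinomial(free, np.full(len(idxs) + 1, 1 / (len(idxs) + 1))) \
            if idxs else np.array([free])
        pos = margin
        for k, i in enumerate(idxs):
            pos += int(gaps[k])
            slots[i] = (chrom, pos, pos + widths[k])
            pos += widths[k]
    return slots  # type: ignore[return-value]


def _draw_width(config: SyntheticConfig, rng: np.random.Generator) -> int:
    w = rng.normal(config.peak_width_mean, config.peak_width_sd)
    return int(np.clip(w, 50, config.peak_width_mean + 4 * config.peak_width_sd))


# ---------------------------------------------------------------------------
# landscape


def simulate_landscape(config: SyntheticConfig) -> Landscape:
    """Generate genome sequence, repeat annotation and motif placements.

    Repeats are non-overlapping labeled intervals (classes LINE/SINE at
    ``line_fraction``); motif instances are written into the emitted
    sequence at recorded positions on a random strand; the sequence
    background is i.i.d. uniform over ACGT.
    """
    streams = _rng_streams(config.seed)
    layout, widths_rng = streams["layout"], streams["widths"]
    signs = streams["signs"]

    n_shift = config.n_shifted
    if config.n_barrier_loss > n_shift or config.n_barrier_gain > n_shift:
        raise ValueError(
            f"barrier sites ({config.n_barrier_loss} loss, "
            f"{config.n_barrier_gain} gain) must fit within the "
            f"{n_shift} condition-exclusive peaks on each side"
        )

    peak_max = int(config.peak_width_mean + 4 * config.peak_width_sd)
    barrier_slot = 2 * (config.flank_bases + 500) + peak_max
    plain_slot = peak_max + 400
    decoy_repeat_slot = 2600
    decoy_motif_slot = 200

    # scaffold composition, in a fixed deterministic order
    entries: list[tuple[str, str, str]] = []   # (klass, membership, barrier)
    for i in range(n_shift):
        barrier = "LOSS" if i < config.n_barrier_loss else "NONE"
        entries.append(("REPEAT_ONLY", "CT", barrier))
    for i in range(n_shift):
        barrier = "GAIN" if i < config.n_barrier_gain else "NONE"
        entries.append(("MOTIF_ONLY", "KD", barrier))
    entries += [("REPEAT_ONLY", "both", "NONE")] * (config.n_repeat_peaks - n_shift)
    entries += [("MOTIF_ONLY", "both", "NONE")] * config.n_motif_peaks
    entries += [("OTHER", "both", "NONE")] * config.n_other_peaks

    items: list[tuple[str, int]] = [
        ("peak", barrier_slot if b != "NONE" else plain_slot)
        for (_, _, b) in entries
    ]
    items += [("decoy_repeat", decoy_repeat_slot)] * config.n_decoy_repeats
    items += [("decoy_motif", decoy_motif_slot)] * config.n_decoy_motifs
    slots = _allocate_slots(config, items, layout)

    pwm = DEFAULT_CTCF_PWM
    motif_w = pwm.width
    scaffold: list[_PeakSpec] = []
    repeats: list[GenomicInterval] = []
    motifs: list[GenomicInterval] = []
    rep_counter = 0

    def _add_repeat(chrom: str, start: int, end: int) -> None:
        nonlocal rep_counter
        klass = "LINE" if signs.random() < config.line_fraction else "SINE"
        rep_counter += 1
        repeats.append(
            GenomicInterval(chrom, start, end, name=f"{klass}/rep{rep_counter}")
        )

    for i, ((kind, _), slot) in enumerate(zip(items, slots)):
        chrom, s0, s1 = slot
        if kind == "peak":
            klass, membership, barrier = entries[i]
            w = _draw_width(config, widths_rng)
            center = (s0 + s1) // 2
            iv = GenomicInterval(
                chrom, center - w // 2, center - w // 2 + w, name=f"peak_{i:05d}"
            )
            planted = 0.0
            if barrier != "NONE" and config.planted_abs_M > 0:
                sign = 1.0 if signs.random() < 0.5 else -1.0
                planted = sign * config.planted_abs_M
            scaffold.append(
                _PeakSpec(iv.name, iv, slot, klass, membership, barrier, planted)
            )
            if klass == "REPEAT_ONLY":
                ext_l = int(widths_rng.integers(100, 1200))
                ext_r = int(widths_rng.integers(100, 1200))
                _add_repeat(chrom, max(s0, iv.start - ext_l), min(s1, iv.end + ext_r))
            elif klass == "MOTIF_ONLY":
                m0 = iv.midpoint - motif_w // 2
                strand = "+" if signs.random() < 0.5 else "-"
                motifs.append(
                    GenomicInterval(chrom, m0, m0 + motif_w,
                                    name=pwm.name, strand=strand)
                )
        elif kind == "decoy_repeat":
            length = int(widths_rng.integers(300, decoy_repeat_slot - 100))
            _add_repeat(chrom, s0, s0 + length)
        else:  # decoy_motif
            strand = "+" if signs.random() < 0.5 else "-"
            m0 = (s0 + s1) // 2 - motif_w // 2
            motifs.append(
                GenomicInterval(chrom, m0, m0 + motif_w, name=pwm.name, strand=strand)
            )

    genome = Genome({f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)})

    # sequence: uniform background, motif consensus written at placements
    seq_rng = streams["sequence"]
    base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)
    sequences: dict[str, str] = {}
    per_chrom = {
        chrom: base_bytes[seq_rng.integers(0, 4, size=config.chrom_length)]
        for chrom in genome.chrom_names
    }
    consensus = pwm.consensus
    for m in motifs:
        word = consensus if m.strand == "+" else reverse_complement(consensus)
        per_chrom[m.chrom][m.start:m.end] = np.frombuffer(
            word.encode("ascii"), dtype=np.uint8
        )
    for chrom, arr in per_chrom.items():
        sequences[chrom] = arr.tobytes().decode("ascii")

    return Landscape(
        genome=genome,
        repeats=IntervalSet(repeats),
        motif_placements=IntervalSet(motifs),
        sequences=sequences,
        pwm=pwm,
        scaffold=scaffold,
    )


# ---------------------------------------------------------------------------
# peaks + coverage


def _h3k9me3_log2_multiplier(
    landscape: Landscape, condition: str
) -> dict[str, np.ndarray]:
    """Per-base log2 rate multiplier encoding the planted barrier steps."""
    fields = {
        c: np.zeros(landscape.genome.size(c)) for c in landscape.genome.chrom_names
    }
    active = {"CT": "LOSS", "KD": "GAIN"}[condition]
    for spec in landscape.scaffold:
        if spec.barrier != active or spec.planted_m == 0.0:
            continue
        chrom, s0, s1 = spec.slot
        center = spec.interval.midpoint
        half = spec.planted_m / 2.0
        fields[chrom][s0:center] += half       # upstream (left) side
        fields[chrom][center:s1] -= half       # downstream (right) side
    return fields


def simulate_peaks_and_coverage(
    config: SyntheticConfig, landscape: Landscape
) -> SyntheticDataset:
    """Draw condition peak sets, all coverage tracks and the truth table."""
    streams = _rng_streams(config.seed)
    genome = landscape.genome

    peaks = {
        cond: IntervalSet(
            spec.interval.with_name(spec.name)
            for spec in landscape.scaffold
            if spec.membership in (cond, "both")
        )
        for cond in CONDITIONS
    }

    tracks: dict[str, CoverageTrack] = {}
    for cond in CONDITIONS:
        # CTCF: flat background + enrichment inside this condition's peaks
        rng = streams[f"CTCF_{cond}"]
        vals = {}
        for chrom in genome.chrom_names:
            lam = np.full(genome.size(chrom), config.background_rate)
            for iv in peaks[cond]:
                if iv.chrom == chrom:
                    lam[iv.start:iv.end] += config.peak_enrichment
            vals[chrom] = rng.poisson(lam).astype(np.float64)
        tracks[f"CTCF_{cond}"] = CoverageTrack(genome, vals)

        # histone marks: flat Poisson; H3K9me3 carries the planted steps
        for mark in ("H3K4me3", "H3K9me3", "H3K27me3"):
            rng = streams[f"{mark}_{cond}"]
            vals = {}
            if mark == "H3K9me3":
                mult = _h3k9me3_log2_multiplier(landscape, cond)
            for chrom in genome.chrom_names:
                lam = np.full(genome.size(chrom), config.background_rate)
                if mark == "H3K9me3":
                    lam = lam * np.exp2(mult[chrom])
                vals[chrom] = rng.poisson(lam).astype(np.float64)
            tracks[f"{mark}_{cond}"] = CoverageTrack(genome, vals)

    # RNA mirrors (inversely) the CT H3K9me3 asymmetry field
    rng = streams["RNA"]
    mult_ct = _h3k9me3_log2_multiplier(landscape, "CT")
    vals = {}
    for chrom in genome.chrom_names:
        lam = config.background_rate * np.exp2(-config.rna_coupling * mult_ct[chrom])
        vals[chrom] = rng.poisson(lam).astype(np.float64)
    tracks["RNA"] = CoverageTrack(genome, vals)

    truth = pd.DataFrame(
        [
            {
                "peak": spec.name,
                "chrom": spec.interval.chrom,
                "start": spec.interval.start,
                "end": spec.interval.end,
                "membership": spec.membership,
                "class": spec.klass,
                "barrier": spec.barrier,
                "planted_m_h3k9me3_ct": spec.planted_m if spec.barrier == "LOSS" else 0.0,
                "planted_m_h3k9me3_kd": spec.planted_m if spec.barrier == "GAIN" else 0.0,
            }
            for spec in landscape.scaffold
        ]
    )
    return SyntheticDataset(config, landscape, peaks, tracks, truth)


def simulate(config: SyntheticConfig) -> SyntheticDataset:
    """Landscape + peaks + coverage in one call."""
    return simulate_peaks_and_coverage(config, simulate_landscape(config))


# ---------------------------------------------------------------------------
# output


def write_outputs(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Write the full dataset as plain-text files consumable by the readers.

    Emits genome.fa, chrom.sizes, repeats.bed, peaks_CT.bed / peaks_KD.bed,
    motif.meme, one bedGraph per mark per condition, rna.bedGraph and
    truth.tsv.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    land = dataset.landscape
    bio.write_fasta(land.sequences, outdir / "genome.fa")
    bio.write_chrom_sizes(land.genome, outdir / "chrom.sizes")
    bio.write_bed(land.repeats, outdir / "repeats.bed")
    write_meme_pwm([land.pwm], outdir / "motif.meme")
    for cond in CONDITIONS:
        bio.write_bed(dataset.peaks[cond], outdir / f"peaks_{cond}.bed")
        for mark in MARKS:
            bio.write_bedgraph(
                dataset.tracks[f"{mark}_{cond}"],
                outdir / f"{mark.lower()}_{cond.lower()}.bedGraph",
            )
    bio.write_bedgraph(dataset.tracks["RNA"], outdir / "rna.bedGraph")
    dataset.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    dataset.config.to_yaml(outdir / "config.yaml")
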