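"""Readers/writers for the plain-text formats the pipeline touches.

BED3/BED6 and bedGraph are parsed by hand (they are line formats, and the
strict-mode/line-number error contract is specific to this pipeline);
FASTA goes through Biopython.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import CoverageTrack, Genome, GenomicInterval, IntervalSet

logger = logging.getLogger(__name__)

__all__ = [
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_fasta",
    "write_fasta",
    "BedParseError",
]


class BedParseError(ValueError):
    """Malformed BED/bedGraph line; message carries the 1-based line number."""


def read_chrom_sizes(path: str | Path) -> Genome:
    """Read a two-column ``chrom.sizes`` table into a :class:`Genome`."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise BedParseError(f"{path}:{lineno}: expected 'name<TAB>length'")
            sizes[parts[0]] = int(parts[1])
    return Genome(sizes)


def write_chrom_sizes(genome: Genome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in genome.chrom_names:
            fh.write(f"{name}\t{genome.chrom_sizes[name]}\n")


def _is_skippable(line: str) -> bool:
    s = line.strip()
    return (
        not s
        or s.startswith("#")
        or s.startswith("track")
        or s.startswith("browser")
    )


def read_bed(
    path: str | Path,
    genome: Genome,
    strict: bool = True,
) -> IntervalSet:
    """Read BED3/BED6 into an :class:`IntervalSet`.

    Comment/track/browser lines are ignored. Records on chromosomes absent
    from *genome* raise in strict mode, or are skipped (with a logged
    count) otherwise. Malformed coordinates raise :class:`BedParseError`
    naming the offending line.
    """
    intervals: list[GenomicInterval] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if _is_skippable(line):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            if chrom not in genome:
                if strict:
                    raise BedParseError(
                        f"{path}:{lineno}: unknown chromosome {chrom!r}"
                    )
                skipped += 1
                continue
            name = parts[3] if len(parts) > 3 else "."
            score: float | None = None
            if len(parts) > 4 and parts[4] not in (".", ""):
                score = float(parts[4])
            strand = parts[5] if len(parts) > 5 else "."
            try:
                iv = GenomicInterval(chrom, start, end, name, score, strand)
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from None
            try:
                genome.check_interval(iv)
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from None
            intervals.append(iv)
    if skipped:
        logger.warning("read_bed(%s): skipped %d records on unknown chromosomes",
                       path, skipped)
    return IntervalSet(intervals)


def _fmt_score(score: float | None) -> str:
    if score is None:
        return "."
    if float(score).is_integer():
        return str(int(score))
    return repr(float(score))


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED6 (tab-separated, half-open)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t"
                f"{_fmt_score(iv.score)}\t{iv.strand}\n"
            )


def read_bedgraph(path: str | Path, genome: Genome) -> CoverageTrack:
    """Read a 4-column bedGraph into a dense :class:`CoverageTrack`.

    Uncovered positions are 0. Overlapping records are an error (the
    signal they would assign is ambiguous).
    """
    track = CoverageTrack(genome)
    # covered-extent watermark per chromosome to detect overlaps in
    # sorted files cheaply; unsorted files are checked against the array.
    touched: dict[str, np.ndarray] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if _is_skippable(line):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise BedParseError(f"{path}:{lineno}: expected 4 columns")
            chrom = parts[0]
            try:
                start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError:
                raise BedParseError(f"{path}:{lineno}: malformed record") from None
            if chrom not in genome:
                raise BedParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            size = genome.size(chrom)
            if start < 0 or start >= end or end > size:
                raise BedParseError(
                    f"{path}:{lineno}: bad window {start}-{end} (chrom size {size})"
                )
            if value < 0:
                raise BedParseError(f"{path}:{lineno}: negative coverage value")
            mask = touched.setdefault(chrom, np.zeros(size, dtype=bool))
            if mask[start:end].any():
                raise BedParseError(
                    f"{path}:{lineno}: overlapping bedGraph intervals"
                )
            mask[start:end] = True
            track.values[chrom][start:end] = value
    return track


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a track as bedGraph, run-length-encoded, zero runs omitted."""
    import pandas as pd

    with open(path, "w") as fh:
        for chrom in track.genome.chrom_names:
            arr = track.values[chrom]
            if arr.size == 0:
                continue
            # boundaries where the value changes
            change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            vals = arr[starts]
            keep = vals != 0
            starts, ends, vals = starts[keep], ends[keep], vals[keep]
            if starts.size == 0:
                continue
            # format each distinct value once (counts repeat heavily)
            uniq, inverse = np.unique(vals, return_inverse=True)
            rendered = np.array(
                [str(int(v)) if float(v).is_integer() else repr(float(v))
                 for v in uniq],
                dtype=object,
            )
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends,
                 "value": rendered[inverse]}
            ).to_csv(fh, sep="\t", header=False, index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into a mapping of sequence name to uppercase string."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")
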