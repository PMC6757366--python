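"""Peak classification by motif vs repeat content.

A peak is MOTIF_ONLY when it contains at least one motif hit and overlaps
no repeat bases; REPEAT_ONLY when it has no motif hit and at least
``min_repeat_bases`` of repeat overlap; everything that cannot be
unambiguously assigned — including peaks with both features or neither —
is OTHER. The three classes partition any peak set.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping

import pandas as pd

from .core import GenomicInterval, IntervalSet

__all__ = [
    "PeakClass",
    "PeakClassification",
    "classify_peaks",
    "repeat_content",
    "peak_summary",
    "REPEAT_CLASSES",
]

#: RepeatMasker-style class vocabulary; anything else counts as "other".
REPEAT_CLASSES = ("LINE", "SINE", "LTR", "DNA", "Simple_repeat")


class PeakClass(str, Enum):
    MOTIF_ONLY = "MOTIF_ONLY"
    REPEAT_ONLY = "REPEAT_ONLY"
    OTHER = "OTHER"


@dataclass(frozen=True)
class PeakClassification:
    peak: GenomicInterval
    n_motif_hits: int
    repeat_overlap_bases: int
    klass: PeakClass

    @property
    def repeat_fraction(self) -> float:
        return self.repeat_overlap_bases / len(self.peak)


def _repeat_class(name: str) -> str:
    # repeats.bed carries "class" or "class/family" in the name field
    base = name.split("/")[0]
    return base if base in REPEAT_CLASSES else "other"


def classify_peaks(
    peaks: IntervalSet,
    motif_hits: Mapping[str, int],
    repeats: IntervalSet,
    min_repeat_bases: int = 1,
) -> list[PeakClassification]:
    """Assign each peak exactly one of {MOTIF_ONLY, REPEAT_ONLY, OTHER}.

    *motif_hits* maps peak name to its combined two-strand hit count and
    must cover every peak (a missing peak id is an error — it usually
    means hits were computed on a different peak set).
    """
    out: list[PeakClassification] = []
    for peak in peaks:
        if peak.name not in motif_hits:
            raise KeyError(f"motif-hit table is missing peak {peak.name!r}")
        n_hits = int(motif_hits[peak.name])
        rep_bases = repeats.overlap_bases(peak)
        if n_hits >= 1 and rep_bases == 0:
            klass = PeakClass.MOTIF_ONLY
        elif n_hits == 0 and rep_bases >= min_repeat_bases:
            klass = PeakClass.REPEAT_ONLY
        else:
            klass = PeakClass.OTHER
        out.append(PeakClassification(peak, n_hits, rep_bases, klass))
    return out


def repeat_content(peaks: IntervalSet, repeats: IntervalSet) -> pd.DataFrame:
    """Per-peak repeat base fractions split by repeat class.

    Overlapping repeat records of the same class are merged before
    counting, so no base is counted twice within a class. Returns one row
    per peak with a ``fraction_<class>`` column per recognized class plus
    ``fraction_other`` and the total (union over classes may exceed none:
    classes can overlap each other, so the total is computed from the
    merged union of all repeats).
    """
    classes = list(REPEAT_CLASSES) + ["other"]
    by_class: dict[str, IntervalSet] = {
        c: IntervalSet(iv for iv in repeats if _repeat_class(iv.name) == c)
        for c in classes
    }
    rows = []
    for peak in peaks:
        row: dict[str, object] = {
            "peak": peak.name,
            "chrom": peak.chrom,
            "start": peak.start,
            "end": peak.end,
        }
        for c in classes:
            row[f"fraction_{c}"] = by_class[c].overlap_bases(peak) / len(peak)
        row["fraction_total"] = repeats.overlap_bases(peak) / len(peak)
        rows.append(row)
    cols = ["peak", "chrom", "start", "end"] + [
        f"fraction_{c}" for c in classes
    ] + ["fraction_total"]
    return pd.DataFrame(rows, columns=cols)


def peak_summary(
    peaks: IntervalSet,
    motif_hits: Mapping[str, int],
    repeats: IntervalSet,
    tandem_count: int | None = None,
    sample: str = "sample",
) -> pd.DataFrame:
    """One-row summary of a peak set: size, motif density, repeat content.

    ``motifs_per_peak`` is total hits / n_peaks exactly;
    ``repeat_fraction`` is the mean per-peak repeat base fraction.
    """
    n = len(peaks)
    if n == 0:
        row = {
            "sample": sample, "n_peaks": 0, "total_motif_hits": 0,
            "motifs_per_peak": 0.0, "repeat_fraction": 0.0,
            "fraction_LINE": 0.0, "fraction_SINE": 0.0,
            "tandem_motif_pairs": 0 if tandem_count is None else tandem_count,
        }
        return pd.DataFrame([row])
    total_hits = sum(int(motif_hits[p.name]) for p in peaks)
    content = repeat_content(peaks, repeats)
    row = {
        "sample": sample,
        "n_peaks": n,
        "total_motif_hits": total_hits,
        "motifs_per_peak": total_hits / n,
        "repeat_fraction": float(content["fraction_total"].mean()),
        "fraction_LINE": float(content["fraction_LINE"].mean()),
        "fraction_SINE": float(content["fraction_SINE"].mean()),
        "tandem_motif_pairs": 0 if tandem_count is None else tandem_count,
    }
    return pd.DataFrame([row])


def classification_table(classifications: list[PeakClassification]) -> pd.DataFrame:
    """Flat TSV-ready table of per-peak classifications."""
    return pd.DataFrame(
        [
            {
                "peak": c.peak.name,
                "chrom": c.peak.chrom,
                "start": c.peak.start,
                "end": c.peak.end,
                "n_motif_hits": c.n_motif_hits,
                "repeat_overlap_bases": c.repeat_overlap_bases,
                "repeat_fraction": c.repeat_fraction,
                "class": c.klass.value,
            }
            for c in classifications
        ]
    )
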