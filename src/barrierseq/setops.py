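"""Condition-exclusive / shared peak algebra and domain-level counting.

The exclusive-peak call replicates the bedtools-intersect contract: a
peak of A is "shared" iff at least ``min_overlap_fraction`` of its own
length overlaps some peak of B (merged across B partners), otherwise it
is A-only; symmetric for B. Strand is ignored throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenomicInterval, IntervalSet, closest_distance, UNDEFINED_DISTANCE

__all__ = [
    "ExclusiveSets",
    "exclusive_peaks",
    "domain_peak_counts",
    "closest_distance_histogram",
]

#: bedtools default: any single base of overlap qualifies.
DEFAULT_OVERLAP_FRACTION = 1e-9


@dataclass(frozen=True)
class ExclusiveSets:
    """The quartet of exclusive/shared sets for two conditions A and B."""

    a_only: IntervalSet
    b_only: IntervalSet
    shared_a: IntervalSet
    shared_b: IntervalSet
    overlap_fraction: float

    def venn_counts(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "a_only": len(self.a_only),
                    "b_only": len(self.b_only),
                    "shared_a": len(self.shared_a),
                    "shared_b": len(self.shared_b),
                    "overlap_fraction": self.overlap_fraction,
                }
            ]
        )


def _split(
    src: IntervalSet, other: IntervalSet, min_overlap_fraction: float
) -> tuple[IntervalSet, IntervalSet]:
    only, shared = [], []
    for iv in src:
        # merged overlap across all partners, as a fraction of iv's length
        frac = other.overlap_bases(iv) / len(iv)
        (shared if frac >= min_overlap_fraction else only).append(iv)
    return IntervalSet(only), IntervalSet(shared)


def exclusive_peaks(
    a: IntervalSet,
    b: IntervalSet,
    min_overlap_fraction: float = DEFAULT_OVERLAP_FRACTION,
) -> ExclusiveSets:
    """Partition A and B into condition-exclusive and shared subsets.

    Deterministic; |a_only| + |shared_a| == |A| and symmetrically for B.
    """
    if not (0 < min_overlap_fraction <= 1):
        raise ValueError("min_overlap_fraction must be in (0, 1]")
    a_only, shared_a = _split(a, b, min_overlap_fraction)
    b_only, shared_b = _split(b, a, min_overlap_fraction)
    return ExclusiveSets(a_only, b_only, shared_a, shared_b, min_overlap_fraction)


def domain_peak_counts(
    domains: IntervalSet,
    peaks_a: IntervalSet,
    peaks_b: IntervalSet,
) -> pd.DataFrame:
    """Per-domain peak counts for two conditions, by peak midpoint.

    A peak counts toward a domain if its midpoint lies inside the domain
    interval; peaks whose midpoint falls in no domain are tallied in a
    final ``outside`` row, so column totals equal the input peak counts.
    A domain is ``lost`` if it holds A peaks but no B peaks, ``gained``
    if the reverse.
    """
    rows = []
    counted_a = counted_b = 0
    for dom in domains:
        point = lambda p: dom.chrom == p.chrom and dom.start <= p.midpoint < dom.end
        n_a = sum(1 for p in peaks_a if point(p))
        n_b = sum(1 for p in peaks_b if point(p))
        counted_a += n_a
        counted_b += n_b
        rows.append(
            {
                "domain": dom.name,
                "chrom": dom.chrom,
                "start": dom.start,
                "end": dom.end,
                "n_a": n_a,
                "n_b": n_b,
                "lost": n_a > 0 and n_b == 0,
                "gained": n_b > 0 and n_a == 0,
            }
        )
    rows.append(
        {
            "domain": "outside",
            "chrom": ".",
            "start": -1,
            "end": -1,
            "n_a": len(peaks_a) - counted_a,
            "n_b": len(peaks_b) - counted_b,
            "lost": False,
            "gained": False,
        }
    )
    return pd.DataFrame(rows)


def closest_distance_histogram(
    a: IntervalSet,
    b: IntervalSet,
    bin_bases: int,
) -> pd.DataFrame:
    """Histogram of midpoint-to-midpoint closest distances, binned.

    One distance per interval of *a* (to the nearest *b* midpoint);
    records with no partner on the chromosome are excluded from the
    histogram and reported via the ``n_undefined`` attribute column.
    Bins are ``[k*bin_bases, (k+1)*bin_bases)``.
    """
    if bin_bases <= 0:
        raise ValueError("bin_bases must be positive")
    pairs = closest_distance(a, b, mode="midpoint")
    dists = [d for _, d in pairs if d != UNDEFINED_DISTANCE]
    n_undefined = len(pairs) - len(dists)
    if dists:
        arr = np.asarray(dists)
        max_bin = int(arr.max() // bin_bases)
        counts = np.bincount(arr // bin_bases, minlength=max_bin + 1)
    else:
        counts = np.zeros(0, dtype=int)
    df = pd.DataFrame(
        {
            "bin_start": np.arange(counts.size) * bin_bases,
            "bin_end": (np.arange(counts.size) + 1) * bin_bases,
            "count": counts,
        }
    )
    df.attrs["n_undefined"] = n_undefined
    return df
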