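"""Coordinate model and interval-arithmetic engine.

All coordinates are 0-based half-open (BED convention) everywhere in the
package; conversion to 1-based displays, if any, is a rendering concern.

The atoms are :class:`GenomicInterval` (a chromosome-anchored range with
optional name/score/strand), :class:`IntervalSet` (an overlap-indexed
collection backed by :mod:`intervaltree`), :class:`Genome` (the chromosome
name/size space every interval must lie within) and :class:`CoverageTrack`
(dense per-base non-negative signal, the substrate of all flank/AUC
statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "Genome",
    "GenomicInterval",
    "IntervalSet",
    "CoverageTrack",
    "closest_distance",
]

#: Sentinel distance reported when no partner exists on the chromosome.
UNDEFINED_DISTANCE = -1


@dataclass(frozen=True)
class Genome:
    """Ordered chromosome space.

    Parameters
    ----------
    chrom_sizes
        Mapping of chromosome name to length in bases. Iteration order of
        the mapping defines the stable chromosome order for the run.
    """

    chrom_sizes: Mapping[str, int]

    def __post_init__(self) -> None:
        sizes = dict(self.chrom_sizes)
        for name, size in sizes.items():
            if not isinstance(size, (int, np.integer)) or size <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive size {size!r}")
        object.__setattr__(self, "chrom_sizes", sizes)

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chrom_sizes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_sizes

    def size(self, chrom: str) -> int:
        try:
            return self.chrom_sizes[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    @property
    def total_size(self) -> int:
        return sum(self.chrom_sizes.values())

    def check_interval(self, iv: "GenomicInterval") -> None:
        """Raise ``ValueError`` unless *iv* lies within this genome."""
        if iv.chrom not in self.chrom_sizes:
            raise ValueError(f"interval on unknown chromosome {iv.chrom!r}")
        if iv.end > self.chrom_sizes[iv.chrom]:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"size {self.chrom_sizes[iv.chrom]}"
            )


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic range ``[start, end)`` with BED6-style metadata."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Peak center, defined as ``floor((start + end) / 2)``."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bases(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def with_name(self, name: str) -> "GenomicInterval":
        return replace(self, name=name)


class IntervalSet:
    """An ordered collection of intervals with O(log n) overlap queries.

    Input order is preserved (``intervals`` and iteration); overlap queries
    are answered from per-chromosome interval trees built lazily.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):  # noqa: D401
        self.intervals: list[GenomicInterval] = list(intervals)
        self._trees: dict[str, IntervalTree] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)})"

    @property
    def chroms(self) -> set[str]:
        return {iv.chrom for iv in self.intervals}

    def _tree(self, chrom: str) -> IntervalTree | None:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for idx, iv in enumerate(self.intervals):
                trees.setdefault(iv.chrom, IntervalTree()).addi(
                    iv.start, iv.end, idx
                )
            self._trees = trees
        return self._trees.get(chrom)

    def overlapping(self, query: GenomicInterval) -> list[GenomicInterval]:
        """All member intervals overlapping *query*, in input order."""
        tree = self._tree(query.chrom)
        if tree is None:
            return []
        hits = sorted(node.data for node in tree.overlap(query.start, query.end))
        return [self.intervals[i] for i in hits]

    def overlap_bases(self, query: GenomicInterval) -> int:
        """Bases of *query* covered by at least one member (merged)."""
        hits = self.overlapping(query)
        if not hits:
            return 0
        segs = sorted(
            (max(iv.start, query.start), min(iv.end, query.end)) for iv in hits
        )
        covered = 0
        cur_s, cur_e = segs[0]
        for s, e in segs[1:]:
            if s > cur_e:
                covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        covered += cur_e - cur_s
        return covered

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        """Members of self with any overlap in *other* (bedtools -u contract)."""
        return IntervalSet(
            iv for iv in self.intervals if other.overlapping(iv)
        )

    def subtract_whole(self, other: "IntervalSet") -> "IntervalSet":
        """Members of self with no overlap in *other* (bedtools -v contract)."""
        return IntervalSet(
            iv for iv in self.intervals if not other.overlapping(iv)
        )


def _closest_one(
    iv: GenomicInterval,
    starts: np.ndarray,
    ends: np.ndarray,
    mids: np.ndarray,
    mode: str,
) -> int:
    if mode == "edge":
        # gap between nearest edges; 0 on overlap
        d = np.maximum(starts - iv.end, iv.start - ends)
        d = np.maximum(d, 0)
    else:
        d = np.abs(mids - iv.midpoint)
    return int(d.min())


def closest_distance(
    a: IntervalSet,
    b: IntervalSet,
    mode: str = "edge",
) -> list[tuple[GenomicInterval, int]]:
    """Distance from each interval of *a* to its nearest interval of *b*.

    ``mode="edge"`` measures between nearest edges (0 for overlapping
    pairs); ``mode="midpoint"`` measures between interval midpoints.
    Intervals of *a* on chromosomes absent from *b* are reported with the
    sentinel distance ``-1``. Ties between partners do not affect the
    reported distance (the minimum is unique by value).
    """
    if mode not in ("edge", "midpoint"):
        raise ValueError(f"unknown mode {mode!r}")
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in b.chroms:
        ivs = [iv for iv in b if iv.chrom == chrom]
        starts = np.array([iv.start for iv in ivs], dtype=np.int64)
        ends = np.array([iv.end for iv in ivs], dtype=np.int64)
        mids = np.array([iv.midpoint for iv in ivs], dtype=np.int64)
        by_chrom[chrom] = (starts, ends, mids)
    out: list[tuple[GenomicInterval, int]] = []
    for iv in a:
        if iv.chrom not in by_chrom:
            out.append((iv, UNDEFINED_DISTANCE))
            continue
        starts, ends, mids = by_chrom[iv.chrom]
        out.append((iv, _closest_one(iv, starts, ends, mids, mode)))
    return out


class CoverageTrack:
    """Dense per-base non-negative signal over a genome.

    Values are stored as one float64 array per chromosome. Queries over a
    window return exactly the per-base slice (or its sum); querying beyond
    chromosome bounds is an error — flank-window policies (drop/clip) live
    in the callers, not here.
    """

    def __init__(self, genome: Genome, values: Mapping[str, np.ndarray] | None = None):
        self.genome = genome
        self.values: dict[str, np.ndarray] = {}
        for chrom, size in genome.chrom_sizes.items():
            if values is not None and chrom in values:
                arr = np.asarray(values[chrom], dtype=np.float64)
                if arr.shape != (size,):
                    raise ValueError(
                        f"values for {chrom} have shape {arr.shape}, "
                        f"expected ({size},)"
                    )
                if (arr < 0).any():
                    raise ValueError(f"negative coverage values on {chrom}")
            else:
                arr = np.zeros(size, dtype=np.float64)
            self.values[chrom] = arr

    def _check_window(self, chrom: str, start: int, end: int) -> None:
        size = self.genome.size(chrom)
        if start < 0 or end > size or start > end:
            raise ValueError(
                f"window {chrom}:{start}-{end} outside chromosome bounds [0, {size})"
            )

    def window(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over ``[start, end)`` (a view, do not mutate)."""
        self._check_window(chrom, start, end)
        return self.values[chrom][start:end]

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        self._check_window(chrom, start, end)
        return float(self.values[chrom][start:end].sum())

    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.values.values()))

    def binned(self, chrom: str, start: int, end: int, bin_bases: int) -> np.ndarray:
        """Mean per-base signal in consecutive bins tiling ``[start, end)``.

        ``end - start`` must be a multiple of ``bin_bases``.
        """
        if bin_bases <= 0:
            raise ValueError("bin_bases must be positive")
        if (end - start) % bin_bases != 0:
            raise ValueError("window length must be a multiple of bin_bases")
        vals = self.window(chrom, start, end)
        return vals.reshape(-1, bin_bases).mean(axis=1)

    def __add__(self, other: "CoverageTrack") -> "CoverageTrack":
        if other.genome.chrom_sizes != self.genome.chrom_sizes:
            raise ValueError("tracks on different genomes")
        return CoverageTrack(
            self.genome,
            {c: self.values[c] + other.values[c] for c in self.values},
        )
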