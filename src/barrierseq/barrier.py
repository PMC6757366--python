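"""Upstream/downstream flank statistics and the M/dM barrier-element caller.

For each peak, the signal of a histone mark is summed in the 10 kb
windows immediately left ("upstream") and right ("downstream") of the
peak edges, in genome orientation. The per-condition statistic is

    M = log2(up + pc) - log2(down + pc)
    A = (log2(up + pc) + log2(down + pc)) / 2

with pseudocount ``pc`` (default 1 read) so empty flanks stay finite.
dM = M(KD) - M(CT). A condition-exclusive peak is called a barrier
change when both (i) the M of the condition in which the peak is bound
exceeds the M threshold in magnitude and (ii) |dM| exceeds the dM
threshold: CT-exclusive peaks satisfying both are LOSS calls, KD-
exclusive peaks are GAIN calls; everything else is NONE. Default
thresholds per mark: H3K9me3 1.5/1.5, H3K4me3 2/2, H3K27me3 1/1.
Thresholds are applied to magnitudes (asymmetry in either direction
qualifies); no sign concordance between marks is enforced and no
multiple-testing correction is applied — the calls are fixed-threshold
classifications, not hypothesis tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import CoverageTrack, GenomicInterval, IntervalSet
from .setops import ExclusiveSets, exclusive_peaks

logger = logging.getLogger(__name__)

__all__ = [
    "FlankCounts",
    "BarrierCall",
    "BarrierRecord",
    "DEFAULT_THRESHOLDS",
    "flank_counts",
    "m_value",
    "call_barriers",
    "m_distribution",
    "rna_asymmetry",
    "RnaAsymmetryResult",
]

#: (m_threshold, delta_m_threshold) per histone mark.
DEFAULT_THRESHOLDS: dict[str, tuple[float, float]] = {
    "H3K9me3": (1.5, 1.5),
    "H3K4me3": (2.0, 2.0),
    "H3K27me3": (1.0, 1.0),
}


class BarrierCall(str, Enum):
    LOSS = "LOSS"
    GAIN = "GAIN"
    NONE = "NONE"


@dataclass(frozen=True)
class FlankCounts:
    """Total signal in the windows abutting a peak's edges."""

    peak: GenomicInterval
    up_count: float
    down_count: float
    flank_bases: int


@dataclass(frozen=True)
class BarrierRecord:
    peak: GenomicInterval
    mark: str
    m_ct: float
    m_kd: float
    a_ct: float
    a_kd: float
    call: BarrierCall
    exclusive_set: str  # "CT", "KD" or "shared"

    @property
    def delta_m(self) -> float:
        return self.m_kd - self.m_ct


def flank_counts(
    peaks: IntervalSet,
    track: CoverageTrack,
    flank_bases: int,
) -> list[FlankCounts]:
    """Signal sums in ``[start - flank, start)`` and ``[end, end + flank)``.

    The windows abut the peak edges and exclude the peak body. Peaks
    whose windows would extend past a chromosome end are dropped with a
    logged count rather than clipped (clipping would bias M toward the
    intact side).
    """
    if flank_bases <= 0:
        raise ValueError("flank_bases must be positive")
    out: list[FlankCounts] = []
    dropped = 0
    for peak in peaks:
        size = track.genome.size(peak.chrom)
        if peak.start - flank_bases < 0 or peak.end + flank_bases > size:
            dropped += 1
            continue
        up = track.window_sum(peak.chrom, peak.start - flank_bases, peak.start)
        down = track.window_sum(peak.chrom, peak.end, peak.end + flank_bases)
        out.append(FlankCounts(peak, up, down, flank_bases))
    if dropped:
        logger.info("flank_counts: dropped %d peaks with out-of-bounds flanks",
                    dropped)
    return out


def m_value(
    up_count: float, down_count: float, pseudocount: float = 1.0
) -> tuple[float, float]:
    """M (log2 up/down fold change) and A (average log2 count) of a peak."""
    if up_count < 0 or down_count < 0:
        raise ValueError("counts must be non-negative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    lu = np.log2(up_count + pseudocount)
    ld = np.log2(down_count + pseudocount)
    return float(lu - ld), float((lu + ld) / 2.0)


def call_barriers(
    counts_ct: Sequence[FlankCounts],
    counts_kd: Sequence[FlankCounts],
    exclusive_sets: ExclusiveSets,
    mark: str,
    m_threshold: float | None = None,
    delta_threshold: float | None = None,
    pseudocount: float = 1.0,
    scale_ct: float = 1.0,
    scale_kd: float = 1.0,
) -> list[BarrierRecord]:
    """Classify peaks into LOSS / GAIN / NONE barrier-change calls.

    *counts_ct* / *counts_kd* are per-condition flank counts for *mark*
    over the same peaks (keyed by peak name; peaks present in only one
    list are skipped — usually edge-dropped ones). ``exclusive_sets`` is
    the CT-vs-KD peak algebra: only CT-exclusive peaks can be LOSS and
    only KD-exclusive peaks can be GAIN. Thresholds default per mark
    (error for an unknown mark with no explicit thresholds).
    ``scale_ct``/``scale_kd`` are optional per-track depth factors
    multiplied into the counts before the log.
    """
    if m_threshold is None or delta_threshold is None:
        if mark not in DEFAULT_THRESHOLDS:
            raise ValueError(
                f"no configured thresholds for mark {mark!r}; pass "
                "m_threshold and delta_threshold explicitly"
            )
        default_m, default_d = DEFAULT_THRESHOLDS[mark]
        m_threshold = default_m if m_threshold is None else m_threshold
        delta_threshold = default_d if delta_threshold is None else delta_threshold

    ct_names = {iv.name for iv in exclusive_sets.a_only}
    kd_names = {iv.name for iv in exclusive_sets.b_only}
    by_name_kd = {fc.peak.name: fc for fc in counts_kd}
    records: list[BarrierRecord] = []
    for fc_ct in counts_ct:
        name = fc_ct.peak.name
        fc_kd = by_name_kd.get(name)
        if fc_kd is None:
            continue
        m_ct, a_ct = m_value(
            fc_ct.up_count * scale_ct, fc_ct.down_count * scale_ct, pseudocount
        )
        m_kd, a_kd = m_value(
            fc_kd.up_count * scale_kd, fc_kd.down_count * scale_kd, pseudocount
        )
        delta = m_kd - m_ct
        if name in ct_names:
            subset = "CT"
            call = (
                BarrierCall.LOSS
                if abs(m_ct) > m_threshold and abs(delta) > delta_threshold
                else BarrierCall.NONE
            )
        elif name in kd_names:
            subset = "KD"
            call = (
                BarrierCall.GAIN
                if abs(m_kd) > m_threshold and abs(delta) > delta_threshold
                else BarrierCall.NONE
            )
        else:
            subset = "shared"
            call = BarrierCall.NONE
        records.append(
            BarrierRecord(fc_ct.peak, mark, m_ct, m_kd, a_ct, a_kd, call, subset)
        )
    return records


def peak_union(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Union of two peak sets keyed by peak name (A's copy wins on overlap)."""
    names_a = {iv.name for iv in a}
    return IntervalSet(list(a) + [iv for iv in b if iv.name not in names_a])


def barrier_pipeline(
    peaks_ct: IntervalSet,
    peaks_kd: IntervalSet,
    track_ct: CoverageTrack,
    track_kd: CoverageTrack,
    mark: str = "H3K9me3",
    flank_bases: int = 10_000,
    m_threshold: float | None = None,
    delta_threshold: float | None = None,
    overlap_fraction: float = 1e-9,
    pseudocount: float = 1.0,
) -> tuple[ExclusiveSets, list[BarrierRecord]]:
    """Exclusive-peak algebra + flank counts + barrier calls in one step.

    Flank counts for both conditions are computed on the name-keyed union
    of the two peak sets, so every distinct peak is scored in both
    conditions.
    """
    sets = exclusive_peaks(peaks_ct, peaks_kd, overlap_fraction)
    union = peak_union(peaks_ct, peaks_kd)
    counts_ct = flank_counts(union, track_ct, flank_bases)
    counts_kd = flank_counts(union, track_kd, flank_bases)
    records = call_barriers(
        counts_ct, counts_kd, sets, mark, m_threshold, delta_threshold, pseudocount
    )
    return sets, records


def records_table(records: Sequence[BarrierRecord]) -> pd.DataFrame:
    """Flat TSV-ready table of barrier records."""
    return pd.DataFrame(
        [
            {
                "peak": r.peak.name,
                "chrom": r.peak.chrom,
                "start": r.peak.start,
                "end": r.peak.end,
                "mark": r.mark,
                "m_ct": r.m_ct,
                "m_kd": r.m_kd,
                "a_ct": r.a_ct,
                "a_kd": r.a_kd,
                "delta_m": r.delta_m,
                "exclusive_set": r.exclusive_set,
                "call": r.call.value,
            }
            for r in records
        ]
    )


def m_distribution(
    records: Sequence[BarrierRecord],
    labels: Mapping[str, str] | None = None,
    condition: str = "CT",
    bin_width: float = 0.25,
) -> pd.DataFrame:
    """Binned frequency distribution of M values per peak subset.

    *labels* maps peak name to a subset label (e.g. "common" vs
    "CT-exclusive", or a repeat/motif class); unlabeled records fall
    under the record's own ``exclusive_set``. Bins are centered on
    multiples of ``bin_width``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if condition not in ("CT", "KD"):
        raise ValueError("condition must be 'CT' or 'KD'")
    rows = []
    for r in records:
        label = (labels or {}).get(r.peak.name, r.exclusive_set)
        m = r.m_ct if condition == "CT" else r.m_kd
        rows.append((r.mark, label, np.round(m / bin_width) * bin_width))
    df = pd.DataFrame(rows, columns=["mark", "subset", "bin_center"])
    out = (
        df.groupby(["mark", "subset", "bin_center"])
        .size()
        .rename("count")
        .reset_index()
    )
    return out


@dataclass(frozen=True)
class RnaAsymmetryResult:
    per_site: pd.DataFrame
    statistic: float
    pvalue: float
    median_barrier: float
    median_control: float


def rna_asymmetry(
    records: Sequence[BarrierRecord],
    rna_track: CoverageTrack,
    flank_bases: int,
    calls: tuple[str, ...] = ("LOSS",),
    pseudocount: float = 1.0,
    seed: int = 0,
    min_sites: int = 10,
) -> RnaAsymmetryResult:
    """RNA signal asymmetry across called barriers vs matched controls.

    Sums RNA signal in the upstream/downstream flanks of every barrier
    site (records whose call is in *calls*) and of an equally sized
    control set sampled from the NONE-call records, and compares the
    per-site |log2 up/down| between the two groups with a two-sided
    Wilcoxon rank-sum test. No biological interpretation is attached to
    the p-value; an all-tied degenerate input reports statistic 0 and
    p = 1.
    """
    barrier_peaks = [r.peak for r in records if r.call.value in calls]
    control_pool = [r.peak for r in records if r.call is BarrierCall.NONE]
    if len(barrier_peaks) < min_sites:
        raise ValueError(
            f"need >= {min_sites} barrier sites, have {len(barrier_peaks)}"
        )
    if not control_pool:
        raise ValueError("control set of NONE-call peaks is empty")
    rng = np.random.default_rng(seed)
    k = min(len(barrier_peaks), len(control_pool))
    controls = [control_pool[i] for i in rng.choice(len(control_pool), k, replace=False)]

    def _asym(peaks: list[GenomicInterval], group: str) -> list[dict]:
        out = []
        for fc in flank_counts(IntervalSet(peaks), rna_track, flank_bases):
            ratio = abs(
                float(
                    np.log2(fc.up_count + pseudocount)
                    - np.log2(fc.down_count + pseudocount)
                )
            )
            out.append(
                {
                    "peak": fc.peak.name,
                    "group": group,
                    "up": fc.up_count,
                    "down": fc.down_count,
                    "abs_log2_ratio": ratio,
                }
            )
        return out

    per_site = pd.DataFrame(
        _asym(barrier_peaks, "barrier") + _asym(controls, "control")
    )
    x = per_site.loc[per_site.group == "barrier", "abs_log2_ratio"].to_numpy()
    y = per_site.loc[per_site.group == "control", "abs_log2_ratio"].to_numpy()
    if np.ptp(np.concatenate([x, y])) == 0:
        stat, p = 0.0, 1.0
    else:
        # exact Mann-Whitney when sample sizes permit (no ties), else the
        # tie-corrected normal approximation
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
        stat, p = float(res.statistic), float(res.pvalue)
    return RnaAsymmetryResult(
        per_site=per_site,
        statistic=stat,
        pvalue=p,
        median_barrier=float(np.median(x)) if x.size else float("nan"),
        median_control=float(np.median(y)) if y.size else float("nan"),
    )
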