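"""Flank counts, the M/A statistic, barrier calls and RNA asymmetry."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import barrierseq as bq
from barrierseq.barrier import (
    BarrierCall,
    BarrierRecord,
    barrier_pipeline,
    call_barriers,
    flank_counts,
    m_distribution,
    m_value,
    rna_asymmetry,
)
from barrierseq.core import CoverageTrack, Genome, GenomicInterval, IntervalSet
from barrierseq.setops import ExclusiveSets, exclusive_peaks

from conftest import random_track


@pytest.fixture
def wide_genome():
    return Genome({"chr1": 200_000})


def _const(genome, value=1.0):
    return CoverageTrack(
        genome, {c: np.full(s, float(value)) for c, s in genome.chrom_sizes.items()}
    )


class TestFlankCounts:
    def test_constant_track_sums_flank_length(self, wide_genome):
        peaks = IntervalSet([GenomicInterval("chr1", 20_000, 20_100, "p")])
        (fc,) = flank_counts(peaks, _const(wide_genome), 10_000)
        assert fc.up_count == 10_000.0
        assert fc.down_count == 10_000.0

    def test_peak_too_close_to_chromosome_start_dropped(self, wide_genome):
        peaks = IntervalSet([
            GenomicInterval("chr1", 5_000, 5_100, "edge"),
            GenomicInterval("chr1", 50_000, 50_100, "ok"),
        ])
        out = flank_counts(peaks, _const(wide_genome), 10_000)
        assert [fc.peak.name for fc in out] == ["ok"]

    def test_windows_exclude_peak_body(self, wide_genome):
        # signal only inside the peak: both flanks must be zero
        vals = np.zeros(200_000)
        vals[20_000:20_100] = 100.0
        track = CoverageTrack(wide_genome, {"chr1": vals})
        peaks = IntervalSet([GenomicInterval("chr1", 20_000, 20_100, "p")])
        (fc,) = flank_counts(peaks, track, 10_000)
        assert fc.up_count == 0.0 and fc.down_count == 0.0

    def test_matches_brute_force_per_base_summation(self, wide_genome):
        rng = np.random.default_rng(0)
        track = random_track(rng, wide_genome)
        peaks = IntervalSet(
            GenomicInterval("chr1", p, p + 150, name=f"p{i}")
            for i, p in enumerate(rng.integers(15_000, 180_000, size=40))
        )
        for fc in flank_counts(peaks, track, 10_000):
            s, e = fc.peak.start, fc.peak.end
            assert fc.up_count == pytest.approx(
                float(track.values["chr1"][s - 10_000:s].sum())
            )
            assert fc.down_count == pytest.approx(
                float(track.values["chr1"][e:e + 10_000].sum())
            )


class TestMValue:
    def test_equal_flanks_give_zero(self):
        for v in (0, 1, 7, 12345):
            m, _ = m_value(v, v)
            assert m == 0.0

    def test_hand_computed_example(self):
        m, a = m_value(800, 200, pseudocount=1)
        assert m == pytest.approx(np.log2(801 / 201))
        assert m == pytest.approx(1.9946, abs=1e-4)
        assert a == pytest.approx((np.log2(801) + np.log2(201)) / 2)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            m_value(-1, 5)

    def test_antisymmetry_on_many_random_pairs(self):
        rng = np.random.default_rng(1)
        ups = rng.integers(0, 10_000, size=10_000)
        downs = rng.integers(0, 10_000, size=10_000)
        for u, d in zip(ups, downs):
            assert m_value(u, d)[0] == pytest.approx(-m_value(d, u)[0])


def _record(name, m_ct, m_kd, subset, call=BarrierCall.NONE, mark="H3K9me3"):
    peak = GenomicInterval("chr1", 50_000, 50_400, name)
    return BarrierRecord(peak, mark, m_ct, m_kd, 5.0, 5.0, call, subset)


def _sets_from(ct_names, kd_names):
    mk = lambda names: IntervalSet(
        GenomicInterval("chr1", 1000 * (i + 20), 1000 * (i + 20) + 100, n)
        for i, n in enumerate(names)
    )
    return ExclusiveSets(mk(ct_names), mk(kd_names), IntervalSet(), IntervalSet(), 1e-9)


def _counts_for(ms, flank=10_000, base=1000.0):
    """FlankCounts whose M (pseudocount 1) is approximately the given value."""
    out = []
    for name, m in ms.items():
        up = base * 2 ** m
        out.append(
            bq.FlankCounts(
                GenomicInterval("chr1", 50_000, 50_400, name), up, base, flank
            )
        )
    return out


class TestCallBarriers:
    def test_ct_exclusive_with_lost_asymmetry_is_loss(self):
        sets = _sets_from(["p1"], [])
        recs = call_barriers(
            _counts_for({"p1": 2.5}), _counts_for({"p1": 0.1}), sets, "H3K9me3"
        )
        assert recs[0].call is BarrierCall.LOSS

    def test_small_delta_m_is_none_despite_large_m(self):
        sets = _sets_from(["p1"], [])
        recs = call_barriers(
            _counts_for({"p1": 2.5}), _counts_for({"p1": 2.4}), sets, "H3K9me3"
        )
        assert recs[0].call is BarrierCall.NONE  # |dM| = 0.1

    def test_kd_exclusive_gain_uses_kd_m(self):
        sets = _sets_from([], ["p1"])
        recs = call_barriers(
            _counts_for({"p1": 0.0}), _counts_for({"p1": -2.2}), sets, "H3K9me3"
        )
        assert recs[0].call is BarrierCall.GAIN

    def test_shared_peaks_are_never_called(self):
        sets = _sets_from([], [])
        recs = call_barriers(
            _counts_for({"p1": 3.0}), _counts_for({"p1": -3.0}), sets, "H3K9me3"
        )
        assert recs[0].call is BarrierCall.NONE
        assert recs[0].exclusive_set == "shared"

    def test_unknown_mark_without_thresholds_is_error(self):
        sets = _sets_from(["p1"], [])
        with pytest.raises(ValueError, match="threshold"):
            call_barriers(
                _counts_for({"p1": 2.5}), _counts_for({"p1": 0.0}), sets, "H3K36me3"
            )

    def test_per_mark_default_thresholds(self):
        # |M|=1.7, dM=1.7: above the 1.5 H3K9me3 cut, below the 2.0 H3K4me3 cut
        sets = _sets_from(["p1"], [])
        ct, kd = _counts_for({"p1": 1.7}), _counts_for({"p1": 0.0})
        assert call_barriers(ct, kd, sets, "H3K9me3")[0].call is BarrierCall.LOSS
        assert call_barriers(ct, kd, sets, "H3K4me3")[0].call is BarrierCall.NONE
        # |M|=1.2 passes only the permissive H3K27me3 1.0 cut
        ct2, kd2 = _counts_for({"p1": 1.2}), _counts_for({"p1": 0.0})
        assert call_barriers(ct2, kd2, sets, "H3K27me3")[0].call is BarrierCall.LOSS
        assert call_barriers(ct2, kd2, sets, "H3K9me3")[0].call is BarrierCall.NONE

    def test_raising_thresholds_is_monotone(self):
        rng = np.random.default_rng(2)
        names = [f"p{i}" for i in range(60)]
        ms_ct = {n: float(rng.normal(0, 2)) for n in names}
        ms_kd = {n: float(rng.normal(0, 2)) for n in names}
        sets = _sets_from(names[:30], names[30:])
        prev = None
        for thr in (0.5, 1.0, 1.5, 2.0, 3.0):
            recs = call_barriers(
                _counts_for(ms_ct), _counts_for(ms_kd), sets, "H3K9me3",
                m_threshold=thr, delta_threshold=thr,
            )
            n_called = sum(r.call is not BarrierCall.NONE for r in recs)
            if prev is not None:
                assert n_called <= prev
            prev = n_called

    def test_condition_swap_exchanges_loss_and_gain(self):
        rng = np.random.default_rng(3)
        names = [f"p{i}" for i in range(40)]
        ms_ct = {n: float(rng.normal(0, 2)) for n in names}
        ms_kd = {n: float(rng.normal(0, 2)) for n in names}
        sets = _sets_from(names[:20], names[20:])
        swapped = ExclusiveSets(sets.b_only, sets.a_only, sets.shared_b,
                                sets.shared_a, sets.overlap_fraction)
        fwd = call_barriers(_counts_for(ms_ct), _counts_for(ms_kd), sets, "H3K9me3")
        rev = call_barriers(_counts_for(ms_kd), _counts_for(ms_ct), swapped, "H3K9me3")
        fwd_by = {r.peak.name: r.call for r in fwd}
        rev_by = {r.peak.name: r.call for r in rev}
        flip = {BarrierCall.LOSS: BarrierCall.GAIN,
                BarrierCall.GAIN: BarrierCall.LOSS,
                BarrierCall.NONE: BarrierCall.NONE}
        assert rev_by == {n: flip[c] for n, c in fwd_by.items()}

    def test_m_values_agree_with_direct_recomputation(self, wide_genome):
        rng = np.random.default_rng(4)
        track_ct = random_track(rng, wide_genome)
        track_kd = random_track(rng, wide_genome)
        peaks = IntervalSet(
            GenomicInterval("chr1", 15_000 + 4000 * i, 15_200 + 4000 * i, f"p{i}")
            for i in range(10)
        )
        sets = exclusive_peaks(peaks, IntervalSet())
        recs = call_barriers(
            flank_counts(peaks, track_ct, 10_000),
            flank_counts(peaks, track_kd, 10_000),
            sets, "H3K9me3",
        )
        for r in recs:
            s, e = r.peak.start, r.peak.end
            up = track_ct.values["chr1"][s - 10_000:s].sum()
            down = track_ct.values["chr1"][e:e + 10_000].sum()
            assert r.m_ct == pytest.approx(np.log2((up + 1) / (down + 1)))
            assert r.delta_m == pytest.approx(r.m_kd - r.m_ct)


class TestMDistribution:
    def test_symmetric_flanks_center_the_distribution_at_zero(self):
        rng = np.random.default_rng(5)
        recs = [
            _record(f"p{i}", float(rng.normal(0, 0.05)), 0.0, "shared")
            for i in range(400)
        ]
        df = m_distribution(recs, bin_width=0.25)
        center_mass = df.loc[df.bin_center.abs() < 0.125, "count"].sum()
        assert center_mass > 350
        assert df["count"].sum() == 400

    def test_histogram_mass_per_subset_matches_subset_size(self):
        recs = [_record(f"a{i}", 0.0, 0.0, "CT") for i in range(7)]
        recs += [_record(f"b{i}", 1.0, 0.0, "shared") for i in range(5)]
        df = m_distribution(recs)
        by = df.groupby("subset")["count"].sum()
        assert by["CT"] == 7 and by["shared"] == 5

    def test_exclusive_barrier_subset_has_larger_variance(self, small_dataset):
        """Planted barriers widen the M distribution of exclusive peaks
        relative to common peaks."""
        ds = small_dataset
        _, recs = barrier_pipeline(
            ds.peaks["CT"], ds.peaks["KD"],
            ds.tracks["H3K9me3_CT"], ds.tracks["H3K9me3_KD"],
        )
        m_excl = [r.m_ct for r in recs if r.exclusive_set == "CT"]
        m_common = [r.m_ct for r in recs if r.exclusive_set == "shared"]
        assert np.var(m_excl) > 4 * np.var(m_common)


class TestRnaAsymmetry:
    def test_identical_up_down_rna_gives_flat_null(self, wide_genome):
        track = _const(wide_genome, 2.0)
        recs = [
            dataclasses.replace(
                _record(f"p{i}", 0.0, 0.0, "CT"),
                peak=GenomicInterval("chr1", 20_000 + 5000 * i,
                                     20_300 + 5000 * i, f"p{i}"),
                call=BarrierCall.LOSS if i < 12 else BarrierCall.NONE,
            )
            for i in range(30)
        ]
        res = rna_asymmetry(recs, track, 5_000, seed=0)
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_too_few_barrier_sites_is_error(self, wide_genome):
        recs = [_record("p0", 0.0, 0.0, "CT", call=BarrierCall.LOSS)]
        recs += [_record(f"n{i}", 0.0, 0.0, "CT") for i in range(5)]
        with pytest.raises(ValueError, match="barrier sites"):
            rna_asymmetry(recs, _const(wide_genome), 5_000)

    def test_empty_control_set_is_error(self, wide_genome):
        recs = [
            _record(f"p{i}", 0.0, 0.0, "CT", call=BarrierCall.LOSS)
            for i in range(12)
        ]
        with pytest.raises(ValueError, match="control"):
            rna_asymmetry(recs, _const(wide_genome), 5_000)

    def test_planted_rna_coupling_detected(self, small_dataset, small_config):
        """With rna_coupling > 0, RNA asymmetry at CT-barrier (LOSS) sites
        exceeds matched controls."""
        ds = small_dataset
        _, recs = barrier_pipeline(
            ds.peaks["CT"], ds.peaks["KD"],
            ds.tracks["H3K9me3_CT"], ds.tracks["H3K9me3_KD"],
        )
        res = rna_asymmetry(recs, ds.tracks["RNA"],
                            small_config.flank_bases, seed=0)
        assert res.median_barrier > res.median_control
        assert res.pvalue < 0.01


@settings(deadline=None, max_examples=50)
@given(
    up=st.integers(0, 10**6),
    down=st.integers(0, 10**6),
    pc=st.floats(0.1, 10.0),
)
def test_m_value_sign_tracks_flank_ordering(up, down, pc):
    """M > 0 iff upstream > downstream; |M| bounded by log2 dynamic range."""
    m, a = m_value(up, down, pc)
    if up > down:
        assert m > 0
    elif up < down:
        assert m < 0
    else:
        assert m == 0.0
    assert abs(m) <= np.log2((10**6 + pc) / pc)
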