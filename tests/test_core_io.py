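"""Interval/coverage model, BED/bedGraph round-trips, closest distances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import barrierseq as bq
from barrierseq.core import (
    Genome,
    GenomicInterval,
    IntervalSet,
    UNDEFINED_DISTANCE,
    closest_distance,
)
from barrierseq.io import BedParseError

from conftest import random_intervals, random_track


class TestGenomicInterval:
    def test_rejects_empty_and_negative(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -5, 10)

    def test_midpoint_is_floor_of_center(self):
        assert GenomicInterval("chr1", 0, 101).midpoint == 50

    def test_overlap_bases(self):
        a = GenomicInterval("chr1", 0, 100)
        assert a.overlap_bases(GenomicInterval("chr1", 50, 150)) == 50
        assert a.overlap_bases(GenomicInterval("chr2", 50, 150)) == 0


class TestBed:
    def test_bed6_line_parses_all_fields(self, genome, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t100\tpeak1\t5\t+\n")
        (iv,) = bq.read_bed(p, genome)
        assert (iv.chrom, iv.start, iv.end, iv.name, iv.score, iv.strand) == (
            "chr1", 0, 100, "peak1", 5.0, "+",
        )

    def test_empty_interval_is_parse_error_with_line_number(self, genome, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t10\nchr1\t100\t100\n")
        with pytest.raises(BedParseError, match="bad.bed:2"):
            bq.read_bed(p, genome)

    def test_unknown_chromosome_strict_vs_lenient(self, genome, tmp_path):
        p = tmp_path / "c.bed"
        p.write_text("chrUn\t0\t10\nchr1\t0\t10\n")
        with pytest.raises(BedParseError):
            bq.read_bed(p, genome, strict=True)
        assert len(bq.read_bed(p, genome, strict=False)) == 1

    def test_comment_and_track_lines_ignored(self, genome, tmp_path):
        p = tmp_path / "d.bed"
        p.write_text("# comment\ntrack name=x\nbrowser position\nchr1\t0\t10\n")
        assert len(bq.read_bed(p, genome)) == 1

    def test_thousand_line_round_trip_identity(self, genome, tmp_path):
        rng = np.random.default_rng(0)
        ivs = random_intervals(rng, genome, 1000)
        # give some intervals scores and strands
        ivs = IntervalSet(
            GenomicInterval(iv.chrom, iv.start, iv.end, iv.name,
                            float(i % 7), "+-."[i % 3])
            for i, iv in enumerate(ivs)
        )
        p = tmp_path / "rt.bed"
        bq.write_bed(ivs, p)
        assert bq.read_bed(p, genome) == ivs


class TestBedGraph:
    def test_sum_over_covered_window(self, genome, tmp_path):
        p = tmp_path / "a.bedGraph"
        p.write_text("chr1\t0\t10\t2.0\n")
        track = bq.read_bedgraph(p, genome)
        assert track.window_sum("chr1", 0, 10) == 20.0

    def test_uncovered_positions_are_zero(self, genome, tmp_path):
        p = tmp_path / "a.bedGraph"
        p.write_text("chr1\t0\t10\t2.0\n")
        track = bq.read_bedgraph(p, genome)
        assert track.window_sum("chr1", 10, 20) == 0.0

    def test_overlapping_records_rejected(self, genome, tmp_path):
        p = tmp_path / "bad.bedGraph"
        p.write_text("chr1\t0\t10\t2.0\nchr1\t5\t15\t1.0\n")
        with pytest.raises(BedParseError, match="overlap"):
            bq.read_bedgraph(p, genome)

    def test_random_track_round_trip_per_base_identical(self, genome, tmp_path):
        rng = np.random.default_rng(1)
        track = random_track(rng, genome)
        p = tmp_path / "rt.bedGraph"
        bq.write_bedgraph(track, p)
        back = bq.read_bedgraph(p, genome)
        for chrom in genome.chrom_names:
            np.testing.assert_array_equal(back.values[chrom], track.values[chrom])

    def test_coverage_conservation_total_equals_records(self, genome, tmp_path):
        rng = np.random.default_rng(2)
        track = random_track(rng, genome)
        p = tmp_path / "c.bedGraph"
        bq.write_bedgraph(track, p)
        total = 0.0
        for line in p.read_text().splitlines():
            _, s, e, v = line.split("\t")
            total += (int(e) - int(s)) * float(v)
        assert total == pytest.approx(track.total())

    def test_out_of_bounds_query_is_error(self, genome):
        track = bq.CoverageTrack(genome)
        with pytest.raises(ValueError):
            track.window_sum("chr1", 99_990, 100_010)


class TestIntervalEngine:
    """Overlap queries must agree with a quadratic brute-force scan."""

    @pytest.mark.parametrize("seed", range(5))
    def test_intersect_subtract_match_brute_force(self, genome, seed):
        rng = np.random.default_rng(seed)
        a = random_intervals(rng, genome, 300, prefix="a")
        b = random_intervals(rng, genome, 300, prefix="b")
        brute_hit = {
            iv.name for iv in a if any(iv.overlaps(j) for j in b)
        }
        assert {iv.name for iv in a.intersect(b)} == brute_hit
        assert {iv.name for iv in a.subtract_whole(b)} == (
            {iv.name for iv in a} - brute_hit
        )

    def test_indexing_conserves_set_size(self, genome):
        rng = np.random.default_rng(3)
        a = random_intervals(rng, genome, 100)
        a.overlapping(a[0])  # force index build
        assert len(a) == 100

    def test_overlap_bases_merges_partners(self):
        a = IntervalSet([
            GenomicInterval("chr1", 0, 60, "x"),
            GenomicInterval("chr1", 40, 100, "y"),
        ])
        assert a.overlap_bases(GenomicInterval("chr1", 0, 100)) == 100


class TestClosestDistance:
    def test_overlapping_pair_is_zero(self):
        a = IntervalSet([GenomicInterval("chr1", 0, 100)])
        b = IntervalSet([GenomicInterval("chr1", 50, 60)])
        assert closest_distance(a, b)[0][1] == 0

    def test_edge_and_midpoint_modes(self):
        a = IntervalSet([GenomicInterval("chr1", 0, 100)])
        b = IntervalSet([GenomicInterval("chr1", 150, 160)])
        assert closest_distance(a, b, mode="edge")[0][1] == 50
        assert closest_distance(a, b, mode="midpoint")[0][1] == 105

    def test_missing_chromosome_gives_sentinel(self):
        a = IntervalSet([GenomicInterval("chr2", 0, 10)])
        b = IntervalSet([GenomicInterval("chr1", 0, 10)])
        assert closest_distance(a, b)[0][1] == UNDEFINED_DISTANCE

    @pytest.mark.parametrize("mode", ["edge", "midpoint"])
    def test_matches_brute_force_all_pairs(self, genome, mode):
        rng = np.random.default_rng(7)
        a = random_intervals(rng, genome, 100, prefix="a")
        b = random_intervals(rng, genome, 100, prefix="b")
        result = dict(
            (iv.name, d) for iv, d in closest_distance(a, b, mode=mode)
        )
        for iv in a:
            ds = []
            for j in b:
                if j.chrom != iv.chrom:
                    continue
                if mode == "edge":
                    ds.append(max(0, max(j.start - iv.end, iv.start - j.end)))
                else:
                    ds.append(abs(j.midpoint - iv.midpoint))
            expected = min(ds) if ds else UNDEFINED_DISTANCE
            assert result[iv.name] == expected

    def test_agrees_with_bedtools_closest(self, genome, tmp_path):
        """Independent cross-check against bedtools on a small fixture."""
        import shutil
        import subprocess

        if shutil.which("bedtools") is None:
            pytest.skip("bedtools not on PATH")
        rng = np.random.default_rng(11)
        a = random_intervals(rng, genome, 40, prefix="a")
        b = random_intervals(rng, genome, 40, prefix="b")
        fa, fb, fg = tmp_path / "a.bed", tmp_path / "b.bed", tmp_path / "g.txt"
        order = {c: i for i, c in enumerate(genome.chrom_names)}
        key = lambda iv: (order[iv.chrom], iv.start, iv.end)
        bq.write_bed(sorted(a, key=key), fa)
        bq.write_bed(sorted(b, key=key), fb)
        bq.write_chrom_sizes(genome, fg)
        out = subprocess.run(
            ["bedtools", "closest", "-a", fa, "-b", fb, "-d", "-t", "first",
             "-g", fg],
            capture_output=True, text=True, check=True,
        ).stdout
        ours = {iv.name: d for iv, d in closest_distance(a, b, mode="edge")}
        for line in out.strip().splitlines():
            cols = line.split("\t")
            name, dist = cols[3], int(cols[-1])
            if dist == -1:  # bedtools sentinel for no partner
                assert ours[name] == UNDEFINED_DISTANCE
            elif dist == 0:  # overlap
                assert ours[name] == 0
            else:
                # bedtools counts a bookended pair as 1; we report the
                # pure edge gap (bookended = 0)
                assert ours[name] == dist - 1


@settings(deadline=None, max_examples=30)
@given(
    data=st.lists(
        st.tuples(st.integers(0, 900), st.integers(1, 100)),
        min_size=1, max_size=40,
    )
)
def test_overlap_bases_never_exceeds_query_length(data):
    """Merged repeat coverage of a window is bounded by the window length."""
    ivs = IntervalSet(
        GenomicInterval("chr1", s, s + l, name=f"i{k}")
        for k, (s, l) in enumerate(data)
    )
    q = GenomicInterval("chr1", 100, 400)
    covered = ivs.overlap_bases(q)
    assert 0 <= covered <= len(q)
    # agrees with per-base brute force
    mask = np.zeros(1000, dtype=bool)
    for s, l in data:
        mask[s:s + l] = True
    assert covered == int(mask[100:400].sum())
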