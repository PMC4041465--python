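"""Interval algebra against brute-force per-base oracles, and peak-file I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from p53cistrome.intervals import (
    GenomicInterval,
    Peak,
    PeakParseError,
    PeakSet,
    merge_intervals,
    overlap_pairs,
    overlapping,
    read_peaks,
    subtract,
    write_peaks,
)
from .conftest import coverage_mask, random_peakset


class TestTypes:
    def test_interval_invariants(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 10)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)

    def test_summit_must_lie_inside(self):
        iv = GenomicInterval("chr1", 100, 200)
        with pytest.raises(ValueError):
            Peak(iv, 200, 0, 0)
        assert Peak(iv, 100, 0, 0).summit == 100

    def test_duplicate_peaks_rejected(self):
        iv = GenomicInterval("chr1", 0, 10)
        with pytest.raises(ValueError):
            PeakSet([Peak(iv, 5, 0, 0, "s"), Peak(iv, 3, 0, 0, "s")])


class TestIO:
    def test_narrowpeak_summit_from_offset(self, tmp_path):
        f = tmp_path / "a.narrowPeak"
        f.write_text("chr1\t100\t200\tp1\t50\t.\t8.1\t5.2\t4.0\t30\n")
        ps = read_peaks(f, format="narrowPeak")
        p = ps[0]
        assert (p.start, p.end, p.summit) == (100, 200, 130)
        assert p.reads == 50 and p.score == pytest.approx(8.1)

    def test_narrowpeak_unknown_offset_uses_midpoint(self, tmp_path):
        f = tmp_path / "a.narrowPeak"
        f.write_text("chr1\t100\t201\tp1\t0\t.\t1\t-1\t-1\t-1\n")
        assert read_peaks(f)[0].summit == 150

    def test_bed3_summit_is_floor_midpoint(self, tmp_path):
        f = tmp_path / "a.bed"
        f.write_text("chr1\t100\t201\n")
        assert read_peaks(f, format="bed")[0].summit == 150

    def test_empty_file(self, tmp_path):
        f = tmp_path / "a.bed"
        f.write_text("")
        assert len(read_peaks(f, format="bed")) == 0

    def test_malformed_line_names_line_number(self, tmp_path):
        f = tmp_path / "a.bed"
        f.write_text("chr1\t0\t10\nchr1\t50\t40\n")
        with pytest.raises(PeakParseError, match="line 2"):
            read_peaks(f, format="bed")

    def test_unknown_format(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            read_peaks(tmp_path / "x", format="gff")

    @pytest.mark.parametrize("fmt", ["narrowPeak", "bed"])
    def test_round_trip_exact(self, tmp_path, rng, fmt):
        ps = random_peakset(rng, 50).with_names("rt")
        f = tmp_path / f"rt.{fmt}"
        write_peaks(ps, f, format=fmt)
        back = read_peaks(f, format=fmt)
        for a, b in zip(ps, back):
            assert (a.chrom, a.start, a.end) == (b.chrom, b.start, b.end)
            if fmt == "narrowPeak":
                assert a.summit == b.summit and a.reads == b.reads


class TestMerge:
    def test_overlapping_pair(self):
        ps = PeakSet(
            [
                Peak(GenomicInterval("c", 0, 10), 5, 1.0, 3, "a"),
                Peak(GenomicInterval("c", 5, 15), 7, 2.0, 4, "b"),
            ]
        )
        m = merge_intervals(ps)
        assert len(m) == 1
        assert (m[0].start, m[0].end) == (0, 15)
        assert m[0].summit == 7  # from the higher-score constituent
        assert m[0].reads == 7

    def test_disjoint_unchanged(self):
        ps = PeakSet(
            [
                Peak(GenomicInterval("c", 0, 10), 5),
                Peak(GenomicInterval("c", 20, 30), 25),
            ]
        )
        assert [(p.start, p.end) for p in merge_intervals(ps)] == [(0, 10), (20, 30)]

    def test_book_ended_coalesced(self):
        ps = PeakSet(
            [
                Peak(GenomicInterval("c", 0, 10), 5),
                Peak(GenomicInterval("c", 10, 20), 15),
            ]
        )
        m = merge_intervals(ps)
        assert [(p.start, p.end) for p in m] == [(0, 20)]

    def test_against_per_base_oracle(self, rng):
        for _ in range(20):
            ps = random_peakset(rng, 200, chrom_len=10_000)
            merged = merge_intervals(ps)
            mask = coverage_mask(ps, "chrA", 10_000)
            assert coverage_mask(merged, "chrA", 10_000).tolist() == mask.tolist()
            # component count = number of 0->1 transitions in the mask
            ncomp = int(np.diff(mask.astype(int), prepend=0).clip(min=0).sum())
            assert len(merged) == ncomp

    def test_idempotent(self, rng):
        ps = random_peakset(rng, 100)
        once = merge_intervals(ps)
        twice = merge_intervals(once)
        assert [(p.start, p.end) for p in once] == [(p.start, p.end) for p in twice]


class TestOverlapSubtract:
    def _single(self, a_iv, b_iv):
        a = PeakSet([Peak(GenomicInterval("c", *a_iv), a_iv[0])], label="a")
        b = PeakSet([Peak(GenomicInterval("c", *b_iv), b_iv[0])], label="b")
        return a, b

    def test_one_bp_overlap(self):
        a, b = self._single((100, 200), (199, 300))
        assert len(overlap_pairs(a, b, 1)) == 1

    def test_half_open_touching(self):
        a, b = self._single((100, 200), (200, 300))
        assert overlap_pairs(a, b, 1) == []

    def test_min_bp_validation(self):
        a, b = self._single((0, 10), (5, 15))
        with pytest.raises(ValueError):
            overlap_pairs(a, b, 0)

    def test_pairs_match_brute_force_and_symmetry(self, rng):
        for _ in range(10):
            a = random_peakset(rng, 100, label="a")
            b = random_peakset(rng, 100, label="b")
            got = {
                (pa.start, pa.end, pb.start, pb.end) for pa, pb in overlap_pairs(a, b, 1)
            }
            want = {
                (pa.start, pa.end, pb.start, pb.end)
                for pa in a
                for pb in b
                if pa.interval.overlap_bp(pb.interval) >= 1
            }
            assert got == want
            swapped = {
                (pb.start, pb.end, pa.start, pa.end) for pa, pb in overlap_pairs(b, a, 1)
            }
            assert got == swapped

    def test_subtract_examples(self):
        a = PeakSet(
            [
                Peak(GenomicInterval("c", 0, 10), 0, name="x"),
                Peak(GenomicInterval("c", 50, 60), 50, name="y"),
            ]
        )
        b = PeakSet([Peak(GenomicInterval("c", 5, 7), 5)])
        assert [(p.start, p.end) for p in subtract(a, b)] == [(50, 60)]
        assert len(subtract(a, PeakSet([]))) == 2

    def test_subtract_overlap_partition(self, rng):
        for _ in range(10):
            a = random_peakset(rng, 80, label="a")
            b = random_peakset(rng, 80, label="b")
            assert len(subtract(a, b)) + len(overlapping(a, b, 1)) == len(a)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(
        st.tuples(st.integers(0, 500), st.integers(1, 60)), min_size=1, max_size=40
    )
)
def test_merge_preserves_covered_bases(raw):
    peaks, seen = [], set()
    for start, length in raw:
        if (start, start + length) in seen:
            continue
        seen.add((start, start + length))
        peaks.append(Peak(GenomicInterval("c", start, start + length), start))
    ps = PeakSet(peaks)
    merged = merge_intervals(ps)
    assert coverage_mask(merged, "c", 600).tolist() == coverage_mask(ps, "c", 600).tolist()
    starts = [p.start for p in merged]
    assert starts == sorted(starts)
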