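import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cistrovar.intervals import (
    ConsensusLocus,
    GenomicInterval,
    PeakSet,
    fractional_intersect,
    merge_consensus,
    normalize_chrom,
    overlap_snps,
)
from oracles import covered_bp, naive_point_overlap, naive_union


def iv(s, e, chrom="chr1"):
    return GenomicInterval(chrom, s, e)


def loci_of(*spans, chrom="chr1"):
    return [ConsensusLocus(iv(s, e, chrom), frozenset({"x"})) for s, e in spans]


class TestGenomicInterval:
    def test_rejects_malformed(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 50)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 50)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 50)

    def test_chrom_dialects_normalized(self):
        assert GenomicInterval("1", 0, 10).chrom == "chr1"
        assert normalize_chrom("CHRX") == "chrX"


class TestMergeConsensus:
    def test_identity_on_disjoint_single_set(self):
        ps = PeakSet("only", [iv(0, 100), iv(200, 300)])
        loci = merge_consensus([ps])
        assert [(l.start, l.end) for l in loci] == [(0, 100), (200, 300)]
        assert all(l.sources == frozenset({"only"}) for l in loci)

    def test_overlapping_spans_union(self):
        loci = merge_consensus(
            [PeakSet("a", [iv(0, 100)]), PeakSet("b", [iv(50, 150)])]
        )
        assert len(loci) == 1
        assert (loci[0].start, loci[0].end) == (0, 150)
        assert loci[0].sources == frozenset({"a", "b"})

    def test_half_open_abutment_does_not_merge(self):
        loci = merge_consensus(
            [PeakSet("a", [iv(0, 100)]), PeakSet("b", [iv(100, 200)])]
        )
        assert [(l.start, l.end) for l in loci] == [(0, 100), (100, 200)]
        # one shared base pair does merge
        loci2 = merge_consensus(
            [PeakSet("a", [iv(0, 100)]), PeakSet("b", [iv(99, 200)])]
        )
        assert len(loci2) == 1

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 60)), max_size=200),
           st.data())
    def test_matches_naive_union_oracle(self, raw, data):
        spans = [(s, s + w) for s, w in raw]
        n_sets = data.draw(st.integers(1, 4))
        sets = [PeakSet(f"s{i}", []) for i in range(n_sets)]
        buckets = [[] for _ in range(n_sets)]
        for i, (s, e) in enumerate(spans):
            buckets[i % n_sets].append(iv(s, e))
        sets = [PeakSet(f"s{i}", b) for i, b in enumerate(buckets) if b]
        loci = merge_consensus(sets)
        assert [(l.start, l.end) for l in loci] == naive_union(spans)
        # covered bp preserved
        assert sum(len(l) for l in loci) == covered_bp(spans)
        # pairwise non-overlap and every input contained in exactly one locus
        for a, b in zip(loci, loci[1:]):
            assert a.end <= b.start or a.chrom != b.chrom
        for s, e in spans:
            containing = [l for l in loci if l.start <= s and e <= l.end]
            assert len(containing) == 1

    def test_sources_require_one_bp_overlap(self):
        loci = merge_consensus(
            [
                PeakSet("a", [iv(0, 50)]),
                PeakSet("b", [iv(40, 90)]),
                PeakSet("c", [iv(90, 120)]),  # abuts, stays separate
            ]
        )
        assert loci[0].sources == frozenset({"a", "b"})
        assert loci[1].sources == frozenset({"c"})


class TestOverlapSnps:
    def test_half_open_boundaries(self):
        loci = loci_of((0, 100))
        assign, n = overlap_snps(
            [("in", "chr1", 50), ("at_end", "chr1", 100), ("at_start", "chr1", 0)],
            loci,
        )
        assert set(assign.snp_id) == {"in", "at_start"}
        assert n == 2

    def test_deduplicated_count_and_unassigned_chrom(self):
        loci = merge_consensus(
            [PeakSet("a", [iv(0, 100)]), PeakSet("b", [iv(50, 150)])]
        )
        snps = [("s1", "chr1", 60), ("s2", "chr1", 500), ("s3", "chr9", 60)]
        assign, n = overlap_snps(snps, loci)
        assert n == 1 and list(assign.snp_id) == ["s1"]
        assert "a,b" in assign.sources.iloc[0]

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        st.lists(st.tuples(st.integers(0, 400), st.integers(1, 50)), max_size=40),
        st.lists(st.integers(0, 450), max_size=60),
    )
    def test_matches_linear_scan_oracle(self, raw, positions):
        spans = naive_union([(s, s + w) for s, w in raw])
        loci = loci_of(*spans)
        points = [(f"p{i}", pos) for i, pos in enumerate(positions)]
        assign, n = overlap_snps([(pid, "chr1", pos) for pid, pos in points], loci)
        expected = naive_point_overlap(points, spans)
        assert set(assign.snp_id) == expected
        assert n == len(expected)


class TestFractionalIntersect:
    def test_reflexive_at_any_fraction(self):
        a = loci_of((0, 100), (300, 450))
        for f in (0.01, 0.25, 1.0):
            summary = fractional_intersect(a, a, f)
            assert summary.n_shared == len(a)
            assert summary.n_only_a == summary.n_only_b == 0

    def test_threshold_is_inclusive_at_25_percent(self):
        a = loci_of((0, 100))
        b = loci_of((75, 200))
        assert fractional_intersect(a, b, 0.25).n_shared == 1
        assert fractional_intersect(a, b, 0.26).n_shared == 0

    def test_partition_invariants(self):
        a = loci_of((0, 100), (200, 300), (1000, 1100))
        b = loci_of((90, 260), (5000, 5100))
        s = fractional_intersect(a, b, 0.25)
        assert s.n_shared + s.n_only_a == len(a)
        assert s.n_shared_b + s.n_only_b == len(b)

    def test_empty_inputs_give_zero_counts(self):
        s = fractional_intersect([], loci_of((0, 10)), 0.25)
        assert s.n_shared == 0 and s.n_only_b == 1

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            fractional_intersect([], [], 0.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(st.tuples(st.integers(0, 900), st.integers(5, 80)), max_size=30),
        st.lists(st.tuples(st.integers(0, 900), st.integers(5, 80)), max_size=30),
    )
    def test_monotone_in_fraction_and_any_overlap_limit(self, ra, rb):
        a = loci_of(*naive_union([(s, s + w) for s, w in ra]))
        b = loci_of(*naive_union([(s, s + w) for s, w in rb]))
        fracs = [1e-9, 0.1, 0.25, 0.5, 0.75, 1.0]
        counts = [fractional_intersect(a, b, f).n_shared for f in fracs]
        assert counts == sorted(counts, reverse=True)
        # min_fraction -> 0+ equals any-overlap intersection
        any_overlap = sum(
            1 for la in a if any(la.interval.overlaps(lb.interval) for lb in b)
        )
        assert counts[0] == any_overlap

    def test_multiple_subject_pieces_accumulate(self):
        # 20 bp + 10 bp = 30% of a 100 bp query
        a = loci_of((0, 100))
        b = loci_of((0, 20), (50, 60))
        assert fractional_intersect(a, b, 0.30).n_shared == 1
        assert fractional_intersect(a, b, 0.31).n_shared == 0
        # reciprocal mode needs one subject piece to satisfy both sides
        assert fractional_intersect(a, b, 0.30, reciprocal=True).n_shared == 0
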