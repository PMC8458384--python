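import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from secall.enhancer_stitch import (
    exclude_tss_contained,
    filter_blacklist,
    stitch,
    union_peaks,
)
from secall.genome_io import GeneModel, GenomicInterval

from conftest import random_intervals


def oracle_stitch(peaks, distance):
    """Naive O(n^2) transitive merge: union-find over gap <= distance.

    Returns sorted (chrom, start, end, num_loci) tuples, where num_loci
    counts constituents after merging overlapping/abutting input peaks.
    """
    n = len(peaks)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def gap(a, b):
        return max(a.start, b.start) - min(a.end, b.end)

    for i in range(n):
        for j in range(i + 1, n):
            if peaks[i].chrom == peaks[j].chrom and gap(peaks[i], peaks[j]) <= distance:
                parent[find(i)] = find(j)
    clusters = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(peaks[i])
    out = []
    for members in clusters.values():
        members.sort(key=lambda p: p.start)
        # count constituents: merge overlapping/abutting members naively
        loci = 0
        cur_end = None
        for p in members:
            if cur_end is None or p.start > cur_end:
                loci += 1
                cur_end = p.end
            else:
                cur_end = max(cur_end, p.end)
        out.append(
            (members[0].chrom, members[0].start,
             max(p.end for p in members), loci)
        )
    return sorted(out)


class TestFilterBlacklist:
    def test_one_bp_overlap_removes(self):
        reads = [GenomicInterval("chr1", 100, 175, "+")]
        bl = [GenomicInterval("chr1", 150, 400)]
        assert filter_blacklist(reads, bl) == []

    def test_half_open_abutment_retains(self):
        reads = [GenomicInterval("chr1", 100, 150, "+")]
        bl = [GenomicInterval("chr1", 150, 400)]
        assert filter_blacklist(reads, bl) == reads

    def test_empty_blacklist_is_identity(self, rng, small_genome):
        reads = random_intervals(rng, small_genome, 50)
        assert filter_blacklist(reads, []) == reads

    def test_survivor_order_preserved_and_count_conserved(self, rng, small_genome):
        reads = random_intervals(rng, small_genome, 200, max_len=100)
        bl = random_intervals(rng, small_genome, 5, max_len=500)
        kept = filter_blacklist(reads, bl)
        expected = [r for r in reads if not any(r.overlaps(b) for b in bl)]
        assert kept == expected
        assert len(kept) + sum(
            any(r.overlaps(b) for b in bl) for r in reads
        ) == len(reads)


class TestUnionPeaks:
    def test_overlap_merges(self):
        merged = union_peaks(
            [[GenomicInterval("chr1", 0, 100)], [GenomicInterval("chr1", 50, 150)]]
        )
        assert merged == [GenomicInterval("chr1", 0, 150)]

    def test_disjoint_stay_separate(self):
        merged = union_peaks(
            [[GenomicInterval("chr1", 0, 100)], [GenomicInterval("chr1", 200, 300)]]
        )
        assert [(m.start, m.end) for m in merged] == [(0, 100), (200, 300)]

    def test_abutting_merge_and_single_set_identity(self):
        merged = union_peaks(
            [[GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 0, 100)]]
        )
        assert merged == [GenomicInterval("chr1", 0, 200)]

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            union_peaks([])


class TestExcludeTssContained:
    GENES = [GeneModel("G1", "chr1", "+", 50_000, 60_000)]

    def test_fully_contained_peak_excluded(self):
        keep, out = exclude_tss_contained(
            [GenomicInterval("chr1", 48_500, 49_000)], self.GENES
        )
        assert keep == [] and len(out) == 1

    def test_straddling_peak_stays_stitchable(self):
        keep, out = exclude_tss_contained(
            [GenomicInterval("chr1", 47_900, 48_100)], self.GENES
        )
        assert len(keep) == 1 and out == []

    def test_no_genes_keeps_everything(self):
        peaks = [GenomicInterval("chr1", 0, 10)]
        keep, out = exclude_tss_contained(peaks, [])
        assert keep == peaks and out == []

    def test_partition_is_lossless(self, rng, small_genome):
        peaks = random_intervals(rng, small_genome, 100, max_len=3000)
        genes = [
            GeneModel(f"G{i}", "chr1", "+", s, s + 1000)
            for i, s in enumerate(range(500, 9_000, 2_500))
        ]
        keep, out = exclude_tss_contained(peaks, genes)
        assert len(keep) + len(out) == len(peaks)
        assert sorted((p.chrom, p.start) for p in keep + out) == sorted(
            (p.chrom, p.start) for p in peaks
        )


class TestStitch:
    def test_gap_below_distance_stitches(self):
        out = stitch(
            [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 10_000, 10_100)]
        )
        assert len(out) == 1
        assert (out[0].region.start, out[0].region.end) == (0, 10_100)
        assert out[0].num_loci == 2

    def test_boundary_gap_exactly_at_distance(self):
        at = stitch(
            [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 12_600, 12_700)]
        )
        over = stitch(
            [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 12_601, 12_701)]
        )
        assert len(at) == 1 and len(over) == 2

    def test_no_cross_chromosome_stitching(self):
        out = stitch(
            [GenomicInterval("chr1", 0, 100), GenomicInterval("chr2", 50, 150)]
        )
        assert len(out) == 2

    def test_matches_quadratic_oracle(self, rng, small_genome):
        genome = {"chr1": 200_000, "chr2": 150_000}
        for _ in range(50):
            n = int(rng.integers(2, 120))
            peaks = []
            for _ in range(n):
                chrom = "chr1" if rng.integers(2) else "chr2"
                start = int(rng.integers(0, genome[chrom] - 5_000))
                peaks.append(
                    GenomicInterval(chrom, start, start + int(rng.integers(100, 5_000)))
                )
            got = sorted(
                (e.region.chrom, e.region.start, e.region.end, e.num_loci)
                for e in stitch(peaks, 12_500)
            )
            assert got == oracle_stitch(peaks, 12_500)

    def test_idempotent(self, rng):
        peaks = [
            GenomicInterval("chr1", int(s), int(s) + 500)
            for s in rng.integers(0, 500_000, size=60)
        ]
        once = stitch(peaks)
        twice = stitch([e.region for e in once])
        assert [(e.region.start, e.region.end) for e in twice] == [
            (e.region.start, e.region.end) for e in once
        ]

    def test_constituent_conservation(self, rng):
        # after sanitation the constituent count equals merged-peak count
        peaks = []
        for s in rng.integers(0, 300_000, size=80):
            peaks.append(GenomicInterval("chr1", int(s), int(s) + 400))
        merged = union_peaks([peaks])
        stitched = stitch(merged)
        assert sum(e.num_loci for e in stitched) == len(merged)

    def test_ids_follow_genomic_order(self):
        out = stitch(
            [GenomicInterval("chr2", 0, 100), GenomicInterval("chr1", 0, 100)]
        )
        assert [e.id for e in out] == ["EN_00001", "EN_00002"]
        assert out[0].region.chrom == "chr1"

    @settings(max_examples=40, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(0, 100_000), st.integers(1, 4_000)),
            min_size=1, max_size=40,
        )
    )
    def test_stitch_never_loses_span(self, spans):
        peaks = [GenomicInterval("chr1", s, s + l) for s, l in spans]
        out = stitch(peaks)
        assert min(e.region.start for e in out) == min(p.start for p in peaks)
        assert max(e.region.end for e in out) == max(p.end for p in peaks)
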