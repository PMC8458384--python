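import numpy as np
import pytest

from secall.enhancer_stitch import StitchedEnhancer, stitch
from secall.genome_io import GeneModel, GenomeDefinition, GenomicInterval
from secall.se_rank import (
    ActiveGeneSet,
    DegenerateCurveError,
    ScoredEnhancer,
    active_genes,
    assign_gene,
    score_enhancers,
    se_gene_set,
    tangent_cutoff,
)
from secall.signal_track import build_track, normalize_rpm, region_signal

from conftest import random_intervals


def exhaustive_cutoff(signals, tol=1e-12):
    """Oracle: loop over every index, maximum of scaled_rank - scaled_signal,
    ties (within tol, both axes on [0, 1]) to the largest index."""
    s = sorted(signals)
    n = len(s)
    d = [i / (n - 1) - (s[i] - s[0]) / (s[-1] - s[0]) for i in range(n)]
    best = max(d)
    return max(i for i in range(n) if d[i] >= best - tol)


def _stitched(chrom, start, end, id="E1"):
    region = GenomicInterval(chrom, start, end)
    return StitchedEnhancer(region, (region,), id)


class TestTangentCutoff:
    def test_quadratic_curve_tangency_at_half(self):
        # y = x^2 sampled at x = 0, 0.1, ..., 1.0: the slope-1 tangent of
        # x - x^2 sits at x = 0.5, scaled signal 0.25
        x = np.linspace(0, 1, 11)
        curve = tangent_cutoff(x**2)
        assert curve.scaled_rank[curve.cutoff_index] == pytest.approx(0.5)
        assert curve.scaled_signal[curve.cutoff_index] == pytest.approx(0.25)

    def test_linear_curve_yields_zero_ses(self):
        signals = np.linspace(3.0, 9.0, 20)
        curve = tangent_cutoff(signals)
        # every point ties at distance 0; the largest index wins, so
        # nothing lies strictly above the cutoff
        assert curve.cutoff_index == len(signals) - 1
        assert np.sum(signals > curve.cutoff_signal) == 0

    def test_random_convex_curves_match_exhaustive_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 200))
            increments = np.sort(rng.exponential(scale=1.0, size=n - 1))
            signals = np.concatenate([[0.0], np.cumsum(increments)])
            curve = tangent_cutoff(signals)
            assert curve.cutoff_index == exhaustive_cutoff(signals)

    def test_scaling_invariance(self, rng):
        signals = rng.exponential(size=50) ** 2
        base = tangent_cutoff(signals)
        for c in (0.01, 7.0, 1e6):
            scaled = tangent_cutoff(c * signals)
            assert scaled.cutoff_index == base.cutoff_index
            n_base = np.sum(base.signals > base.cutoff_signal)
            n_scaled = np.sum(scaled.signals > scaled.cutoff_signal)
            assert n_scaled == n_base

    def test_degenerate_inputs_raise(self):
        with pytest.raises(DegenerateCurveError):
            tangent_cutoff([1.0])
        with pytest.raises(DegenerateCurveError):
            tangent_cutoff([2.0, 2.0, 2.0])

    def test_negative_nets_allowed_and_rank_low(self):
        curve = tangent_cutoff([-5.0, -1.0, 0.5, 30.0])
        assert curve.signals[0] == -5.0
        assert curve.cutoff_signal < 30.0


class TestScoreEnhancers:
    def test_net_is_chip_minus_input(self, small_genome, rng):
        chip_reads = random_intervals(rng, small_genome, 500)
        input_reads = random_intervals(rng, small_genome, 500)
        chip = build_track(chip_reads, small_genome)
        inp = build_track(input_reads, small_genome)
        enh = [_stitched("chr1", 1000, 3000)]
        (s,) = score_enhancers(enh, chip, inp)
        assert s.chip_signal == pytest.approx(region_signal(chip, enh[0].region))
        assert s.net_signal == pytest.approx(s.chip_signal - s.input_signal)

    def test_zero_input_gives_net_equal_chip(self, small_genome, rng):
        chip = build_track(random_intervals(rng, small_genome, 300), small_genome)
        zero_counts = {c: np.zeros(-(-small_genome[c] // 50), dtype=int)
                       for c in small_genome}
        inp = normalize_rpm(zero_counts, 1_000_000, small_genome)
        enhancers = [
            _stitched("chr1", 0, 2000, "a"), _stitched("chr2", 100, 900, "b")
        ]
        for s in score_enhancers(enhancers, chip, inp):
            assert s.net_signal == pytest.approx(s.chip_signal)

    def test_rank_descending_and_unique(self, small_genome, rng):
        chip = build_track(random_intervals(rng, small_genome, 800), small_genome)
        inp = build_track(random_intervals(rng, small_genome, 800), small_genome)
        enhancers = [
            _stitched("chr1", s, s + 500, f"e{s}")
            for s in range(0, 9_000, 1_000)
        ]
        scored = score_enhancers(enhancers, chip, inp)
        nets = [s.net_signal for s in scored]
        assert nets == sorted(nets, reverse=True)
        assert [s.rank for s in scored] == list(range(1, len(scored) + 1))

    def test_mismatched_genomes_error(self, small_genome, rng):
        other = GenomeDefinition({"chr1": 10_000})
        chip = build_track(random_intervals(rng, small_genome, 10), small_genome)
        inp = build_track([GenomicInterval("chr1", 0, 75, "+")], other)
        with pytest.raises(ValueError):
            score_enhancers([_stitched("chr1", 0, 100)], chip, inp)


class TestActiveGenes:
    def _genes(self, n, spacing=1_000, chrom="chr1"):
        return [
            GeneModel(f"G{i:02d}", chrom, "+", i * spacing, i * spacing + 500)
            for i in range(n)
        ]

    def test_two_thirds_cardinality(self, small_genome, rng):
        track = build_track(random_intervals(rng, small_genome, 200), small_genome)
        for n, expected in [(9, 6), (10, 6), (1, 0), (3, 2), (30, 20)]:
            active = active_genes(self._genes(n, spacing=300), track)
            assert len(active.genes) == expected

    def test_top_signal_genes_selected(self, small_genome):
        genes = self._genes(9)
        reads = []
        # pile reads only on the promoters of the last three genes
        for g in genes[-3:]:
            reads += [
                GenomicInterval("chr1", g.tss, g.tss + 75, "+")
            ] * 50
        reads += [GenomicInterval("chr1", 9_000, 9_075, "+")]
        track = build_track(reads, small_genome)
        active = active_genes(genes, track)
        top3 = {g.name for g in genes[-3:]}
        assert top3 <= active.names

    def test_all_zero_track_breaks_ties_lexicographically(self, small_genome):
        zero = {c: np.zeros(-(-small_genome[c] // 50), dtype=int)
                for c in small_genome}
        track = normalize_rpm(zero, 1_000_000, small_genome)
        genes = self._genes(10)
        active = active_genes(genes, track)
        assert [g.name for g in active.genes] == sorted(
            g.name for g in genes
        )[:6]


class TestAssignGene:
    def _active(self, positions):
        genes = [
            GeneModel(name, "chr1", "+", pos, pos + 100)
            for name, pos in positions
        ]
        return ActiveGeneSet(genes, {g.name: 0.0 for g in genes})

    def test_nearest_tss_wins(self):
        enh = _stitched("chr1", 9_000, 11_000)  # center 10,000
        active = self._active([("A", 9_000), ("B", 12_000)])
        assert assign_gene(enh, active) == "A"

    def test_equidistant_tie_breaks_lexicographically(self):
        enh = _stitched("chr1", 9_000, 11_000)
        active = self._active([("B", 9_000), ("A", 11_000)])
        assert assign_gene(enh, active) == "A"

    def test_no_same_chromosome_gene_gives_none(self):
        enh = _stitched("chr1", 0, 100)
        genes = [GeneModel("A", "chr2", "+", 0, 100)]
        active = ActiveGeneSet(genes, {"A": 0.0})
        assert assign_gene(enh, active) is None

    def test_nearest_property_brute_force(self, rng):
        # no other active gene may be strictly closer than the assignment
        for _ in range(200):
            n = int(rng.integers(1, 15))
            positions = sorted(rng.choice(100_000, size=n, replace=False))
            active = self._active(
                [(f"G{i:02d}", int(p)) for i, p in enumerate(positions)]
            )
            start = int(rng.integers(0, 90_000))
            enh = _stitched("chr1", start, start + int(rng.integers(1, 9_000)))
            chosen = assign_gene(enh, active)
            center = enh.region.center
            d_chosen = min(
                abs(g.tss - center) for g in active.genes if g.name == chosen
            )
            assert all(
                abs(g.tss - center) >= d_chosen for g in active.genes
            )


class TestSeMembership:
    def test_downward_closed_in_rank(self, rng):
        from secall.se_rank import flag_super_enhancers

        for _ in range(30):
            nets = rng.exponential(size=25) ** 2
            scored = [
                ScoredEnhancer(_stitched("chr1", 100 * i, 100 * i + 50, f"e{i}"),
                               float(net), 0.0, float(net))
                for i, net in enumerate(nets)
            ]
            scored.sort(key=lambda s: -s.net_signal)
            for r, s in enumerate(scored, 1):
                s.rank = r
            scored, _ = flag_super_enhancers(scored)
            flags = [s.is_super for s in scored]  # sorted by rank
            assert flags == sorted(flags, reverse=True)

    def test_se_gene_set_collects_assigned_supers(self):
        rows = [
            ScoredEnhancer(_stitched("chr1", 0, 10, "a"), 1, 0, 1,
                           rank=1, is_super=True, assigned_gene="G1"),
            ScoredEnhancer(_stitched("chr1", 20, 30, "b"), 1, 0, 1,
                           rank=2, is_super=True, assigned_gene=None),
            ScoredEnhancer(_stitched("chr1", 40, 50, "c"), 1, 0, 1,
                           rank=3, is_super=False, assigned_gene="G2"),
        ]
        assert se_gene_set(rows) == {"G1"}
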