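"""Input-subtracted enhancer ranking, tangent cutoff, gene assignment.

Stitched enhancers are scored by H3K27ac signal (length x density) with the
matched input-control signal subtracted, ranked, and split into
super-enhancers (SEs) and typical enhancers at the point where a slope-1
line is tangent to the ranked-signal curve after both axes are scaled to
[0, 1]. On the discrete, sorted curve that tangency point is exactly the
index maximising (scaled rank - scaled signal) — the point of maximum
vertical distance below the diagonal — which is robust where a numerical
derivative of a step curve would not be. Each stitched enhancer is then
assigned to the single active gene (top two-thirds of genes by promoter
H3K27ac) whose TSS is nearest the enhancer's centre.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .enhancer_stitch import StitchedEnhancer
from .genome_io import GeneModel
from .signal_track import SignalTrack, region_signal
from .genome_io import GenomicInterval

PROMOTER_RANK_HALFWIDTH = 500
ACTIVE_FRACTION_NUM = 2
ACTIVE_FRACTION_DEN = 3


class DegenerateCurveError(ValueError):
    """Raised when no SE cutoff is definable (n < 2 or all signals equal)."""


@dataclass
class ScoredEnhancer:
    """A stitched enhancer with ChIP/input signals, rank and SE call."""

    enhancer: StitchedEnhancer
    chip_signal: float
    input_signal: float
    net_signal: float
    rank: int | None = None
    is_super: bool = False
    assigned_gene: str | None = None

    @property
    def region(self) -> GenomicInterval:
        return self.enhancer.region


@dataclass
class RankedCurve:
    """Ascending net signals with scaled axes and the tangent cutoff.

    ``scaled_rank[i] = i / (n - 1)`` and ``scaled_signal`` is min-max
    scaled, so both axes run over [0, 1]. Enhancers with net signal
    strictly above ``cutoff_signal`` are super-enhancers.
    """

    signals: np.ndarray
    scaled_rank: np.ndarray
    scaled_signal: np.ndarray
    cutoff_index: int
    cutoff_signal: float


def score_enhancers(
    stitched: list[StitchedEnhancer],
    chip_track: SignalTrack,
    input_track: SignalTrack,
) -> list[ScoredEnhancer]:
    """Score each stitched enhancer and sort descending by net signal.

    Net signal is ChIP minus input over the stitched region, each track
    rpm-normalised to its own depth; negative nets are kept (they rank
    last). Rank 1 is the strongest enhancer. Ties are broken by genomic
    position so reruns are byte-stable.
    """
    if chip_track.genome != input_track.genome:
        raise ValueError("ChIP and input tracks are on different genomes")
    scored = []
    for e in stitched:
        chip = region_signal(chip_track, e.region)
        inp = region_signal(input_track, e.region)
        scored.append(ScoredEnhancer(e, chip, inp, chip - inp))
    scored.sort(
        key=lambda s: (-s.net_signal, s.region.chrom, s.region.start)
    )
    for rank, s in enumerate(scored, start=1):
        s.rank = rank
    return scored


def tangent_cutoff(net_signals) -> RankedCurve:
    """Find the SE cutoff where the line y = x is tangent to the ranked curve.

    Signals are sorted ascending and both axes scaled to [0, 1]; the cutoff
    is the index maximising (scaled_rank - scaled_signal). For a convex
    ranked curve this is the tangency point of a slope-1 line. Ties break
    to the largest index, so a perfectly linear curve yields zero SEs.
    """
    signals = np.sort(np.asarray(net_signals, dtype=float))
    n = len(signals)
    if n < 2:
        raise DegenerateCurveError(f"need >= 2 enhancers, got {n}")
    lo, hi = signals[0], signals[-1]
    if hi == lo:
        raise DegenerateCurveError("all net signals equal; no cutoff definable")
    scaled_rank = np.arange(n) / (n - 1)
    scaled_signal = (signals - lo) / (hi - lo)
    diff = scaled_rank - scaled_signal
    # ties broken to the largest index; both axes live on [0, 1], so a tiny
    # absolute tolerance absorbs rounding on exactly-linear curves
    cutoff_index = int(np.nonzero(diff >= diff.max() - 1e-12)[0][-1])
    return RankedCurve(
        signals=signals,
        scaled_rank=scaled_rank,
        scaled_signal=scaled_signal,
        cutoff_index=cutoff_index,
        cutoff_signal=float(signals[cutoff_index]),
    )


def flag_super_enhancers(
    scored: list[ScoredEnhancer],
) -> tuple[list[ScoredEnhancer], RankedCurve]:
    """Apply the tangent cutoff; enhancers with net > cutoff become SEs."""
    curve = tangent_cutoff([s.net_signal for s in scored])
    for s in scored:
        s.is_super = s.net_signal > curve.cutoff_signal
    return scored, curve


@dataclass
class ActiveGeneSet:
    """The top two-thirds of genes by promoter (TSS +/- 500 bp) H3K27ac."""

    genes: list[GeneModel]
    promoter_signal: dict[str, float]

    @property
    def names(self) -> set[str]:
        return {g.name for g in self.genes}


def active_genes(
    genes: list[GeneModel],
    chip_track: SignalTrack,
    promoter_halfwidth: int = PROMOTER_RANK_HALFWIDTH,
) -> ActiveGeneSet:
    """Rank genes by raw ChIP rpm in TSS +/- halfwidth; keep floor(2N/3).

    Promoter windows are clipped to the chromosome. Ties at the boundary
    break lexicographically by gene name for determinism.
    """
    if not genes:
        raise ValueError("need >= 1 gene")
    sig: dict[str, float] = {}
    for g in genes:
        chrom_len = chip_track.genome[g.chrom]
        lo = max(g.tss - promoter_halfwidth, 0)
        hi = min(g.tss + promoter_halfwidth, chrom_len)
        sig[g.name] = region_signal(
            chip_track, GenomicInterval(g.chrom, lo, hi)
        )
    n_active = (ACTIVE_FRACTION_NUM * len(genes)) // ACTIVE_FRACTION_DEN
    ordered = sorted(genes, key=lambda g: (-sig[g.name], g.name))
    return ActiveGeneSet(genes=ordered[:n_active], promoter_signal=sig)


def assign_gene(
    enhancer: ScoredEnhancer | StitchedEnhancer,
    active: ActiveGeneSet,
) -> str | None:
    """Nearest active-gene TSS to the enhancer centre, same chromosome only.

    Equidistant ties break to the lexicographically smaller gene name;
    with no active gene on the chromosome the enhancer stays unassigned.
    """
    region = enhancer.region
    center = region.center
    best: tuple[int, str] | None = None
    for g in active.genes:
        if g.chrom != region.chrom:
            continue
        key = (abs(g.tss - center), g.name)
        if best is None or key < best:
            best = key
    return best[1] if best else None


def call_super_enhancers(
    stitched: list[StitchedEnhancer],
    chip_track: SignalTrack,
    input_track: SignalTrack,
    genes: list[GeneModel],
    promoter_halfwidth: int = PROMOTER_RANK_HALFWIDTH,
) -> tuple[list[ScoredEnhancer], RankedCurve, ActiveGeneSet]:
    """Score, cut and assign in one step; scored list is sorted by rank."""
    scored = score_enhancers(stitched, chip_track, input_track)
    scored, curve = flag_super_enhancers(scored)
    active = active_genes(genes, chip_track, promoter_halfwidth)
    for s in scored:
        s.assigned_gene = assign_gene(s, active)
    return scored, curve, active


def se_gene_set(scored: list[ScoredEnhancer]) -> set[str]:
    """Genes associated with SEs: assigned genes of enhancers flagged super."""
    return {
        s.assigned_gene
        for s in scored
        if s.is_super and s.assigned_gene is not None
    }


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

SE_TABLE_COLUMNS = [
    "id", "chrom", "start", "end", "num_loci", "size_bp",
    "chip_signal", "input_signal", "net_signal", "rank", "is_super",
    "assigned_gene",
]


def write_se_table(scored: list[ScoredEnhancer], path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        fh.write("\t".join(SE_TABLE_COLUMNS) + "\n")
        for s in scored:
            r = s.region
            fh.write(
                f"{s.enhancer.id}\t{r.chrom}\t{r.start}\t{r.end}\t"
                f"{s.enhancer.num_loci}\t{s.enhancer.size}\t"
                f"{s.chip_signal:.6f}\t{s.input_signal:.6f}\t"
                f"{s.net_signal:.6f}\t{s.rank}\t{int(s.is_super)}\t"
                f"{s.assigned_gene if s.assigned_gene is not None else '.'}\n"
            )


def read_se_table(path) -> list[ScoredEnhancer]:
    """Re-ingest a table written by :func:`write_se_table`.

    Constituents are not recorded in the table; each row comes back as a
    single-constituent stitched enhancer, which is sufficient for
    annotation (only the region, SE flag and assigned gene are consumed).
    """
    out: list[ScoredEnhancer] = []
    with open(path) as fh:
        rows = [ln.rstrip("\n") for ln in fh if not ln.startswith("#")]
    if not rows:
        return out
    cols = rows[0].split("\t")
    idx = {c: i for i, c in enumerate(cols)}
    for row in rows[1:]:
        if not row:
            continue
        f = row.split("\t")
        region = GenomicInterval(
            f[idx["chrom"]], int(f[idx["start"]]), int(f[idx["end"]])
        )
        enh = StitchedEnhancer(region, (region,), f[idx["id"]])
        gene = f[idx["assigned_gene"]]
        out.append(
            ScoredEnhancer(
                enh,
                chip_signal=float(f[idx["chip_signal"]]),
                input_signal=float(f[idx["input_signal"]]),
                net_signal=float(f[idx["net_signal"]]),
                rank=int(f[idx["rank"]]),
                is_super=bool(int(f[idx["is_super"]])),
                assigned_gene=None if gene == "." else gene,
            )
        )
    return out


def write_curve(curve: RankedCurve, path, header: str | None = None) -> None:
    """Two-column TSV of the ranked curve for hockey-stick plotting."""
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        fh.write("scaled_rank\tnet_signal\n")
        for x, s in zip(curve.scaled_rank, curve.signals):
            fh.write(f"{x:.6f}\t{s:.6f}\n")
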