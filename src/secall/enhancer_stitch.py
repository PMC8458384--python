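"""Blacklist filtering, peak-set union, TSS exclusion and 12.5-kb stitching.

The enhancer universe is built ROSE-style: reads overlapping ENCODE-type
blacklist regions are removed before any track is built; enhancer peak
calls from multiple upstream parameter sets are unioned; peaks fully
contained in a +/-2 kb promoter window are excluded from stitching; and the
remaining peaks are merged transitively whenever the gap between two peaks
on the same chromosome is at most 12,500 bp.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .genome_io import GeneModel, GenomicInterval, ReadFootprint

STITCH_DISTANCE = 12_500
TSS_EXCLUSION_WINDOW = 2_000


@dataclass(frozen=True)
class StitchedEnhancer:
    """A merged cluster of enhancer peaks.

    ``region`` spans from the first constituent's start to the last
    constituent's end; ``num_loci`` counts the constituents.
    """

    region: GenomicInterval
    constituents: tuple[GenomicInterval, ...]
    id: str

    def __post_init__(self) -> None:
        if not self.constituents:
            raise ValueError("stitched enhancer needs >= 1 constituent")
        if self.region.start != min(c.start for c in self.constituents):
            raise ValueError("region start != min constituent start")
        if self.region.end != max(c.end for c in self.constituents):
            raise ValueError("region end != max constituent end")

    @property
    def num_loci(self) -> int:
        return len(self.constituents)

    @property
    def size(self) -> int:
        return len(self.region)


def _merged_by_chrom(
    intervals: Iterable[GenomicInterval],
) -> dict[str, np.ndarray]:
    """Merge overlapping/abutting intervals; per-chrom (n, 2) sorted arrays."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out: dict[str, np.ndarray] = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        merged: list[list[int]] = []
        for s, e in pairs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = np.asarray(merged, dtype=np.int64)
    return out


def filter_blacklist(
    reads: list[ReadFootprint],
    blacklist: list[GenomicInterval],
) -> list[ReadFootprint]:
    """Drop reads overlapping any blacklist interval by >= 1 bp.

    Survivors keep their original order. Half-open abutment (read end equals
    blacklist start) is no overlap.
    """
    if not blacklist or not reads:
        return list(reads)
    merged = _merged_by_chrom(blacklist)
    # vectorised per chromosome: a read [s, e) hits the merged blacklist iff
    # the first blacklist block with end > s starts before e
    keep = np.ones(len(reads), dtype=bool)
    by_chrom: dict[str, list[int]] = {}
    for i, r in enumerate(reads):
        by_chrom.setdefault(r.chrom, []).append(i)
    for chrom, idx in by_chrom.items():
        blocks = merged.get(chrom)
        if blocks is None:
            continue
        idx_arr = np.asarray(idx)
        starts = np.asarray([reads[i].start for i in idx], dtype=np.int64)
        ends = np.asarray([reads[i].end for i in idx], dtype=np.int64)
        j = np.searchsorted(blocks[:, 1], starts, side="right")
        in_range = j < len(blocks)
        hit = np.zeros(len(idx_arr), dtype=bool)
        hit[in_range] = blocks[j[in_range], 0] < ends[in_range]
        keep[idx_arr[hit]] = False
    return [r for r, k in zip(reads, keep) if k]


def union_peaks(
    peak_sets: list[list[GenomicInterval]],
) -> list[GenomicInterval]:
    """Union peak calls across parameter sets into maximal merged intervals.

    Overlapping and abutting peaks merge; output is sorted by
    (chromosome, start). Two peak sets over the same mark describe one
    enhancer landscape, hence the merge.
    """
    if not peak_sets:
        raise ValueError("need >= 1 peak set")
    merged = _merged_by_chrom(iv for peaks in peak_sets for iv in peaks)
    out: list[GenomicInterval] = []
    for chrom in sorted(merged):
        for s, e in merged[chrom]:
            out.append(GenomicInterval(chrom, int(s), int(e)))
    return out


def exclude_tss_contained(
    peaks: list[GenomicInterval],
    genes: list[GeneModel],
    window: int = TSS_EXCLUSION_WINDOW,
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Partition peaks into (stitchable, excluded) by promoter containment.

    A peak is excluded iff it lies entirely inside the ``TSS +/- window``
    region of at least one gene. Peaks that merely straddle a window edge
    remain stitchable.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append(g.tss)  # type: ignore[arg-type]
    tss_by_chrom = {c: np.sort(np.asarray(v)) for c, v in tss_by_chrom.items()}
    stitchable: list[GenomicInterval] = []
    excluded: list[GenomicInterval] = []
    for p in peaks:
        tss = tss_by_chrom.get(p.chrom)
        contained = False
        if tss is not None:
            # contained in [t - w, t + w) iff t in [end - w, start + w]
            lo = np.searchsorted(tss, p.end - window, side="left")
            hi = np.searchsorted(tss, p.start + window, side="right")
            contained = hi > lo
        (excluded if contained else stitchable).append(p)
    return stitchable, excluded


def stitch(
    peaks: list[GenomicInterval],
    distance: int = STITCH_DISTANCE,
) -> list[StitchedEnhancer]:
    """Stitch peaks whose same-chromosome gap is <= ``distance``.

    The merge is the transitive closure of gap(p, q) <= distance with
    gap = next.start - previous cluster end; a gap of exactly ``distance``
    stitches. Overlapping/abutting input peaks are first merged into single
    constituents. Ids follow genomic order (chromosomes sorted by name).
    """
    merged = _merged_by_chrom(peaks)
    out: list[StitchedEnhancer] = []
    counter = 0
    for chrom in sorted(merged):
        blocks = merged[chrom]
        cluster: list[GenomicInterval] = []
        cluster_end = -1

        def flush() -> None:
            nonlocal counter
            if cluster:
                counter += 1
                region = GenomicInterval(
                    chrom, cluster[0].start, max(c.end for c in cluster)
                )
                out.append(
                    StitchedEnhancer(region, tuple(cluster), f"EN_{counter:05d}")
                )

        for s, e in blocks:
            iv = GenomicInterval(chrom, int(s), int(e))
            if cluster and iv.start - cluster_end > distance:
                flush()
                cluster = []
            cluster.append(iv)
            cluster_end = max(cluster_end, iv.end)
        flush()
    return out


def write_stitched(
    enhancers: list[StitchedEnhancer],
    path,
    header: str | None = None,
) -> None:
    """Emit stitched enhancers as TSV: id, chrom, start, end, num_loci, size."""
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        fh.write("id\tchrom\tstart\tend\tnum_loci\tsize\n")
        for e in enhancers:
            r = e.region
            fh.write(
                f"{e.id}\t{r.chrom}\t{r.start}\t{r.end}\t{e.num_loci}\t{e.size}\n"
            )
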