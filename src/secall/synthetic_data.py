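"""Synthetic ChIP-seq landscapes with known ground truth.

Generates every input the SE pipeline consumes — genome, gene table,
blacklist, planted typical enhancers and multi-constituent super-enhancer
clusters, ChIP and input read sets, enhancer peak calls, TF peaks,
differential-gene lists and an expression matrix with planted driver
correlations — plus a manifest of the planted truth, so every stage can be
scored for precision/recall without any external download.

The generator emulates the statistical structure of H3K27ac ChIP-seq over
a small genome: narrow high-density typical peaks and broad clustered SE
constituents over a uniform sequencing background, with an input library
that is background only. Reads are fixed-length single-end 75-bp
footprints with random strand, matching the short single-end libraries
such tracks are typically built from. Placement keeps planted regions far
apart (>= 25 kb) and clear of promoter windows, so planted enhancers are
stitchable and TSS exclusion never removes them by construction.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import (
    GeneModel,
    GenomeDefinition,
    GenomicInterval,
    write_bed,
    write_gene_list,
    write_gene_table,
    write_genome,
)

REGION_SPACING = 25_000       # minimum edge-to-edge gap between planted regions
PLACEMENT_MARGIN = 13_000     # per-slot margin guaranteeing the spacing
TSS_CLEARANCE = 4_000         # enhancer edge to TSS: > 2 kb beyond the 2 kb window


class SimulationError(ValueError):
    """Infeasible or inconsistent simulation configuration."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic landscape; defaults are the study scale.

    The default bundle is a 2 x 5 Mb genome with 50 genes, 30 typical
    enhancers and 5 super-enhancers of 3-7 constituents each, sequenced to
    200k ChIP + 200k input reads. Per-constituent read counts put roughly
    10x more net signal in an SE than in a typical enhancer.
    """

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000}
    )
    n_genes: int = 50
    gene_length_range: tuple[int, int] = (3_000, 15_000)
    n_typical_enhancers: int = 30
    n_super_enhancers: int = 5
    constituent_width_range: tuple[int, int] = (800, 1_500)
    se_constituent_range: tuple[int, int] = (3, 7)
    se_gap_min: int = 2_000
    se_gap_max: int = 12_400
    se_span_range: tuple[int, int] = (10_000, 60_000)
    reads_per_typical_enhancer: int = 500
    reads_per_se_constituent: int = 1_000
    reads_per_active_promoter: int = 150
    n_chip_reads: int = 200_000
    n_input_reads: int = 200_000
    read_length: int = 75
    blacklist_per_chrom: int = 1
    blacklist_width: int = 10_000
    blacklist_read_fraction: float = 0.01
    peak_jitter: int = 25
    n_deg_down: int = 20
    n_deg_up: int = 20
    frac_down_bound: float = 0.6
    frac_up_bound: float = 0.4
    tf_peak_width: int = 300
    expr_n_samples: int = 23
    expr_n_correlated: int = 10
    expr_rho_range: tuple[float, float] = (0.4, 0.9)
    expr_noise_sd: float = 1.0

    def validate(self) -> None:
        counts = (
            self.n_genes, self.n_typical_enhancers, self.n_super_enhancers,
            self.n_chip_reads, self.n_input_reads, self.blacklist_per_chrom,
            self.n_deg_down, self.n_deg_up,
        )
        if any(c < 0 for c in counts):
            raise SimulationError("all counts must be >= 0")
        if not self.chrom_lengths:
            raise SimulationError("need >= 1 chromosome")
        if any(l <= 0 for l in self.chrom_lengths.values()):
            raise SimulationError("chromosome lengths must be > 0")
        if self.se_gap_max >= 12_500:
            raise SimulationError(
                "intra-SE gaps must stay below the 12,500 bp stitch distance"
            )
        if self.se_gap_min < 1 or self.se_gap_min > self.se_gap_max:
            raise SimulationError("invalid intra-SE gap range")
        if self.read_length < 1:
            raise SimulationError("read_length must be >= 1")
        if not 0 <= self.blacklist_read_fraction <= 1:
            raise SimulationError("blacklist_read_fraction must be in [0, 1]")
        if self.expr_n_samples < 3:
            raise SimulationError("expression needs >= 3 samples")
        if self.n_deg_down + self.n_deg_up > self.n_genes:
            raise SimulationError("more DEG genes requested than genes exist")
        if self.expr_n_correlated + 1 > max(self.n_genes, 1):
            raise SimulationError("more correlated genes than genes exist")


@dataclass
class PlantedEnhancer:
    """A planted enhancer region with its constituents and intended gene."""

    id: str
    region: GenomicInterval
    constituents: tuple[GenomicInterval, ...]
    intended_gene: str | None


@dataclass
class GroundTruth:
    """Everything needed to score each pipeline stage against the plant."""

    genome: GenomeDefinition
    genes: list[GeneModel]
    blacklist: list[GenomicInterval]
    super_enhancers: list[PlantedEnhancer]
    typical_enhancers: list[PlantedEnhancer]
    active_gene_names: list[str]
    expression_rho: dict[str, float]
    expression_driver: str | None
    deg_down: list[str]
    deg_up: list[str]
    tf_bound: dict[str, bool]


# ---------------------------------------------------------------------------
# Placement
# ---------------------------------------------------------------------------

def _round_robin(n: int, chroms: list[str]) -> dict[str, int]:
    out = {c: n // len(chroms) for c in chroms}
    for i in range(n % len(chroms)):
        out[chroms[i]] += 1
    return out


def _se_geometry(cfg: SimulationConfig, rng: np.random.Generator):
    """Draw constituent widths and gaps for one SE cluster."""
    k = int(rng.integers(cfg.se_constituent_range[0],
                         cfg.se_constituent_range[1] + 1))
    widths = rng.integers(cfg.constituent_width_range[0],
                          cfg.constituent_width_range[1] + 1, size=k)
    w_sum = int(widths.sum())
    span_lo = max(cfg.se_span_range[0], w_sum + (k - 1) * cfg.se_gap_min)
    span_hi = min(cfg.se_span_range[1], w_sum + (k - 1) * cfg.se_gap_max)
    if span_hi < span_lo:
        raise SimulationError(
            "SE span range infeasible for the constituent geometry"
        )
    span = int(rng.integers(span_lo, span_hi + 1))
    total_gap = span - w_sum
    gaps = np.full(k - 1, total_gap // (k - 1), dtype=int) if k > 1 else np.array([], dtype=int)
    if k > 1:
        gaps[: total_gap % (k - 1)] += 1
    return widths.tolist(), gaps.tolist(), span


def _place_elements(cfg: SimulationConfig, rng: np.random.Generator):
    """Lay out genes, enhancers and blacklist in spaced per-chromosome slots.

    Each chromosome is divided into equal slots; every planted element gets
    one slot and sits at a random offset inside it, at least
    PLACEMENT_MARGIN away from either slot edge, which enforces the
    >= 25 kb inter-region spacing and TSS clearance by construction.
    Raises before any file is written if the genome is too small.
    """
    chroms = list(cfg.chrom_lengths)
    gene_alloc = _round_robin(cfg.n_genes, chroms)
    typ_alloc = _round_robin(cfg.n_typical_enhancers, chroms)
    se_alloc = _round_robin(cfg.n_super_enhancers, chroms)

    genes_raw: list[tuple[str, int, int, str]] = []   # chrom, start, end, strand
    typical: list[GenomicInterval] = []
    ses: list[tuple[GenomicInterval, tuple[GenomicInterval, ...]]] = []
    blacklist: list[GenomicInterval] = []

    for chrom in chroms:
        chrom_len = cfg.chrom_lengths[chrom]
        spans: list[tuple[str, int, object]] = []
        for _ in range(gene_alloc[chrom]):
            length = int(rng.integers(*cfg.gene_length_range))
            spans.append(("gene", length, None))
        for _ in range(typ_alloc[chrom]):
            width = int(rng.integers(cfg.constituent_width_range[0],
                                     cfg.constituent_width_range[1] + 1))
            spans.append(("typical", width, None))
        for _ in range(se_alloc[chrom]):
            widths, gaps, span = _se_geometry(cfg, rng)
            spans.append(("se", span, (widths, gaps)))
        for _ in range(cfg.blacklist_per_chrom):
            spans.append(("blacklist", cfg.blacklist_width, None))
        if not spans:
            continue
        slot_len = chrom_len // len(spans)
        for kind, span, _extra in spans:
            if slot_len < span + 2 * PLACEMENT_MARGIN:
                raise SimulationError(
                    f"genome too small: {chrom} needs slots of "
                    f">= {span + 2 * PLACEMENT_MARGIN} bp for {len(spans)} "
                    f"elements but has {slot_len} bp"
                )
        order = rng.permutation(len(spans))
        for slot_idx, el_idx in enumerate(order):
            kind, span, extra = spans[el_idx]
            slot_start = slot_idx * slot_len
            room = slot_len - span - 2 * PLACEMENT_MARGIN
            start = slot_start + PLACEMENT_MARGIN + int(rng.integers(0, room + 1))
            end = start + span
            if kind == "gene":
                strand = "+" if rng.integers(0, 2) == 0 else "-"
                genes_raw.append((chrom, start, end, strand))
            elif kind == "typical":
                typical.append(GenomicInterval(chrom, start, end))
            elif kind == "se":
                widths, gaps = extra
                pos = start
                constituents = []
                for i, w in enumerate(widths):
                    constituents.append(GenomicInterval(chrom, pos, pos + w))
                    pos += w + (gaps[i] if i < len(gaps) else 0)
                region = GenomicInterval(chrom, start, constituents[-1].end)
                ses.append((region, tuple(constituents)))
            else:
                blacklist.append(GenomicInterval(chrom, start, end))

    genes_raw.sort()
    genes = [
        GeneModel(f"GENE{i + 1:03d}", chrom, strand, start, end)
        for i, (chrom, start, end, strand) in enumerate(genes_raw)
    ]
    typical.sort(key=lambda r: (r.chrom, r.start))
    ses.sort(key=lambda t: (t[0].chrom, t[0].start))
    blacklist.sort(key=lambda r: (r.chrom, r.start))
    _check_placement(genes, typical, ses, blacklist)
    return genes, typical, ses, blacklist


def _check_placement(genes, typical, ses, blacklist) -> None:
    """Verify spacing and TSS-clearance invariants of the layout."""
    regions = (
        [("typical", r) for r in typical]
        + [("se", r) for r, _ in ses]
        + [("blacklist", r) for r in blacklist]
    )
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for _, r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, rs in by_chrom.items():
        rs.sort(key=lambda r: r.start)
        for a, b in zip(rs, rs[1:]):
            if b.start - a.end < REGION_SPACING:
                raise SimulationError(
                    f"planted regions closer than {REGION_SPACING} bp on {chrom}"
                )
    tss_by_chrom: dict[str, list[int]] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append(g.tss)
    for kind, r in regions:
        if kind == "blacklist":
            continue
        for tss in tss_by_chrom.get(r.chrom, []):
            if r.start - TSS_CLEARANCE < tss < r.end + TSS_CLEARANCE:
                raise SimulationError("planted enhancer too close to a TSS")


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def _reads_in_region(
    region: GenomicInterval, n: int, read_len: int, rng: np.random.Generator
) -> list[GenomicInterval]:
    """n reads with footprints uniform inside the region, random strand."""
    hi = max(region.end - read_len, region.start + 1)
    starts = rng.integers(region.start, hi, size=n)
    strands = rng.integers(0, 2, size=n)
    return [
        GenomicInterval(region.chrom, int(s), int(s) + read_len,
                        "+" if st == 0 else "-")
        for s, st in zip(starts, strands)
    ]


def _background_reads(
    genome: GenomeDefinition,
    blacklist: list[GenomicInterval],
    n_total: int,
    blacklist_fraction: float,
    read_len: int,
    rng: np.random.Generator,
) -> list[GenomicInterval]:
    """Uniform background over the genome, with a planted blacklist fraction."""
    n_bl = int(round(n_total * blacklist_fraction)) if blacklist else 0
    n_uniform = n_total - n_bl
    chroms = list(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    alloc = rng.multinomial(n_uniform, lengths / lengths.sum())
    reads: list[GenomicInterval] = []
    for chrom, n in zip(chroms, alloc):
        if n == 0:
            continue
        starts = rng.integers(0, genome[chrom] - read_len, size=n)
        strands = rng.integers(0, 2, size=n)
        reads.extend(
            GenomicInterval(chrom, int(s), int(s) + read_len,
                            "+" if st == 0 else "-")
            for s, st in zip(starts, strands)
        )
    if n_bl:
        widths = np.array([len(b) for b in blacklist], dtype=float)
        alloc_bl = rng.multinomial(n_bl, widths / widths.sum())
        for region, n in zip(blacklist, alloc_bl):
            if n:
                reads.extend(_reads_in_region(region, int(n), read_len, rng))
    return reads


def _jitter_peaks(
    regions: list[GenomicInterval],
    jitter: int,
    genome: GenomeDefinition,
    rng: np.random.Generator,
) -> list[GenomicInterval]:
    out = []
    for r in regions:
        ds, de = rng.integers(-jitter, jitter + 1, size=2)
        start = max(0, r.start + int(ds))
        end = min(genome[r.chrom], r.end + int(de))
        out.append(GenomicInterval(r.chrom, start, max(end, start + 1)))
    out.sort(key=lambda r: (r.chrom, r.start))
    return out


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(
    gene_names: list[str],
    n_samples: int,
    rho: dict[str, float],
    driver: str,
    rng: np.random.Generator,
    noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Genes x samples matrix with planted driver correlations.

    The driver is standard normal; a gene with target correlation rho_g is
    ``rho_g * driver + sqrt(1 - rho_g^2) * noise`` (unit-variance when
    ``noise_sd`` is 1); all other genes are independent standard normal.
    """
    if n_samples < 3:
        raise SimulationError("expression needs >= 3 samples")
    if driver not in gene_names:
        raise SimulationError(f"driver {driver!r} not among gene names")
    d = rng.standard_normal(n_samples)
    rows = []
    for name in gene_names:
        if name == driver:
            rows.append(d)
        elif name in rho:
            r = rho[name]
            noise = rng.standard_normal(n_samples) * noise_sd
            rows.append(r * d + np.sqrt(max(0.0, 1 - r * r)) * noise)
        else:
            rows.append(rng.standard_normal(n_samples) * noise_sd)
    cols = [f"S{i + 1:02d}" for i in range(n_samples)]
    return pd.DataFrame(np.vstack(rows), index=gene_names, columns=cols)


# ---------------------------------------------------------------------------
# Gene assignment truth
# ---------------------------------------------------------------------------

def _intended_gene(
    region: GenomicInterval, active: list[GeneModel]
) -> str | None:
    center = region.center
    best: tuple[int, str] | None = None
    for g in active:
        if g.chrom != region.chrom:
            continue
        key = (abs(g.tss - center), g.name)
        if best is None or key < best:
            best = key
    return best[1] if best else None


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

BUNDLE_FILES = {
    "genome": "genome.tsv",
    "genes": "genes.tsv",
    "blacklist": "blacklist.bed",
    "chip_reads": "chip_reads.bed",
    "input_reads": "input_reads.bed",
    "peaks": "peaks.bed",
    "tf_peaks": "tf_peaks.bed",
    "deg_down": "deg_down.txt",
    "deg_up": "deg_up.txt",
    "expression": "expression.tsv",
}


def simulate(config: SimulationConfig, out_dir: str | Path) -> GroundTruth:
    """Generate the full input bundle plus ground truth under ``out_dir``.

    Identical seeds produce byte-identical bundles. The total ChIP read
    count written equals ``n_chip_reads`` exactly: enriched and promoter
    reads are planted first and the remainder is uniform background (with
    ``blacklist_read_fraction`` of it inside blacklist regions); a config
    whose planted reads exceed the library size is rejected, as is a
    genome too small for the spacing constraints — in both cases before
    any file is written.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genome = GenomeDefinition(config.chrom_lengths)
    genes, typical, ses, blacklist = _place_elements(config, rng)

    n_active = (2 * len(genes)) // 3
    active_idx = sorted(rng.choice(len(genes), size=n_active, replace=False)) if genes else []
    active = [genes[i] for i in active_idx]
    active_names = [g.name for g in active]

    typical_truth = [
        PlantedEnhancer(f"TE_{i + 1:03d}", r, (r,), _intended_gene(r, active))
        for i, r in enumerate(typical)
    ]
    se_truth = [
        PlantedEnhancer(f"SE_{i + 1:03d}", region, constituents,
                        _intended_gene(region, active))
        for i, (region, constituents) in enumerate(ses)
    ]

    n_planted = (
        config.reads_per_typical_enhancer * len(typical)
        + config.reads_per_se_constituent
        * sum(len(s.constituents) for s in se_truth)
        + config.reads_per_active_promoter * len(active)
    )
    if n_planted > config.n_chip_reads:
        raise SimulationError(
            f"planted reads ({n_planted}) exceed n_chip_reads "
            f"({config.n_chip_reads})"
        )

    chip_reads: list[GenomicInterval] = []
    for r in typical:
        chip_reads.extend(
            _reads_in_region(r, config.reads_per_typical_enhancer,
                             config.read_length, rng)
        )
    for s in se_truth:
        for c in s.constituents:
            chip_reads.extend(
                _reads_in_region(c, config.reads_per_se_constituent,
                                 config.read_length, rng)
            )
    for g in active:
        lo = max(g.tss - 500, 0)
        window = GenomicInterval(g.chrom, lo, min(g.tss + 500, genome[g.chrom]))
        chip_reads.extend(
            _reads_in_region(window, config.reads_per_active_promoter,
                             config.read_length, rng)
        )
    chip_reads.extend(
        _background_reads(genome, blacklist,
                          config.n_chip_reads - n_planted,
                          config.blacklist_read_fraction,
                          config.read_length, rng)
    )
    input_reads = _background_reads(
        genome, blacklist, config.n_input_reads,
        config.blacklist_read_fraction, config.read_length, rng,
    )

    constituents_all = [c for s in se_truth for c in s.constituents] + typical
    peaks = _jitter_peaks(constituents_all, config.peak_jitter, genome, rng)

    # DEG lists and TF peaks planted in bound genes' promoter windows
    deg_pool = rng.choice(len(genes), size=config.n_deg_down + config.n_deg_up,
                          replace=False) if genes else np.array([], dtype=int)
    deg_down = sorted(genes[i].name for i in deg_pool[: config.n_deg_down])
    deg_up = sorted(genes[i].name for i in deg_pool[config.n_deg_down:])
    gene_by_name = {g.name: g for g in genes}
    tf_peaks: list[GenomicInterval] = []
    tf_bound: dict[str, bool] = {}
    for names, frac in ((deg_down, config.frac_down_bound),
                        (deg_up, config.frac_up_bound)):
        n_bound = int(round(frac * len(names)))
        bound_idx = set(
            rng.choice(len(names), size=n_bound, replace=False).tolist()
        ) if names else set()
        for i, name in enumerate(names):
            tf_bound[name] = i in bound_idx
            if i in bound_idx:
                g = gene_by_name[name]
                half = config.tf_peak_width // 2
                center = g.tss + int(rng.integers(-1_500, 1_501))
                start = max(0, center - half)
                tf_peaks.append(
                    GenomicInterval(g.chrom, start,
                                    min(start + config.tf_peak_width,
                                        genome[g.chrom]))
                )
    tf_peaks.sort(key=lambda r: (r.chrom, r.start))

    # expression with planted driver correlations
    gene_names = [g.name for g in genes]
    driver = gene_names[0] if gene_names else None
    rho: dict[str, float] = {}
    if driver is not None and config.expr_n_correlated:
        targets = gene_names[1: 1 + config.expr_n_correlated]
        for name in targets:
            rho[name] = float(rng.uniform(*config.expr_rho_range))
    expr = (
        simulate_expression(gene_names, config.expr_n_samples, rho, driver,
                            rng, config.expr_noise_sd)
        if driver is not None
        else pd.DataFrame()
    )

    truth = GroundTruth(
        genome=genome, genes=genes, blacklist=blacklist,
        super_enhancers=se_truth, typical_enhancers=typical_truth,
        active_gene_names=active_names, expression_rho=rho,
        expression_driver=driver, deg_down=deg_down, deg_up=deg_up,
        tf_bound=tf_bound,
    )
    _write_bundle(config, truth, chip_reads, input_reads, peaks, tf_peaks,
                  expr, Path(out_dir))
    return truth


def _write_bundle(config, truth, chip_reads, input_reads, peaks, tf_peaks,
                  expr, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_genome(truth.genome, out_dir / BUNDLE_FILES["genome"])
    write_gene_table(truth.genes, out_dir / BUNDLE_FILES["genes"])
    write_bed(truth.blacklist, out_dir / BUNDLE_FILES["blacklist"])
    write_bed(chip_reads, out_dir / BUNDLE_FILES["chip_reads"])
    write_bed(input_reads, out_dir / BUNDLE_FILES["input_reads"])
    write_bed(peaks, out_dir / BUNDLE_FILES["peaks"])
    write_bed(tf_peaks, out_dir / BUNDLE_FILES["tf_peaks"])
    write_gene_list(truth.deg_down, out_dir / BUNDLE_FILES["deg_down"])
    write_gene_list(truth.deg_up, out_dir / BUNDLE_FILES["deg_up"])
    if len(expr):
        expr.to_csv(out_dir / BUNDLE_FILES["expression"], sep="\t",
                    index_label="gene", float_format="%.6f")

    tdir = out_dir / "truth"
    tdir.mkdir(exist_ok=True)
    with open(tdir / "super_enhancers.tsv", "w") as fh:
        fh.write("id\tchrom\tstart\tend\tnum_constituents\tconstituents\tintended_gene\n")
        for s in truth.super_enhancers:
            cons = ";".join(f"{c.start}-{c.end}" for c in s.constituents)
            fh.write(
                f"{s.id}\t{s.region.chrom}\t{s.region.start}\t{s.region.end}\t"
                f"{len(s.constituents)}\t{cons}\t{s.intended_gene or '.'}\n"
            )
    with open(tdir / "typical_enhancers.tsv", "w") as fh:
        fh.write("id\tchrom\tstart\tend\tintended_gene\n")
        for s in truth.typical_enhancers:
            fh.write(
                f"{s.id}\t{s.region.chrom}\t{s.region.start}\t{s.region.end}\t"
                f"{s.intended_gene or '.'}\n"
            )
    write_gene_list(truth.active_gene_names, tdir / "active_genes.txt")
    with open(tdir / "expression_rho.tsv", "w") as fh:
        fh.write("gene\trho\n")
        if truth.expression_driver is not None:
            fh.write(f"{truth.expression_driver}\t1.0\n")
        for name in sorted(truth.expression_rho):
            fh.write(f"{name}\t{truth.expression_rho[name]:.6f}\n")
    with open(tdir / "deg_bound.tsv", "w") as fh:
        fh.write("gene\tdirection\tbound\n")
        for name in truth.deg_down:
            fh.write(f"{name}\tdown\t{int(truth.tf_bound[name])}\n")
        for name in truth.deg_up:
            fh.write(f"{name}\tup\t{int(truth.tf_bound[name])}\n")
    with open(tdir / "config.txt", "w") as fh:
        for key, value in asdict(config).items():
            fh.write(f"{key}\t{value}\n")


def read_ground_truth(out_dir: str | Path) -> dict:
    """Re-read the truth manifest into plain dictionaries (round-trip aid)."""
    tdir = Path(out_dir) / "truth"
    ses = pd.read_csv(tdir / "super_enhancers.tsv", sep="\t")
    typ = pd.read_csv(tdir / "typical_enhancers.tsv", sep="\t")
    rho = pd.read_csv(tdir / "expression_rho.tsv", sep="\t")
    deg = pd.read_csv(tdir / "deg_bound.tsv", sep="\t")
    with open(tdir / "active_genes.txt") as fh:
        active = [ln.strip() for ln in fh if ln.strip()]
    return {
        "super_enhancers": ses, "typical_enhancers": typ,
        "active_genes": active, "expression_rho": rho, "deg_bound": deg,
    }


def bundle_checksums(out_dir: str | Path) -> dict[str, str]:
    """SHA-256 of every bundle file, for determinism checks."""
    out_dir = Path(out_dir)
    sums = {}
    for key, name in BUNDLE_FILES.items():
        path = out_dir / name
        if path.exists():
            sums[key] = hashlib.sha256(path.read_bytes()).hexdigest()
    return sums
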