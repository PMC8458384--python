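"""Precedence-based peak annotation and direct-target classification.

TF ChIP-seq peaks are classified into exactly one genomic feature category
by fixed precedence — super-enhancer, then typical enhancer, then promoter
(4-kb window centred on the TSS), then gene body (the remaining portion of
genes longer than 2 kb, from 2 kb downstream of the TSS to the TES), else
intergenic. Differential genes are split into direct and indirect TF
targets by whether any TF peak overlaps the gene's regulatory region,
defined here as promoter window, gene body and every stitched enhancer
assigned to the gene.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .genome_io import GeneModel, GenomicInterval
from .se_rank import ScoredEnhancer

PROMOTER_HALFWIDTH = 2_000
MIN_GENE_BODY_LENGTH = 2_000

DEFAULT_PRECEDENCE = (
    "super_enhancer", "typical_enhancer", "promoter", "gene_body",
)
CATEGORIES = DEFAULT_PRECEDENCE + ("intergenic",)


@dataclass
class FeatureCatalog:
    """Feature intervals the annotation precedence runs over."""

    super_enhancers: list[GenomicInterval]
    typical_enhancers: list[GenomicInterval]
    promoters: dict[str, GenomicInterval]
    gene_bodies: dict[str, GenomicInterval]


def build_catalog(
    scored: list[ScoredEnhancer],
    genes: list[GeneModel],
    promoter_halfwidth: int = PROMOTER_HALFWIDTH,
    min_gene_body_length: int = MIN_GENE_BODY_LENGTH,
) -> FeatureCatalog:
    """Derive promoter/gene-body windows and split enhancers by SE flag.

    Promoters are ``2 * promoter_halfwidth`` windows centred on the TSS,
    clipped at the chromosome start. The gene body runs from the promoter's
    inner edge (2 kb downstream of the TSS in transcription direction) to
    the TES, and exists only for genes longer than ``min_gene_body_length``.
    """
    ses = [s.region for s in scored if s.is_super]
    typical = [s.region for s in scored if not s.is_super]
    promoters: dict[str, GenomicInterval] = {}
    gene_bodies: dict[str, GenomicInterval] = {}
    for g in genes:
        lo = max(g.tss - promoter_halfwidth, 0)
        promoters[g.name] = GenomicInterval(
            g.chrom, lo, g.tss + promoter_halfwidth
        )
        if g.length > min_gene_body_length:
            if g.strand == "+":
                body = (g.tx_start + min_gene_body_length, g.tx_end)
            else:
                body = (g.tx_start, g.tx_end - min_gene_body_length)
            if body[1] > body[0]:
                gene_bodies[g.name] = GenomicInterval(g.chrom, *body)
    return FeatureCatalog(ses, typical, promoters, gene_bodies)


def _hits_any(peak: GenomicInterval, features) -> bool:
    return any(peak.overlaps(f) for f in features)


def classify_peak(
    peak: GenomicInterval,
    catalog: FeatureCatalog,
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
) -> str:
    """First category in precedence order with >= 1 bp overlap, else intergenic."""
    pools = {
        "super_enhancer": catalog.super_enhancers,
        "typical_enhancer": catalog.typical_enhancers,
        "promoter": catalog.promoters.values(),
        "gene_body": catalog.gene_bodies.values(),
    }
    for category in precedence:
        if _hits_any(peak, pools[category]):
            return category
    return "intergenic"


def annotate_peaks(
    peaks: list[GenomicInterval],
    catalog: FeatureCatalog,
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
) -> tuple[list[str], Counter]:
    """Classify every peak; returns per-peak categories and category counts."""
    categories = [classify_peak(p, catalog, precedence) for p in peaks]
    return categories, Counter(categories)


@dataclass
class DirectTargetReport:
    """Counts and per-gene flags from the direct/indirect target split."""

    n_down_bound: int
    n_down: int
    n_up_bound: int
    n_up: int
    bound: dict[str, bool] = field(default_factory=dict)
    evidence: dict[str, str] = field(default_factory=dict)
    unmatched: list[str] = field(default_factory=list)

    @property
    def frac_down(self) -> float:
        return self.n_down_bound / self.n_down if self.n_down else float("nan")

    @property
    def frac_up(self) -> float:
        return self.n_up_bound / self.n_up if self.n_up else float("nan")


def direct_target_split(
    deg_down: list[str],
    deg_up: list[str],
    tf_peaks: list[GenomicInterval],
    catalog: FeatureCatalog,
    gene_assignments: dict[str, list[GenomicInterval]],
) -> DirectTargetReport:
    """Split differential genes into direct (TF-bound) and indirect targets.

    A gene shows TF binding iff at least one TF peak overlaps its
    regulatory region: promoter window, gene body (if any) and every
    stitched enhancer assigned to it. Genes absent from the catalog's gene
    table go to ``unmatched`` and are excluded from the denominators.
    ``evidence`` records which feature carried the first hit.
    """
    report = DirectTargetReport(0, 0, 0, 0)

    def gene_bound(gene: str) -> bool | None:
        if gene not in catalog.promoters:
            return None
        features = [("promoter", catalog.promoters[gene])]
        if gene in catalog.gene_bodies:
            features.append(("gene_body", catalog.gene_bodies[gene]))
        features.extend(
            ("assigned_enhancer", r) for r in gene_assignments.get(gene, [])
        )
        for label, feature in features:
            if any(p.overlaps(feature) for p in tf_peaks):
                report.evidence[gene] = label
                return True
        return False

    for gene in deg_down:
        hit = gene_bound(gene)
        if hit is None:
            report.unmatched.append(gene)
            continue
        report.n_down += 1
        report.n_down_bound += hit
        report.bound[gene] = hit
    for gene in deg_up:
        hit = gene_bound(gene)
        if hit is None:
            report.unmatched.append(gene)
            continue
        report.n_up += 1
        report.n_up_bound += hit
        report.bound[gene] = hit
    return report


def assignments_from_scored(
    scored: list[ScoredEnhancer],
) -> dict[str, list[GenomicInterval]]:
    """Map each gene to the stitched-enhancer regions assigned to it."""
    out: dict[str, list[GenomicInterval]] = {}
    for s in scored:
        if s.assigned_gene is not None:
            out.setdefault(s.assigned_gene, []).append(s.region)
    return out


def write_annotation(
    peaks: list[GenomicInterval],
    categories: list[str],
    path,
    header: str | None = None,
) -> None:
    """Annotated peaks as BED6+ TSV with a category column."""
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        fh.write("chrom\tstart\tend\tname\tscore\tstrand\tcategory\n")
        for i, (p, cat) in enumerate(zip(peaks, categories, strict=True)):
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i+1}\t0\t{p.strand}\t{cat}\n")


def write_direct_targets(
    report: DirectTargetReport,
    deg_down: list[str],
    deg_up: list[str],
    path,
    header: str | None = None,
) -> None:
    """Direct-target report as TSV: gene, direction, bound, evidence_feature."""
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        fh.write("gene\tdirection\tbound\tevidence_feature\n")
        for direction, genes in (("down", deg_down), ("up", deg_up)):
            for gene in genes:
                if gene in report.bound:
                    bound = int(report.bound[gene])
                    ev = report.evidence.get(gene, ".")
                    fh.write(f"{gene}\t{direction}\t{bound}\t{ev}\n")
                else:
                    fh.write(f"{gene}\t{direction}\tNA\tunmatched\n")
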