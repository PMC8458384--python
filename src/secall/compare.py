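"""Cross-sample SE-gene comparison, driver-correlation screen, histoscore.

Implements the three comparative analyses downstream of SE calling: the
Venn-style intersection of SE-associated gene sets across samples, the
per-gene Pearson correlation screen against a driver gene (two-sided
P value from the t distribution with n - 2 degrees of freedom, as is
standard for testing r = 0), and the immunohistochemistry histoscore
(intensity 0-3 times percent positively stained cells, with positivity
requiring staining in more than 1% of cells).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

HISTOSCORE_POSITIVITY_PERCENT = 1.0


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with unique gene names.

    Rows with missing values are dropped at ingest and recorded in
    ``dropped_genes`` rather than silently discarded.
    """

    data: pd.DataFrame
    dropped_genes: list[str] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a TSV with gene names in the first column, samples in the header."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene names in expression matrix: {dups}")
    dropped = df.index[df.isna().any(axis=1)].tolist()
    return ExpressionMatrix(df.dropna(axis=0), dropped_genes=dropped)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene",
                       float_format="%.6f")


# ---------------------------------------------------------------------------
# SE-gene set intersection (Venn report)
# ---------------------------------------------------------------------------

@dataclass
class IntersectionReport:
    """Shared/exclusive SE-gene counts across named samples."""

    set_names: list[str]
    shared: list[str]                      # genes in every set, sorted
    pairwise: dict[tuple[str, str], int]   # |A & B| per unordered pair
    exclusive: dict[str, list[str]]        # genes in exactly one set
    sizes: dict[str, int]


def shared_se_genes(gene_sets: dict[str, set[str]]) -> IntersectionReport:
    """Intersect >= 2 named gene sets; all outputs sorted for determinism."""
    if len(gene_sets) < 2:
        raise ValueError("need >= 2 gene sets to compare")
    names = list(gene_sets)
    shared = set.intersection(*(set(gene_sets[n]) for n in names))
    pairwise: dict[tuple[str, str], int] = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pairwise[(a, b)] = len(gene_sets[a] & gene_sets[b])
    exclusive = {}
    for name in names:
        others = set().union(
            *(gene_sets[o] for o in names if o != name)
        )
        exclusive[name] = sorted(gene_sets[name] - others)
    return IntersectionReport(
        set_names=names,
        shared=sorted(shared),
        pairwise=pairwise,
        exclusive=exclusive,
        sizes={n: len(gene_sets[n]) for n in names},
    )


def write_intersection_report(
    report: IntersectionReport, path: str | Path, header: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        fh.write("metric\tsets\tcount\tgenes\n")
        all_names = "+".join(report.set_names)
        fh.write(
            f"shared_all\t{all_names}\t{len(report.shared)}\t"
            f"{','.join(report.shared) or '.'}\n"
        )
        for (a, b), count in sorted(report.pairwise.items()):
            fh.write(f"shared_pair\t{a}+{b}\t{count}\t.\n")
        for name in report.set_names:
            excl = report.exclusive[name]
            fh.write(
                f"exclusive\t{name}\t{len(excl)}\t{','.join(excl) or '.'}\n"
            )
        for name in report.set_names:
            fh.write(f"size\t{name}\t{report.sizes[name]}\t.\n")


# ---------------------------------------------------------------------------
# Driver-correlation screen
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    gene: str
    r: float           # nan for zero-variance genes (undefined)
    t_stat: float
    p_value: float
    rank: int | None   # None for genes excluded from ranking


def correlate_with_driver(
    matrix: ExpressionMatrix,
    driver_gene: str,
    fdr: bool = False,
) -> list[CorrelationResult]:
    """Pearson-correlate every other gene with the driver gene.

    t = r * sqrt((n - 2) / (1 - r^2)); P is the two-sided tail of the
    Student t distribution with n - 2 df. |r| = 1 gives P reported at the
    smallest positive float rather than zero. Zero-variance genes have
    undefined r; they are reported with r = nan and excluded from ranking.
    Results are ranked descending by r. With ``fdr`` an additional
    Benjamini-Hochberg q value is attached to each result as ``q_value``.
    """
    if driver_gene not in matrix.data.index:
        raise KeyError(f"driver gene {driver_gene!r} not in matrix")
    n = matrix.n_samples
    if n < 3:
        raise ValueError(f"need >= 3 samples for correlation, got {n}")
    driver = matrix.data.loc[driver_gene].to_numpy(dtype=float)
    others = matrix.data.drop(index=driver_gene)
    X = others.to_numpy(dtype=float)
    dc = driver - driver.mean()
    d_ss = float(np.dot(dc, dc))
    if d_ss == 0.0:
        raise ValueError("driver gene has zero variance")
    Xc = X - X.mean(axis=1, keepdims=True)
    x_ss = np.einsum("ij,ij->i", Xc, Xc)
    cov = Xc @ dc
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(x_ss * d_ss)
    r = np.where(x_ss == 0.0, np.nan, np.clip(r, -1.0, 1.0))
    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isinf(t), np.nextafter(0.0, 1.0), p)
    p = np.maximum(p, np.nextafter(0.0, 1.0))

    results = [
        CorrelationResult(g, float(r[i]), float(t[i]),
                          float(p[i]) if not math.isnan(r[i]) else float("nan"),
                          None)
        for i, g in enumerate(others.index)
    ]
    defined = [res for res in results if not math.isnan(res.r)]
    defined.sort(key=lambda res: (-res.r, res.gene))
    for rank, res in enumerate(defined, start=1):
        res.rank = rank
    if fdr:
        from statsmodels.stats.multitest import multipletests
        pvals = np.array([res.p_value for res in defined])
        q = multipletests(pvals, method="fdr_bh")[1]
        for res, qv in zip(defined, q):
            res.q_value = float(qv)  # type: ignore[attr-defined]
    undefined = [res for res in results if math.isnan(res.r)]
    return defined + sorted(undefined, key=lambda res: res.gene)


def write_correlation_report(
    results: list[CorrelationResult], path: str | Path, header: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        has_q = any(hasattr(res, "q_value") for res in results)
        cols = ["gene", "r", "t", "p", "rank"] + (["q"] if has_q else [])
        fh.write("\t".join(cols) + "\n")
        for res in results:
            rank = res.rank if res.rank is not None else "NA"
            if math.isnan(res.r):
                row = [res.gene, "NA", "NA", "NA", "NA"]
            else:
                row = [res.gene, f"{res.r:.6f}", f"{res.t_stat:.6g}",
                       f"{res.p_value:.6g}", str(rank)]
            if has_q:
                qv = getattr(res, "q_value", None)
                row.append("NA" if qv is None else f"{qv:.6g}")
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Histoscore
# ---------------------------------------------------------------------------

def histoscore(intensity: int, percent_positive: float) -> float:
    """IHC histoscore: intensity (0-3) x percent positively stained cells.

    Staining present in <= 1% of cells does not count as positive, so such
    samples score 0. The score ranges over [0, 300].
    """
    if intensity not in (0, 1, 2, 3):
        raise ValueError(f"intensity must be in {{0,1,2,3}}, got {intensity}")
    if not 0 <= percent_positive <= 100:
        raise ValueError(
            f"percent_positive must be in [0, 100], got {percent_positive}"
        )
    if percent_positive <= HISTOSCORE_POSITIVITY_PERCENT:
        return 0.0
    return float(intensity * percent_positive)
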