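"""On-disk formats and coordinate conventions.

Every coordinate inside the package is 0-based half-open (BED-native).
WIG is 1-based/fixedStep; the shift by one happens only at the write/read
boundary in this module. Chromosome names are matched as exact strings —
there is no "chr" aliasing, so mixed naming in the inputs surfaces as an
error instead of silently producing empty overlaps.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator


class ParseError(ValueError):
    """A malformed record in an input file; message names file and line."""


# strand symbols accepted on input; the unicode minus shows up in
# spreadsheet-exported gene tables and is normalised to ASCII
_STRAND_ALIASES = {"+": "+", "-": "-", "−": "-", ".": "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic region, 0-based half-open, with optional strand.

    Parameters
    ----------
    chrom : str
        Chromosome name (non-empty, matched exactly).
    start : int
        0-based inclusive start.
    end : int
        0-based exclusive end; must exceed ``start``.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share at least one base pair."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def center(self) -> int:
        """Midpoint, floor((start + end) / 2)."""
        return (self.start + self.end) // 2


# Reads are plain stranded intervals; the alias documents intent at call
# sites that consume alignment footprints rather than generic regions.
ReadFootprint = GenomicInterval


class GenomeDefinition:
    """Ordered map of chromosome name to length in base pairs."""

    def __init__(self, lengths: dict[str, int] | Iterable[tuple[str, int]]):
        items = list(lengths.items()) if isinstance(lengths, dict) else list(lengths)
        seen: dict[str, int] = {}
        for name, length in items:
            if not name:
                raise ValueError("chromosome name must be non-empty")
            if name in seen:
                raise ValueError(f"duplicate chromosome {name!r}")
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
            seen[name] = int(length)
        self._lengths = seen

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __getitem__(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in genome") from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._lengths)

    def __len__(self) -> int:
        return len(self._lengths)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeDefinition):
            return NotImplemented
        return self._lengths == other._lengths

    def items(self) -> Iterable[tuple[str, int]]:
        return self._lengths.items()

    @property
    def total_length(self) -> int:
        return sum(self._lengths.values())

    def __repr__(self) -> str:
        return f"GenomeDefinition({self._lengths!r})"


@dataclass(frozen=True)
class GeneModel:
    """A gene with a transcript span; TSS/TES derive from strand.

    On ``+`` the TSS is ``txStart`` and the TES is ``txEnd - 1``; on ``-``
    the TSS is ``txEnd - 1`` and the TES is ``txStart`` (coordinates are
    0-based half-open, so ``txEnd - 1`` is the last transcribed base).
    """

    name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene name must be non-empty")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if self.tx_end <= self.tx_start:
            raise ValueError(
                f"txEnd must be > txStart, got [{self.tx_start}, {self.tx_end})"
            )

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def tes(self) -> int:
        return self.tx_end - 1 if self.strand == "+" else self.tx_start

    @property
    def length(self) -> int:
        return self.tx_end - self.tx_start


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals, in file order.

    Column 6, when present, is the strand; otherwise strand is ``.``.
    Lines starting with ``#``, ``track`` or ``browser`` are skipped.
    A malformed line (too few columns, non-integer coordinates,
    end <= start) raises :class:`ParseError` naming the line number.
    """
    path = Path(path)
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            strand = "."
            if len(fields) >= 6:
                strand = _STRAND_ALIASES.get(fields[5])
                if strand is None:
                    raise ParseError(
                        f"{path}:{lineno}: unknown strand {fields[5]!r}"
                    )
            try:
                out.append(GenomicInterval(fields[0], start, end, strand))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return out


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    names: Iterable[str] | None = None,
    header: str | None = None,
) -> None:
    """Write intervals as BED6 (name column defaults to ``.``, score 0)."""
    intervals = list(intervals)
    if names is None:
        names = ["."] * len(intervals)
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        for iv, name in zip(intervals, names, strict=True):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Gene table (flat 5-column TSV: name, chrom, strand, txStart, txEnd)
# ---------------------------------------------------------------------------

def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a refFlat-style gene table with a header row.

    Raises :class:`ParseError` on an unknown strand symbol or a duplicate
    gene name — duplicates would make gene assignment ambiguous.
    """
    path = Path(path)
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    if not lines:
        raise ParseError(f"{path}: empty gene table (header row required)")
    for lineno, raw in enumerate(lines[1:], start=2):
        line = raw.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 5:
            raise ParseError(f"{path}:{lineno}: expected 5 columns")
        name, chrom, strand_raw = fields[0], fields[1], fields[2]
        strand = _STRAND_ALIASES.get(strand_raw)
        if strand not in ("+", "-"):
            raise ParseError(f"{path}:{lineno}: unknown strand {strand_raw!r}")
        if name in seen:
            raise ParseError(f"{path}:{lineno}: duplicate gene name {name!r}")
        seen.add(name)
        try:
            genes.append(
                GeneModel(name, chrom, strand, int(fields[3]), int(fields[4]))
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tchrom\tstrand\ttxStart\ttxEnd\n")
        for g in genes:
            fh.write(f"{g.name}\t{g.chrom}\t{g.strand}\t{g.tx_start}\t{g.tx_end}\n")


# ---------------------------------------------------------------------------
# Genome definition TSV
# ---------------------------------------------------------------------------

def read_genome(path: str | Path) -> GenomeDefinition:
    """Read a two-column TSV (chromosome, length) into a genome definition."""
    pairs: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            try:
                pairs.append((fields[0], int(fields[1])))
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer length") from None
    return GenomeDefinition(pairs)


def write_genome(genome: GenomeDefinition, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.items():
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# fixedStep WIG
# ---------------------------------------------------------------------------

def write_wig(track, path: str | Path) -> None:
    """Write a 50-bp-binned signal track as fixedStep WIG.

    One block per chromosome: ``fixedStep chrom=<c> start=1 step=50 span=50``
    followed by one value per bin, printed with 4 decimal places. WIG is
    1-based, hence start=1 for the bin covering bases [0, 50).
    """
    bs = track.bin_size
    with open(path, "w") as fh:
        for chrom in track.genome:
            values = track.values[chrom]
            if len(values) == 0:
                continue
            fh.write(f"fixedStep chrom={chrom} start=1 step={bs} span={bs}\n")
            fh.write("\n".join(f"{v:.4f}" for v in values))
            fh.write("\n")


_FIXEDSTEP_RE = re.compile(
    r"^fixedStep\s+chrom=(\S+)\s+start=(\d+)\s+step=(\d+)\s+span=(\d+)\s*$"
)


def read_wig(path: str | Path, genome: GenomeDefinition | None = None):
    """Read a fixedStep WIG written by :func:`write_wig` back into a track.

    If ``genome`` is omitted, chromosome lengths are inferred as
    ``n_bins * bin_size``. Only start=1 blocks (whole-chromosome tracks,
    as this package writes them) are supported.
    """
    import numpy as np

    from .signal_track import SignalTrack

    path = Path(path)
    chrom_values: dict[str, list[float]] = {}
    current: list[float] | None = None
    bin_size: int | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("track"):
                continue
            m = _FIXEDSTEP_RE.match(line)
            if m:
                chrom, start, step, span = m.group(1), *map(int, m.group(2, 3, 4))
                if start != 1 or step != span:
                    raise ParseError(
                        f"{path}:{lineno}: only start=1 full-chromosome blocks supported"
                    )
                if bin_size is None:
                    bin_size = step
                elif bin_size != step:
                    raise ParseError(f"{path}:{lineno}: inconsistent step")
                current = chrom_values.setdefault(chrom, [])
            else:
                if current is None:
                    raise ParseError(f"{path}:{lineno}: value before block header")
                try:
                    current.append(float(line))
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: bad value {line!r}") from None
    if bin_size is None:
        bin_size = 50
    if genome is None:
        genome = GenomeDefinition(
            {c: len(v) * bin_size for c, v in chrom_values.items()}
        )
    values = {}
    for chrom in genome:
        n_bins = -(-genome[chrom] // bin_size)
        vec = np.zeros(n_bins, dtype=float)
        got = chrom_values.get(chrom, [])
        if len(got) > n_bins:
            raise ParseError(f"{path}: more bins than fit chromosome {chrom!r}")
        vec[: len(got)] = got
        values[chrom] = vec
    return SignalTrack(genome=genome, bin_size=bin_size, values=values,
                       total_reads=None)


# ---------------------------------------------------------------------------
# Plain gene lists (one symbol per line)
# ---------------------------------------------------------------------------

def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
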